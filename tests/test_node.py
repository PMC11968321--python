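"""Server-side dispatch flow: auth, views, subsets, audit completeness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from fedshield.client import payload_vector_lengths
from fedshield.errors import FedShieldError
from fedshield.node import (
    DataView,
    Node,
    SiteDataset,
    StatusMessage,
    UserAccount,
    _evaluate_predicate,
    hash_token,
)
from fedshield.parser import Arg, Request
from fedshield.settings import default_settings

from conftest import make_node, small_frame


def subset_req(predicate, target="S1", source="D"):
    return Request(
        user="a",
        function="subsetDS",
        kind="assign",
        args=(Arg("symbol", source), Arg("string", predicate, "long")),
        target=target,
    )


class TestAuthentication:
    def test_login_gives_empty_workspace(self, node):
        session = node.login("a", "t")
        assert session.workspace == {} and session.user == "a"

    def test_wrong_token_and_unknown_user_indistinguishable(self, node):
        with pytest.raises(FedShieldError) as e1:
            node.login("a", "wrong")
        with pytest.raises(FedShieldError) as e2:
            node.login("nobody", "t")
        assert e1.value.code == e2.value.code == "AUTH_FAILED"
        assert str(e1.value) == str(e2.value)

    def test_two_logins_have_independent_workspaces(self, node):
        s1, s2 = node.login("a", "t"), node.login("a", "t")
        node.dispatch(s1, subset_req("age > 0"))
        with pytest.raises(FedShieldError) as err:
            node.dispatch(s2, Request("a", "summaryDS", "aggregate", (Arg("symbol", "S1.age"),)))
        assert err.value.code == "UNKNOWN_SYMBOL"

    def test_foreign_session_rejected(self, node):
        other = make_node(small_frame(), site="elsewhere")
        foreign = other.login("a", "t")
        with pytest.raises(FedShieldError) as err:
            node.dispatch(foreign, subset_req("age > 0"))
        assert err.value.code == "SESSION_INVALID"


class TestDataViews:
    def test_projection_keeps_rows_and_permitted_columns(self):
        frame = small_frame(8)
        node = make_node(frame, permitted={"age", "bmi"})
        view = node.resolve_view(node.login("a", "t"), "D")
        assert list(view.columns) == ["age", "bmi"] and len(view) == 8

    def test_unpermitted_variable_denied(self):
        node = make_node(small_frame(), permitted={"age"})
        session = node.login("a", "t")
        with pytest.raises(FedShieldError) as err:
            node.dispatch(session, Request("a", "summaryDS", "aggregate", (Arg("symbol", "D.bmi"),)))
        assert err.value.code == "VARIABLE_DENIED"

    def test_no_view_on_dataset_denied(self):
        frame = small_frame()
        account = UserAccount("a", hash_token("t"), views=())
        node = Node("s1", [SiteDataset("D", frame)], [account], custodian_token="c")
        with pytest.raises(FedShieldError) as err:
            node.resolve_view(node.login("a", "t"), "D")
        assert err.value.code == "VIEW_DENIED"

    def test_snapshot_never_mutated_by_assigns(self, node, session):
        before = node.datasets["D"].table.copy()
        node.dispatch(session, subset_req("age > 0"))
        session.workspace["S1"]["age"] += 100.0
        pd.testing.assert_frame_equal(node.datasets["D"].table, before)


class TestSubsets:
    def test_small_subset_blocked_without_revealing_size(self, node, session):
        frame = node.datasets["D"].table
        cut = float(np.sort(frame["age"])[1])  # keeps 2 rows at most
        with pytest.raises(FedShieldError) as err:
            node.dispatch(session, subset_req(f"age < {cut + 0.001}"))
        assert err.value.code == "SUBSET_TOO_SMALL"
        assert not any(ch.isdigit() for ch in str(err.value))
        # the custodian-side log does record the size
        assert node.log.events_unsafe()[-1].metadata["subset_size"] == 2

    def test_boundary_subset_of_exactly_three_created(self, node, session):
        frame = node.datasets["D"].table
        cut = float(np.sort(frame["age"])[2] + 0.001)
        status = node.dispatch(session, subset_req(f"age < {cut!r}"))
        assert status == StatusMessage(True, "data.frame", True)
        assert len(session.workspace["S1"]) == 3

    def test_empty_subset_blocked(self, node, session):
        with pytest.raises(FedShieldError) as err:
            node.dispatch(session, subset_req("age > 100000"))
        assert err.value.code == "SUBSET_TOO_SMALL"


class TestDispatchContract:
    def test_assign_returns_status_without_values(self, node, session):
        req = Request("a", "asNumericDS", "assign", (Arg("symbol", "D.age"),), "num")
        status = node.dispatch(session, req)
        assert isinstance(status, StatusMessage) and status.object_class == "numeric"
        assert payload_vector_lengths(status) == set()

    def test_parser_rejection_is_logged(self, node, session):
        before = len(node.log)
        with pytest.raises(FedShieldError) as err:
            node.dispatch(session, Request("a", "setSeedDS", "assign", (Arg("number", 1),), "s"))
        assert err.value.code == "PARSE_REJECTED"
        assert len(node.log) == before + 1
        assert node.log.events_unsafe()[-1].outcome == "error:PARSE_REJECTED"

    def test_audit_completeness_across_outcomes(self, node, session):
        attempts = [
            subset_req("age > 0"),  # executed
            subset_req("age > 100000", target="S2"),  # blocked
            Request("a", "summaryDS", "aggregate", (Arg("symbol", "ghost"),)),  # error
            Request("a", "nopeDS", "aggregate", ()),  # parser
        ]
        before = len(node.log)
        for req in attempts:
            try:
                node.dispatch(session, req)
            except FedShieldError:
                pass
        assert len(node.log) == before + len(attempts)

    def test_stub_functions_not_executable_even_when_unblocked(self, node, session):
        req = Request("a", "repDS", "assign", (), "r")  # allowed under banana, stub
        with pytest.raises(FedShieldError) as err:
            node.dispatch(session, req)
        assert err.value.code == "NOT_IMPLEMENTED"

    @given(
        st.text(max_size=30),
        st.sampled_from(["assign", "aggregate", "junk"]),
        st.lists(
            st.sampled_from(
                [Arg("symbol", "D.age"), Arg("string", "x;y", "long"), Arg("number", float("nan")), Arg("vector", [1.0]), Arg("junk", None)]
            ),
            max_size=3,
        ),
    )
    @hyp_settings(max_examples=120, derandomize=True, deadline=None)
    def test_dispatch_is_total(self, function, kind, args):
        """Every structurally complete request yields a payload, a status or a
        typed error — never an unhandled exception."""
        node = make_node(small_frame())
        session = node.login("a", "t")
        req = Request("a", function, kind, tuple(args), "T" if kind == "assign" else None)
        try:
            node.dispatch(session, req)
        except FedShieldError:
            pass
        assert len(node.log) == 1


class TestPredicates:
    FRAME = pd.DataFrame({"x": [1.0, 2.0, 3.0, None], "g": ["a", "b", "a", "b"]})

    @pytest.mark.parametrize(
        "predicate,expected",
        [
            ("x > 1", [False, True, True, False]),
            ("x <= 2", [True, True, False, False]),
            ("x >= 1 & x < 3", [True, True, False, False]),
            ("x == 1 | x == 3", [True, False, True, False]),
            ("g == 'a'", [True, False, True, False]),
            ("g != 'a' & x < 99", [False, True, False, False]),
        ],
    )
    def test_evaluation(self, predicate, expected):
        assert _evaluate_predicate(self.FRAME, predicate).tolist() == expected

    def test_missing_values_never_match(self):
        assert not _evaluate_predicate(self.FRAME, "x < 100").tolist()[3]

    @pytest.mark.parametrize("bad", ["", "x >", "drop table", "x ~ 3", "y > 1 &"])
    def test_malformed_predicates_are_typed_errors(self, bad):
        with pytest.raises(FedShieldError):
            _evaluate_predicate(self.FRAME, bad)


class TestSettingsEnforcement:
    def test_invalid_site_settings_abort_node_start(self):
        bad = dataclasses.replace(default_settings(), glm_ratio=2.0)
        with pytest.raises(FedShieldError) as err:
            make_node(small_frame(), settings=bad)
        assert err.value.code == "CONFIG_ERROR"

    def test_profile_overrides_apply_only_when_stricter(self):
        frame = small_frame()
        account = UserAccount(
            "a",
            hash_token("t"),
            views=(DataView("D", frozenset(frame.columns)),),
            profile={"disclosure": {"nfilter.tab": 5, "nfilter.subset": 1}},
        )
        node = Node("s1", [SiteDataset("D", frame)], [account], custodian_token="c")
        s = node.login("a", "t").settings
        assert s.tab_threshold == 5  # stricter: applied
        assert s.subset_threshold == 3  # laxer: ignored

    def test_profile_privacy_level_only_tightens(self):
        frame = small_frame()
        mk = lambda level: Node(
            "s1",
            [SiteDataset("D", frame)],
            [
                UserAccount(
                    "a",
                    hash_token("t"),
                    views=(DataView("D", frozenset(frame.columns)),),
                    profile={"privacyControlLevel": level},
                )
            ],
            custodian_token="c",
        )
        assert mk("non-permissive").login("a", "t").settings.privacy_level == "non-permissive"
        assert mk("permissive").login("a", "t").settings.privacy_level == "banana"
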