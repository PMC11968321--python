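"""Client orchestration: all-or-nothing connect, pooling, settings isolation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fedshield.client import AggregateOutcome, SiteError, connect
from fedshield.errors import FedShieldError
from fedshield.fedstats import ContingencyTable
from fedshield.settings import default_settings

from conftest import make_node, small_frame


def three_nodes(sizes=(30, 40, 50), seed0=0, **kw):
    nodes = [
        make_node(small_frame(n, seed=seed0 + i), site=f"s{i + 1}", **kw)
        for i, n in enumerate(sizes)
    ]
    creds = [{"site": n.site, "user": "a", "token": "t"} for n in nodes]
    return nodes, creds


class TestConnect:
    def test_three_valid_credentials(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        assert conn.sites == ("s1", "s2", "s3")
        assert all(s.workspace == {} for s in conn.sessions.values())

    def test_one_bad_credential_aborts_naming_the_site(self):
        nodes, creds = three_nodes()
        creds[1]["token"] = "wrong"
        with pytest.raises(FedShieldError) as err:
            connect(nodes, creds)
        assert err.value.code == "AUTH_FAILED" and err.value.site == "s2"

    def test_duplicate_site_names_rejected(self):
        nodes, creds = three_nodes()
        nodes[1].site = "s1"
        with pytest.raises(FedShieldError) as err:
            connect(nodes, creds)
        assert err.value.code == "CONFIG_ERROR"


class TestAggregateAll:
    def test_summary_pools_to_concatenation_oracle(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        out = conn.aggregate_all(conn.summary_request("D.age"))
        everything = np.concatenate([n.datasets["D"].table["age"].to_numpy() for n in nodes])
        assert out.pooled["mean"] == pytest.approx(everything.mean(), abs=1e-12)
        assert out.pooled["variance"] == pytest.approx(everything.var(ddof=1), abs=1e-12)

    def test_tables_pool_and_match_row_totals(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        out = conn.aggregate_all(conn.table_request("D.group"))
        assert isinstance(out.pooled, ContingencyTable)
        assert out.pooled.counts.sum() == sum(len(n.datasets["D"].table) for n in nodes)

    def test_one_suppressed_site_blocks_pooling(self):
        nodes, creds = three_nodes()
        # force one site's table under the threshold: a lone 'c' row
        frame = nodes[1].datasets["D"].table
        frame.loc[frame.index[-1], "group"] = "c"
        conn = connect(nodes, creds)
        out = conn.aggregate_all(conn.table_request("D.group"))
        assert out.per_site["s2"].suppressed
        assert out.pooled is None

    def test_per_site_errors_reported_with_catalogue_message(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        out = conn.aggregate_all(conn.summary_request("D.ghost"))
        assert all(isinstance(p, SiteError) for p in out.per_site.values())
        assert {p.code for p in out.per_site.values()} == {"UNKNOWN_SYMBOL"}
        assert out.pooled is None

    def test_site_order_invariance_of_pooled_results(self):
        nodes, creds = three_nodes()
        forward = connect(nodes, creds).aggregate_all
        backward = connect(nodes[::-1], creds[::-1]).aggregate_all
        a = forward(connect(nodes, creds).summary_request("D.bmi")).pooled
        b = backward(connect(nodes, creds).summary_request("D.bmi")).pooled
        assert a["mean"] == pytest.approx(b["mean"], abs=1e-12)
        assert a["variance"] == pytest.approx(b["variance"], abs=1e-12)


class TestAssignAll:
    def test_subset_failure_is_per_site(self):
        # site 2 gets young ages only, so 'age > 60' keeps ~0 rows there
        nodes, creds = three_nodes()
        nodes[1].datasets["D"].table["age"] = 20.0
        conn = connect(nodes, creds)
        out = conn.assign_all(conn.subset_request("D", "age > 45", "S1"))
        assert out["s1"].ok and out["s3"].ok
        assert isinstance(out["s2"], SiteError) and out["s2"].code == "SUBSET_TOO_SMALL"

    def test_unknown_source_uniform_error(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        out = conn.assign_all(conn.subset_request("ghost", "age > 45", "S1"))
        assert {p.code for p in out.values()} == {"UNKNOWN_SYMBOL"}

    def test_kind_mismatch_rejected_client_side(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        with pytest.raises(FedShieldError):
            conn.assign_all(conn.summary_request("D.age"))


class TestFederatedGlmThroughDispatch:
    def test_model_dimension_blocked_at_the_small_site(self):
        """p = 5 against a site of N = 12 exceeds 0.33 x N and aborts the fit."""
        frame = small_frame(12)
        for extra in ("x1", "x2", "x3"):
            frame[extra] = np.arange(12.0) * (1 + hash(extra) % 5)
        node = make_node(frame)
        conn = connect([node], [{"site": "s1", "user": "a", "token": "t"}])
        with pytest.raises(FedShieldError) as err:
            conn.glm("D", "bmi ~ age + x1 + x2 + x3", "gaussian")
        assert err.value.code == "GLM_DIM_BLOCKED"
        # the analyst-facing message names no sample size
        assert not any(ch.isdigit() for ch in str(err.value))

    def test_three_site_fit_matches_single_concatenated_site(self):
        frames = [small_frame(n, seed=i) for i, n in enumerate((25, 30, 35))]
        nodes = [make_node(f, site=f"s{i + 1}") for i, f in enumerate(frames)]
        creds = [{"site": n.site, "user": "a", "token": "t"} for n in nodes]
        fed = connect(nodes, creds).glm("D", "bmi ~ age", "gaussian")
        big = make_node(pd.concat(frames, ignore_index=True), site="one")
        single = connect([big], [{"site": "one", "user": "a", "token": "t"}]).glm(
            "D", "bmi ~ age", "gaussian"
        )
        np.testing.assert_allclose(fed.beta, single.beta, atol=1e-10)
        np.testing.assert_allclose(fed.se, single.se, atol=1e-10)


class TestShowSettings:
    def test_default_nodes_report_defaults(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        assert all(s == default_settings() for s in conn.show_settings().values())

    def test_custodian_override_visible(self):
        custom = dataclasses.replace(default_settings(), tab_threshold=5)
        nodes, creds = three_nodes(settings=custom)
        conn = connect(nodes, creds)
        assert all(s.tab_threshold == 5 for s in conn.show_settings().values())

    def test_returned_copies_cannot_change_node_behaviour(self):
        nodes, creds = three_nodes()
        conn = connect(nodes, creds)
        shown = conn.show_settings()["s1"]
        with pytest.raises(dataclasses.FrozenInstanceError):
            shown.tab_threshold = 1
        # node still enforces its own threshold after the attempt
        frame = nodes[0].datasets["D"].table
        frame.loc[frame.index[-1], "group"] = "rare"
        out = conn.aggregate_all(conn.table_request("D.group"))
        assert out.per_site["s1"].suppressed
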