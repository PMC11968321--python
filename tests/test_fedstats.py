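"""Aggregate statistics and the federated GLM.

The federated fit is checked against two independent oracles: closed-form
least squares for the gaussian family and statsmodels' pooled IRLS on the
concatenated data for all families.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fedshield import fedstats
from fedshield.client import payload_vector_lengths
from fedshield.errors import FedShieldError
from fedshield.fedstats import (
    ContingencyTable,
    federated_glm,
    glm_share,
    parse_formula,
    pool_summaries,
    pool_tables,
    site_contingency,
    site_summary,
)
from fedshield.settings import default_settings

S = default_settings()


class TestContingency:
    def test_one_dim_counts_returned(self):
        frame = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 6})
        t = site_contingency(frame, ["g"], S)
        assert not t.suppressed
        assert dict(zip(t.levels[0], t.counts)) == {"a": 4, "b": 6}

    def test_rare_cell_suppresses_whole_table(self):
        frame = pd.DataFrame(
            {"g": ["a"] * 5 + ["b"] * 5, "h": ["x"] * 4 + ["y"] + ["x"] * 5}
        )
        t = site_contingency(frame, ["g", "h"], S)
        assert t.suppressed and t.counts is None

    def test_custodian_threshold_one_disables_suppression(self):
        frame = pd.DataFrame(
            {"g": ["a"] * 5 + ["b"] * 5, "h": ["x"] * 4 + ["y"] + ["x"] * 5}
        )
        s1 = dataclasses.replace(S, tab_threshold=1)
        t = site_contingency(frame, ["g", "h"], s1)
        assert not t.suppressed and t.counts.sum() == 10

    def test_counts_conserve_nonmissing_rows(self):
        frame = pd.DataFrame({"g": ["a", "b", None, "a", "b", "a", "b", "a"]})
        t = site_contingency(frame, ["g"], dataclasses.replace(S, tab_threshold=1))
        assert t.counts.sum() == 7 and t.n_missing == 1

    def test_pooling_sums_counts(self):
        mk = lambda counts: ContingencyTable(("g",), (("a", "b"),), np.array(counts), False)
        pooled = pool_tables([mk([4, 6]), mk([3, 9])])
        assert pooled.counts.tolist() == [7, 15]

    def test_single_site_pool_is_identity(self):
        t = ContingencyTable(("g",), (("a", "b"),), np.array([4, 6]), False)
        assert pool_tables([t]).counts.tolist() == [4, 6]

    def test_any_suppressed_input_blocks_pooling(self):
        ok = ContingencyTable(("g",), (("a", "b"),), np.array([4, 6]), False)
        bad = ContingencyTable(("g",), (("a", "b"),), None, True)
        with pytest.raises(FedShieldError) as err:
            pool_tables([ok, bad])
        assert err.value.code == "POOL_BLOCKED"

    def test_level_mismatch_blocks_pooling(self):
        a = ContingencyTable(("g",), (("a", "b"),), np.array([4, 6]), False)
        b = ContingencyTable(("g",), (("a", "c"),), np.array([4, 6]), False)
        with pytest.raises(FedShieldError) as err:
            pool_tables([a, b])
        assert err.value.code == "POOL_MISMATCH"


class TestSummaries:
    def test_pooled_mean_and_variance_match_concatenation(self):
        a = site_summary(pd.Series([1.0, 2.0, 3.0]), S)
        b = site_summary(pd.Series([4.0, 5.0, 6.0]), S)
        pooled = pool_summaries([a, b])
        assert pooled["mean"] == pytest.approx(3.5)
        assert pooled["variance"] == pytest.approx(3.5)
        assert pooled["N"] == 6

    def test_pooled_equals_numpy_on_random_partitions(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 3, 200)
        shares = [site_summary(pd.Series(part), S) for part in np.array_split(x, 3)]
        pooled = pool_summaries(shares)
        assert pooled["mean"] == pytest.approx(x.mean(), abs=1e-12)
        assert pooled["variance"] == pytest.approx(x.var(ddof=1), abs=1e-12)

    def test_too_few_rows_refused(self):
        with pytest.raises(FedShieldError) as err:
            site_summary(pd.Series([1.0, 2.0]), S)
        assert err.value.code == "SUMMARY_TOO_SMALL"

    def test_missing_values_dropped_and_counted(self):
        share = site_summary(pd.Series([1.0, None, 2.0, 3.0]), S)
        assert share.N == 3 and share.n_missing == 1


class TestGlmShare:
    X = np.column_stack([np.ones(4), np.array([0.0, 1.0, 2.0, 3.0])])
    y = np.array([0.0, 0.0, 1.0, 1.0])

    def test_binomial_at_beta_zero(self):
        sh = glm_share(self.X, self.y, np.zeros(2), "binomial")
        np.testing.assert_allclose(sh.U, self.X.T @ (self.y - 0.5))
        np.testing.assert_allclose(sh.I, 0.25 * self.X.T @ self.X)

    def test_gaussian_information_ignores_beta(self):
        a = glm_share(self.X, self.y, np.zeros(2), "gaussian")
        b = glm_share(self.X, self.y, np.array([3.0, -2.0]), "gaussian")
        np.testing.assert_allclose(a.I, b.I)
        np.testing.assert_allclose(a.I, self.X.T @ self.X)

    def test_poisson_intercept_only_hand_computation(self):
        X = np.ones((4, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sh = glm_share(X, y, np.zeros(1), "poisson")
        assert sh.U[0] == pytest.approx(6.0)  # sum(y - 1)
        assert sh.I[0, 0] == pytest.approx(4.0)
        assert sh.N == 4

    def test_information_symmetric_psd(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.integers(0, 2, 30).astype(float)
        sh = glm_share(X, y, rng.normal(size=3), "binomial")
        np.testing.assert_allclose(sh.I, sh.I.T)
        assert np.linalg.eigvalsh(sh.I).min() >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(FedShieldError):
            glm_share(self.X, self.y[:3], np.zeros(2), "binomial")


def _sites_xy(seed, n_sites=3, n_total=240, family="binomial"):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n_total), rng.normal(size=n_total), rng.binomial(1, 0.4, n_total)])
    eta = X @ np.array([0.2, 0.7, -0.4])
    if family == "gaussian":
        y = eta + rng.normal(0, 1.1, n_total)
    elif family == "binomial":
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    else:
        y = rng.poisson(np.exp(eta * 0.5)).astype(float)
    cuts = np.array_split(np.arange(n_total), n_sites)
    return [(X[idx], y[idx]) for idx in cuts], X, y


def _share_fn(parts, family):
    return lambda beta: [glm_share(X, y, beta, family) for X, y in parts]


class TestFederatedGlm:
    def test_single_site_gaussian_equals_least_squares(self):
        parts, X, y = _sites_xy(1, n_sites=1, family="gaussian")
        res = federated_glm(_share_fn(parts, "gaussian"), 3, "gaussian")
        beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta_ls, atol=1e-10)

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_matches_pooled_statsmodels(self, family):
        sm = pytest.importorskip("statsmodels.api")
        fam = {
            "gaussian": sm.families.Gaussian(),
            "binomial": sm.families.Binomial(),
            "poisson": sm.families.Poisson(),
        }[family]
        parts, X, y = _sites_xy(3, family=family)
        res = federated_glm(_share_fn(parts, family), 3, family)
        fit = sm.GLM(y, X, family=fam).fit()
        assert np.abs(res.beta - fit.params).max() < 1e-6
        assert np.abs(res.se - fit.bse).max() < 1e-6
        assert res.converged

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_partition_invariance(self, family):
        results = []
        for n_sites in (1, 2, 5):
            parts, _, _ = _sites_xy(7, n_sites=n_sites, n_total=300, family=family)
            results.append(federated_glm(_share_fn(parts, family), 3, family))
        for other in results[1:]:
            assert np.abs(results[0].beta - other.beta).max() < 1e-8
            assert np.abs(results[0].se - other.se).max() < 1e-8

    def test_singular_information_is_typed(self):
        X = np.column_stack([np.ones(20), np.ones(20)])  # collinear
        y = np.zeros(20)
        with pytest.raises(FedShieldError) as err:
            federated_glm(_share_fn([(X, y)], "gaussian"), 2, "gaussian")
        assert err.value.code == "SINGULAR_INFORMATION"

    def test_result_carries_no_observation_length_vector(self):
        parts, X, y = _sites_xy(9, family="binomial")
        res = federated_glm(_share_fn(parts, "binomial"), 3, "binomial")
        lengths = payload_vector_lengths(res)
        assert res.N_total == len(y)
        assert len(y) not in lengths and not any(len(part[1]) in lengths for part in parts)


class TestModelSpec:
    def test_formula_parsing(self):
        m = parse_formula("case ~ age + smoker", "binomial")
        assert m.outcome == "case" and m.covariates == ("age", "smoker") and m.p == 3

    def test_outcome_cannot_be_covariate(self):
        with pytest.raises(FedShieldError):
            parse_formula("y ~ y + x", "gaussian")

    @pytest.mark.parametrize("bad", ["y x", "~ x", "y ~ x", " ~ "])
    def test_malformed_formula_or_family(self, bad):
        if bad == "y ~ x":
            with pytest.raises(FedShieldError):
                parse_formula(bad, "gamma")  # unknown family
        else:
            with pytest.raises(FedShieldError):
                parse_formula(bad, "gaussian")
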