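"""Aggregate statistics and the federated generalized linear model.

The federated GLM exploits the fact that for a GLM with canonical link the
Newton/IRLS update depends on the data only through the score vector
U = X'(y − μ) and the expected information I = X'WX.  Each site computes
(U, I, deviance, N) at the current coefficient vector; the client sums them
across sites and updates β ← β + (ΣI)⁻¹(ΣU).  Because the summed quantities
are exactly those of the concatenated data, the federated fit is numerically
identical to fitting the physically pooled dataset, while each site only ever
releases p numbers and a p×p matrix.

Supported families (canonical links): gaussian/identity, binomial/logit,
poisson/log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import FedShieldError
from .filters import check_levels, check_table
from .settings import DisclosureSettings

__all__ = [
    "ContingencyTable",
    "GlmResult",
    "GlmShare",
    "ModelSpec",
    "SummaryShare",
    "federated_glm",
    "glm_share",
    "parse_formula",
    "pool_summaries",
    "pool_tables",
    "site_contingency",
    "site_summary",
]

FAMILIES = ("gaussian", "binomial", "poisson")


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """A 1- to 3-dimensional cross-tabulation, possibly suppressed.

    When ``suppressed`` is True the counts are withheld entirely: no field of
    a client-bound payload may carry them.
    """

    variables: tuple[str, ...]
    levels: tuple[tuple[str, ...], ...]
    counts: np.ndarray | None
    suppressed: bool
    n_missing: int = 0

    @property
    def total(self) -> int:
        if self.counts is None:
            raise FedShieldError("TABLE_SUPPRESSED")
        return int(self.counts.sum())


def site_contingency(
    frame: pd.DataFrame, variables: Sequence[str], s: DisclosureSettings
) -> ContingencyTable:
    """Cross-tabulate complete cases of up to three categorical variables.

    The level-density filters run per variable first; the cell-count filter
    then decides suppression.  A suppressed table is still a successful
    return — it carries the flag and nothing else.
    """
    variables = tuple(variables)
    if not 1 <= len(variables) <= 3:
        raise FedShieldError("SEMANTIC_ERROR")
    for v in variables:
        if v not in frame.columns:
            raise FedShieldError("UNKNOWN_SYMBOL")
    sub = frame.loc[:, list(variables)]
    n_missing = int(sub.isna().any(axis=1).sum())
    complete = sub.dropna()
    level_sets = []
    for v in variables:
        lv = tuple(sorted(map(str, complete[v].unique())))
        decision = check_levels(len(lv), max(len(frame), 1), s)
        if not decision.allowed:
            raise FedShieldError("LEVELS_BLOCKED")
        level_sets.append(lv)

    shape = tuple(len(lv) for lv in level_sets)
    counts = np.zeros(shape, dtype=np.int64)
    index = [{lab: i for i, lab in enumerate(lv)} for lv in level_sets]
    for row in complete.itertuples(index=False):
        pos = tuple(index[d][str(val)] for d, val in enumerate(row))
        counts[pos] += 1

    decision = check_table(counts, s)
    if not decision.allowed:
        return ContingencyTable(variables, tuple(level_sets), None, True, n_missing)
    return ContingencyTable(variables, tuple(level_sets), counts, False, n_missing)


def pool_tables(tables: Sequence[ContingencyTable]) -> ContingencyTable:
    """Element-wise sum of structurally identical site tables.

    Any suppressed input blocks pooling entirely: pooling the remaining sites
    would let an analyst recover the suppressed site's counts by subtracting
    from a later full pool (a difference attack at the site level).
    """
    if not tables:
        raise FedShieldError("POOL_MISMATCH")
    first = tables[0]
    if any(t.suppressed for t in tables):
        raise FedShieldError("POOL_BLOCKED")
    for t in tables[1:]:
        if t.variables != first.variables or t.levels != first.levels:
            raise FedShieldError("POOL_MISMATCH")
    counts = np.sum([t.counts for t in tables], axis=0)
    return ContingencyTable(
        first.variables,
        first.levels,
        counts,
        False,
        int(sum(t.n_missing for t in tables)),
    )


# ---------------------------------------------------------------------------
# univariate summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryShare:
    """Sufficient statistics for a pooled mean/variance: N, Σx, Σx²."""

    N: int
    sum: float
    sum_sq: float
    n_missing: int = 0


def site_summary(values: pd.Series, s: DisclosureSettings) -> SummaryShare:
    """Per-site share for a numeric variable, complete cases only.

    A variable with fewer non-missing rows than the subset threshold is
    treated like a small subset and refused.
    """
    x = pd.to_numeric(values, errors="coerce")
    n_missing = int(x.isna().sum())
    x = x.dropna().to_numpy(dtype=float)
    if len(x) < s.subset_threshold:
        raise FedShieldError("SUMMARY_TOO_SMALL")
    return SummaryShare(N=len(x), sum=float(x.sum()), sum_sq=float((x**2).sum()), n_missing=n_missing)


def pool_summaries(shares: Sequence[SummaryShare]) -> dict:
    """Pooled mean and variance from per-site sufficient statistics.

    variance = (Σx² − (Σx)²/N) / (N − 1), the one-pass identity on the
    combined sums; identical to the variance of the concatenated values.
    """
    if not shares:
        raise FedShieldError("POOL_MISMATCH")
    n = int(sum(sh.N for sh in shares))
    total = float(sum(sh.sum for sh in shares))
    total_sq = float(sum(sh.sum_sq for sh in shares))
    mean = total / n
    variance = (total_sq - total**2 / n) / (n - 1) if n > 1 else float("nan")
    return {
        "mean": mean,
        "variance": variance,
        "N": n,
        "n_missing": int(sum(sh.n_missing for sh in shares)),
    }


# ---------------------------------------------------------------------------
# federated GLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A GLM specification: outcome ~ covariates, canonical link per family."""

    outcome: str
    covariates: tuple[str, ...]
    family: str
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FedShieldError("SEMANTIC_ERROR")
        if self.outcome in self.covariates:
            raise FedShieldError("SEMANTIC_ERROR")

    @property
    def p(self) -> int:
        return len(self.covariates) + (1 if self.intercept else 0)


def parse_formula(formula: str, family: str, intercept: bool = True) -> ModelSpec:
    """Parse ``"outcome ~ cov1 + cov2"`` (no interactions or transforms)."""
    if "~" not in formula:
        raise FedShieldError("SEMANTIC_ERROR")
    lhs, rhs = formula.split("~", 1)
    outcome = lhs.strip()
    covariates = tuple(t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1")
    if not outcome:
        raise FedShieldError("SEMANTIC_ERROR")
    return ModelSpec(outcome=outcome, covariates=covariates, family=family, intercept=intercept)


@dataclass(frozen=True)
class GlmShare:
    """One site's contribution at the current β: score, information, deviance."""

    U: np.ndarray
    I: np.ndarray
    deviance: float
    N: int


def _mu_and_weights(eta: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
    if family == "gaussian":
        return eta, np.ones_like(eta)
    if family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        return mu, mu * (1.0 - mu)
    if family == "poisson":
        mu = np.exp(eta)
        return mu, mu
    raise FedShieldError("SEMANTIC_ERROR")


def _deviance(y: np.ndarray, mu: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.sum((y - mu) ** 2))
    if family == "binomial":
        eps = np.finfo(float).tiny
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(np.maximum(y, eps) / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log(np.maximum(1 - y, eps) / (1 - mu)), 0.0)
        return float(2.0 * np.sum(t1 + t2))
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(t - (y - mu)))
    raise FedShieldError("SEMANTIC_ERROR")


def glm_share(X: np.ndarray, y: np.ndarray, beta: np.ndarray, family: str) -> GlmShare:
    """Compute one site's (U, I, deviance, N) at coefficient vector β.

    With η = Xβ and canonical weights w (1, μ(1−μ), μ): U = X'(y − μ) and
    I = X' diag(w) X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],) or beta.shape != (X.shape[1],):
        raise FedShieldError("SEMANTIC_ERROR")
    eta = X @ beta
    mu, w = _mu_and_weights(eta, family)
    U = X.T @ (y - mu)
    info = X.T @ (X * w[:, None])
    return GlmShare(U=U, I=info, deviance=_deviance(y, mu, family), N=len(y))


@dataclass(frozen=True)
class GlmResult:
    """Pooled fit.  Carries coefficients and uncertainty only — no fitted
    values, residuals or linear predictors ever appear here."""

    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    deviance: float
    N_total: int
    iterations: int
    converged: bool
    family: str
    terms: tuple[str, ...]
    deviance_trace: tuple[float, ...] = ()


def federated_glm(
    share_fn: Callable[[np.ndarray], Sequence[GlmShare]],
    p: int,
    family: str,
    terms: tuple[str, ...] = (),
    tol: float = 1e-8,
    max_iter: int = 25,
) -> GlmResult:
    """Drive the distributed IRLS loop through ``share_fn``.

    ``share_fn(beta)`` must return one :class:`GlmShare` per site evaluated at
    β.  Iteration starts at β = 0 and stops when the relative change in the
    total deviance drops below ``tol``.  The coefficient covariance is the
    inverse pooled information, scaled for the gaussian family by the
    dispersion estimate deviance/(N − p) so that standard errors agree with a
    pooled ordinary fit.
    """
    beta = np.zeros(p)
    deviance_prev = np.inf
    deviance = np.inf
    trace: list[float] = []
    converged = False
    iterations = 0
    info_total = np.zeros((p, p))
    n_total = 0

    for iterations in range(1, max_iter + 1):
        shares = list(share_fn(beta))
        if not shares:
            raise FedShieldError("SEMANTIC_ERROR")
        score_total = np.sum([sh.U for sh in shares], axis=0)
        info_total = np.sum([sh.I for sh in shares], axis=0)
        deviance = float(sum(sh.deviance for sh in shares))
        n_total = int(sum(sh.N for sh in shares))
        trace.append(deviance)
        if np.isfinite(deviance_prev):
            if abs(deviance - deviance_prev) / (abs(deviance_prev) + 0.1) < tol:
                converged = True
                break
        deviance_prev = deviance
        try:
            step = np.linalg.solve(info_total, score_total)
        except np.linalg.LinAlgError:
            raise FedShieldError("SINGULAR_INFORMATION") from None
        if not np.all(np.isfinite(step)):
            raise FedShieldError("SINGULAR_INFORMATION")
        beta = beta + step

    try:
        vcov = np.linalg.inv(info_total)
    except np.linalg.LinAlgError:
        raise FedShieldError("SINGULAR_INFORMATION") from None
    if family == "gaussian" and n_total > p:
        vcov = vcov * (deviance / (n_total - p))
    se = np.sqrt(np.diag(vcov))
    return GlmResult(
        beta=beta,
        se=se,
        vcov=vcov,
        deviance=deviance,
        N_total=n_total,
        iterations=iterations,
        converged=converged,
        family=family,
        terms=tuple(terms),
        deviance_trace=tuple(trace),
    )
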