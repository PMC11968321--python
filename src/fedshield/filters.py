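"""Pure disclosure-filter decision functions.

Each check maps an input summary (cell counts, subset size, model dimension,
...) plus the active :class:`~fedshield.settings.DisclosureSettings` to a
:class:`FilterDecision`.  The functions are stateless and total; boundary
comparisons on fractional thresholds use a small tolerance resolved in favour
of blocking (fail safe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .settings import DisclosureSettings

__all__ = [
    "FilterDecision",
    "check_table",
    "check_subset_size",
    "check_glm_dimension",
    "check_levels",
    "check_knn",
    "check_noise_fraction",
]

#: Tolerance for float-boundary comparisons such as p vs glm_ratio * N.
_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of one disclosure check.

    ``rule`` names the triggering parameter when blocked (empty when allowed);
    ``detail`` is a machine-readable reason intended for the custodian-side
    audit log only — it may reference exact sizes and must never be surfaced
    to the analyst.
    """

    allowed: bool
    rule: str = ""
    detail: str = ""

    def __post_init__(self) -> None:
        if self.allowed != (self.rule == ""):
            raise ValueError("allowed decisions carry no rule; blocked ones must")


_ALLOW = FilterDecision(True)


def check_table(counts, s: DisclosureSettings) -> FilterDecision:
    """Cell-suppression rule for contingency tables (``nfilter.tab``).

    Blocks when any *non-empty* cell holds fewer than ``tab_threshold``
    observations.  Empty (zero) cells never trigger: a zero reveals only the
    absence of a category combination.  Tables of more than 3 dimensions are
    outside the table aggregate's scope and are rejected.
    """
    arr = np.asarray(counts)
    if arr.ndim < 1 or arr.ndim > 3:
        raise ValueError(f"contingency tables are 1- to 3-dimensional, got ndim={arr.ndim}")
    if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer)):
        raise ValueError("cell counts must be non-negative integers")
    nonempty = arr[arr > 0]
    if nonempty.size and int(nonempty.min()) < s.tab_threshold:
        return FilterDecision(
            False, "nfilter.tab", f"min non-empty cell {int(nonempty.min())} < {s.tab_threshold}"
        )
    return _ALLOW


def check_subset_size(n: int, s: DisclosureSettings) -> FilterDecision:
    """Minimum-rows rule for subset creation (``nfilter.subset``)."""
    if n < 0:
        raise ValueError("subset size must be non-negative")
    if n < s.subset_threshold:
        return FilterDecision(False, "nfilter.subset", f"subset rows {n} < {s.subset_threshold}")
    return _ALLOW


def check_glm_dimension(p: int, n_obs: int, s: DisclosureSettings) -> FilterDecision:
    """Model-dimension rule (``nfilter.glm``): at most glm_ratio * N parameters.

    Blocks when ``p > glm_ratio * N``; a p exactly on the (float) boundary is
    treated as blocked within a 1e-12 tolerance, erring toward protection.
    """
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    if n_obs < 1:
        raise ValueError("sample size must be >= 1")
    limit = s.glm_ratio * n_obs
    if p > limit - _BOUNDARY_TOL:
        return FilterDecision(
            False, "nfilter.glm", f"parameters {p} > {s.glm_ratio} x N={n_obs} ({limit:.6g})"
        )
    return _ALLOW


def check_levels(n_levels: int, n_obs: int, s: DisclosureSettings) -> FilterDecision:
    """Unique-levels rules (``nfilter.levels.density`` and ``.max``).

    Both caps guard the same operation; exceeding either blocks the return of
    the level set.
    """
    if n_levels < 0:
        raise ValueError("level count must be non-negative")
    if n_obs < 1:
        raise ValueError("vector length must be >= 1")
    if n_levels > s.levels_max:
        return FilterDecision(
            False, "nfilter.levels.max", f"levels {n_levels} > {s.levels_max}"
        )
    # same fail-safe boundary convention as the model-dimension check
    limit = s.levels_density * n_obs
    if n_levels > limit - _BOUNDARY_TOL:
        return FilterDecision(
            False,
            "nfilter.levels.density",
            f"levels {n_levels} > {s.levels_density} x N={n_obs} ({limit:.6g})",
        )
    return _ALLOW


def check_knn(k: int, n_points: int, s: DisclosureSettings) -> FilterDecision:
    """Neighbourhood-size rule for k-NN centroid obfuscation (``nfilter.kNN``).

    k below the custodian minimum is blocked; k larger than the point count is
    an infeasible neighbourhood and rejected as well.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if n_points < 1:
        raise ValueError("point count must be >= 1")
    if k < s.knn_min:
        return FilterDecision(False, "nfilter.kNN", f"k={k} < {s.knn_min}")
    if k > n_points:
        return FilterDecision(False, "nfilter.kNN", f"k={k} > n={n_points} (infeasible)")
    return _ALLOW


def check_noise_fraction(fraction: float, s: DisclosureSettings) -> FilterDecision:
    """Minimum-noise rule for Gaussian-noise obfuscation (``nfilter.noise``)."""
    if not fraction > 0:
        raise ValueError("noise fraction must be positive")
    if fraction < s.noise_min_fraction - _BOUNDARY_TOL:
        return FilterDecision(
            False, "nfilter.noise", f"fraction {fraction} < {s.noise_min_fraction}"
        )
    return _ALLOW
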