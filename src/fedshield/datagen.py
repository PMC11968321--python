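"""Synthetic multi-site data with known generative parameters.

Emulates a horizontally partitioned epidemiological study: each site draws
the same covariate distributions and the outcome follows one shared GLM, with
optional per-site intercept shifts as the only between-site heterogeneity.
Because the generative coefficients are known, the same datasets support both
parameter-recovery checks and the federated-versus-pooled equivalence tests.

Per-site RNG streams are split from the master seed, so adding a site never
perturbs the data of existing sites.

Also houses the snapshot-preparation utilities: keyed pseudonymization of
direct identifiers (linkage kept separately) and date coarsening to month or
year granularity.
"""

from __future__ import annotations

import datetime
import hmac
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FedShieldError
from .node import SiteDataset

__all__ = [
    "Covariate",
    "Outcome",
    "SyntheticSpec",
    "coarsen_date",
    "default_demo_spec",
    "generate_multisite",
    "pseudonymize",
    "write_site_csvs",
]


@dataclass(frozen=True)
class Covariate:
    """One covariate: ``normal(mu, sd)``, ``bernoulli(p)`` or
    ``categorical(levels, probs)``."""

    name: str
    kind: str
    params: Mapping

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "bernoulli", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            probs = list(self.params["probs"])
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("categorical probs must lie in [0,1] and sum to 1")
            if len(probs) != len(list(self.params["levels"])):
                raise ValueError("levels and probs must align")
        if self.kind == "bernoulli" and not 0.0 <= self.params["p"] <= 1.0:
            raise ValueError("bernoulli p must lie in [0,1]")


@dataclass(frozen=True)
class Outcome:
    """Outcome model: η = β₀ + Σ βⱼxⱼ (+ site shift); family draws around η.

    ``beta`` holds the intercept followed by one coefficient per covariate in
    order.  Categorical covariates do not enter the linear predictor and must
    carry coefficient 0 — they exist for tabulation, not regression.
    """

    name: str
    family: str
    beta: tuple[float, ...]
    sigma: float = 1.0  # gaussian residual sd

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    sites: tuple[tuple[str, int], ...]
    covariates: tuple[Covariate, ...]
    outcome: Outcome
    site_shift: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.sites):
            raise ValueError("every site needs n >= 1")
        if len(self.outcome.beta) != len(self.covariates) + 1:
            raise ValueError("beta must be intercept + one coefficient per covariate")
        if self.site_shift and len(self.site_shift) != len(self.sites):
            raise ValueError("site_shift must align with sites")
        for cov, b in zip(self.covariates, self.outcome.beta[1:]):
            if cov.kind == "categorical" and b != 0.0:
                raise ValueError("categorical covariates must have coefficient 0")


def _site_rng(master_seed: int, site_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(site_index,)))


def generate_multisite(spec: SyntheticSpec) -> list[SiteDataset]:
    """Draw one dataset per site, fully reproducible from ``spec.seed``."""
    datasets = []
    for i, (name, n) in enumerate(spec.sites):
        rng = _site_rng(spec.seed, i)
        columns: dict[str, np.ndarray] = {}
        eta = np.full(n, spec.outcome.beta[0], dtype=float)
        if spec.site_shift:
            eta += spec.site_shift[i]
        for cov, b in zip(spec.covariates, spec.outcome.beta[1:]):
            if cov.kind == "normal":
                x = rng.normal(cov.params["mu"], cov.params["sd"], n)
            elif cov.kind == "bernoulli":
                x = rng.binomial(1, cov.params["p"], n).astype(np.int64)
            else:
                x = rng.choice(list(cov.params["levels"]), size=n, p=list(cov.params["probs"]))
            columns[cov.name] = x
            if cov.kind != "categorical":
                eta += b * np.asarray(x, dtype=float)
        fam = spec.outcome.family
        if fam == "gaussian":
            y = eta + rng.normal(0.0, spec.outcome.sigma, n)
        elif fam == "binomial":
            y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
        else:
            y = rng.poisson(np.exp(eta)).astype(np.int64)
        columns[spec.outcome.name] = y
        frame = pd.DataFrame(columns)
        # 0/1 indicators are factors for tabulation; the GLM coerces them
        # numerically regardless of the declared type
        types = {
            c.name: ("numeric" if c.kind == "normal" else "categorical")
            for c in spec.covariates
        }
        types[spec.outcome.name] = (
            "categorical" if spec.outcome.family == "binomial" else "numeric"
        )
        datasets.append(SiteDataset(name=name, table=frame, types=types))
    return datasets


def default_demo_spec(seed: int = 0, sizes: Sequence[int] = (120, 180, 150)) -> SyntheticSpec:
    """A small three-site case-control style study used by the demo and CLI.

    Age in years, body-mass index, a smoking indicator and an arm label;
    binary outcome with moderate prevalence (≈30%) so contingency cells are
    comfortably populated at the default suppression threshold.
    """
    return SyntheticSpec(
        sites=tuple((f"site{c}", n) for c, n in zip("ABC", sizes)),
        covariates=(
            Covariate("age", "normal", {"mu": 50.0, "sd": 10.0}),
            Covariate("bmi", "normal", {"mu": 27.0, "sd": 4.0}),
            Covariate("smoker", "bernoulli", {"p": 0.3}),
            Covariate("arm", "categorical", {"levels": ("A", "B"), "probs": (0.5, 0.5)}),
        ),
        outcome=Outcome("case", "binomial", beta=(-4.0, 0.06, 0.0, 0.8, 0.0)),
        site_shift=(0.0, 0.1, -0.1),
        seed=seed,
    )


def write_site_csvs(datasets: Iterable[SiteDataset], out_dir, spec: SyntheticSpec | None = None) -> list[Path]:
    """One CSV per site plus a JSON sidecar recording the spec and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in datasets:
        p = out / f"{ds.name}.csv"
        ds.table.to_csv(p, index=False)
        paths.append(p)
    if spec is not None:
        sidecar = {
            "seed": spec.seed,
            "sites": [{"name": s, "n": n} for s, n in spec.sites],
            "covariates": [
                {"name": c.name, "kind": c.kind, "params": dict(c.params)} for c in spec.covariates
            ],
            "outcome": {
                "name": spec.outcome.name,
                "family": spec.outcome.family,
                "beta": list(spec.outcome.beta),
                "sigma": spec.outcome.sigma,
            },
            "site_shift": list(spec.site_shift),
        }
        (out / "generation.json").write_text(json.dumps(sidecar, indent=2))
    return paths


# ---------------------------------------------------------------------------
# pseudonymization and date coarsening
# ---------------------------------------------------------------------------


def pseudonymize(
    table: pd.DataFrame, id_column: str, key: str, length: int = 16
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Replace identifiers with keyed-hash pseudonyms (HMAC-SHA256, hex).

    Deterministic within a key, so records of the same person link within a
    study; a different key yields unlinkable pseudonyms.  The linkage map
    (pseudonym → original) is returned as a separate object and must be kept
    apart from the table.
    """
    if id_column not in table.columns:
        raise FedShieldError("SEMANTIC_ERROR")
    if not key:
        raise FedShieldError("SEMANTIC_ERROR")

    def pseud(value) -> str:
        return hmac.new(key.encode(), str(value).encode(), hashlib.sha256).hexdigest()[:length]

    originals = table[id_column].astype(str)
    pseudonyms = originals.map(pseud)
    out = table.copy()
    out[id_column] = pseudonyms
    linkage = dict(zip(pseudonyms, originals))
    return out, linkage


def coarsen_date(dates: Iterable[str], granularity: str) -> list[str]:
    """Truncate ISO dates (YYYY-MM-DD) to month or year granularity."""
    if granularity not in ("month", "year"):
        raise FedShieldError("SEMANTIC_ERROR")
    out = []
    for value in dates:
        try:
            d = datetime.date.fromisoformat(str(value))
        except ValueError:
            raise FedShieldError("SEMANTIC_ERROR") from None
        out.append(f"{d.year:04d}-{d.month:02d}" if granularity == "month" else f"{d.year:04d}")
    return out
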