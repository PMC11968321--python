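"""Data-level obfuscation for privacy-preserving visualization.

Two mechanisms: deterministic replacement of every point by the centroid of
its k-nearest neighbourhood, and addition of seeded zero-mean Gaussian noise
whose variance is a custodian-bounded fraction of the data variance.  Both
run behind the corresponding disclosure filters (``nfilter.kNN``,
``nfilter.noise``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import FedShieldError
from .filters import check_knn, check_noise_fraction
from .settings import DisclosureSettings

__all__ = ["ObfuscatedPoints", "gaussian_noise_obfuscate", "knn_centroid_obfuscate"]


@dataclass(frozen=True)
class ObfuscatedPoints:
    """Obfuscated coordinates (n×d, d = 1 or 2) plus the method used."""

    coords: np.ndarray
    method: str
    params: Mapping

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_csv(self) -> str:
        header = "x" if self.coords.shape[1] == 1 else "x,y"
        lines = [header]
        for row in self.coords:
            lines.append(",".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"


def _as_matrix(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise FedShieldError("SEMANTIC_ERROR")
    return arr


def knn_centroid_obfuscate(points, k: int, s: DisclosureSettings) -> ObfuscatedPoints:
    """Replace each point by the centroid of itself plus its k−1 nearest others.

    Distances are Euclidean on per-dimension standardized coordinates (each
    dimension divided by its sample standard deviation, so axis units do not
    dominate); the centroid is taken on the original scale.  Fully
    deterministic: distance ties are broken toward the lowest input index.
    With k = n every output collapses to the global centroid.
    """
    arr = _as_matrix(points)
    n = arr.shape[0]
    decision = check_knn(k, n, s)
    if not decision.allowed:
        raise FedShieldError("OBFUSCATION_BLOCKED")

    sd = arr.std(axis=0, ddof=1) if n > 1 else np.ones(arr.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    scaled = arr / sd

    out = np.empty_like(arr)
    for i in range(n):
        d = np.sqrt(((scaled - scaled[i]) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")  # stable: ties fall to lowest index
        others = order[order != i][: k - 1]
        neighbourhood = np.concatenate(([i], others))
        out[i] = arr[neighbourhood].mean(axis=0)
    return ObfuscatedPoints(coords=out, method="knn", params={"k": k})


def gaussian_noise_obfuscate(
    x, noise_fraction: float, seed: int, s: DisclosureSettings
) -> ObfuscatedPoints:
    """Add seeded zero-mean Gaussian noise with variance fraction·var(x).

    Reproducible given the seed.  A constant input has zero variance, hence
    mathematically zero noise: it is returned unchanged rather than erroring.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise FedShieldError("SEMANTIC_ERROR")
    if arr.shape[0] < 2:
        raise FedShieldError("SEMANTIC_ERROR")
    decision = check_noise_fraction(noise_fraction, s)
    if not decision.allowed:
        raise FedShieldError("OBFUSCATION_BLOCKED")
    variance = float(np.var(arr, ddof=1))
    if variance == 0.0:
        coords = arr.copy()[:, None]
    else:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, np.sqrt(noise_fraction * variance), size=arr.shape[0])
        coords = (arr + noise)[:, None]
    return ObfuscatedPoints(
        coords=coords, method="noise", params={"fraction": noise_fraction, "seed": seed}
    )
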