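"""Disclosure-control parameter set, privacy-control levels and function registry.

Every filter decision made by a node is governed by a single
:class:`DisclosureSettings` vector chosen by the data custodian.  Analysts may
inspect these values through the client but can never change them.  The
privacy-control level additionally selects a predefined set of server-side
functions that are blocked outright because they enable known inference or
subsetting/difference attacks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PRIVACY_LEVELS",
    "DisclosureSettings",
    "FunctionEntry",
    "FunctionRegistry",
    "SettingsValidation",
    "blocked_functions",
    "default_registry",
    "default_settings",
    "settings_from_mapping",
    "settings_to_mapping",
    "validate_settings",
]

#: Functions blocked under each privacy-control level.  ``permissive`` blocks
#: nothing; ``banana`` blocks functions usable for inference attacks (seeded
#: random generation, sequence construction); ``avocado`` blocks functions
#: usable for subsetting/difference attacks; ``non-permissive`` blocks both
#: groups plus ``repDS``.
_BANANA_BLOCKED = frozenset(
    {"cDS", "dmtC2SDS", "rBinomDS", "rNormDS", "rPoisDS", "rUnifDS", "seqDS", "setSeedDS"}
)
_AVOCADO_BLOCKED = frozenset(
    {
        "BooleDS",
        "cbindDS",
        "dataFrameDS",
        "dataFrameSortDS",
        "dataFrameSubsetDS1",
        "dataFrameSubsetDS2",
        "levelsDS",
        "rbindDS",
        "recodeLevelsDS",
        "recodeValuesDS",
        "reShapeDS",
        "subsetByClassDS",
        "subsetDS",
        "vectorDS",
    }
)
_NON_PERMISSIVE_BLOCKED = frozenset(_AVOCADO_BLOCKED | _BANANA_BLOCKED | {"repDS"})

PRIVACY_LEVELS: Mapping[str, frozenset[str]] = {
    "permissive": frozenset(),
    "non-permissive": _NON_PERMISSIVE_BLOCKED,
    "avocado": _AVOCADO_BLOCKED,
    "banana": _BANANA_BLOCKED,
}

#: Config-file keys (custodian-facing spelling) for each settings field.
_CONFIG_KEYS: Mapping[str, str] = {
    "tab_threshold": "nfilter.tab",
    "subset_threshold": "nfilter.subset",
    "glm_ratio": "nfilter.glm",
    "string_max": "nfilter.string",
    "string_short_max": "nfilter.stringShort",
    "levels_density": "nfilter.levels.density",
    "levels_max": "nfilter.levels.max",
    "knn_min": "nfilter.kNN",
    "noise_min_fraction": "nfilter.noise",
    "privacy_level": "datashield.privacyControlLevel",
}
_FIELD_FOR_KEY = {v: k for k, v in _CONFIG_KEYS.items()}


@dataclass(frozen=True)
class DisclosureSettings:
    """Custodian-chosen disclosure-control parameters.

    Attributes
    ----------
    tab_threshold:
        Minimum count allowed in a non-empty contingency-table cell
        (non-negative integer; 1 disables the check).
    subset_threshold:
        Minimum number of rows a created subset may have (positive integer).
    glm_ratio:
        Maximum number of regression parameters as a fraction of the site
        sample size N, in (0, 1).
    string_max, string_short_max:
        Maximum lengths for long (formula/predicate) and short (name) string
        arguments.
    levels_density, levels_max:
        Caps on the number of unique levels of a categorical variable that may
        be returned: a fraction of the vector length and an absolute count.
    knn_min:
        Minimum neighbourhood size k for k-NN centroid obfuscation.
    noise_min_fraction:
        Minimum variance of added Gaussian noise, as a fraction of the data
        variance.
    privacy_level:
        One of ``permissive``, ``non-permissive``, ``avocado``, ``banana``.
    """

    tab_threshold: int = 3
    subset_threshold: int = 3
    glm_ratio: float = 0.33
    string_max: int = 80
    string_short_max: int = 20
    levels_density: float = 0.33
    levels_max: int = 40
    knn_min: int = 3
    noise_min_fraction: float = 0.25
    privacy_level: str = "banana"

    def blocked_functions(self) -> frozenset[str]:
        return blocked_functions(self.privacy_level)


@dataclass(frozen=True)
class SettingsValidation:
    """Verdict of :func:`validate_settings`: accepted iff no violations."""

    accepted: bool
    violations: tuple[str, ...] = ()


def default_settings() -> DisclosureSettings:
    """Return a fresh settings object carrying every default value."""
    return DisclosureSettings()


def _is_int(x) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


def validate_settings(s: DisclosureSettings) -> SettingsValidation:
    """Check every field against its permitted domain.

    Returns a verdict listing each violated field name; never raises.
    """
    bad: list[str] = []
    if not (_is_int(s.tab_threshold) and s.tab_threshold >= 0):
        bad.append("tab_threshold")
    for name in ("subset_threshold", "string_max", "string_short_max", "levels_max", "knn_min"):
        v = getattr(s, name)
        if not (_is_int(v) and v >= 1):
            bad.append(name)
    for name in ("glm_ratio", "levels_density"):
        v = getattr(s, name)
        if not (isinstance(v, (int, float)) and 0.0 < float(v) < 1.0):
            bad.append(name)
    if not (isinstance(s.noise_min_fraction, (int, float)) and float(s.noise_min_fraction) > 0):
        bad.append("noise_min_fraction")
    if s.privacy_level not in PRIVACY_LEVELS:
        bad.append("privacy_level")
    return SettingsValidation(accepted=not bad, violations=tuple(bad))


def blocked_functions(level: str) -> frozenset[str]:
    """Return the exact set of server-side functions blocked under ``level``."""
    try:
        return PRIVACY_LEVELS[level]
    except KeyError:
        raise ValueError(f"unknown privacy control level: {level!r}") from None


def settings_to_mapping(s: DisclosureSettings) -> dict:
    """Serialize to the custodian config-file key spelling (``nfilter.*``)."""
    return {key: getattr(s, fld) for fld, key in _CONFIG_KEYS.items()}


def settings_from_mapping(mapping: Mapping, *, strict: bool = True) -> DisclosureSettings:
    """Build settings from a config ``disclosure:`` block.

    Unknown keys raise; missing keys take the defaults. With ``strict`` the
    result must validate, otherwise construction aborts — a custodian override
    that fails its domain check must never fall back silently.
    """
    overrides: dict = {}
    for key, value in mapping.items():
        if key not in _FIELD_FOR_KEY:
            raise ValueError(f"unknown disclosure setting key: {key!r}")
        overrides[_FIELD_FOR_KEY[key]] = value
    s = dataclasses.replace(DisclosureSettings(), **overrides)
    if strict:
        verdict = validate_settings(s)
        if not verdict.accepted:
            raise ValueError(
                "invalid disclosure settings: " + ", ".join(verdict.violations)
            )
    return s


def settings_to_json(s: DisclosureSettings) -> str:
    return json.dumps(settings_to_mapping(s), sort_keys=True)


def settings_from_json(text: str) -> DisclosureSettings:
    return settings_from_mapping(json.loads(text))


@dataclass(frozen=True)
class FunctionEntry:
    name: str
    kind: str  # "assign" | "aggregate"
    implemented: bool = True


@dataclass
class FunctionRegistry:
    """Server-side function whitelist: name -> kind and implementation status.

    Every name appearing in any privacy-level blocked list is present (as a
    stub if unimplemented) so a block verdict is always resolvable.
    """

    entries: dict[str, FunctionEntry] = field(default_factory=dict)

    def add(self, name: str, kind: str, implemented: bool = True) -> None:
        if kind not in ("assign", "aggregate"):
            raise ValueError(f"kind must be assign or aggregate, got {kind!r}")
        self.entries[name] = FunctionEntry(name, kind, implemented)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str) -> FunctionEntry | None:
        return self.entries.get(name)

    def names(self) -> frozenset[str]:
        return frozenset(self.entries)


# Stub kinds for blocked-list functions we do not execute.  Assign-like
# object constructors vs aggregate-like value returners, following their
# naming; only `kind` matters for parser checks on stubs.
_STUB_KINDS = {
    "BooleDS": "assign",
    "cbindDS": "assign",
    "cDS": "assign",
    "dataFrameDS": "assign",
    "dataFrameSortDS": "assign",
    "dataFrameSubsetDS1": "assign",
    "dataFrameSubsetDS2": "assign",
    "dmtC2SDS": "assign",
    "rbindDS": "assign",
    "rBinomDS": "assign",
    "recodeLevelsDS": "assign",
    "recodeValuesDS": "assign",
    "repDS": "assign",
    "reShapeDS": "assign",
    "rNormDS": "assign",
    "rPoisDS": "assign",
    "rUnifDS": "assign",
    "seqDS": "assign",
    "subsetByClassDS": "assign",
    "vectorDS": "assign",
}


def default_registry() -> FunctionRegistry:
    """Registry with the implemented functions plus stubs for every name any
    privacy level can block."""
    reg = FunctionRegistry()
    # implemented server functions
    reg.add("asNumericDS", "assign")
    reg.add("subsetDS", "assign")
    reg.add("setSeedDS", "assign")
    reg.add("tableDS", "aggregate")
    reg.add("summaryDS", "aggregate")
    reg.add("levelsDS", "aggregate")
    reg.add("glmShareDS", "aggregate")
    reg.add("scatterPlotDS", "aggregate")
    # stubs so blocking is always resolvable
    for name, kind in _STUB_KINDS.items():
        if name not in reg:
            reg.add(name, kind, implemented=False)
    for level, blocked in PRIVACY_LEVELS.items():
        missing = blocked - reg.names()
        if missing:  # pragma: no cover - registry construction invariant
            raise RuntimeError(f"unresolvable blocked names for {level}: {missing}")
    return reg
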