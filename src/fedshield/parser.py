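"""Syntactic validation of incoming analyst commands.

Every request passes through :func:`parse_and_validate` before a node will
touch data: the function must be whitelisted in the registry and not blocked
under the active privacy-control level, its declared kind (assign/aggregate)
must match the registry, and every string argument must pass the length and
character-set filters.  All failures are collected and reported together —
an attacker probing the parser learns nothing about check ordering.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field

from .settings import DisclosureSettings, FunctionRegistry, blocked_functions

__all__ = [
    "PERMITTED_CHARACTERS",
    "Arg",
    "Request",
    "Verdict",
    "ValidationOutcome",
    "check_charset",
    "check_string",
    "parse_and_validate",
]

#: Characters a string argument may contain: enough for variable names,
#: comparison predicates and model formulas (hence '~'), while excluding ';',
#: backticks, '$', '@', '#', backslash, braces, brackets and control
#: characters that would enable command injection.
PERMITTED_CHARACTERS = frozenset(
    string.ascii_letters + string.digits + " ._,()=<>!&|+-*/'\"~"
)


@dataclass(frozen=True)
class Arg:
    """One typed request argument.

    kind:
        ``symbol`` — a server-side object or variable name (short string
        filter); ``string`` — free text such as a predicate or formula
        (slot selects long/short filter); ``number`` — a scalar;
        ``vector`` — a numeric vector (e.g. current GLM coefficients);
        ``flag`` — a boolean.
    """

    kind: str
    value: object
    slot: str = "long"  # for kind == "string": which length filter applies


@dataclass(frozen=True)
class Request:
    """A parsed analyst command heading for a node."""

    user: str
    function: str
    kind: str  # "assign" | "aggregate"
    args: tuple[Arg, ...] = ()
    target: str | None = None  # assign only

    def to_envelope(self) -> str:
        """JSON wire/log form of the request."""
        return json.dumps(
            {
                "user": self.user,
                "function": self.function,
                "kind": self.kind,
                "args": [
                    {"kind": a.kind, "value": _jsonable(a.value), "slot": a.slot}
                    for a in self.args
                ],
                "target": self.target,
            },
            sort_keys=True,
        )


def _jsonable(v):
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if hasattr(v, "tolist"):
        return v.tolist()
    return v


def request_from_envelope(text: str) -> Request:
    d = json.loads(text)
    args = tuple(Arg(a["kind"], a["value"], a.get("slot", "long")) for a in d["args"])
    return Request(d["user"], d["function"], d["kind"], args, d.get("target"))


@dataclass(frozen=True)
class Verdict:
    accepted: bool
    code: str = ""
    offending: str = ""


@dataclass(frozen=True)
class ValidationOutcome:
    """Parser verdict; ``accepted`` iff ``reasons`` is empty."""

    accepted: bool
    reasons: tuple[Verdict, ...] = field(default_factory=tuple)

    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.reasons)


def check_string(value: str, slot: str, s: DisclosureSettings) -> Verdict:
    """Length filter: long slot vs ``nfilter.string``, short vs
    ``nfilter.stringShort``.  Lengths strictly greater than the threshold are
    blocked, so a string exactly at the threshold passes."""
    limit = s.string_max if slot == "long" else s.string_short_max
    if len(value) > limit:
        return Verdict(False, "STRING_TOO_LONG", f"{slot}:{len(value)}")
    return Verdict(True)


def check_charset(value: str) -> Verdict:
    """Character filter: every character must be in the permitted set."""
    for ch in value:
        if ch not in PERMITTED_CHARACTERS:
            return Verdict(False, "ILLEGAL_CHARACTER", repr(ch))
    return Verdict(True)


def parse_and_validate(
    r: Request, registry: FunctionRegistry, s: DisclosureSettings
) -> ValidationOutcome:
    """Run every syntactic check and report all failures.

    Checks: function known to the registry; not blocked under the active
    privacy level; declared kind matches the registry entry; assign requests
    carry a target and aggregates do not; each string/symbol argument passes
    the length and charset filters (symbols always use the short filter);
    numeric arguments are finite.
    """
    reasons: list[Verdict] = []

    if not isinstance(r.function, str) or not r.function:
        reasons.append(Verdict(False, "UNKNOWN_FUNCTION", ""))
        entry = None
    else:
        entry = registry.get(r.function)
        if entry is None:
            reasons.append(Verdict(False, "UNKNOWN_FUNCTION", r.function))

    if isinstance(r.function, str) and r.function in blocked_functions(s.privacy_level):
        reasons.append(Verdict(False, "BLOCKED_BY_PRIVACY_LEVEL", r.function))

    if r.kind not in ("assign", "aggregate"):
        reasons.append(Verdict(False, "INVALID_KIND", str(r.kind)))
    elif entry is not None and entry.kind != r.kind:
        reasons.append(Verdict(False, "KIND_MISMATCH", r.kind))

    if r.kind == "assign" and not r.target:
        reasons.append(Verdict(False, "MISSING_TARGET", ""))
    if r.kind == "aggregate" and r.target:
        reasons.append(Verdict(False, "UNEXPECTED_TARGET", str(r.target)))
    if r.target is not None and isinstance(r.target, str):
        for v in (check_string(r.target, "short", s), check_charset(r.target)):
            if not v.accepted:
                reasons.append(Verdict(False, v.code, "target"))

    for i, a in enumerate(r.args):
        if a.kind in ("string", "symbol"):
            if not isinstance(a.value, str):
                reasons.append(Verdict(False, "MALFORMED_ARGUMENT", f"arg{i}"))
                continue
            slot = "short" if a.kind == "symbol" else a.slot
            v = check_string(a.value, slot, s)
            if not v.accepted:
                reasons.append(Verdict(False, v.code, f"arg{i}"))
            v = check_charset(a.value)
            if not v.accepted:
                reasons.append(Verdict(False, v.code, f"arg{i}:{v.offending}"))
        elif a.kind == "number":
            if not _finite_number(a.value):
                reasons.append(Verdict(False, "MALFORMED_ARGUMENT", f"arg{i}"))
        elif a.kind == "vector":
            vals = a.value
            ok = isinstance(vals, (list, tuple)) or hasattr(vals, "__iter__")
            if ok:
                try:
                    ok = all(_finite_number(x) for x in vals)
                except TypeError:
                    ok = False
            if not ok:
                reasons.append(Verdict(False, "MALFORMED_ARGUMENT", f"arg{i}"))
        elif a.kind == "flag":
            if not isinstance(a.value, bool):
                reasons.append(Verdict(False, "MALFORMED_ARGUMENT", f"arg{i}"))
        else:
            reasons.append(Verdict(False, "MALFORMED_ARGUMENT", f"arg{i}:{a.kind}"))

    return ValidationOutcome(accepted=not reasons, reasons=tuple(reasons))


def _finite_number(x) -> bool:
    if isinstance(x, bool):
        return False
    if not isinstance(x, (int, float)):
        return False
    return x == x and x not in (float("inf"), float("-inf"))
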