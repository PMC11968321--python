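"""Append-only per-site command log and multi-step attack detectors.

Every dispatched command leaves exactly one immutable event in the site log;
the full log (including custodian-side metadata such as exact subset sizes)
is exportable only with the custodian credential.  Two post-hoc detectors are
provided: a difference-attack detector that looks for pairs of subsets of the
same parent whose sizes differ by exactly one row, each followed by an
aggregate request, and a seed-abuse detector that flags seed-setting requests
preceding noise obfuscation within the same session.

A disclosure achieved in a single command is indistinguishable in the log
from legitimate analysis — single-step protection is the filters' job, not
the log's.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Callable, Iterable, Mapping

from .errors import FedShieldError

__all__ = [
    "Alert",
    "AuditEvent",
    "AuditLog",
    "detect_difference_attacks",
    "detect_seed_abuse",
    "scan_log",
]


def digest_args(envelope: str) -> str:
    """Stable short digest of a serialized request, for log compaction."""
    return hashlib.sha256(envelope.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AuditEvent:
    """One logged command.  Immutable once appended.

    ``outcome`` is one of ``executed``, ``blocked:<rule>`` or
    ``error:<code>``.  ``metadata`` holds custodian-only detail (exact subset
    sizes, table dimensions, drawn seeds) and must never be surfaced to the
    analyst.
    """

    seq: int
    timestamp: float
    user: str
    site: str
    session_id: str
    function: str
    kind: str
    arg_digest: str
    predicate: str = ""
    outcome: str = "executed"
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "metadata", MappingProxyType(dict(self.metadata)))

    def to_json(self) -> str:
        d = {
            "seq": self.seq,
            "timestamp": self.timestamp,
            "user": self.user,
            "site": self.site,
            "session_id": self.session_id,
            "function": self.function,
            "kind": self.kind,
            "arg_digest": self.arg_digest,
            "predicate": self.predicate,
            "outcome": self.outcome,
            "metadata": dict(self.metadata),
        }
        return json.dumps(d, sort_keys=True)

    @staticmethod
    def from_json(line: str) -> "AuditEvent":
        d = json.loads(line)
        return AuditEvent(**d)


class AuditLog:
    """Append-only event store for one site.

    Timestamps come from an injectable ``clock`` so tests are deterministic.
    Export requires the custodian credential; analysts get ACCESS_DENIED.
    """

    def __init__(self, site: str, custodian_token: str = "", clock: Callable[[], float] | None = None):
        self.site = site
        self._custodian_token = custodian_token
        self._clock = clock or time.time
        self._events: list[AuditEvent] = []

    def __len__(self) -> int:
        return len(self._events)

    def record(
        self,
        *,
        user: str,
        session_id: str,
        function: str,
        kind: str,
        arg_digest: str = "",
        predicate: str = "",
        outcome: str = "executed",
        metadata: Mapping | None = None,
    ) -> AuditEvent:
        """Append one event; sequence numbers are 1-based and strictly increasing."""
        event = AuditEvent(
            seq=len(self._events) + 1,
            timestamp=float(self._clock()),
            user=user,
            site=self.site,
            session_id=session_id,
            function=function,
            kind=kind,
            arg_digest=arg_digest,
            predicate=predicate,
            outcome=outcome,
            metadata=metadata or {},
        )
        self._events.append(event)
        return event

    def export(self, credential: str) -> tuple[AuditEvent, ...]:
        """Full log, custodian-only."""
        if credential != self._custodian_token or not self._custodian_token:
            raise FedShieldError("ACCESS_DENIED")
        return tuple(self._events)

    def events_unsafe(self) -> tuple[AuditEvent, ...]:
        """Direct access for in-process custodian tooling and tests."""
        return tuple(self._events)

    def to_ndjson(self, credential: str) -> str:
        return "\n".join(e.to_json() for e in self.export(credential))

    @staticmethod
    def events_from_ndjson(text: str) -> tuple[AuditEvent, ...]:
        return tuple(
            AuditEvent.from_json(line) for line in text.splitlines() if line.strip()
        )


@dataclass(frozen=True)
class Alert:
    """One detected multi-step disclosure pattern."""

    type: str  # "difference_attack" | "seed_abuse"
    events: tuple[int, ...]  # sequence numbers of the implicated events
    explanation: str

    def __post_init__(self) -> None:
        if self.type == "difference_attack" and len(self.events) < 2:
            raise ValueError("difference_attack alerts must reference >= 2 events")


def _root_symbol(symbol: str) -> str:
    return symbol.split(".", 1)[0]


def detect_difference_attacks(events: Iterable[AuditEvent]) -> list[Alert]:
    """Find subset pairs differing by exactly one row, each later aggregated.

    Subsets are grouped by (user, source symbol).  A pair alerts when both
    subset creations succeeded, their custodian-recorded sizes differ by
    exactly 1, and each subset's target was subsequently the source of an
    aggregate request by the same user.  Predicate refinement (one predicate
    a substring of the other) is annotated as advisory context only.
    """
    events = list(events)
    subsets: dict[tuple[str, str], list[AuditEvent]] = {}
    for e in events:
        if e.function == "subsetDS" and e.outcome == "executed" and "subset_size" in e.metadata:
            key = (e.user, _root_symbol(str(e.metadata.get("source", ""))))
            subsets.setdefault(key, []).append(e)

    def first_aggregate_after(sub: AuditEvent) -> AuditEvent | None:
        target = str(sub.metadata.get("target", ""))
        for e in events:
            if (
                e.seq > sub.seq
                and e.kind == "aggregate"
                and e.user == sub.user
                and _root_symbol(str(e.metadata.get("source", ""))) == target
            ):
                return e
        return None

    alerts: list[Alert] = []
    for (user, source), subs in subsets.items():
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                a, b = subs[i], subs[j]
                if abs(int(a.metadata["subset_size"]) - int(b.metadata["subset_size"])) != 1:
                    continue
                agg_a = first_aggregate_after(a)
                agg_b = first_aggregate_after(b)
                if agg_a is None or agg_b is None:
                    continue
                note = ""
                if a.predicate and b.predicate and (
                    a.predicate in b.predicate or b.predicate in a.predicate
                ):
                    note = "; predicates are nested refinements (advisory)"
                alerts.append(
                    Alert(
                        type="difference_attack",
                        events=(a.seq, agg_a.seq, b.seq, agg_b.seq),
                        explanation=(
                            "two subsets of the same source differ by exactly one row "
                            "and each was followed by an aggregate request" + note
                        ),
                    )
                )
    return alerts


def detect_seed_abuse(events: Iterable[AuditEvent]) -> list[Alert]:
    """Flag seed-setting (even if blocked) followed by noise obfuscation.

    A seed the analyst controls makes added noise reproducible and hence
    subtractable; any setSeedDS request preceding a noise-method obfuscation
    by the same user in the same session is flagged, advisory under
    permissive levels where seed control is allowed.
    """
    events = list(events)
    alerts: list[Alert] = []
    for e in events:
        if e.function != "setSeedDS":
            continue
        for later in events:
            if (
                later.seq > e.seq
                and later.user == e.user
                and later.session_id == e.session_id
                and later.function == "scatterPlotDS"
                and str(later.metadata.get("method", "")) == "noise"
            ):
                alerts.append(
                    Alert(
                        type="seed_abuse",
                        events=(e.seq, later.seq),
                        explanation=(
                            "a seed-setting request preceded a noise obfuscation "
                            "request within the same session"
                        ),
                    )
                )
                break  # one alert per seed request
    return alerts


def scan_log(events: Iterable[AuditEvent]) -> list[Alert]:
    """Run every detector over a log."""
    events = list(events)
    return detect_difference_attacks(events) + detect_seed_abuse(events)
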