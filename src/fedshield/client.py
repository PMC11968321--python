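"""Analyst-facing orchestrator.

A :class:`Connection` holds one authenticated session per site and broadcasts
requests to all of them.  Pooled results are computed client-side from the
per-site non-disclosive payloads and only when every site returned
successfully.  The federated GLM loop is driven through the same broadcast
primitive, so the per-iteration deviance trace is visible to the analyst —
those are a handful of numbers, not data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import fedstats
from .errors import FedShieldError, error_message
from .fedstats import ContingencyTable, GlmResult, GlmShare, SummaryShare
from .node import Node, Session
from .parser import Arg, Request
from .settings import DisclosureSettings

__all__ = [
    "AggregateOutcome",
    "Connection",
    "SiteError",
    "connect",
    "payload_vector_lengths",
]


@dataclass(frozen=True)
class SiteError:
    """A per-site failure, surfaced with its catalogue message only."""

    code: str

    @property
    def message(self) -> str:
        return error_message(self.code)


@dataclass(frozen=True)
class AggregateOutcome:
    """Per-site payloads (or errors) plus the pooled combination if possible."""

    per_site: Mapping[str, object]
    pooled: object | None = None


@dataclass
class Connection:
    nodes: dict[str, Node] = field(default_factory=dict)
    sessions: dict[str, Session] = field(default_factory=dict)

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    # -- broadcast primitives ------------------------------------------------

    def dispatch_all(self, request: Request) -> dict[str, object]:
        """Send one request to every site; failures become SiteError entries."""
        results: dict[str, object] = {}
        for site, node in self.nodes.items():
            try:
                results[site] = node.dispatch(self.sessions[site], request)
            except FedShieldError as err:
                results[site] = SiteError(err.code)
        return results

    def aggregate_all(self, request: Request) -> AggregateOutcome:
        """Broadcast an aggregate request and pool when every site succeeded.

        Tables pool by element-wise summation, summaries through their
        sufficient statistics.  A suppressed site table blocks pooling
        (the suppression is reported for that site instead).
        """
        if request.kind != "aggregate":
            raise FedShieldError("SEMANTIC_ERROR")
        per_site = self.dispatch_all(request)
        pooled = None
        payloads = list(per_site.values())
        if not any(isinstance(p, SiteError) for p in payloads):
            if all(isinstance(p, ContingencyTable) for p in payloads):
                try:
                    pooled = fedstats.pool_tables(payloads)
                except FedShieldError:
                    pooled = None
            elif all(isinstance(p, SummaryShare) for p in payloads):
                pooled = fedstats.pool_summaries(payloads)
        return AggregateOutcome(per_site=per_site, pooled=pooled)

    def assign_all(self, request: Request) -> dict[str, object]:
        """Broadcast an assign request; per-site status messages only."""
        if request.kind != "assign":
            raise FedShieldError("SEMANTIC_ERROR")
        return self.dispatch_all(request)

    def show_settings(self) -> dict[str, DisclosureSettings]:
        """Read-only copies of each site's active disclosure settings."""
        return {
            site: dataclasses.replace(self.sessions[site].settings)
            for site in self.nodes
        }

    # -- request builders ----------------------------------------------------

    def _user(self) -> str:
        return next(iter(self.sessions.values())).user

    def table_request(self, *symbols: str) -> Request:
        return Request(
            user=self._user(),
            function="tableDS",
            kind="aggregate",
            args=tuple(Arg("symbol", s) for s in symbols),
        )

    def summary_request(self, symbol: str) -> Request:
        return Request(
            user=self._user(),
            function="summaryDS",
            kind="aggregate",
            args=(Arg("symbol", symbol),),
        )

    def subset_request(self, source: str, predicate: str, target: str) -> Request:
        return Request(
            user=self._user(),
            function="subsetDS",
            kind="assign",
            args=(Arg("symbol", source), Arg("string", predicate, "long")),
            target=target,
        )

    def scatter_request(
        self,
        *symbols: str,
        method: str,
        param: float,
        seed: int | None = None,
    ) -> Request:
        args = [Arg("symbol", s) for s in symbols]
        args.append(Arg("string", method, "short"))
        args.append(Arg("number", float(param)))
        if seed is not None:
            args.append(Arg("number", int(seed)))
        return Request(
            user=self._user(), function="scatterPlotDS", kind="aggregate", args=tuple(args)
        )

    # -- federated GLM -------------------------------------------------------

    def glm(
        self,
        source: str,
        formula: str,
        family: str,
        tol: float = 1e-8,
        max_iter: int = 25,
    ) -> GlmResult:
        """Fit a pooled GLM by iterated score/information exchange.

        Every site must pass the model-dimension filter against its own
        sample size; any site-level failure aborts the fit with that site's
        typed error.
        """
        model = fedstats.parse_formula(formula, family)
        user = self._user()

        def share_fn(beta: np.ndarray) -> list[GlmShare]:
            request = Request(
                user=user,
                function="glmShareDS",
                kind="aggregate",
                args=(
                    Arg("symbol", source),
                    Arg("string", formula, "long"),
                    Arg("string", family, "short"),
                    Arg("vector", [float(b) for b in beta]),
                ),
            )
            shares = []
            for site, node in self.nodes.items():
                shares.append(node.dispatch(self.sessions[site], request))
            return shares

        terms = (("(intercept)",) if model.intercept else ()) + model.covariates
        return fedstats.federated_glm(
            share_fn, model.p, family, terms=terms, tol=tol, max_iter=max_iter
        )


def connect(nodes: Sequence[Node], credentials: Sequence[Mapping]) -> Connection:
    """Log in to every site, all-or-nothing.

    ``credentials`` is a list of ``{site, user, token}``; a single failed
    login (or a duplicate site name) leaves no sessions behind.
    """
    by_site: dict[str, Node] = {}
    for node in nodes:
        if node.site in by_site:
            raise FedShieldError("CONFIG_ERROR")
        by_site[node.site] = node
    sessions: dict[str, Session] = {}
    conn_nodes: dict[str, Node] = {}
    for cred in credentials:
        site = cred["site"]
        node = by_site.get(site)
        if node is None or site in sessions:
            raise FedShieldError("CONFIG_ERROR")
        try:
            sessions[site] = node.login(cred["user"], cred["token"])
        except FedShieldError as err:
            err.site = site  # attribution without touching the fixed message
            raise
        conn_nodes[site] = node
    if not sessions:
        raise FedShieldError("CONFIG_ERROR")
    return Connection(nodes=conn_nodes, sessions=sessions)


def connect_from_config(path) -> Connection:
    """Build a connection from a YAML/JSON file listing per-site entries:
    ``sites: [{site, config, user, token}, ...]`` with site-config paths
    resolved relative to the connection file."""
    import json
    from pathlib import Path

    from .node import load_site_config

    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    try:
        entries = cfg["sites"]
        nodes = [load_site_config(path.parent / e["config"]) for e in entries]
        creds = [{"site": e["site"], "user": e["user"], "token": e["token"]} for e in entries]
    except (KeyError, TypeError) as err:
        raise FedShieldError("CONFIG_ERROR") from err
    return connect(nodes, creds)


# ---------------------------------------------------------------------------
# payload hygiene
# ---------------------------------------------------------------------------


def payload_vector_lengths(payload) -> set[int]:
    """Collect the length of every vector-like field in a client-bound payload.

    Used to assert that no payload smuggles an individual-level column: no
    collected length may equal any site's row count.  Strings are scalars
    here; matrices contribute both of their dimensions.
    """
    lengths: set[int] = set()
    _walk(payload, lengths)
    return lengths


def _walk(obj, lengths: set[int]) -> None:
    if obj is None or isinstance(obj, (bool, int, float, complex, str, bytes)):
        return
    if isinstance(obj, np.ndarray):
        lengths.update(int(d) for d in obj.shape if d > 0)
        return
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            _walk(getattr(obj, f.name), lengths)
        return
    if isinstance(obj, Mapping):
        for v in obj.values():
            _walk(v, lengths)
        return
    if isinstance(obj, (list, tuple, set, frozenset)):
        if len(obj) > 0:
            lengths.add(len(obj))
        for v in obj:
            _walk(v, lengths)
        return
    if hasattr(obj, "__len__"):
        try:
            n = len(obj)
        except TypeError:
            return
        if n > 0:
            lengths.add(int(n))
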