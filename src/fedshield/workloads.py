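"""Seeded analyst workload generators for exercising the audit detectors.

Each generator builds a single-site node with a continuous study variable,
plays a scripted analyst session against it through the real dispatch path,
and returns the node's audit log.  Benign workloads create random subsets
whose sizes are pairwise at least two apart (no one-row difference exists to
find); attack workloads deliberately construct two nested subsets differing
by exactly one row and aggregate both — the textbook difference attack.

Because the study variable is drawn continuously, "keep the k smallest
values" predicates yield subsets of exactly size k, so workload sizes are
under precise control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audit import AuditEvent
from .client import Connection, connect
from .errors import FedShieldError
from .node import DataView, Node, SiteDataset, UserAccount, hash_token

__all__ = ["attack_workload", "benign_workload"]

_N = 40  # rows in the workload dataset


def _workload_connection(rng: np.random.Generator) -> tuple[Node, Connection, np.ndarray]:
    age = rng.normal(50.0, 10.0, _N)
    ds = SiteDataset("D", pd.DataFrame({"age": age}))
    node = Node(
        site="w1",
        datasets=[ds],
        accounts=[
            UserAccount(
                "analyst", hash_token("tok"), views=(DataView("D", frozenset({"age"})),)
            )
        ],
        custodian_token="cust",
    )
    conn = connect([node], [{"site": "w1", "user": "analyst", "token": "tok"}])
    return node, conn, np.sort(age)


def _threshold_for_size(sorted_values: np.ndarray, k: int) -> float:
    """A cutpoint c such that ``value <= c`` keeps exactly k rows."""
    if k >= len(sorted_values):
        return float(sorted_values[-1] + 1.0)
    return float((sorted_values[k - 1] + sorted_values[k]) / 2.0)


def _subset_and_mean(conn: Connection, target: str, cut: float) -> None:
    predicate = f"age <= {cut!r}"
    status = conn.assign_all(conn.subset_request("D", predicate, target))
    if any(isinstance(v, FedShieldError) for v in status.values()):  # pragma: no cover
        raise RuntimeError("workload subset unexpectedly failed")
    conn.aggregate_all(conn.summary_request(f"{target}.age"))


def benign_workload(seed: int) -> tuple[AuditEvent, ...]:
    """Three subsets with pairwise size gaps >= 2, each followed by a mean."""
    rng = np.random.default_rng(seed)
    node, conn, sorted_age = _workload_connection(rng)
    sizes: list[int] = []
    while len(sizes) < 3:
        k = int(rng.integers(4, _N - 2))
        if all(abs(k - other) >= 2 for other in sizes):
            sizes.append(k)
    for i, k in enumerate(sizes):
        _subset_and_mean(conn, f"S{i}", _threshold_for_size(sorted_age, k))
    return node.export_log("cust")


def attack_workload(seed: int) -> tuple[AuditEvent, ...]:
    """Two nested subsets differing by exactly one row, each aggregated."""
    rng = np.random.default_rng(seed)
    node, conn, sorted_age = _workload_connection(rng)
    k = int(rng.integers(3, _N - 2))
    _subset_and_mean(conn, "S0", _threshold_for_size(sorted_age, k))
    _subset_and_mean(conn, "S1", _threshold_for_size(sorted_age, k + 1))
    return node.export_log("cust")
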