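"""End-to-end demonstration run used by the examples, CLI and checks.

Generates a three-site synthetic study, stands up one node per site with an
analyst account, and walks the whole analysis surface: contingency table,
pooled summary, federated logistic regression, subset creation, and both
obfuscation methods.  Every client-bound payload produced along the way is
collected so the payload-hygiene property (no vector of any site's row count
ever reaches the client) can be asserted over the complete run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .client import Connection, connect, payload_vector_lengths
from .datagen import default_demo_spec, generate_multisite
from .node import DataView, Node, SiteDataset, UserAccount, hash_token
from .parser import Arg, Request

__all__ = ["DemoRun", "build_demo_connection", "run_demo"]


@dataclass
class DemoRun:
    """Everything the demo produced, plus the payload inventory."""

    connection: Connection
    site_rows: Mapping[str, int]
    table: object
    summary: object
    glm: object
    subset_status: Mapping[str, object]
    subset_sizes: Mapping[str, int]
    knn: object
    noise: object
    payloads: list
    payload_lengths: set[int]

    @property
    def hygiene_ok(self) -> bool:
        return not (self.payload_lengths & set(self.site_rows.values()))


def build_demo_connection(seed: int = 0, sizes=(120, 180, 150)) -> tuple[Connection, dict[str, int]]:
    """Three default-settings nodes over synthetic data, one analyst login each."""
    spec = default_demo_spec(seed, sizes=sizes)
    datasets = generate_multisite(spec)
    nodes = []
    creds = []
    for i, ds in enumerate(datasets):
        token = f"token-{ds.name}"
        account = UserAccount(
            "analyst",
            hash_token(token),
            views=(DataView("D", frozenset(ds.table.columns)),),
        )
        nodes.append(
            Node(
                site=ds.name,
                datasets=[SiteDataset("D", ds.table, dict(ds.types))],
                accounts=[account],
                custodian_token=f"custodian-{ds.name}",
                node_seed=seed * 1000 + i,
            )
        )
        creds.append({"site": ds.name, "user": "analyst", "token": token})
    conn = connect(nodes, creds)
    rows = {ds.name: len(ds.table) for ds in datasets}
    return conn, rows


def run_demo(seed: int = 0) -> DemoRun:
    conn, site_rows = build_demo_connection(seed)
    payloads: list = []

    def keep(payload):
        payloads.append(payload)
        return payload

    # 1. contingency table: smoking status x case status, per site and pooled
    table_out = conn.aggregate_all(conn.table_request("D.smoker", "D.case"))
    keep(table_out)

    # 2. pooled summary of body-mass index
    summary_out = conn.aggregate_all(conn.summary_request("D.bmi"))
    keep(summary_out)

    # 3. federated logistic regression
    glm_result = conn.glm("D", "case ~ age + smoker", "binomial")
    keep(glm_result)
    # the raw per-site shares of the final iteration are client-bound too
    share_req = Request(
        user="analyst",
        function="glmShareDS",
        kind="aggregate",
        args=(
            Arg("symbol", "D"),
            Arg("string", "case ~ age + smoker", "long"),
            Arg("string", "binomial", "short"),
            Arg("vector", [float(b) for b in glm_result.beta]),
        ),
    )
    keep(conn.dispatch_all(share_req))

    # 4. subset assign: only status messages come back
    subset_status = conn.assign_all(conn.subset_request("D", "age > 50", "S1"))
    keep(subset_status)
    subset_sizes = {
        site: int(node.log.events_unsafe()[-1].metadata["subset_size"])
        for site, node in conn.nodes.items()
    }

    # 5. obfuscated visualization payloads on the derived subset
    knn_out = conn.aggregate_all(
        conn.scatter_request("S1.age", "S1.bmi", method="knn", param=3)
    )
    keep(knn_out)
    noise_out = conn.aggregate_all(
        conn.scatter_request("S1.bmi", method="noise", param=0.25)
    )
    keep(noise_out)

    lengths: set[int] = set()
    for p in payloads:
        lengths |= payload_vector_lengths(p)

    return DemoRun(
        connection=conn,
        site_rows=site_rows,
        table=table_out,
        summary=summary_out,
        glm=glm_result,
        subset_status=subset_status,
        subset_sizes=subset_sizes,
        knn=knn_out,
        noise=noise_out,
        payloads=payloads,
        payload_lengths=lengths,
    )
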