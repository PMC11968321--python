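"""Contingency tables with cell suppression, and pooled summaries.

A rare category makes one site's table disclosive: that site returns a
suppressed table (flag only), and pooling is withheld entirely so the rare
cell cannot be recovered by subtraction.
"""

import pandas as pd

from fedshield.client import connect
from fedshield.node import DataView, Node, SiteDataset, UserAccount, hash_token

def make_site(name, groups, bmi):
    frame = pd.DataFrame({"group": groups, "bmi": bmi})
    account = UserAccount("a", hash_token("t"), views=(DataView("D", frozenset(frame.columns)),))
    return Node(name, [SiteDataset("D", frame, {"group": "categorical"})], [account], custodian_token="c")

site1 = make_site("site1", ["a"] * 6 + ["b"] * 6, [24.0, 25, 26, 27, 28, 29, 30, 31, 22, 23, 24, 25])
site2 = make_site("site2", ["a"] * 5 + ["b"] * 6 + ["rare"], [20.0, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31])

conn = connect(
    [site1, site2],
    [{"site": s, "user": "a", "token": "t"} for s in ("site1", "site2")],
)

out = conn.aggregate_all(conn.table_request("D.group"))
for site, t in out.per_site.items():
    if t.suppressed:
        print(f"{site}: SUPPRESSED (a non-empty cell is below the threshold of 3)")
    else:
        print(f"{site}: {dict(zip(t.levels[0], t.counts))}")
print(f"pooled table: {out.pooled}  <- withheld because one site suppressed")

summary = conn.aggregate_all(conn.summary_request("D.bmi"))
p = summary.pooled
print(f"\npooled bmi over both sites: mean={p['mean']:.3f} variance={p['variance']:.3f} N={p['N']}")
# The pooled moments come from per-site sufficient statistics (N, sum, sum of
# squares) and equal the moments of the concatenated values exactly.
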