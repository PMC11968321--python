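# fedshield

A simulation of a multi-site **federated analysis** platform with active
**statistical disclosure control**, built for methodologists and data
custodians in epidemiology and biomedicine who want to study — or teach —
how "analysis to the data" systems protect individual-level records while
still delivering exact pooled statistics.

Each simulated data-holding site executes only whitelisted *assign* (create a
server-side object, return a status) and *aggregate* (return low-dimensional
statistics after disclosure checks) commands. A client connects to several
sites, broadcasts commands, and pools the returned summaries. Nothing
individual-level ever crosses the site boundary.

## The statistics at the core

For a GLM with canonical link, the Newton/IRLS update depends on the data
only through per-site sufficient statistics: the score vector and expected
information

&nbsp;&nbsp;&nbsp;&nbsp;U<sub>s</sub> = X<sub>s</sub>ᵀ(y<sub>s</sub> − μ<sub>s</sub>),&nbsp;&nbsp;&nbsp;
I<sub>s</sub> = X<sub>s</sub>ᵀW<sub>s</sub>X<sub>s</sub>,&nbsp;&nbsp;&nbsp;
β ← β + (Σ<sub>s</sub> I<sub>s</sub>)⁻¹ Σ<sub>s</sub> U<sub>s</sub>

so iterating this exchange from β = 0 reproduces the pooled-data fit
*exactly* (to numerical precision) while each site releases only p numbers
and a p×p matrix per iteration. Around the model sit the classical
disclosure-control rules, enforced server-side on every request:

| rule | blocks | default |
|---|---|---|
| `nfilter.tab` | a contingency table with any non-empty cell < threshold | 3 |
| `nfilter.subset` | creation of a subset with fewer rows | 3 |
| `nfilter.glm` | a model with p > fraction × N parameters (per site) | 0.33 |
| `nfilter.string` / `.stringShort` | over-long string arguments | 80 / 20 |
| `nfilter.levels.density` / `.max` | returning too many factor levels | 0.33 / 40 |
| `nfilter.kNN` | centroid obfuscation with too small a neighbourhood | 3 |
| `nfilter.noise` | noise obfuscation with too little variance | 0.25 |
| `privacyControlLevel` | whole function groups (`permissive`, `banana`, `avocado`, `non-permissive`) | `banana` |

An append-only, custodian-only audit log records every command; post-hoc
detectors flag multi-step disclosure patterns (one-row-difference subset
pairs, seed-setting before noise requests).

## Worked example

```bash
fedshield demo --seed 1
```

```
sites: {'siteA': 120, 'siteB': 180, 'siteC': 150}
pooled ('smoker', 'case') counts:
[[250  80]
 [ 64  56]]
pooled bmi: mean=27.003 variance=16.392 N=450
glm (intercept): beta=-4.0888 se=0.6439
glm age: beta=+0.0580 se=0.0121
glm smoker: beta=+1.1158 se=0.2328
glm converged=True iterations=5 deviance=506.26 N=450
subset sizes (custodian log): {'siteA': 52, 'siteB': 87, 'siteC': 68}
payload hygiene ok: True
```

Three synthetic sites (450 people total, generative logistic model
β = (−4, 0.06·age, 0.8·smoker)) are stood up in-process. The pooled
smoker×case table sums the per-site tables that passed cell suppression; the
pooled BMI moments come from per-site (N, Σx, Σx²); the federated logistic
fit recovers the generative coefficients within two standard errors — and is
identical to what fitting the concatenated 450-row dataset would give. The
subset sizes appear only in the custodian-side log, and the final line
reports that no payload returned to the client contained a vector as long as
any site's table.

The `examples/` directory walks each capability in isolation (settings and
privacy levels, the federated GLM, suppression and pooling, obfuscation,
attack detection, pseudonymization). A file-based deployment for the other
CLI subcommands (`tabulate`, `summary`, `glm`, `obfuscate`, `show-settings`,
`audit-scan`) is written by `fedshield gen-data --out demo/ --seed 1`.

## Layout

- `src/fedshield/settings.py` — disclosure parameters, privacy levels, function registry
- `src/fedshield/parser.py` — command whitelisting, string/charset filters
- `src/fedshield/filters.py` — the pure disclosure decision rules
- `src/fedshield/node.py` — simulated server: snapshots, views, dispatch flow
- `src/fedshield/fedstats.py` — tables, summaries, federated GLM
- `src/fedshield/obfuscation.py` — k-NN centroid and Gaussian-noise obfuscation
- `src/fedshield/audit.py` — append-only log, difference/seed-abuse detectors
- `src/fedshield/client.py` — multi-site connection, broadcasting, pooling
- `src/fedshield/datagen.py` — synthetic multi-site generator, pseudonymization
- `src/fedshield/workloads.py`, `demo.py`, `cli.py` — benchmarks, end-to-end run, CLI

See `docs/methods.md` for the modelling assumptions, parameter semantics,
and design decisions.
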