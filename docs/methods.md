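# Methods

This note records the model, the disclosure rules as implemented, the
numerical choices, and the places where the design was genuinely open.

## Setting

We simulate a client–server federated analysis platform. Data never leave a
site; an analyst's command is dispatched to every connected site, runs
against a read-only snapshot there, and only non-disclosive summaries
return. All transport is in-process: nodes are Python objects the client
calls directly. Network security (TLS, firewalls, middleware products) is
real-world infrastructure that this simulation deliberately omits — the
object of study is the disclosure-control and federated-statistics layer,
which is unchanged by the transport.

Commands are restricted to two shapes. An **assign** creates a derived
object in a per-session, volatile workspace and returns a status message
carrying only an ok flag, an object class, and a dimensions-validity flag.
An **aggregate** returns a statistical payload after disclosure checks.
Every dispatch — successful, blocked, or failed — appends exactly one event
to the site's append-only audit log. Error messages come from a fixed
catalogue and never interpolate data values; exact sizes appear only in
custodian-side log metadata.

## Disclosure filters

All filters are pure functions of (input summary, settings vector).

- **Cell suppression** (`nfilter.tab`, default 3): a 1–3 dimensional
  contingency table is withheld entirely if any *non-empty* cell is below
  the threshold. Empty cells never trigger: a zero count reveals only the
  absence of a combination. A threshold of 1 disables the check (useful for
  rare-disease settings); 5 or 10 replicate common custodian rules.
- **Subset size** (`nfilter.subset`, default 3): subsets smaller than the
  threshold are not created. We block empty subsets too (0 < threshold),
  reading the rule literally; an empty subset reveals little, but the
  stricter reading costs nothing analytically.
- **Model dimension** (`nfilter.glm`, default 0.33): a regression with
  p > ratio × N parameters is refused, evaluated *per site* against that
  site's complete-case N; the pooled model must pass at every site. Float
  boundary comparisons carry a 1e-12 tolerance resolved toward blocking
  (fail safe), so p exactly on the boundary is refused.
- **Levels** (`nfilter.levels.density` 0.33, `.max` 40): returning the
  unique levels of a factor is refused if the level count exceeds either
  cap. The two caps guard the same operation; we block on either (the
  stricter of the two possible readings).
- **String filters** (`nfilter.string` 80, `nfilter.stringShort` 20):
  lengths strictly greater than the threshold are blocked, so a string
  exactly at the limit passes. Symbol/variable-name arguments always use
  the short filter; predicate and formula arguments use the long one —
  names are short by nature, formulas need room.
- **Obfuscation floors** (`nfilter.kNN` 3, `nfilter.noise` 0.25): see below.

The permitted character set for string arguments is letters, digits, space,
and `. _ , ( ) = < > ! & | + - * / ' " ~` — enough for names, comparison
predicates, and model formulas, while excluding `;`, backticks, `$`, `@`,
`#`, backslash, braces, brackets, and control characters that enable
injection. The tilde is included because model formulas
(`outcome ~ cov1 + cov2`) are part of the analyst interface.

Four privacy-control levels block whole function groups server-side:
`permissive` (nothing), `banana` (eight functions enabling seeded-randomness
inference attacks; the default), `avocado` (fourteen functions enabling
subsetting/difference attacks), and `non-permissive` (all of the above plus
`repDS`). The three non-empty lists are treated as authoritative verbatim
sets rather than deriving one from the others; the implementation checks at
registry construction that every blockable name is resolvable.

Settings are immutable per session. Custodians set them in the site config;
an invalid override aborts node start rather than silently reverting to
defaults. Analysts can read effective settings through the client but the
returned objects are frozen copies — mutating them is an error and cannot
affect the node. Per-user profiles may override site settings **only toward
strictness** (higher thresholds where higher is stricter, lower where lower
is; a privacy level only if its blocked set is a superset of the site's).
Precedence between site and profile values is not otherwise defined, and
applying only-stricter overrides is our interpretation: a profile should
never be able to weaken a custodian's floor.

## Federated GLM

Families: gaussian/identity, binomial/logit, poisson/log (canonical links
only). At the current β each site computes η = Xβ, μ = g⁻¹(η), canonical
weights w (1, μ(1−μ), μ), and releases

    U = Xᵀ(y − μ),   I = Xᵀ diag(w) X,   deviance,   N.

The client iterates β ← β + (ΣI)⁻¹(ΣU) from β₀ = 0 and stops when the
relative change in total deviance, |D − D′|/(|D′| + 0.1), drops below
`tol = 1e-8`, or after `max_iter = 25` iterations (the result then carries
`converged = False`). These are conventional IRLS defaults. Because the
summed statistics are exactly those of the concatenated data, the federated
estimate equals the pooled fit to numerical precision; the test suite
verifies coefficients and standard errors against statsmodels' pooled IRLS
to 1e-6 and partition invariance (1 vs 2 vs 5 sites) to 1e-8.

The covariance is (ΣI)⁻¹, scaled for the gaussian family by the dispersion
estimate deviance/(N − p) so that standard errors match an ordinary pooled
least-squares fit; binomial and poisson use fixed unit dispersion. Results
carry coefficients, standard errors, the covariance, total deviance, N,
iteration count, and the per-iteration deviance trace — a handful of
numbers — and never fitted values, residuals, or linear predictors.
A singular pooled information matrix is a typed error, not a crash.
Formulas support main effects only (`y ~ x1 + x2`); covariates are numeric
(0/1 indicators included), complete cases per request.

Missing data throughout are handled complete-case per request, with the
missing count reported as a single aggregate number.

## Pooling rules

Tables pool by element-wise summation over structurally identical level
sets; summaries pool through (N, Σx, Σx²) with variance
(Σx² − (Σx)²/N)/(N − 1). If any site suppressed its table, pooling is
withheld entirely: pooling the remaining sites would let the analyst
recover the suppressed site's counts by subtraction from a later full pool.
Per-site univariate summaries reuse the subset threshold as their minimum N
— a summary of fewer rows is a small subset in disguise; no dedicated
filter exists for this case, so reusing `nfilter.subset` is our choice.

## Obfuscation

- **k-NN centroid**: each point is replaced by the arithmetic centroid of
  itself plus its k−1 nearest other points. Including the point itself makes
  the output well defined at k = 1 and collapses exactly to the global
  centroid at k = n. Distances are Euclidean on per-dimension standardized
  coordinates (each axis divided by its sample SD; a zero-SD axis is left
  unscaled) so that axis units cannot dominate; centroids are reported on
  the original scale. Whether standardization precedes the distance
  computation is an implementation interpretation. The procedure is
  deterministic; distance ties break toward the lowest input index.
- **Gaussian noise**: x + e with e ~ N(0, f·var(x)), f ≥ `nfilter.noise`.
  A constant vector has zero variance and is returned unchanged rather than
  erroring. The draw is reproducible given a seed, but analyst seed control
  is honoured only where `setSeedDS` is not blocked by the active privacy
  level; otherwise the node draws the seed itself and records it in the
  custodian-side log only — analyst-chosen seeds enable noise-subtraction
  attacks, which is precisely what the default level forbids.

Obfuscated coordinates necessarily have one output point per input point.
Hygiene with respect to raw-column leakage is therefore asserted as: no
client-bound payload contains a vector whose length equals a site's full
table size. In the demonstration workflow the obfuscated variables are
columns of an analyst-created subset, so their length differs from every
site's N; obfuscating a full column is legitimate but is exactly the case
the k-NN/noise floors exist to protect.

## Audit log and detectors

Events are immutable, strictly sequenced, timestamped through an injectable
clock (tests are deterministic), and exportable as newline-delimited JSON
only with the custodian credential. Two detectors run post hoc:

- **Difference attack**: subsets of the same parent by the same user whose
  custodian-recorded sizes differ by exactly one, each later aggregated —
  one alert per offending pair, citing all four events. Size-difference-one
  is the sole implemented signature; predicate refinement (one predicate a
  substring of the other) is annotated as advisory context only, since
  predicates are opaque strings.
- **Seed abuse**: any seed-setting request (even a blocked one) preceding a
  noise-obfuscation request by the same user in the same session, advisory
  under levels where seeding is permitted.

A disclosure achieved in a single step is indistinguishable in the log from
legitimate analysis — the suite documents this negative property — so
single-step protection belongs to the filters, and detection here is post
hoc, not real-time blocking.

Detector error rates are benchmarked on scripted workloads replayed through
the real dispatch path: benign sessions draw three subset sizes with
pairwise gaps ≥ 2 (no one-row pair exists), attack sessions construct a
nested pair differing by one row. Because the study variable is continuous,
"keep the k smallest values" predicates give exact control of subset sizes.
Over 100 seeds each: 0% false alarms, 100% detection.

## Synthetic data

The generator emulates a horizontally partitioned cohort: covariates drawn
i.i.d. per site from shared distributions (normal, Bernoulli, categorical),
an outcome from one shared GLM (gaussian σ configurable, binomial, poisson),
and per-site intercept shifts as the only heterogeneity — enough to exercise
multi-site pooling without confounding the federated-vs-pooled equivalence
tests, which is their purpose. Categorical covariates exist for tabulation
and must carry coefficient 0; 0/1 indicators are declared categorical for
tabulation but enter regressions numerically. Per-site RNG streams are
spawned from the master seed by site index, so adding a site never perturbs
existing sites' data.

The demonstration study uses three sites of 120/180/150 people, age ~
N(50, 10²), BMI ~ N(27, 4²), smoking ~ Bernoulli(0.3), a two-arm label, and
a binary outcome with η = −4 + 0.06·age + 0.8·smoker (≈30% prevalence, so
default-threshold tables are comfortably populated). Equivalence checks use
3 sites totalling N = 600 with three covariates; recovery checks use
β = (0, 1, −0.5) at N = 5000. These sizes make every distributional check
statistically comfortable while keeping the full suite fast.

What passing tests on these data do **not** show: robustness to covariate
shift or outcome-model heterogeneity across sites beyond intercepts, to
informative missingness (the generator produces complete data; missingness
handling is only exercised structurally), or to real-data pathologies such
as separation in logistic models.

## Pseudonymization utilities

Identifiers are replaced by HMAC-SHA256 pseudonyms (16 hex characters by
default) keyed by a custodian secret: deterministic within a key, unlinkable
across keys, with the pseudonym→identifier linkage returned as a separate
object that must be stored apart from the data. Dates coarsen from ISO
`YYYY-MM-DD` to month or year; malformed dates are errors, not guesses.

## Known limitations

- No real transport or persistence; sessions and workspaces are in-memory.
- The predicate grammar is intentionally tiny (`var op constant` with
  `&`/`|`); no parentheses, arithmetic, or cross-variable comparisons.
- Detection is limited to the two implemented signatures; a determined
  adversary has other multi-step routes (e.g. repeated noise queries under
  permissive settings).
- Differential privacy and output perturbation beyond the noise floor are
  out of scope.
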