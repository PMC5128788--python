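# Methods

## Diversity measures

The Hill number of order `a >= 0` for an abundance vector with proportions
`p_i` is `N_a = (sum_i p_i^a)^(1/(1-a))`, with two conventions:

* **a = 0** returns observed richness exactly — taxa with zero count never
  contribute, at any order (`0^a` contributes 0, including `a = 0`).
* **a near 1**: the `1/(1-a)` exponent blows up in floating point, so orders
  within `1e-6` of 1 are routed to the analytic limit
  `exp(-sum p_i ln p_i)` (exponential Shannon). Tests check continuity at
  `1 ± 1e-8` to `1e-6` relative.

Orders below 1 are supported but increasingly dominated by the rare tail;
estimates there inherit the instability of raw richness and should be read
accordingly.

Chao1 is `S_obs + F1^2 / (2 F2)` (singletons `F1`, doubletons `F2`). When
`F2 = 0` the classic ratio is undefined and the standard bias-corrected form
`S_obs + F1 (F1 - 1) / (2 (F2 + 1))` is substituted; the substitution is
logged per call. Good's coverage is `1 - F1 / N`. Both require integer read
counts; Hill numbers accept any non-negative abundances.

## Taxa-accumulation curves

The smoothed TAC at order `a` averages, over random sample orderings, the
Hill number of the *pooled counts* of the first k samples. Pooling (rather
than averaging per-sample values) makes the curve rise toward the gamma
diversity of the whole study, which is the asymptote of interest.
Monte-Carlo smoothing (default `n_perm = 100`, seeded) is used because an
analytic expectation exists only for richness; that closed form — the
sample-based rarefaction formula `E[S_k] = sum_i [1 - C(T - t_i, k) / C(T, k)]`
with `t_i` the number of samples containing taxon i — is implemented as
`expected_richness_tac` and serves as a cross-check oracle, not as the
smoother. An `exhaustive=True` mode enumerates all orderings for small
tables, used by tests against a brute-force enumeration.

## Read-depth subsampling and stability

`subsample_reads` draws a fixed number of reads **without replacement**
(multivariate hypergeometric on the counts) — the meaning of subsampling a
sequencing library; a with-replacement multinomial mode exists only for
requesting depths beyond the observed total and is never the default. The
mean observed richness of repeated subsamples is checked against the
closed-form hypergeometric rarefaction expectation
`sum_i [1 - C(N - n_i, d) / C(N, d)]`.

`depth_analysis` evaluates each Hill order on `reps = 10` independent
subsamples at each depth of a grid, then scores each order's mean curve for
stability. The default grid is 8 log-spaced depths spanning a 16-fold range
ending at the full pooled depth (`N/16 .. N`); for a ~400k-read study this
is 25,000–400,000 reads. Tying the grid to the pooled total keeps the same
relative span meaningful for shallow studies, where a fixed absolute grid
would collapse to one or two usable depths.

**Stability criterion.** No standard numeric definition of "the curve has
reached its asymptote" exists, so the package declares one: step `s` is
stable when, over the window from `s` to the first grid point at least
`window_frac` of the full step range beyond `s`, the maximum relative change
from the value at `s` is at most `tol`. Defaults: `window_frac = 0.1`,
`tol = 0.02` (≤ 2% change looking ~10% of the range ahead). Snapping the
window end to the next available grid point keeps every non-final step
eligible on log-spaced grids; the final step can never be declared stable.
The reported `stability_depth` is the first stable depth per order, or
"not reached". The criterion is a convention — results should be quoted
together with `window_frac` and `tol`.

## Rank-abundance models

* **Log-normal** — fitted as a continuous distribution of the observed
  positive abundances; the MLE is the mean and population SD of the logs.
  Counts are treated as continuous (no Poisson-log-normal compounding, no
  veil-line truncation): the simplest defensible reading for read counts
  spanning several orders of magnitude, and the one that keeps the
  bootstrap below exact. A zero-variance input is flagged `degenerate`.
* **Zipf** — a rank model: expected relative abundance `p_r = p_1 r^(-gamma)`
  at rank r, fitted by maximizing the multinomial likelihood of the
  rank-ordered counts. Under the sum-to-one constraint `p_1` is determined
  by gamma, so `n_params = 1`; `p_1` is reported as a derived parameter.
  Gamma at the zero boundary (uniform counts) is flagged `degenerate`.

`select_model` takes the minimum-AIC fit (`AIC = 2k - 2 logL`), breaking
exact ties toward fewer parameters and flagging them. The two likelihoods
live on different data representations (per-taxon density vs per-read
multinomial), so the comparison is a pragmatic convention in the tradition
of rank-abundance model comparison tools; simulation tests show it recovers
the generating family in ≥ 90% of runs at realistic sizes (S = 1000,
N = 1e5) for both families.

**Deviation test.** `D` is the sup-norm (Kolmogorov–Smirnov) distance
between the empirical CDF of log abundances and the fitted Normal CDF.
Because mu and sigma are estimated from the same data, the naive KS p-value
is invalid; the p-value comes from a parametric bootstrap that simulates
`n_boot` (default 999) replicates from the fitted model, *refits each one*,
and recomputes `D*` — a Lilliefors-style correction, with
`p = (1 + #{D* >= D}) / (n_boot + 1)` so p is never exactly zero. With the
standard KS statistic `D` cannot be exactly 0 on finite data (it is at least
`1/(2S)`); the definitional identity is tested at the statistic level
against an independent KS implementation instead. Calibration under the
null (empirical size within [0.02, 0.10] at nominal 0.05) and power against
Zipf communities are verified by simulation in the test suite.

## Synthetic communities

`make_community` builds true relative abundances for `S` taxa from a
log-normal (parameters mu, sigma of log abundance), Zipf (`p_r ∝ r^-gamma`,
deterministic in rank) or uniform TAD; `sample_reads` models
sampling-by-sequencing as a multinomial draw, so rare taxa are observed
once, twice or never exactly as in real libraries. `make_study` draws
`n_samples` independent samples at fixed depth; optional between-sample
heterogeneity is a Dirichlet jitter with concentration `probs /
overdispersion` (0 = identical proportions, the default — real repeat
samples vary more).

Two presets bracket the regimes the method contrasts, chosen to emulate a
deeply and a shallowly sequenced soil survey since no generative parameters
for real communities are published:

* `amazon_like`: log-normal, sigma = 2, S = 5000, 66 samples x 6,000 reads
  (~396k total);
* `texas_like`: Zipf, gamma = 1.1, S = 5000, 36 samples x 860 reads
  (~31k total).

On these presets the expected qualitative pattern emerges and is asserted
in the acceptance tests: in the deep study the order-2 curve is stable at
the first grid depth, order 1 stabilizes mid-grid, and richness never
flattens; in the shallow study only order 2 reaches stability, AIC selects
the Zipf model, and the log-normal deviation test rejects strongly.

What the generator does **not** emulate: sequencing error (chimeras and
homopolymer artifacts that inflate singleton counts), variable per-sample
depth, taxon co-occurrence structure, and 16S copy-number variation.
Passing tests therefore show the estimators behave correctly under clean
multinomial sampling from heavy-tailed communities — not that artifactual
singletons in real libraries are handled; on real data the rare-tail
statistics (F1, Chao1, coverage, low orders) absorb those artifacts
undiminished.

## Problem sizes and defaults

Simulation-backed tests use the sizes above or smaller (recovery at
S = 500–5000 taxa and 1e5 reads; null calibration with 200 runs of
n_boot = 199; selection rates over 50 seeded runs per family), which keeps
the full suite to a few seconds while leaving the binomial/bootstrap error
bands well inside the asserted tolerances. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give bit-identical
curves, subsamples, fits and pipeline output files.

## Pipeline

`run_pipeline` chains load/simulate → diversity table → per-order TACs →
depth analysis → RAD fits into one seeded run, writing CSV/JSON plus a
manifest (effective config, package version, input checksum, SHA-256 of
every output). The manifest carries no timestamps so re-running an
identical configuration reproduces every byte; the embedded config re-runs
to identical checksums (tested). Configuration is a flat `key = value`
file mirrored by CLI flags, flags winning; every stage logs its effective
parameters and timing. Optional plotting was left out; the CSV outputs
(step/mean/sd per curve, long-format depth table, rank-ordered fits) are
the plotting interface.
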