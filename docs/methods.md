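# Methods

This note documents the statistical procedures implemented in
`callrhythm`, the assumptions behind them, and the numerical and design
choices made where several defensible options existed.

## Data model and analysis levels

The unit of input is an annotated vocal event: recording (`file_id`),
call (`call_id`), kind (`pulse` = voiced exhale, `pant` = voiced
inhale), onset in absolute seconds, and duration. Onsets must be
strictly increasing within a call; tied onsets are treated as an
annotation error rather than broken arbitrarily, because continuous-time
event data should never tie and a silent tie-break would corrupt
interval statistics downstream. Calls with fewer than two pulses are
flagged and kept.

Four onset sequences are derived per corpus:

1. **all pulses** — pulse onsets per call, pants ignored;
2. **pulse/pant series** — all onsets of each *section*;
3. **pulses within series**; 4. **pants within series**.

A *section* is a maximal run of at least three events whose kinds
strictly alternate (either phase first) with no inter-onset gap above
`max_gap_s` (default 5 s). Strict alternation is what makes levels 2–4
interpretable as a two-phase respiratory cycle; the gap cap keeps a
section from spanning a silent pause. Both rules are configurable.

## Intervals, ratios, and the bin scheme

For onsets o_1 < … < o_n, intervals are t_k = o_{k+1} − o_k (n − 1 of
them) and ratios r_k = t_k / (t_k + t_{k+1}) (n − 2). Ratios are never
chained across call or section boundaries, so a corpus satisfies
`#r_k = #t_k − #series` exactly — a property test in the suite.

The on/off-integer windows are half-open, lower-inclusive:

| bin | windows | width |
|---|---|---|
| on 1:2 | [0.308, 0.364) | 0.056 |
| off 1:2 | [0.286, 0.308) ∪ [0.364, 0.400) | 0.058 |
| on 1:1 | [0.444, 0.555) | 0.111 |
| off 1:1 | [0.400, 0.444) ∪ [0.555, 0.600) | 0.089 |
| on 2:1 | [0.636, 0.692) | 0.056 |
| off 2:1 | [0.600, 0.636) ∪ [0.692, 0.714) | 0.058 |

Half-open intervals are a measure-zero choice that cannot affect
continuous data but guarantee the six bins are disjoint and tile
[0.286, 0.714) exactly; ratios outside that range stay unbinned.

The *double-meter share* is the pooled (on 1:2 + on 2:1) count divided
by all on-integer counts; because the denominator is a convention, the
variant over all six bins is also reported.

Within-call position densities of the rhythmic categories use a
Gaussian kernel on the ratio's first-onset position expressed as a
fraction of the call span (first onset to last event end), with
reflection at 0 and 1 so the density integrates to one on the unit
interval. Bandwidth defaults to Silverman's rule.

## Zero-inflated Poisson mixed model

Per (file × bin) count y with bin width w: with probability π
(intercept-only, logit link) y is a structural zero; otherwise
y ~ Poisson(μ) with log μ = β_bin + log w + u_file,
u_file ~ N(0, σ_u²). The six bin levels enter as cell means, so the
off-vs-on contrasts of interest are plain coefficient differences.
The log-width offset converts counts to rates per unit of ratio space;
multiplying all widths by a constant provably shifts only the
intercepts and leaves every contrast unchanged (tested).

The marginal likelihood integrates u_file with **adaptive Gauss–Hermite
quadrature** (21 nodes): per file, a damped Newton search finds the
conditional mode and curvature, and the Hermite rule is centred and
scaled there. A Laplace approximation (the quadrature's 1-node limit)
is available as a fast path and is used in the larger simulation
studies. On corpora of ≤ 5 files the quadrature log-likelihood matches
fine-trapezoid numerical integration to 1e-6.

Optimization is L-BFGS-B on (β, logit π, log σ_u) with up to three
seeded random restarts on non-convergence; σ_u estimates at the lower
box bound are flagged as pinned-to-zero. Standard errors come from the
inverse observed information (numerical Hessian); contrasts c'β use
SE = √(c'Vc), z statistics, and two-sided normal p-values with no
multiplicity adjustment (three planned off-vs-on pairs per level).
Bins whose total count is zero carry no rate information (their cell
mean diverges), so they are dropped from the design and their contrasts
are reported as not estimable.

The full-vs-null likelihood-ratio test removes the bin factor but keeps
the random intercept and the zero-inflation intercept; χ² = 2Δℓ with df
equal to the parameter-count difference. Simulation checks in the test
suite: Wald 95% intervals cover true rates at ≈ nominal rate over 200
simulated corpora (40 files, π = 0.2, σ_u = 0.5), and the LRT rejects
flat-rate null data at 3–7% over 500 replicates.

## Tempo model

log t_k is modelled with a Gaussian linear mixed model: a three-level
fixed factor (series / pants / pulses) and a per-section random
intercept, fitted by maximum likelihood (not REML, so that the
full-vs-null LRT on the fixed factor is valid). This rides on
statsmodels' MixedLM; several optimizers are tried in order until one
returns a finite likelihood. Pairwise contrasts use t statistics with
residual degrees of freedom n − p; the data sizes involved (thousands
of intervals) make more elaborate df corrections immaterial, which is
why a Satterthwaite option is not carried.

## Coupling

Pulse-derived and pant-derived series of a section are index-paired and
truncated to the shorter length. The default series is **interval
durations** (t_k), not raw onset times: onset series are monotone
trends whose cross-correlation is near 1 regardless of any real
coupling; an `onset_times` mode exists for literal replication.

The cross-correlation uses the standard biased estimator with
full-series means and standard deviations; lag 0 therefore equals the
Pearson coefficient exactly. Positive lag means the pulse series leads
the pant series (this convention differs between ecosystems and is
stated in the output headers). The effective maximum lag is
min(20, n − 1); the best lag maximizes the signed correlation, ties
broken toward lag 0.

Order-1 Granger causality is the nested-OLS F-test: restricted
y_t ~ 1 + y_{t−1} versus unrestricted y_t ~ 1 + y_{t−1} + x_{t−1},
F(1, n − 4) for paired length n — the convention of R's
`grangertest(order = 1)`, against which the implementation is verified
on a frozen fixture. Series shorter than 5 leave no residual df and are
excluded from p-values (they still appear in the section count).
The causality tally counts sections with p below α (default 0.001) per
direction; bi-directional sections count in both. No detrending or
prewhitening is applied.

## Synthetic corpus generator

Pulse trains are a renewal process: lognormal intervals with mean equal
to the current cycle period (default 2 s ≈ 0.5 Hz) and coefficient of
variation `jitter_cv`; the period is multiplied by `tempo_drift` each
cycle. Lognormal jitter keeps intervals positive and makes the jitter
scale-free across tempi. Each cycle independently receives a pant at
onset + phase·interval with probability `pant_insertion_prob`, phase
N(0.5, 0.05) clipped to [0.15, 0.85]; the `edges` position profile
multiplies the insertion probability by a two-component Beta mixture
(Beta(2, 8) + Beta(8, 2)) over normalized call position, giving the
early/late concentration of pants seen in real calls. Event durations
are 10–14% of the local interval, so onsets cannot collide; configs
whose phase could undercut the duration are rejected. All draws come
from one seeded generator: identical configs give byte-identical
corpora.

Default corpus conditions mirror the study scale: 47 calls of 18–38
pulses (≈ 1250 pulse intervals), 2 s pulse period, `jitter_cv` 0.15,
insertion probability 0.4 (≈ 0.4 pants per cycle, matching a few
hundred pants per corpus). At zero jitter the generator's analytic
limits are exact and are used as oracles: no pants → every r_k = 0.5;
midpoint pants → series intervals exactly half the period, and the
series-vs-pulses tempo contrast exactly log(1/2).

**What the generator does not emulate.** Real pulse intervals are
heavy-tailed (sample SDs larger than means), whereas the lognormal with
moderate cv is thin-tailed; consequently the synthetic level-(i)
double-meter share is far below the ~10% seen in field data, which
arises from genuine tempo jumps. Likewise, because synthetic sections
are strictly alternating and pants sit near the midpoint, level-(ii)
1:2/2:1 ratios occur only through phase jitter. Passing tests therefore
demonstrate correctness of the computations and calibration of the
inference machinery, not that the generator reproduces wild long-call
rhythm statistics.

## Simulated-study sizes

The calibration studies bundled with the test suite use 40-file
corpora, 200 replicates for interval coverage, 500 for LRT size, and
1000 white-noise pairs for Granger size — sizes at which binomial error
on the reported rates is ~1–1.5 percentage points, chosen to keep the
whole suite comfortably runnable on a laptop while leaving the checks
statistically meaningful.

## Reproduction mode

`reproduce_paper` (CLI: `callrhythm reproduce`) starts from a local
copy of the archived annotation tables (their column headers are not
standardized, so the reader uses a per-dialect column mapping that can
be overridden with a YAML file), recomputes interval/ratio counts, mean
tempi, the tempo-model χ², the Granger tallies and the
cross-correlation floor, and prints observed versus published values
with pass/fail at the published precision. The published headline
numbers are attainable only in this mode; nothing outside it reads or
reports them.
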