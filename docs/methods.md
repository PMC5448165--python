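# Methods

## Kinetic model and exact solver

Each transcript follows the delayed linear ODE

    dm/dt = k0 + k · pERK(t − Δt) − γ · m(t),

with rates in expression units per minute, `γ` in 1/min and `Δt` in
minutes. Time is minutes everywhere, with t = 0 the moment of stimulation.
The state `m` is identified with log2-scale expression: fits consume log2
microarray-style values directly, and predicted log2 fold change is
`m(t) − k0/γ`. The model makes no claim about absolute molecule numbers;
identifying the ODE state with the measurement scale keeps the
relative-amplitude formula `(m − k0/γ) / (k/γ)` and the weighting scheme
consistent with the data they are applied to.

Inputs are piecewise trajectories (`step` or `linear` mode), held at
`before_first` (default 0) before the first breakpoint and at the last
value after the last. The delay is implemented by evaluating the input at
`t − Δt`; no richer history is kept. Because the forcing is piecewise
linear, the solution is propagated **exactly** segment-by-segment
(piecewise-exponential with a linear particular solution), so solver output
carries no integration error; the test suite verifies agreement with a
dt = 0.01 min explicit Euler integrator, whose own first-order error sets
the comparison tolerance (1e-4 relative; breakpoints are aligned to the
Euler grid in that comparison so only truncation error remains).

The initial condition defaults to the pre-stimulus steady state `k0/γ`,
matching serum-starved cells at equilibrium before stimulation.

Derived kinetics: half-life `t½ = ln2/γ`, response time `r = Δt + t½`.
Under a sustained step from steady state, the relative amplitude at `r` is
exactly 50% — a closed-form identity the property tests assert to 1e-9
over randomized parameters.

Temporal classes use inclusive boundaries: DEG iff `Δt > 30 min`, else ILG
iff `t½ > 120 min`, else IEG. The 30-min delay threshold reflects the
sampling interval of the emulated designs; 120 min is the half-life at
which a two-hour pulse delivers exactly half the sustained plateau
(`1 − 2^(−120/t½)` = 0.5), which is what `scripts/acceptance.py`
recomputes by root-finding.

### Parameter-space scan

`scan_parameter_space` defaults: half-lives 10–600 min, log-spaced, 25
points; delays 0–300 min, 13 points; times 0–600 min. Amplitude is
invariant to `k0` and `k`, so cells are solved with `k0 = 0, k = 1`. The
companion boolean grid marks cells that ever exceed 50% amplitude within
the simulated window — for the "every cell eventually exceeds half
maximum under sustained input" check the window must extend past the
slowest cell's response time (delay 300 + half-life 600), so that test
simulates to 1,500 min.

The "transient" scenario is an EGF-like interpolated shape (peak 1.4× the
training mean at 10 min, decaying to a 0.2 plateau); its exact form is not
canonical and is config-overridable.

## Empirical-null differential expression

The variance model ranks genes by mean expression across the anchor
replicates (a triplicated 2-h sustained-induction sample) and smooths the
per-gene unbiased replicate variances with a centred moving average,
window 2,000 genes, truncated (not padded) at the rank edges. Lookup
interpolates linearly between ranked neighbours and clamps at the ends;
the level used for lookup is the gene's mean across **all** samples.

z-scores standardize the deviation from the untreated-baseline mean:

    z_ij = (p_ij − mean_UT,i) / sqrt(v(level_i) · (1 + 1/n_UT)).

The `(1 + 1/n_UT)` factor is the variance of a difference between one
observation and a baseline mean of `n_UT` replicates; with it, z has unit
standard deviation under the null (verified on 10,000 pure-null synthetic
genes), and the |z| > 5.6 operating point has the intended rarity.

FDR at a threshold is estimated by leave-one-out contrasts within the
anchor triplicate (each replicate against the mean of the other two,
standardized with the analogous 1 + 1/2 factor), averaged over the three
rotations, divided by the number of genes called in the real contrasts.
Because raw ratios at sparse thresholds need not be monotone, the reported
curve takes the running maximum from the high-threshold end: conservative,
and non-increasing in the threshold by construction. If no threshold
reaches the target the caller returns +inf with a warning.

Secondary filters: (1) the fold-change-SD filter draws a size-matched
random sample of unregulated genes (seeded; sampling with replacement only
when the pool is too small, with a warning) and places the cut-off at the
1 − FDR quantile (default FDR 5%) of their SD_log2fc; (2) the monotonicity
filter keeps a gene iff its replicate-mean trajectory under sustained
induction (anchored at the baseline mean at t = 0) never moves against the
called direction by more than **3 expected step-SDs**, where the step SD is
`sqrt(2·v(level))` from the smoothed variance model. A 1-SD tolerance
rejects ~24% of plateau steps under Gaussian noise and would discard half
of genuinely monotone genes; 3 SDs keeps false rejection per gene near 1%
while still discarding rise-then-fall shapes, which violate the bound by
many step-SDs. Down-regulated genes are called and recorded but the
kinetic modelling downstream applies to up-regulated genes.

Primary response genes: a regulated gene is primary iff any
cycloheximide-co-treatment sample shows a sign-matched z beyond the same
threshold; with no cycloheximide data the flag is missing, not false.

## Per-gene fitting and model selection

Observations are all replicate log2 values in the chosen conditions plus
the baseline mean pinned at t = 0; weights are `1/v(level)` at each
observation's own level (weights as known inverse variances make ΔwRSS
χ²-referable). Rates are optimized in log space; the delay is mapped by a
logistic transform onto [0, max observed time]. Nelder–Mead (wRSS
tolerance 1e-10, max 5,000 iterations) runs from multiple seeded starts:
γ log-uniform over half-lives 5–1,000 min, `k0` and `k` from the earliest
and latest observations, Δt uniform over [0, 300] min. The library default
is 20 restarts; the synthetic benchmark suites use 5–8, which recover the
cohorts to the asserted accuracy at a fraction of the cost. The
complete-model fit always includes the simple-model solution (with Δt→0)
as one start, so `wRSS_complete ≤ wRSS_simple` holds by construction and
the likelihood-ratio statistic is non-negative.

Selection: complete iff `ΔwRSS ≥ 3.84` (χ²₁, P < 0.05) **and** fitted
`Δt ≥ 30 min`; otherwise the simple model supplies the half-life. A fitted
delay at the upper transform bound flags the gene as exceeding the
experiment span and excludes it from class medians. Per-gene failures are
recorded in the batch table, never raised.

## Prediction and decode capacity

Measured pERK log2 fold changes are averaged over replicates per time
point, divided by the training-condition mean (3.89 log2 units in the
emulated system — 100% signalling amplitude), clamped below at zero
(negative pERK would imply active repression, outside this model),
linearly interpolated and held after the last point. Normalization is by
the **training**-condition mean for every scenario: only a common
reference makes amplitudes comparable across scenarios. Predictions solve
the model from the basal steady state and subtract `k0/γ`; with the
training input and training-fitted parameters this reproduces the fitted
trajectory exactly (asserted to 1e-9), so prediction error under new
scenarios is attributable to the scenario transfer, not the machinery.
Errors are means of absolute residuals, evaluated strictly at observed
time points; the relative form divides by the maximum absolute observed
fold change. Decode capacity reports, per gene, the maximum relative
amplitude under each scenario and the long/short amplitude ratio
(sustained over 2-h pulse by default); for the model itself this ratio is
`1/(1 − 2^(−T/t½))` at zero delay, ≥ 1 always, and large exactly for
long-lived transcripts.

## Shutdown-based half-lives

Shutdown samples are normalized so the median log2 expression of the
long-lived reference set (≥ 5 genes required) is identical across time
points; the across-sample mean of the reference medians is added back so
absolute levels stay in range. Decay is fitted on the **linear** scale to
`M(t) = B + A·e^(−γt)` with `A > 0, B ≥ 0, γ > 0` (trust-region least
squares; initial rate from the half-loss time). The offset-only literal
form `M0 + e^(−γt)` cannot represent arbitrary starting levels and is kept
only as a selectable alternative (`form="literal"`). Non-decreasing series
yield an infinite-half-life sentinel flagged unreliable; summaries across
datasets exclude sentinels and report how many were excluded.

## Synthetic data: what it emulates and what it does not

The generator is the ground truth for every recovery benchmark. Study
conditions, chosen once:

* **Noise**: variance(level) = 0.02 + 0.6·2^(−(level−4)) squared log2
  units — a monotone-decreasing level dependence typical of microarrays.
* **Design**: untreated ×3, sustained induction at
  {30, 60, 120, 180, 240, 360, 480, 600} min with a triplicated 120-min
  anchor, a 2-h pulse arm, and a cycloheximide arm in which genes marked
  secondary (30% of induced by default) lose their induction entirely.
* **Parameters**: class-consistent ranges spanning the fitted ranges of
  the emulated system — IEG half-lives 10–117 min, ILG 124–561 min, DEG
  half-lives 30–120 min with delays 45–180 min; delays of immediate genes
  uniform on [0, 30].
* **Induction strength**: induced genes have basal log2 levels U(6, 11)
  and steady-state inductions of 3–6 log2 units; primary response genes in
  this kind of system are strongly induced, and transcripts below median
  expression are excluded from such analyses upstream. Uninduced genes
  span U(4, 12).
* **pERK scenarios**: sustained at 3.89 log2 units; pulse with a 10-min
  shutdown timescale after pulse end; transient peaking at 5.43 at 10 min.
* **Decay series**: times {0, 30, 60, 120, 240, 480} min, 61 long-lived
  reference transcripts modelled as stable over the window (their real
  counterparts, half-life > 16 h, decay slightly and would bias half-lives
  upward by a few percent), optional linear log2 drift emulating
  library-size artefacts.

Limitations the benchmarks inherit: noise is Gaussian with exactly the
modelled variance (no outliers, no probe effects), the cycloheximide arm
zeroes `k` rather than modelling mediator kinetics, replicates are
independent (no batch structure), and secondary-gene behaviour under
translation block is idealized. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not performance on real arrays; cohort numbers from the original
microarray study (189 induced genes, 102 primary, class medians 53/160/204
min, prediction errors of 18–21%) require those external data and are
documented rather than asserted.

## Problem sizes and determinism

Benchmark sizes: 10,000 genes (200 induced) for the caller; 200 genes for
parameter recovery (9 time points × 3 replicates, noise SD 0.1); 500 genes
for selection calibration; 60 genes (20 per class) for classification;
1,000 draws for the half-max property; 100 random inputs for the solver
oracle. Every stochastic step — generator, multi-start fitting, SD-filter
sampling — takes an explicit seed (package default 20170503), and
generator output is byte-identical for a fixed seed.
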