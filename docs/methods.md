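# Methods

This note documents the models, the generative assumptions behind the
cohort simulator, the numerical choices, and the known limitations of
`immersim`.

## Session metrics

A session trace is the associate's 1 Hz Immersion series from the customer
greeting (t = 0) to departure (T). Four statistics summarise it: the
discrete sum (total Immersion), the mean, the peak-over-threshold cut-off
`M = median + 0.5·sd` (sample SD, n−1 denominator; even-length medians are
midpoints of the central order statistics), and the peak fraction — the
share of total Immersion carried by samples strictly above `M`. Ties at
exactly `M` are excluded; the statistic is invariant to rescaling of the
signal and to reordering of the samples, and lies in [0, 1).

Numerical choices:

* The integral over the session is evaluated as a plain 1 Hz sum — the
  platform emits a single 1 Hz stream, so no interpolation is warranted. At
  fixed 1 Hz, "sum" and "time-integral" differ only by a 1 s factor that
  cancels in the peak fraction.
* What accumulates above the threshold is the full signal value. The
  indicator (time share above threshold) and the excess over the threshold
  are exposed as named variants for sensitivity analysis; only the
  value-sum variant produces fractions near 0.24–0.26 when session means
  are near 4.4, the empirically observed regime.
* Signal drop-outs of up to 5 s are forward-filled with the last observed
  value; longer gaps invalidate the session. A session needs at least 10
  samples for a stable SD.
* The threshold is computed per session, i.e. the baseline is the session
  itself, not a longer history.

## Choice model

The two-good log-utility problem `max e·ln c₁ + ln c₂` subject to
`p(c₁+c₂) ≤ M` is Cobb–Douglas; its optimum is the expenditure share
`p·c₁* = M·e/(1+e)`, independent of the price level. A second variant,
`M·e/(p+e)`, is kept available because it appears in print in this
literature, but it is dimensionally inconsistent with the derivation (an
independent grid-search maximiser sides with the share form whenever
p ≠ 1). The package defaults to the derived form and the simulator uses
p = 1 as numeraire, where the two coincide. `e = 0` is accepted and flagged
as a corner solution; dwell is linked to the experience multiplier through
a simple proportionality `dwell = κ·e` (κ in minutes per unit e).

## Cohort simulator

The simulator is the ground truth against which every downstream stage is
tested. Each session draws a latent experiential value
`e ~ LogNormal(μ_e, σ_e)` and derives:

* **dwell** `= κ·e·exp(ε)`, ε ~ N(0, 0.30²), floored at 1.5 min — the
  proportionality of experience value and time, with multiplicative noise
  producing the observed heavy right tail (WS dwell SD ≈ its mean);
* **purchase incidence** ~ Bernoulli(logistic(β₀ + β₁·e)) with a shared
  slope β₁ = 0.9 and store-specific intercepts (−0.85 WS, −1.05 MS),
  interpreted as store-level conversion propensity; the slope sets how
  discriminable purchasers are from the physiologic/behavioural signal,
  the intercepts pin the two stores' purchase frequencies (≈ 0.73 / 0.52);
* **purchase amount** (given incidence) `= M·e/(1+e)·exp(η)`,
  η ~ N(0, 1.15²) — the model's expenditure share at p = 1 with log-normal
  noise, giving zero-inflated, heavy-tailed spending (occasional
  multi-thousand-dollar purchases over means of ~$140–270);
* **covariates**: age ~ N(store mean, store SD) clipped to [18, 90];
  female/loyal per the observed store rates; companion rates are not
  published, so plausible values (0.45 WS, 0.35 MS) were fixed once.

### Trace process

The associate trace is a stationary AR(1) baseline (mean ≈ 4.2, marginal SD
0.07, coefficient 0.85) plus half-sine burst episodes arriving as a Poisson
process (durations exponential with mean 6 s, clipped to [4, 45] s;
amplitudes ≈ 1 Immersion unit with log-normal spread). The burst *arrival
rate* carries the e-dependence through a gentle log-linear gain
`1 + 0.28·ln(e/3)` (floored at 0.3); the amplitude is deliberately *not*
e-scaled.

This architecture is the result of an explicit design analysis of the peak
statistic. For a near-Gaussian trace the expected peak fraction is ≈ 0.31
regardless of scale, *above* the empirical 0.24–0.26 band; adding sparse
bursts initially *lowers* the fraction (they inflate the median + 0.5·SD
threshold faster than they add above-threshold mass), so a scheme in which
both rate and amplitude grow with e is non-monotone in e over realistic
ranges. With a small baseline SD and fixed amplitude, the threshold is
burst-dominated, the cut on burst samples becomes amplitude-invariant, and
the peak fraction rises monotonically with the burst time-fraction — i.e.
with e — across both stores' e-ranges. Consequently, ablating the bursts
does not drop the peak fraction toward zero: it returns it to the Gaussian
level (≈ 0.32) and removes its e-dependence, which is what the ablation
test asserts.

Peak Immersion — not average Immersion — is thereby the monotone physiologic
correlate of e, consistent with peak-over-threshold statistics being the
better behavioural predictor for long recordings.

### Calibration

Store profile defaults were calibrated once, by simulation at large n,
against the published store summaries: dwell means ≈ 32.2 / 14.7 min,
purchase frequencies ≈ 0.73 / 0.52, session-mean Immersion ≈ 4.42 / 4.49,
and mean peak fractions ≈ 0.242 (WS) / 0.255 (MS). Two aspects of the
observed data are *not* reproduced: the within-store session SD of the peak
fraction comes out near 0.05 (observed: 0.017 WS / 0.032 MS) — tightening
it further would destroy the peak–dwell correlation the mediation stage
needs — and simulated amounts can exceed the observed WS maximum
($2,734) because the log-normal amount tail is unbounded. Mean purchase
amounts are matched only loosely (they are extremely noisy at n = 56).
Passing tests therefore demonstrate correctness of the analysis chain under
a faithful *generative idealisation*, not distributional identity with the
field data.

The pipeline-wide default seed is 1969. A single global seed is expanded
into per-stage child seeds via `numpy.random.SeedSequence.spawn` in a fixed
order, so any stage can be rerun in isolation with unchanged randomness.

## Tabular synthesis

The expansion step refits the session table as a chain of parametric
conditionals in a fixed visit order (age → female → loyal → companion →
avg Immersion → peak Immersion → dwell → purchased → amount), one chain per
store: normal-linear models for continuous variables (dwell and amount on a
log1p scale for their heavy tails), near-unpenalised logistic regressions
for binaries, and the amount gated by the incidence flag (fitted on
purchasers only, forced to zero otherwise) so zero-inflation is reproduced
in rate. Sampling proceeds sequentially from the fitted chain;
n = 10,000 per store is the default expansion size.

Fidelity is summarised per variable by the two-sample Kolmogorov–Smirnov
test (asymptotic p) for continuous variables, the rate difference for
binaries, and a quantile-grid MSE — the mean squared difference of the two
tables' 1st–99th percentile grids — which is independent of the two sample
sizes and exactly zero for identical tables. Because the chain is fitted to
the very table it is compared against, KS p-values are conservative (they
concentrate near 1 when the parametric forms fit), which is precisely the
operating regime of a synthesis-fidelity check.

## Mediation

Two OLS equations — mediator on predictor, outcome on predictor plus
mediator, covariates optionally in both — estimated per store. OLS is the
Gaussian maximum-likelihood estimator here, so no iterative optimiser is
needed. The indirect effect is a·b, the total effect c′ + a·b equals the
predictor-only slope exactly (nested linear fits), and inference for the
indirect effect uses a percentile bootstrap over row resampling (5,000
replicates by default; the closed-form Sobel z is reported alongside). The
default outcome is the continuous purchase amount; the loyal/companion
covariates enter both equations when enabled. A degenerate (collinear)
design is rejected with the offending columns named.

## Purchase classification

The label is `purchase_usd > 0`. Three heterogeneous tree learners — a
random forest and two independent gradient-boosting implementations
(XGBoost and LightGBM) — are each tuned by an exhaustive inner grid search
(3-fold, accuracy) on the outer training fold, and their predicted
probabilities are averaged with equal weights; a scaled logistic regression
is always run as the baseline. The outer loop is a stratified 5-fold CV
(stratification protects the minority class at purchase rates of
0.5–0.75); pooled metrics aggregate the out-of-fold predictions as
confusion counts, not fold means. Metrics: sensitivity, specificity,
accuracy at a 0.5 threshold, rank AUC, and the Brier-style MSE of
probabilities. A 50/50 tune-then-holdout variant is provided
(`holdout_evaluate`) for designs that train on one half of an expanded
table. Classification of the discretised label is the default; the grids
are small by design (two to three candidates per hyperparameter) so a full
nested CV at n = 2,000–10,000 stays in seconds-to-minutes on one CPU.

## Problem sizes used in the test suite

The shipped tests run the chain at the study's observed scale (31 + 25
sessions with full 1 Hz traces), expand to n = 10,000 per store for the
synthesis/mediation checks, use n = 2,000 sessions for classifier
calibration, 100 seeded replicates for bootstrap-coverage and
KS-fidelity rates, and 1,000 random traces for metric/oracle equivalence.
These sizes give stable pass/fail behaviour at desk scale while exercising
every stage at the same n as the full analysis where it matters
(n = 10,000).

## Limitations

* The Immersion index itself is a proprietary transform of cardiac data;
  the simulator emulates only its 1 Hz summary statistics, not its
  internals, and no PPG-to-Immersion conversion is attempted.
* The latent experiential value e is not identified from behavioural data
  here; it is a simulation construct (only its monotone links are tested).
* Mediation estimates carry the usual caveat: the decomposition is causal
  only under the model's own no-unmeasured-confounding assumptions; no
  sensitivity analysis is provided.
* The synthesizer is strictly parametric (no CART/nonparametric mode) and
  its visit order is fixed a priori; different orders give slightly
  different joint distributions.
* Printed-summary reconstructions use pooled-variance t-tests; Welch-style
  corrections are intentionally not applied, as the pooled form is what the
  published statistics correspond to.
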