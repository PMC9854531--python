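# Methods

## The task

The environment is a two-block predictive-inference task on a 0–50
estimation bar.  On each trial the agent reports an estimate, then observes
a target value drawn from a Gaussian with SD 1.7 whose mean follows one of
two fixed 100-trial schedules:

* **gradual block** — the mean moves in 5-unit steps every ten trials
  (25 ×20, 30, 35, 30, 25, 20, 15, 20, 25).  Trials inside the four moving
  segments (1-based 21–30, 41–50, 61–70, 81–90) are *gradually changed*; the
  rest are the block's *fluctuation* baseline.
* **abrupt block** — the mean jumps by 10 units every twenty trials
  (25 ×30, 35 ×20, 25 ×20, 15 ×20, 25 ×10).  Only the first trial of each
  new distribution (trials 30, 50, 70, 90) is *abruptly changed*.

Targets are clipped to the bar, rounded to 0.1 (the bar's click resolution
is unknown; one decimal keeps the Gaussian structure at bar resolution).
Inside the gradual block consecutive targets are constrained to differ by at
most `max_step = 6` units via reject-and-resample, so that no sampling
accident produces a jump comparable to the abrupt block's engineered ~10;
the abrupt block is deliberately unconstrained.  Trend segments realize
their "fluctuating upward/downward trend" by sorting the segment's i.i.d.
draws and adding N(0, 0.5) jitter — this preserves the segment's marginal
distribution exactly (the KS property in the tests), at the cost of
collapsing trial-to-trial target dispersion inside trend segments (see
*Limitations*).

## Generative agents

Agents are delta-rule learners.  With prediction error
`PE_t = target_t − estimate_t` and update
`update_t = estimate_{t+1} − estimate_t`, the generated update is

    update_t = sign(PE_t) · max(0, m(|PE_t|)) + ε_t,   ε_t ~ N(0, σ_u)

with two mean functions `m`:

* **condition-wise (default)** — `m(|PE|) = α_c + λ_c |PE|` with the four
  condition composites α = (1.017, 1.039, 0.756, 2.548) and
  λ = (0.528, 0.533, 0.595, 0.693) for (fluctuation-gradual, gradual,
  fluctuation-abrupt, abrupt).  The frog-in-the-pan pattern — much greater
  sensitivity to the abrupt change — lives in the larger abrupt intercept
  and slope.
* **segmented** — `m(|PE|) = β0 + β1 |PE| + δ max(0, |PE| − ψ)` with
  β0 = 0.916, β1 = 0.536, δ = 0.536, ψ = 5.337: the learning-rate slope
  doubles once the PE is large enough to be surprising.

The mean function operates on |PE| and is applied with the sign of the PE;
a signed linear rule cannot have a positive intercept in both directions,
and all published descriptives are absolute-value based.  With probability
`p_no_update = 0.05` a trial's update is exactly zero, mimicking the
minority of participants who stick to their estimate even after a surprise;
the probability is a calibration choice applied uniformly (whether real
non-updating was confined to the first abrupt trial is unknowable from the
summaries).  Estimates start at the bar midpoint 25 (equal to the first
segment mean; the first trial's update is undefined anyway) and are clipped
to the bar, with the stored update recomputed after clipping so that
cumulative updates reconstruct estimates exactly (the telescoping
invariant).

Reaction times in the secondary letter task are condition-mean based:
`rt = μ_c + b_i + N(0, 0.35)` seconds with condition means
(0.883, 0.85, 0.855, 1.105) — surprise enters only through the abrupt
condition's larger mean — plus a per-agent intercept `b_i ~ N(0, 0.15)`,
a 2% exponential lapse tail (mean 2 s) that exercises the strict >3 s
exclusion, and a 0.15 s floor.  No mechanistic RT process is claimed.

Between-agent heterogeneity: each agent perturbs the update intercept
(SD 0.3) and slope (SD 0.1).  These spreads are calibration, not published
quantities (no variance components were reported); they were chosen so the
simulated condition SDs bracket the published ones (≈1.6–2.4 target units).
σ_u = 1.5 likewise.  All agents see the same realized target sequences
within a cohort, as participants did; block order is counterbalanced
(even-numbered agents see the abrupt block first) and affects only the
`order` column because each block starts from a fresh midpoint estimate.

## Analysis table

Row *t* pairs `pe_t` with the update made in response to it
(`estimate_{t+1} − estimate_t`); the last trial of each block has no paired
update and is dropped from update models.  Derived columns: `abs_pe`,
`abs_update`, the PE-aligned response `dir_update = sign(pe) · update`, the
per-trial empirical rate `update/pe` (undefined, i.e. NaN, when
|PE| < 1e-9), the non-updating flag, baseline-referenced condition dummies
(gradual-block fluctuation is the reference), and `rt_included`
(strictly greater than 3 s ⇒ excluded; 3.00 s stays in).

Two estimator choices matter and are deliberate:

* **Response = `dir_update`, not `|update|`.**  Taking the absolute value of
  a noisy signed update folds the noise distribution wherever the mean
  update is small, biasing intercepts up and slopes down; regressing the
  PE-aligned update leaves the noise symmetric and the estimators
  consistent.  The two responses coincide exactly in the zero-noise limit
  and almost surely on large-PE trials.  Absolute values are retained for
  all descriptive summaries.
* **Non-updating trials are excluded from model fits** (default
  `drop_nonupdating=True`).  Updates of exactly zero form an identifiable
  point mass — under the noise model a continuous update is never exactly
  zero — and mixing them into the regression attenuates every coefficient
  by `1 − p_no_update`.  They remain in all descriptives.

## Models

All linear mixed fits use a per-participant random intercept estimated by
exact profiled maximum likelihood (`frogpan._lmm`): for a fixed variance
ratio the GLS solution is closed-form through per-group sums, leaving a
one-dimensional likelihood search.  One fit on a 21,800-row cohort takes a
few milliseconds, which is what makes the breakpoint profile cheap.  The
implementation is verified against statsmodels `MixedLM` (ML) to numerical
precision in the suite.  A saturated (zero-residual) fit is detected and
returns the exact OLS coefficients with a degenerate flag instead of a
divergent likelihood.

* **Condition model** — `dir_update ~ abs_pe * condition`; the composite
  learning rate of condition *c* is the shared slope plus its interaction.
* **Quadratic probe** — `dir_update ~ abs_pe + abs_pe²`; the squared term's
  sign and Wald z act as the nonlinearity detector.
* **Segmented model** — `dir_update ~ abs_pe + max(0, abs_pe − ψ)` profiled
  over a ψ grid (default 1.0–12.0 by 0.05, covering the observed gap
  between the gradual (~2.5) and abrupt (~10.5) PE regimes), then polished
  by a damped Muggeo linearization step (the gap covariate −1[x > ψ] whose
  coefficient over δ̂ is the breakpoint correction; steps are halved until
  the profile likelihood does not decrease).  Candidates with fewer than 10
  points above them are skipped; a boundary maximizer and a flat profile
  (< 0.5 log-likelihood units of relief across the grid) are flagged, ties
  resolve to the smallest ψ.  The ψ interval comes from profile-likelihood
  inversion (χ²₁ threshold, linear interpolation between grid points) or a
  participant-level nonparametric bootstrap.  Random changepoints per
  participant are *not* fitted — random intercepts only — and the recovery
  harness quantifies the adequacy of that simplification.
* **Threshold logistic** — `1[abs_pe > threshold] ~ condition`, plain
  logistic MLE (threshold defaults to the estimated ψ).  Condition cells
  that are empty or pure raise a quasi-separation flag: abrupt-trial PEs
  exceed any mid-range threshold almost surely, so the abrupt odds ratio is
  reproducible only as sign and ordering, never as a stable magnitude.
* **RT model** — `rt ~ condition` on included rows.

Inference on fixed effects is Wald with a normal reference (no
Satterthwaite degrees of freedom); p-values are descriptive.  Because the
random-effects structure is intercepts-only while the generator has
between-agent slope heterogeneity, model-based SEs for slope terms are
anti-conservative; the fit objects therefore also expose CR1 cluster-robust
SEs (`bse_robust_`), which the recovery harness uses for interval coverage
and the calibration tests use for the quadratic detector.

Convergence: tolerance 1e-10 on the scalar profile optimizer, 200
iterations; non-convergence is flagged on the result, never silent.

## Parameter recovery

`run_recovery` simulates cohorts from known parameters, refits the matching
model and tabulates bias, RMSE and 95% interval coverage per parameter,
logging every replicate seed.  Zero-noise cohorts refit to the generative
coefficients to ≤1e-6 (grid/refinement precision for ψ); at the default
noise with 109 agents and 10 replicates, learning rates and δ recover
within a few percent and ψ within ~0.2.

## Problem sizes

Defaults everywhere mirror the study: 109 agents × 2 blocks × 100 trials.
The acceptance script averages 10 replicate cohorts per quantity; the test
suite uses 5–50-agent cohorts for structural checks and full-size cohorts
where an acceptance criterion requires them.

## What the simulation does and does not establish

Passing recovery shows the estimators return the parameters of data
generated by their own model family at realistic noise — a necessary check
given the human data are unavailable — not that the models are correct for
human behavior.  Known gaps between the synthetic cohorts and the published
summaries:

* **Gradual-trial |PE| runs low** (~1.8 vs 2.558).  Sorting collapses
  within-segment target dispersion, and delta-rule agents parameterized by
  the fitted composites have effective gain ≈1 at small PEs, so they track
  the near-monotone ramp better than participants did (participants'
  gradual-trial |PE| exceeded even their fluctuation-trial |PE|; the
  simulation reverses that ordering).  Fluctuation-trial |PE| (~2.2) and
  the abrupt regime (~10) are reproduced.
* The per-trial empirical ratio `update/PE` is intercept-dominated at small
  PEs and therefore not monotone across conditions — in the published
  means it is near-equal as well (2.400/2.558 ≈ 9.827/10.521).  The
  frog-in-the-pan ordering is a statement about fitted composite learning
  rates, and holds in every default replicate.
* RT generation is descriptive (condition means), so RT fits recover
  inputs rather than test a surprise mechanism.
* Letter-task accuracy, payment, practice block and presentation-order
  effects are not modelled; responses are always correct.
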