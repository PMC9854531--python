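# frogpan

Simulation and inference for **surprise-gated belief updating** in a
two-block changepoint estimation task — the "frog-in-the-pan" effect, where
learners are far more sensitive to one abrupt change than to the same total
change delivered gradually.

The package is for computational cognitive scientists who want a
closed-loop, fully synthetic replica of this experimental paradigm: a
generator of the task's target schedules, a generative cohort of delta-rule
agents (estimates *and* reaction times), and the complete trial-level
inference battery, validated end to end by parameter recovery.

## The model

On trial *t* an agent holds estimate *Eₜ*, observes target *Tₜ*, and forms
the prediction error and update

    PEₜ = Tₜ − Eₜ,      updateₜ = Eₜ₊₁ − Eₜ,      updateₜ ≈ λ · PEₜ

where λ is the learning rate of a delta (Rescorla–Wagner) rule.  The
central hypothesis is that λ is not constant but gated by surprise: in the
**segmented** form

    update = β₀ + β₁·|PE| + δ·max(0, |PE| − ψ)

the slope jumps by δ once the absolute prediction error exceeds a
breakpoint ψ (defaults β₀ = 0.916, β₁ = 0.536, δ = 0.536, ψ = 5.337).  In
the **condition-wise** form each change mode *c* (fluctuating/gradual/
abrupt) has its own composite intercept and rate,
`update = α_c + λ_c·|PE|`, with λ ranging from 0.528 (gradual baseline) to
0.693 (abrupt).  Reaction times in a secondary letter task index surprise:
abrupt-change trials carry a ~0.22 s slowdown, and RTs above 3 s are
excluded.

The inference battery refits all of this from trial tables with
per-participant random intercepts (exact-ML linear mixed models implemented
in `frogpan._lmm`, cross-validated against statsmodels): a condition × PE
interaction model, a quadratic nonlinearity probe, the segmented breakpoint
model (profile likelihood over a ψ grid + Muggeo refinement, profile or
bootstrap CI), a threshold logistic for exceedance odds, and the RT model.

## Worked example

```python
import frogpan as fp

# 109 agents, both canonical blocks, full noise model
cohort = fp.simulate_cohort(seed=7)                  # 21,800 trial rows
table = fp.build_analysis_table(cohort)

m = fp.fit_condition_lr_model(table)
for cond, (lr, se) in m.composite_lr_.items():
    print(f"{cond:22s} {lr:.3f} ({se:.3f})")

seg_table = fp.build_analysis_table(
    fp.simulate_cohort(update_params=fp.UpdateRuleParams.segmented_defaults(),
                       seed=7))
seg = fp.fit_segmented_model(seg_table)
print(f"psi {seg.psi_:.3f} ci {seg.psi_ci_} delta {seg.delta_:.3f}")

rt = fp.fit_rt_model(table)
print(f"rt intercept {rt.intercept_:.3f} "
      f"abrupt offset {rt.offsets_['abruptly_changed']:.3f}")
```

prints

```
fluct_gradual          0.545 (0.012)
gradually_changed      0.542 (0.017)
fluct_abrupt           0.581 (0.010)
abruptly_changed       0.699 (0.039)
psi 5.250 ci (5.004, 5.613) delta 0.528
rt intercept 0.906 abrupt offset 0.219
```

Reading: the composite learning rate on abruptly changed trials (0.699) is
far above the gradual-change rate (0.542) — the frog-in-the-pan ordering —
and the refit breakpoint (ψ̂ ≈ 5.25, δ̂ ≈ 0.53) recovers the generative
surprise threshold from a noisy cohort.  The abrupt RT offset (+0.219 s)
recovers the surprise slowdown.

The same workflow is available from the shell:

```bash
frogpan simulate --n-agents 109 --seed 7 --out cohort.csv
frogpan analyze cohort.csv --model condition --model segmented --out fits.json
frogpan recover --mode segmented --replicates 10 --seed 1
frogpan run --seed 7 --out-dir run/        # full pipeline + report.md
```

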