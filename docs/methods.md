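# Methods

## The generating process

`trapbias` simulates pitfall-trap counts for a spring-active species over a
100-day season split into five 20-day intervals. The design is 3 treatments ×
5 replicate plots × 4 traps (300 trap-interval observations). Counts are
Poisson log-normal: one normal random effect per replicate plot (log-scale SD
`site_sd`) and one per trap (`trap_sd`) multiply a fixed mean

```
λ(t, i) = mean_catch_t1 · multiplier_t · proportion_i
```

per trap and interval. The random effects are drawn once per season and held
constant across intervals — a plot or trap has one persistent peculiarity
(shade, slope, drainage), and nothing in the design identifies an
interval-varying effect. Seasonality enters only through the fixed activity
profile; there is no interval-level random effect, no weather process and no
spatial correlation between traps. These are deliberate simplifications: the
simulation isolates the interaction of seasonal detectability with unequal
effort, so conclusions about real data transfer only insofar as that
interaction dominates.

### Parameters

| parameter | default | units / meaning |
|---|---|---|
| `mean_catch_t1` | 1.47 | expected season catch per trap, treatment 1 |
| `treatment_multipliers` | (1, 2, 4) | relative abundance of the treatments |
| `site_sd`, `trap_sd` | 0.14, 0.30 | log-scale SDs of plot and trap effects |
| seasonal profile | 25/49/13/9/4 % | share of the season's catch per interval |
| design | 3 × 5 × 4 × 5 | treatments × replicates × traps × intervals |

The defaults describe a realistic spring-active carabid at moderate density;
`PARAMETER_SETS` adds six perturbations scaling the mean or each variance
five-fold up or down, spanning sparse-to-abundant species and calm-to-noisy
designs.

### The mean of the process

No `−σ²/2` correction is applied to the log-normal effects (the standard GLMM
formulation), so the realized expected catch exceeds the nominal λ by
`exp((site_sd² + trap_sd²)/2)` ≈ 1.056 at the default SDs. The package keeps
both scales explicit: `expected_cell_catch` reports the nominal
(design-table) expectation, while `true_treatment_values` defaults to the
realized process mean and returns the nominal value with `nominal=True`. Bias
is measured against the realized mean, because that is the actual expectation
of the data the models see; measuring against the nominal value would award
every model a constant spurious bias of +0.164 (summed over three treatments)
that says nothing about how the model handles seasonality or unequal effort.
A test asserts the ≈5.6 % inflation against the closed-form log-normal moment.

## Trap loss

Losses are drawn exactly: `round(fraction × 80)` observations sampled without
replacement from the eligible 80-point block (high-catch: treatments 2–3 ×
intervals 1–2; low-catch: treatments 1–2 × intervals 4–5), giving exactly
15/30/45/60 points at the four severities (5–20 % of the whole design). The
random scenario removes the same totals from all 300 points. Per-observation
Bernoulli thinning would only approximate these totals. Lost observations are
flagged, not deleted; every downstream computation excludes flagged rows from
both counts and trap-days.

## The five models and their common scale

M2–M5 are fitted at the replicate × interval grain with abundance summed over
surviving traps, because the trap count enters as `offset(ln n_traps)` — a
per-row effort term that would be meaningless at trap grain. Rows whose traps
were all lost are dropped (their log offset is undefined) and counted.

Gaussian offsets are exact: with a known coefficient of one the offset is
subtracted from the response before OLS. The negative binomial GLMs (log
link, variance `μ + μ²/θ`) estimate θ by alternating between the IRLS
coefficient step at fixed θ and the maximum-likelihood θ at fixed means
(Newton on the score equation, seeded by a coarse bounded search), stopping
when θ changes by less than 1e-8 (relative above 1, absolute below) or after
50 outer iterations. θ is confined to [1e-3, 1e6]; hitting the upper cap
means the data carry no excess dispersion (the Poisson limit) and is flagged
but treated as converged. An independent test confirms the alternation finds
the joint maximum by exhaustive grid search plus polish on a 12-row fixture.

Each model's treatment predictions are normalized to one scale — expected
catch per 100 trap-days of a full-effort replicate — by evaluating the linear
predictor per interval at 4 traps and the interval's own offset or factor
level, back-transforming per interval (`exp(η) − 1` for the `ln(y+1)` models,
`exp(η)` for the NB models), summing the five intervals and dividing by 4.
Summing before the (nonlinear) back-transformation would be an alternative
convention for the factor models; the per-interval convention was chosen
because it treats M2/M3 and M4/M5 identically and makes the season total the
sum of interval predictions, as it is in the data. A back-transformed
prediction at or below zero (possible for the `ln(y+1)` models at very low
catches) is floored at 1e-12 and flagged.

The `ln(% activity)` offset uses the profile as printed percentages (25, 49,
…); the factor-of-100 difference from proportions is absorbed by the
intercept and cancels from treatment contrasts and from the season-scale
predictions.

## Bias evaluation and the grid

Per fitted model, bias is `ln(prediction_t) − ln(truth_t)` per treatment,
summed over the three treatments; `run_grid` averages it over 100 simulated
datasets per condition (the study size; one condition takes well under a
minute on one CPU) and reports the Monte-Carlo standard error next to every
mean so ordering claims can be judged against sampling noise. The same 100
datasets are reused across scenarios and loss levels, so level-to-level
differences are paired. A dataset where any treatment loses all rows, or
where the NB loop does not converge, is recorded as failed and excluded from
the means; a cell with >10 % failures is marked unreliable. Box-whisker
quantiles (median, quartiles, whiskers at 1.5 IQR clipped to the data) of the
back-transformed predictions are emitted for plotting; figure rendering
itself is a thin optional layer.

Derived randomness is hierarchical and replayable: dataset *i* of a batch
uses a seed hashed from `(master_seed, i)` via `numpy.random.SeedSequence`,
and each loss draw hashes the master seed with the parameter-set, scenario,
level and simulation indices, so any single cell can be reproduced without
rerunning the grid.

## Known limitations

- The traditional model's bias curve passes through zero as loss increases in
  the low-catch scenario (its negative transformation bias cancels against
  the loss-induced overestimation), so at one loss level its *absolute mean*
  bias can dip below the negative binomial models' — an artifact of sign
  cancellation, not evidence the method is reliable there; its spread remains
  far larger.
- The `ln(y+1)` Gaussian models are evaluated exactly as practitioners use
  them; their poor performance at low counts is the finding, not a defect of
  the fitters.
- The NB models are deliberately mis-specified relative to the Poisson
  log-normal generator; their small residual bias (≈ −0.05 summed at the
  default parameters, more negative at low means where the log-scale
  estimator's Jensen gap grows) reflects that mismatch and finite samples.
- Quasi-Poisson, mixed-effects and zero-inflated variants, structured losses
  (whole-replicate vandalism), and refitting of any field data are out of
  scope.
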