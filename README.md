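# trapbias

Seasonal variation in detectability plus unequal sample sizes can badly bias
relative-abundance estimates from count data. The canonical case is pitfall
trapping of a spring-active carabid beetle: most of the season's catch arrives
in the first 40 days, and when traps are lost (vandalism, flooding, animals)
the surviving trap-days are no longer comparable between treatments. `trapbias`
is a simulation laboratory for exactly this problem: it generates clumped
seasonal trap catches, removes traps in structured ways, fits five competing
estimation models, and measures how far each model lands from the truth.

It is aimed at quantitative ecologists who analyze trap or survey counts and
want to see — or teach — what standardizing catch "per 100 trap-days" does to
an unbalanced design, and why count-appropriate models with effort offsets fix it.

## The simulation and the five models

Data are drawn from a Poisson log-normal process over a 3 treatments × 5
replicate plots × 4 traps design observed over five 20-day intervals (300
observations). The count of trap *k* of replicate *r* in interval *i* is

```
y ~ Poisson(λ·exp(b_r + c_k)),   λ = m·g_t·p_i,
b_r ~ N(0, σ_site²),  c_k ~ N(0, σ_trap²)
```

with per-trap season mean `m = 1.47` individuals, treatment multipliers
`g = (1, 2, 4)`, seasonal activity shares `p = (0.25, 0.49, 0.13, 0.09, 0.04)`
and random-effect SDs `σ_site = 0.14`, `σ_trap = 0.30` (plus six perturbed
parameter sets scaling the mean or the variances five-fold up or down).
Trap loss removes 5–20 % of the design, concentrated where the expected catch
is highest (treatments 2–3 × intervals 1–2) or lowest (treatments 1–2 ×
intervals 4–5), or at random.

Five analyses are fitted to every manipulated dataset and their predictions
put on one scale (catch per 100 trap-days at full effort):

| id | model |
|----|-------|
| M1 | traditional standardization: `ln(catch/100 trap-days + 1) ~ Treatment`, Gaussian |
| M2 | `ln(y+1) ~ Treatment + offset(ln % activity) + offset(ln traps)`, Gaussian |
| M3 | `ln(y+1) ~ Treatment + Interval + offset(ln traps)`, Gaussian |
| M4 | `y ~ Treatment + offset(ln % activity) + offset(ln traps)`, negative binomial GLM |
| M5 | `y ~ Treatment + Interval + offset(ln traps)`, negative binomial GLM |

The comparison metric is the mean bias of the treatment means on the log
scale, `Σ_t [ln(prediction_t) − ln(truth_t)]`, averaged over simulations.

## Worked example

```
python examples/five_models_one_dataset.py
```

simulates one field-parameter season, removes 20 % of the design during peak
activity in the high-abundance treatments, and fits all five models:

```
true catch per 100 trap-days: [1.55 3.11 6.21]
model                   T1      T2      T3   summed log bias
M1_trad_normal        1.29    1.69    4.40            -1.142
M2_offset_normal      1.94    4.35    7.06             0.689
M3_factor_normal      1.43    3.22    5.71            -0.128
M4_offset_negbin      1.46    3.27    6.49             0.035
M5_factor_negbin      1.46    3.42    6.69             0.108
```

The traditional method (M1) recovers only 1.69 of the true 3.11 for
Treatment 2: the lost traps took catch-rich trap-days with them, but the
standardization divides by the surviving trap-days as if all days were equal.
The negative binomial models (M4, M5), which see effort and seasonality as
offsets, land within a few percent of the truth. `examples/bias_grid.py` runs
the full grid (scenarios × loss levels × models, 100 simulations) and writes
the bias summaries and box-whisker quantiles as CSV.

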