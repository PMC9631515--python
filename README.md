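# glucomod

Postprandial glucose kinetics from meal-response data: the insulin-based
**oral minimal model** (OMM) and a **glucose-only model** (GOM) that
infers insulin sensitivity, insulin-action dynamics and meal-related
glucose appearance from glucose samples alone.

## Why

Minimal-model analysis of a meal response normally needs plasma insulin
measurements, which are expensive, assay-dependent and impractical
outside a clinical research unit.  The glucose-only model keeps the
two-state minimal-model structure

```
dG/dt = -G·X - p1·(G - Gb) + [RaLN(t) + Rap(t)] / V
dX/dt = -p2·(X - SG·Z(t)),      Z = (G-Gb)/(1+e^{-α(G-Gb)}) + β·RaLN(t)/V
```

but replaces the measured supra-basal insulin `I(t) − Ib` with the
surrogate drive `Z` built from glucose itself and from the meal's
glucose-appearance function `RaLN` — a two-component log-normal curve
with fixed total mass `A` determined by the carbohydrate dose.  The
parameter `SG` (min⁻¹ per mg/dL) takes the structural place of the
insulin sensitivity `SI` and is expected to carry the same information.
Nine free parameters per meal response
(`p1, p2, SG, β, T1, T2, W1, W2, RH`) are estimated with a
variational-Laplace Bayesian scheme under median/CV log-normal priors;
consecutive meals of a day are chained through their initial states and
persisting absorption.  The OMM (piecewise-linear GA input, measured
insulin) is implemented alongside as the validation reference, with
residual, RMSE, SG↔SI and confidence-band-overlap (OL) comparisons.

See `docs/methods.md` for the full model and estimation description.

## A worked example

```python
import glucomod as gm

subject = gm.draw_subject(seed=42, meal_type="STAND")   # known truth
day = gm.make_day(subject, noise_cv=0.02, seed=7)       # 3-meal study day
fit = gm.fit_meal(day.meals[0], model="gom", seed=0)    # glucose-only fit

print(round(gm.rmse(fit, day.meals[0]), 2))             # 1.57  (mg/dL)
print(f"{fit.medians['sg']:.3g} ({100*fit.cvs['sg']:.1f} % CV)")
# 0.000264 (11.9 % CV)   vs. the generating truth 0.00027
```

The fit describes the 17 scheduled glucose samples to 1.57 mg/dL RMSE
and recovers the sensitivity surrogate `SG` within its ~12 % posterior
CV of the generating truth — no insulin values were used.  The same
script is `examples/02_fit_single_meal.py`; the other examples cover
forward simulation, full-day chaining, GOM-vs-OMM validation and a
small recovery experiment, each printing the numbers it computes.

A thin CLI wraps the same functions:

```bash
glucomod generate --n 5 --seed 1 --out cohort.csv   # synthetic cohort + truth
glucomod fit --data cohort.csv --model gom --out fits/
glucomod validate --data cohort.csv --out validation/
glucomod recover --n 20 --seed 7 --out recovery/
```

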