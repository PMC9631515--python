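# Methods

## The models

Both models describe a single 240-minute postprandial glucose response
with two states: plasma glucose `G` (mg/dL) and a remote-compartment
glucose-lowering action `X` (min⁻¹),

```
dG/dt = -G·X - p1·(G - Gb) + [Ra(t) + Rap(t)] / V        G(0) = G0
dX/dt = -p2·(X - S·drive(t))                              X(0) = X0
```

`p1` (min⁻¹) is glucose effectiveness (insulin-independent
self-normalisation), `Gb` the basal glucose, `V` (dL/kg) the glucose
distribution volume per body weight, `Ra` the meal-related glucose
appearance (GA, mg/kg/min) and `Rap` the persisting appearance from an
earlier meal.  The models differ in what drives the action:

* **Oral minimal model (OMM).**  `drive = I(t) - Ib`, the measured
  supra-basal insulin, with `S = SI` (min⁻¹ per mU/L) the insulin
  sensitivity.  The GA input `RaPL` is piecewise linear through the
  origin and seven breakpoints at adjustable heights with a fixed
  trapezoidal AUC.
* **Glucose-only model (GOM).**  The insulin input is replaced by a
  surrogate built from observables:
  `drive = Z = Zpos(G) + β·RaLN(t)/V`, with
  `Zpos = (G - Gb) / (1 + exp[-α(G - Gb)])` a sigmoid-gated supra-basal
  excursion and `RaLN` a two-component log-normal GA function.
  `S = SG` (min⁻¹ per mg/dL) replaces insulin sensitivity and is the
  parameter expected to carry the insulin-sensitivity information; `β`
  (min) couples absorption into the drive so the action can stay
  elevated after glucose has returned to basal, mimicking slow insulin
  decay.

The GA functions conserve the meal mass `A = f·D·1000` mg/kg, where `D`
is the carbohydrate dose (g per kg body weight) and `f` the
bioavailability fraction.  `RaLN` splits `A` between an early component
(peak at `T1` min, width `W1`) and a late one (`T2`, `W2`) with mixing
fraction `RH ∈ (0,1)`; each component is a modified log-normal density
whose mode falls exactly at its `T` parameter.  `RaPL` realises the
fixed-AUC constraint by solving the seventh height in closed form from
the first six (negative solutions mark a proposal infeasible).

Properties worth knowing:

* `Zpos` is **not** hard-clipped at zero.  Its minimum sits at
  `α(G - Gb) ≈ -1.28` (about 13 mg/dL below basal for `α = 0.1`), with
  value ≈ −2.8 mg/dL; below that it saturates back towards zero.  It is
  therefore strictly increasing in `G` only above `Gb − 13` mg/dL.
* `(G, X) = (Gb, 0)` is an equilibrium of both models when all GA
  inputs vanish.
* `X` can dip marginally below zero after sub-basal excursions (`Z`
  briefly negative); when such a state is carried into the next meal of
  a chained day its initial value is clamped to the admissible `X0 ≥ 0`.

## Fixed constants and defaults

| quantity | default | unit | why |
|---|---|---|---|
| `α` | 0.1 | dL/mg | practically unidentifiable from single-meal glucose data; fixed at the value that best mimics the glucose-insulin relationship |
| `V` | 1.45 | dL/kg | standard minimal-model distribution volume; not estimated |
| bioavailability `f` | 0.9 | – | standard oral-minimal-model fraction of ingested carbohydrate appearing in plasma |
| glucose noise SD | 2 % of value | mg/dL | additive Gaussian measurement error of known SD |
| insulin assay CV | 13 % | – | used when propagating insulin error into the Y_OMM band |
| RaPL breakpoints | 10, 30, 60, 90, 120, 180, 240 | min | seven breakpoints spanning the response, standard OMM practice |
| RaPL persistence tail | linear decay to zero over 60 min after 240 | – | the analytic RaLN tail needs no rule |

Default priors (log-normal, median/CV; `RH` logit-Gaussian matched to
its natural-scale median and CV by quadrature): `p1` 0.02/50 %, `p2`
0.02/50 %, `SG` 5·10⁻⁴/50 %, `β` 30 min/10 %, `T1` 30/50 %, `T2`
90/50 %, `W1 = W2` 0.5/50 %, `RH` 0.5/50 %.  `SG` is deliberately wide
and `β` deliberately narrow: the two covary strongly through `Z`, and
widening both degrades the precision of `SG`, the parameter that
matters.  OMM: `p1`, `p2` as above, `SI` 10⁻³/50 %, free heights
centred on the flat profile `A/235` with CV 50 %.  All priors are
configurable per fit and logged with every CLI run.

## Estimation

A variational-Laplace scheme on the transformed (log/logit) scale:

1. The posterior kernel stacks per-sample Gaussian data residuals
   `(y - G(t;θ))/SD` with per-parameter prior residuals
   `(θ - μ)/σ`; the mode is found by trust-region nonlinear least
   squares (damped Gauss-Newton) with five restarts — the first at the
   prior medians, the rest drawn from the prior under a fixed seed.
   The restart with the lowest cost (highest free energy) wins;
   proposals whose simulation fails or whose AUC constraint is
   infeasible are rejected through a large residual sentinel.
2. The posterior is approximated as Gaussian around the mode with
   covariance from a central-difference Hessian of the negative log
   joint (step 0.05 prior-SD per coordinate); if that Hessian is not
   positive definite the Gauss-Newton curvature `JᵀJ` is used instead.
   The two coincide at zero residuals and for the prior-only problem.
3. Posterior medians and CVs are read off the implied log-normal
   (logit-normal for `RH`) marginals, so the reported median/CV
   round-trip exactly with the internal Gaussian mean/SD.
4. The Laplace free energy `log p(y, θ̂) + d/2·log 2π − ½ log det H` is
   reported as the evidence approximation.

ODE solves use adaptive RK45 with `rtol 1e-6`, `atol 1e-8`; the
non-smooth points of piecewise-linear GA inputs (and of persisting
tails) are inserted as integration segment boundaries so the error
control is not defeated by kinks.  Halving the tolerance moves a
240-min endpoint by < 10⁻⁴ mg/dL.

**Chaining.**  The three meals of a day are fitted in order.  Basal
glucose is the mean of the −15, 0, 2 and 5-minute samples of the first
meal and is held constant all day.  Meal 1 starts from the observed
glucose with `X0 = 0` and no persisting GA; each later meal inherits
`(G0, X0)` from the previous posterior-median trajectory evaluated at
the meal time and accumulates the fitted GA functions of all earlier
meals as `Rap`.  A failed fit is recorded and the chain continues from
observed initial conditions.

**Cross-check.**  On one synthetic meal, the Laplace posterior median
of `SG` agrees with a long-run affine-invariant MCMC sample of the same
kernel to within 10 % (test-suite cross-check; MCMC is not part of the
default path).

## Confidence bands and the OL statistic

Time-profile uncertainty (GA curves, insulin-action drives
`Y_GOM = SG·Z`, `Y_OMM = SI·(I − Ib)`) is propagated by seeded
Monte-Carlo draws from the Gaussian posterior (default 2000), each draw
re-evaluated on a 1-minute grid over [0, 240]; `Y_GOM` re-simulates the
model per draw, `Y_OMM` perturbs the insulin samples per draw with
independent 13 %-CV Gaussian noise.  Bands are pointwise 2.5/50/97.5 %
quantiles; OMM draws violating the AUC constraint are dropped (logged).
A singular covariance collapses the band onto the median with a
warning.

The **OL value** between two bands is the fraction of the 241
grid-minutes (endpoints inclusive) at which the vertical intervals
intersect — identical by construction to a naive per-minute scan.
Widening either band can only increase it, and it is symmetric.

## What the synthetic generator emulates — and what it does not

Emulated: the study-day protocol (three identical meals 240 min apart;
samples at 0, 2, 5, 10, 20, 30, 40, 50, 60, then every 15 min to 120
and every 30 min to 240, plus a fasting sample at −15 min; one blood
draw serves as both a meal's 240-min and the next meal's 0-min sample),
carbohydrate doses by meal type and sex (standard 1.2/1.1, high-carb
2.0/1.8 g/kg for males/females), additive 2 %-CV glucose noise, and
insulin with 13 % assay CV.  True parameters are log-normal around the
prior medians: population CV 30 % for the kinetic and GA-shape
parameters, 50 % for `SG` (real sensitivity heterogeneity), and 10 %
for `β` — matching its prior, since `β` is a unit-conversion factor
rather than a subject-level trait, and a `β` population wider than the
estimator's declared prior makes the `SG` posteriors systematically
miscalibrated (the estimation error then tracks the subject's `β`
deviation almost perfectly).  Days whose simulated glucose leaves
(0, 500) mg/dL are rejected and redrawn, with a log record.

Not emulated, hence not demonstrated by passing tests:

* **Insulin realism.**  Synthetic insulin is
  `Ib + k·lag_τ(max(G − Gb, 0))` sampled with 13 %-CV noise
  (`k = 0.6` mU/L per mg/dL, `τ = 15` min, `Ib = 8` mU/L) — an internal
  device to give the OMM an input, not a secretion model.  In
  particular it cannot carry the GA-coupled part of the generating
  drive, so OMM fits to synthetic data are a structural smoke path with
  elevated RMSE, and synthetic GA/Y overlap values sit below the regime
  expected on real data.
* **Undershoot depth.**  At the default parameters the simulated
  glucose dips further below basal than typical normal-glucose-
  tolerance profiles do.  The defaults were placed to match peak
  excursions (+40…+80 mg/dL), and the deep trough is accepted as a
  model-consistent artefact rather than tuned away.
* Inter-subject covariance structure beyond independent log-normal
  draws, day-to-day variability, and meal-composition effects other
  than dose.

## Problem sizes

The recovery experiment used by the test suite and the acceptance
script fits the **first meal** of 20 subjects (the three meals of a day
share one truth, so later meals add cost, not information; chaining has
its own dedicated tests).  Confidence bands in bulk experiments use
300–500 draws; one-off analyses default to 2000.  A single nine-
parameter fit takes a few seconds on one core.

## Known limitations

* Interval coverage is honest only when the fitted priors describe the
  population; deliberately misspecified priors (e.g. a wide `β`
  population against the narrow `β` prior) degrade `SG` calibration
  long before they degrade its ranking ability.
* With a fixed positive meal AUC, a flat glucose trace is *not*
  uninformative: the estimator explains it by pushing the GA mass
  beyond the 240-min window.  Truly prior-pinned GA timing requires a
  negligible dose.
* The OMM's free-height posterior is Gaussian on log-heights with a
  hard AUC constraint; posterior draws that violate the constraint are
  dropped rather than reweighted, which slightly narrows its GA band.
* No hierarchical pooling across subjects or meals; every response is
  fitted independently apart from the deterministic chaining.
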