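# Methods

## The model

Field-scale corn tiller density `y` (tillers ha⁻¹) is treated as a binomial
realization out of an assumed maximum of `y_max = 300 000` tillers ha⁻¹ —
3 tillers per plant at a maximized stand of 100 000 plants ha⁻¹ — so that the
quantity modeled is the probability `m` of attaining that maximum and
`y = m × 300 000`. On the logit scale, `m` is an additive combination of
penalized smooth functions of agroclimatic and soil covariates:

    logit(m) = β₀ + Σⱼ fⱼ(xⱼ)  [+ factor main effects],

with each `fⱼ` a thin-plate regression spline. Interaction candidates use
factor-by smooths: a separate `fⱼ` per level of the interacting factor (the
three plant-density classes A/B/C clustered from targets 25 000 / 42 000 /
60 000 plants ha⁻¹, the genotype, or their combination), plus the factor's
main effect.

Fifteen candidate term sets span the genotype (G), environment (E) and
management (M) variable groups, from the two-smooth Temporal candidate to
the 18-variable Full candidate; the E×M candidate — by-density-class smooths
of GDD, PTQ, mean minimum/maximum temperature, cumulative VPD, soil NO₃ and
soil P — is the structure carried into out-of-season validation.

## Covariates

All climate covariates accumulate or average over the closed window from
planting to observation date:

| Covariate | Definition | Units |
|---|---|---|
| GDD  | Σ max(0, min(T̄, 30 °C) − 10 °C), T̄ = (Tmin+Tmax)/2 | °C day |
| PTQ  | mean radiation / (mean T̄ − 10 °C) | MJ m⁻² °C⁻¹ day⁻¹ |
| VPD  | Σ daily vapor-pressure deficit | kPa |
| CM   | Σ (precipitation + irrigation), window start 30 d pre-sowing | mm |
| T_min, T_max, T_amp | period means of daily min / max / amplitude | °C |
| NO₃, NH₄ (0–60 cm), P (0–15 cm) | conc. × bulk density × depth × 10 | kg ha⁻¹ |

Numerical conventions: the 30 °C cap applies to the daily **mean** (a config
switch `gdd_cap_on: tmax` gives the variant that caps the daily maximum
before averaging); the PTQ denominator uses the uncapped period mean and a
period mean at or below the base temperature is an error, not a NaN; a
degenerate window (observation on the sowing day) accumulates zero and has
no defined period means; missing weather days are hard errors naming the
first missing date — no imputation. Realized plant densities are clustered
to the nearest target (ties to the lower target, the conservative direction
for tillering).

## Fitting engine

The engine (`gam.py`) is a penalized binomial GLM on the logit scale,
written against the proportion-with-weight encoding (weight = 300 000):
mathematically the same likelihood as expanded Bernoulli rows at a tractable
size. Observed densities are rounded to integer successes.

- **Basis.** One-dimensional thin-plate regression splines: radial basis
  |x−knot|³ on the covariate rescaled to [0, 1], eigen-truncated to k = 10
  (fewer when the covariate has fewer unique values), null-space constraint
  absorbed by a QR rotation. Each smooth contributes k−2 penalized columns
  plus one unpenalized linear column, centered on the training data; the
  constant lives in the model intercept.
- **Double penalty.** Each smooth's linear column carries its own shrinkage
  penalty, selected independently, so a covariate with no real effect can be
  shrunk fully to zero instead of retaining a spurious slope. Without this,
  constant-probability data at realistic overdispersion retains smooth
  effects of ~0.2 on the logit scale.
- **Smoothing selection.** Per-block GCV by performance iteration: PIRLS is
  run to convergence, the working weights and response are frozen, penalty
  blocks are rescaled to the curvature of their design block (necessary
  because the binomial weights make X′WX ~10⁷ — a fixed λ grid could never
  span both the unpenalized and fully-smoothed limits otherwise), a shared
  grid seeds per-block cyclic refinement on a multiplicative grid, and PIRLS
  is re-run; two outer cycles. The effective-degrees-of-freedom cost in GCV
  is inflated by γ = 2, counteracting GCV's tendency to undersmooth when
  covariates sit in stage-clusters and the response is strongly
  overdispersed. GCV is dispersion-scale-invariant, so one criterion serves
  both families. A shared-λ selector was tried first and rejected: one sharp
  term forces global under-smoothing, destabilizing predictions at the edge
  of support.
- **Overdispersion.** Nominal binomial variance at 300 000 trials is
  unrealistically small, so the default family is quasibinomial: the Pearson
  dispersion φ (≈ 6 000 under the default generator noise) scales the
  Bayesian coefficient covariance φ(X′WX + S_λ)⁻¹. `family: binomial` fixes
  φ = 1. The fit is deterministic — no randomness anywhere in fitting.
- **Degeneracies.** A tiny ridge (10⁻⁹ × mean curvature) keeps
  rank-deficient designs solvable (soil covariates have one value per
  site-year, so a Soil-only design on 18 site-years has rank ≤ 18);
  a missing density class or single-level factor is a hard error naming the
  level; a constant covariate cannot be smoothed.

An independent cross-check fits the same quasibinomial thin-plate GAM in
R's mgcv on identical data; the two probability curves agree to a mean
absolute difference of ~0.003.

## Evaluation and attribution

The cross-season regime splits 80/20, stratified by site-year (the split is
seeded and recorded). Candidates are ranked by mean absolute error (MAE) of
held-out tiller-density predictions; mean bias error (MBE) is
predicted − observed, so positive bias is over-prediction. Candidates that
fail to fit are kept with infinite MAE and a warning. Ties keep registry
order.

The out-of-season regime holds out each season, trains on the rest, and
evaluates each held-out site-year at the point prediction for stage R6 in
density class B (42 000 plants ha⁻¹); when several plots qualify their
observed densities are averaged. Attribution independently zeroes each
term's full coefficient block — all basis coefficients across all by-levels
of that covariate — with no refit; the no-exclusion case is always a
candidate, so the lowest error never exceeds the full error. Both the
per-site-year best exclusion (the published table's granularity) and the
season-level best exclusion (the single zeroing that most reduces a held-out
season's MAE — the statement the recovery experiments test) are reported.
The acceptable-error threshold is 10 500 tillers ha⁻¹ (25% of the 42 000
target); the summarizer reports the share of site-years below it and each
season's share of the remainder, and applies unchanged to the published
table.

## Thresholds

Response curves vary one covariate over its per-class training support (101
points) with all other covariates held at per-class training medians
(configurable to global medians) and non-traced factors at their first
level; an 11-point centered moving average (edge-truncated, so constants are
preserved) smooths the curve, and 0.50-probability crossings are located by
linear interpolation, each tagged rising (non-limiting above) or falling
(limiting above). Curves that never reach 0.50 carry a none-flag. An
alternative mode evaluates at observed covariate values instead of a grid.

## Prediction intervals

0.95 quantile intervals are simulated from the multivariate-normal
coefficient posterior (seeded; ≥ 200 draws required). By default they
reflect coefficient uncertainty only; with `sampling_noise` the draw of a
new observation is added using the fitted dispersion — beta-binomial with
ρ = (φ−1)/(N−1) — which is what makes the interval a prediction interval
for a new site-year observation. Empirical coverage of new observations
under a well-specified model measures 0.94–0.96.

## Synthetic generator

The generator emulates the structure of a Central High Plains trial
network: 3 seasons × 6 sites (the real network had 17 site-years), three
density targets × two genotypes × two plot replicates, observations at V5 /
V10 / V16 / R3 / R6 (30 / 50 / 65 / 85 / 120 days after late-April–mid-May
sowing). Daily weather follows a seasonal sinusoid peaking in mid-July with
site-level and daily noise; VPD is linked linearly to daily maximum
temperature; precipitation is a Bernoulli–exponential process and half the
sites receive weekly irrigation. Soil chemistry is sampled uniformly within
the observed envelopes of the study region (pH 5.2–7.9, OM 1.0–6.2 %,
NO₃ 1.8–43.5 mg kg⁻¹, P 13.3–118 mg kg⁻¹, bulk density 1.1–1.6 Mg m⁻³).

Ground truth is additive on the logit scale: per-class intercepts plus
logistic ramps `±amp·(2σ((x−loc)/scale)−1)`, each optionally gated by
density class or season. Observation noise defaults to beta-binomial with
ρ = 0.02 (per-observation probability SD ≈ 0.05–0.07 — the overdispersion
the quasibinomial fit must absorb); Gaussian density-scale noise and
noise-free modes exist for calibration tests.

Presets:

- `null` — constant probability 0.1 (mean density ≈ 30 000, matching the
  field study's 28 781).
- `gdd_step` — a single ramp in GDD at 200 °C day (scale 30), with a
  compressed observation schedule (15–80 days) and cooler weather so the
  thermal-time support is dense around the planted threshold.
- `exm` — class-dependent VPD ceilings (falling at 200 kPa for class B,
  150 kPa for C), class-dependent T_max onsets (22 / 22 / 26 °C), GDD and
  PTQ ramps, and class-dependent NO₃/P effects. Intercepts (−4.2 / −4.6 /
  −5.0 for A/B/C) are calibrated so the generated ceiling and mean match
  the published field scale (max < 160 000, mean ≈ 29 000 tillers ha⁻¹).
- `season_shift` — a soil-NO₃ ramp active only in 2019–2020, for
  attribution tests; this preset uses 10 sites per season because with only
  6 distinct soil profiles per season the planted effect is not reliably
  identifiable against smooths of sample-correlated covariates.

What the generator does **not** emulate: spatial correlation between sites,
within-season weather autocorrelation, split-plot blocking (the GAM ignores
it, deliberately), genotype effects (the default truths are
genotype-neutral), or crop-growth mechanisms. Passing recovery tests
therefore demonstrates that the pipeline identifies the structures it
assumes, at realistic noise — not that those structures exhaust real field
variability.

## Problem sizes used in the shipped experiments

Null recovery runs at ~1 980 observations; function/threshold recovery at
~4 950 over 10 seeds; attribution at 20 replicates of ~1 800; ranking at 20
replicates of ~1 080; coverage at 500 predictions (20 replicates × 25).
These sizes put each check at the scale its tolerance was designed for
while keeping a full run of the reproduction script to a few minutes.

## Known limitations

- The published per-candidate MAE values are not recomputable: they depend
  on the undeposited field dataset. The pipeline reproduces the *procedure*
  and the published tables' derived summaries exactly, and the error
  *scale* (ExM ≈ 10 000 vs Soil ≈ 16 000 tillers ha⁻¹ on synthetic data vs
  the published 7 776 vs 19 560) only qualitatively.
- Published covariate thresholds (200 °C day GDD, 1 MJ m⁻² °C⁻¹ day⁻¹ PTQ,
  20–30 kPa VPD, 100 kg P ha⁻¹ …) calibrate the synthetic truths
  qualitatively; they are not test targets.
- The supplementary exact E×M formula was not available; the structure is
  reconstructed from the candidate table and its density-class footnote.
- With ~12 training site-years per out-of-season fit, soil smooths rest on
  very few distinct values; attribution at the real study's size is noisy,
  which mirrors the scattered per-site-year exclusions in the published
  table.
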