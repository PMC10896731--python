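# Methods

## The model

For a crop, let `y_i` be the census-reported yield (t per harvested ha) of
administrative unit `i` in a given year and `a_i` its harvested area (ha).
The *attainable yield* is defined as the 95th-percentile yield observed
among units sharing the same biophysical conditions — a ceiling describing
the best yields achieved anywhere under comparable climate, soils and
irrigation.  It is estimated by quantile regression of yield on the
biophysical covariates of Table-style form

```
Y ~ GDD + MAP + GDD² + MAP² + GDD×MAP + PCI + PCI×MAP
    + IRR + IRR×MAP + IRR×PCI + AWC + SOC + SLOPE30 + PH
    (+ VF + VF×GDD + VF×MAP for the wheat archetype)
```

fitted separately for every year at τ = 0.95 under the area-weighted
pinball loss

```
LF_τ = [ Σ_i w_i |y_i − q_i| a_i ] / Σ_i a_i,   w_i = τ if y_i > q_i else (1 − τ),
```

where `q_i` is the model prediction.  All fitting is done on z-scores of
both covariates and response (one factor table per crop, population-s.d.
convention), so coefficients are unitless and comparable across years.

The pinball loss only weakly pins down how much harvested area lies under
the surface, so the per-year production fits add a calibration penalty

```
λ = s.d.(y) · Σ_i a_i · | (Σ_{j under surface} a_j) / Σ a  −  τ |
```

and the fitted surface is required to leave the area-weighted fraction of
records on or below it as close to τ as the data permit.  Records exactly
on the surface count as encompassed ("ties below"), the same convention
the loss's case split uses; classification uses a 1e-9 absolute tolerance
to absorb LP solver fuzz.

### Optimizing the penalized loss

λ is piecewise constant in the coefficients (its gradient is zero almost
everywhere), so joint smooth optimization is ill-posed.  The implemented
procedure is deterministic:

1. solve the unpenalized problem exactly as a linear program (residual
   split `y = Xβ + u − v`, `u, v ≥ 0`, minimize `Σ a_i (τ u_i + (1−τ) v_i)`;
   HiGHS on a sparse constraint matrix);
2. recalibrate the intercept: the under-surface area share is a monotone
   non-decreasing step function of the intercept, so its λ-minimizing
   value is attained at a residual order statistic — the weighted
   τ-quantile of the residuals, or the adjacent order statistic below,
   whichever achieved share is nearer τ (ties prefer the smaller shift,
   and "no shift" is always a candidate);
3. a refinement pass when step 2 is atomically coarse: achievable shares
   are partial sums of area weights in residual order, so when a
   heavy-area record sits exactly at the τ boundary the nearest share can
   miss τ by that record's whole weight share (heavy-tailed areas make
   shares of 1–3% for a single unit unremarkable at a few thousand
   units).  A small tilt of one slope coefficient reorders the residuals
   and lets lighter records cross the surface instead; the pass scans a
   fixed grid of signed tilts (1e-4 … 3e-2 in z-units) per slope,
   recalibrating the intercept each time (cheap — no LP), and keeps the
   first strict improvement in |share − τ|.  With all grids and orderings
   fixed, the result is reproducible bit for bit.

Predictions are mapped back to physical units through the stored factors
and floored at 0 t/ha (yields cannot be negative).

## Model-term selection

Selection never sees single years: the panel is collapsed into eight
non-overlapping half-decadal layers (central years 1975, 1980, …, 2010),
each unit contributing per layer the area-weighted mean of its yield and
covariates over the central year ±2, weighted by its mean harvested area.
Linear and quadratic time terms (`t`, `t²`, on the layer's central year)
join the candidate terms so secular trends are absorbed during selection.

Phase 1 (pruning): coefficients are fitted on the pooled layers and given
confidence intervals by a 200-replicate case-resampling bootstrap at a
fixed seed; the term whose interval most centrally overlaps zero
(smallest `|lo + hi| / (hi − lo)`) is removed, and the step repeats until
every remaining unprotected term is significant.

Phase 2 (cross-validated search): child models delete one deletable term
each; each child is scored by leave-one-layer-out cross-validation — fit
on seven layers, evaluate the pinball loss on the held-out layer in
physical units, sum over the eight layers.  The lowest-loss child becomes
the parent (ties delete the later-ordered term); the search continues one
generation past the first non-improving generation to avoid stopping in a
local minimum, then returns the best spec seen.

Protected terms — the intercept, `IRR`, `IRR×MAP`, and while present `t`
and `t²` — are never deleted in either phase.  (The pruning phase could
defensibly protect only the irrigation terms; protecting the time terms
throughout keeps the guarantee that they are present to be stripped
before the per-year fits, which is what the per-year stage assumes.)
After selection the time terms are stripped and the surviving spec is
refitted year by year with the regularized loss.

## Inference

All confidence intervals derive from case-resampling bootstrap ensembles:
for each year, B = 1000 (default) resamples of that year's records with
their area weights, each refitted with the regularized procedure under
the shared factor table.  Seeding is a ladder — master seed → per-year →
per-replicate — so any single replicate is reproducible in isolation.
Intervals are equal-tailed empirical percentiles with linear
interpolation; a trend is called significant when both percentile bounds
of the per-realization slopes share a sign.

## Derived quantities

* **Circa-year values**: every "circa Y" statistic is a ±2-year,
  harvested-area-weighted average around Y (partial windows at the panel
  edge use the years available).
* **Gap trends**: per-realization OLS of annual yield gaps on year over
  1998–2012 with the origin at 1998, so the fitted value `x0` is the 1998
  level and the closure time relative to 2010 is `t_close = −x0/x1 − 12`.
  Realizations with zero slope are excluded from the median.  Units whose
  slope bounds differ in sign are "no trend"; a median crossing before
  2010 is "widen"; otherwise the median closure year is reported.
* **Area-with-change tables**: a unit counts toward "area with growth
  (decline)" when the per-realization difference between its windowed
  values at the period's end and start is significantly positive
  (negative); area is measured in the period's reference year (2000 for
  1975–2010 and 2000–2010, 1975 for 1975–1985).  A regression-slope mode
  is available.
* **Global rates**: the slope of the global area-weighted series divided
  by its base-year value, ×100, per realization; realizations with a
  non-positive base gap are rejected (near-zero gaps make relative rates
  blow up), and surviving rates outside mean ± 4 s.d. are rejected
  (two-sided by default; a one-sided literal reading is available).
* **Fixed-area counterfactual**: the same global series with every unit's
  weight frozen at its baseline-year harvested area, excluding units
  absent at baseline from both arms.

## Typology and stagnation

Units are partitioned by a three-way cascade over the 1998–2012 trend
significances: **ceiling pressure** when the gap is significantly closing
or the ceiling is not significantly growing; otherwise **stalled floor**
when the floor (actual yield) is not significantly growing; otherwise
**steady growth**.  Ceiling and gap significances come from the surface
ensemble; the floor has no ensemble, so its call uses the OLS t-interval
of the unit's own series.  The cascade order makes the partition
exhaustive, matching area tables that must sum to 100%.

Stagnation is a plateau after growth: a value-continuous broken-stick fit
over 1986–2012 with the slope break fixed at 2000
(`y = b0 + b1(t−1986) + b2·max(t−2000, 0)`), flagged stagnant when the
95% OLS t-interval of the pre-break slope `b1` is entirely positive and
the lower limit for the post-break slope `b1 + b2` is negative.  The
post-break upper limit may be positive — only the lower limit enters the
rule, read literally.  The risk ratio compares `P(stagnant)` between
units whose 1986–2000 gap trend was significantly closing with projected
closure within 30 years of 2000 and all other units; reversion-to-mean
controls repeat the ratio inside the top and the third quartile of
pre-2000 yield growth (both strata are reported since either reading of
"third quartile" is defensible), and a 75%-interval sensitivity variant
is supported through the `level` arguments.

## The synthetic panel generator

Real census compilations are not redistributable, so every stage runs
against generated panels with known ground truth.  Per unit: static
covariates from plausible ranges (GDD 1500–8000 °C·d, MAP 200–2500 mm,
PCI 9–40, IRR ~ Beta(0.8, 2.5), plus soil and terrain); a base ceiling
linear/quadratic in scaled covariates (≈3–10 t/ha, floored at 0.5);
harvested areas LogNormal(μ=7, σ=1.5) ha with a small deterministic
drift; and one of four scenario trajectories — *steady growth* (ceiling
and floor grow at 1% yr⁻¹ of the 2000 level), *stalled floor* (ceiling
grows, floor flat), *gap-closing* (gap shrinks 2% yr⁻¹ of its 2000
level) and *flat ceiling* (both flat) — mixed 50/20/20/10 by default.

Actual yields are ceiling × attainment.  The default **beta** family
draws attainment from Beta distributions with the scenario's mean
trajectory and concentration κ = 200 (year-to-year yield noise of a few
percent, as expected for large administrative aggregates), and marks a
persistent 5% of units as "exceeders" whose yields sit Uniform(1.0, 1.1)
above the ceiling every year — so ≈5% of harvested area lies above the
attainable surface, as the 95th-percentile definition implies.  The
exceeder draw is per unit rather than per record: per-record exceedance
would inject ±40%-of-ceiling spikes into every unit's series and swamp
the trend statistics the panel exists to exercise, whereas persistent
over-performers are the realistic reading of area above the ceiling.
The **lognormal** family instead draws per-record attainment
`exp(σ(Z − z_τ))`, making the conditional τ-quantile of yield *exactly*
the ceiling with continuous density there; it is the right instrument for
calibration and bootstrap-coverage studies, where the estimand must be
known analytically.  An **exact** family (attainment ≡ 1) provides
noiseless fixtures.

What the generator does *not* emulate: spatial autocorrelation, reporting
and reconciliation error, covariate measurement error, scenario
membership correlated with covariates.  The last point matters for
interpretation: scenario trajectories are deliberately orthogonal to the
covariates, so unit-specific ceiling trends are recoverable from the gap
machinery given the true ceilings, but a single global surface cannot
reproduce them (it can only express trends through covariate-dependent
coefficients).  Typology-recovery checks therefore feed the trend and
classification machinery with ground-truth ceilings plus an emulated
ensemble spread; surface-path correctness is established separately by
the calibration and coverage studies.

## Numerical choices and problem sizes

* LP solver: HiGHS via `scipy.optimize.linprog`, default tolerances;
  designs are checked for full column rank first.
* Calibration tolerance on |share − τ|: 1e-3 before the tilt pass engages.
* Percentile convention: linear interpolation between order statistics.
* Degenerate inputs: zero-variance covariates, empty crop-years, all-zero
  weights and underdetermined designs raise informative errors; sparse
  years (fewer than five records per term) are skipped with a warning.
* Simulation sizes are chosen to make the operating characteristics
  sharp while keeping a full run in minutes on one core: calibration on
  2000-unit panels; coverage with 200 replicate panels of 500 units at
  B = 100; selection consistency across 25 seeds on 60-unit panels with a
  40-replicate pruning bootstrap; typology recovery on 600 units.

## Known limitations

* The regularized objective is optimized by the staged calibration, not
  jointly; this follows the penalty's stated purpose (hit the τ share)
  and is reproducible, but is not a certificate of global optimality of
  the penalized loss.
* λ as written scales with total harvested area, so its magnitude
  dominates the pinball term for large panels; a normalized variant is a
  one-line change but the literal form is kept.
* Bootstrap percentile intervals at an extreme quantile lean on the
  response density near the surface; distributions with a density gap
  below the ceiling (e.g. the beta attainment family) make the interval
  degenerate, which is why coverage is assessed under the lognormal
  family.
* Per-unit typology significance at short windows (15 years) has modest
  power for slopes comparable to the series noise; classification rates
  quoted by the tests are specific to the generator's default noise.
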