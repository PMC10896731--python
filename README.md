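# yieldgap

Attainable-yield surfaces and yield-gap trend analysis for crop census
panels.

Yield gaps — the difference between the yields farmers actually obtain
and the *attainable* yield achieved somewhere in the world under the same
biophysical conditions — frame where agricultural productivity can still
grow and where it is hitting a ceiling.  This package implements a
temporally explicit yield-gap analysis for panels of
(administrative unit × crop × year) census records: for every year it
fits the attainable-yield ceiling as the area-weighted 95th-percentile
(τ = 0.95) quantile-regression surface over climate, soil and irrigation
covariates, and then turns the fitted ceilings plus observed yields into
gap trends, times to gap closure, a three-way typology of trajectories
and stagnation risk ratios.

The statistical core is the area-weighted pinball loss

    LF_τ = [ Σᵢ wᵢ |yᵢ − qᵢ| aᵢ ] / Σᵢ aᵢ ,   wᵢ = τ if yᵢ > qᵢ else (1 − τ),

with harvested areas `aᵢ` as weights, minimized exactly by linear
programming, plus a calibration penalty
`λ = s.d.(y) · Σᵢ aᵢ · |under-surface area share − τ|` that pins the
area-weighted share of records on or below the surface to τ.  Model terms
are chosen by a two-phase search (bootstrap-CI pruning, then child-model
deletion scored by leave-one-half-decadal-layer-out cross-validation),
and all uncertainty statements come from case-resampling bootstrap
ensembles of the per-year coefficients.  `docs/methods.md` has the full
account.

Real census compilations are not redistributable, so the package ships a
synthetic panel generator (`yieldgap.simulate`) producing census-style
records with known ground-truth ceilings, attainment trajectories and
scenario labels; every pipeline stage is tested against it.

## Worked example

```python
import yieldgap as yg

# a 500-unit synthetic census panel, 1973-2012
cfg = yg.ScenarioConfig(n_units=500, seed=1)
records, covariates, truth = yg.generate_panel(cfg)

# QC, per-year regularized 95th-percentile fits
records, rejects = yg.qc_filter(records)
spec = yg.ModelSpec.for_crop("default")
fits = yg.fit_annual_series(records, spec)

fit = fits[2000]
print(f"year 2000: {100 * fit.under_fraction:.2f}% of harvested area on/below the surface")
print(f"pinball loss {fit.loss:.4f} (z-units), {len(fit.coef)} coefficients")
```

```
year 2000: 94.91% of harvested area on/below the surface
pinball loss 0.0610 (z-units), 15 coefficients
```

The fitted surface encompasses 94.91% of the year's harvested area —
the calibration penalty holds the fit at the nominal τ = 0.95 — and the
loss is the area-weighted pinball loss of the z-scored response.  From
here, bootstrap ensembles and trend analytics:

```python
ens = {y: yg.bootstrap_fit(records, spec, y, B=50, seed=1) for y in fits}
gs = yg.gap_series_from_records(records, ens)
trend = yg.linear_gap_trend(gs, gs.unit_ids[0])          # 1998-2012 gap trend
category, years_to_close = yg.time_to_closure(trend)     # relative to 2010
labels = yg.classify_units(gs)                           # three-way typology
```

Or run everything end to end (simulate → QC → fits → bootstrap → trends
→ typology → stagnation), writing delimited report tables with an
embedded config hash:

```bash
yieldgap run-all --n-units 200 --b 50 --seed 1 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `yieldgap.ingest` | schema, QC screens, area-weighted aggregation, z-scoring |
| `yieldgap.covariates` | GDD, PCI, vernalization factor, irrigation scaling |
| `yieldgap.simulate` | synthetic census-panel generator with ground truth |
| `yieldgap.quantile` | pinball loss, λ penalty, LP fitting, per-year surfaces |
| `yieldgap.selection` | half-decadal layers, pruning, cross-validated search |
| `yieldgap.bootstrap` | coefficient ensembles, percentile CIs, sign tests |
| `yieldgap.trends` | gap series, windowed values, trends, t_close, global rates |
| `yieldgap.typology` | typology cascade, broken-stick stagnation, risk ratios |
| `yieldgap.report` / `yieldgap.cli` | pipeline orchestration and the `yieldgap` CLI |
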