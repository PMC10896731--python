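"""Nominal-calibration simulation studies for the fitting machinery.

Two end-to-end checks of the statistical core, each generating its own
synthetic data and measuring an operating characteristic the method is
designed to hit:

* :func:`quantile_calibration_study` — fit the calibration-regularized
  area-weighted quantile surface on one year of a default-scenario panel
  and measure the area-weighted percentage of records on or below the
  fitted surface (nominally 100·τ).
* :func:`bootstrap_coverage_study` — repeatedly simulate panels whose
  attainable-yield ceiling is exactly linear in the raw covariates with a
  known slope (lognormal attainment family, so the conditional τ-quantile
  equals the ceiling), bootstrap the regularized fit, and measure how
  often the percentile interval for the GDD slope covers the truth
  (nominally 100·level).
"""

from __future__ import annotations

import warnings

import numpy as np

from .bootstrap import bootstrap_fit, percentile_ci
from .ingest import zscore
from .quantile import RESPONSE, LossConfig, ModelSpec, fit_annual_series
from .simulate import COVARIATE_SCALE, ScenarioConfig, generate_panel

__all__ = ["quantile_calibration_study", "bootstrap_coverage_study"]

#: linear-only truth used when the estimand must be a known physical slope
LINEAR_TRUTH = {"1": 6.0, "gdd": 1.2, "map": 0.8, "irr": 0.8}
LINEAR_SPEC = ModelSpec(("1", "gdd", "map", "irr"), protected=frozenset({"1"}))


def quantile_calibration_study(
    n_units: int = 2000, seed: int = 0, tau: float = 0.95, year: int = 2000
) -> dict:
    """Area-weighted % of records on/below the regularized surface for one year."""
    cfg = ScenarioConfig(n_units=n_units, seed=seed, tau=tau)
    records, _, _ = generate_panel(cfg)
    spec = ModelSpec.for_crop(cfg.archetype)
    fits = fit_annual_series(records, spec, years=[year], config=LossConfig(tau=tau))
    return {"value": 100.0 * fits[year].under_fraction, "n": n_units}


def bootstrap_coverage_study(
    n_replicates: int = 200,
    n_units: int = 500,
    B: int = 100,
    seed: int = 0,
    tau: float = 0.95,
    level: float = 0.95,
    year: int = 2000,
) -> dict:
    """Empirical coverage (%) of the bootstrap percentile CI for the GDD slope.

    Each replicate draws an independent panel (seed ladder from ``seed``),
    refits the regularized surface on ``B`` case resamples, converts the
    z-score GDD coefficient to physical units (t/ha per degree-day) and
    checks whether the percentile interval covers the generator's true
    slope ``β_GDD / halfwidth_GDD × g(year)``.
    """
    master = np.random.default_rng(seed)
    panel_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    boot_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    j = LINEAR_SPEC.terms.index("gdd")
    hits = 0
    for r in range(n_replicates):
        cfg = ScenarioConfig(
            n_units=n_units,
            seed=int(panel_seeds[r]),
            year_start=year - 2,
            year_end=year + 2,
            tau=tau,
            attainment_family="lognormal",
            scenario_mix={"steady_growth": 1.0},
            true_coefficients=LINEAR_TRUTH,
        )
        records, _, _ = generate_panel(cfg)
        _, factors = zscore(records, columns=LINEAR_SPEC.covariates + [RESPONSE])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = bootstrap_fit(
                records, LINEAR_SPEC, year, B=B, seed=int(boot_seeds[r]),
                config=LossConfig(tau=tau), factors=factors,
            )
        phys = ens.coef[:, j] * factors.sds[RESPONSE] / factors.sds["gdd"]
        lo, hi = percentile_ci(phys, level=level)
        growth = 1.0 + cfg.growth_rate * (year - 2000)
        beta_true = LINEAR_TRUTH["gdd"] / COVARIATE_SCALE["gdd"][1] * growth
        hits += lo <= beta_true <= hi
    return {"value": 100.0 * hits / n_replicates, "n": n_replicates}
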