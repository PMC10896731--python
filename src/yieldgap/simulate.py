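"""Synthetic census-panel generator with known ground truth.

Real attainable-yield analyses run on confidential compilations of
census records; every stage of this package is instead exercised on
generated panels whose attainable-yield ceilings, attainment fractions
and harvested areas are known exactly.

The generative model, per administrative unit ``u`` and year ``t``:

* static biophysical covariates drawn from documented plausible ranges;
* a covariate-driven base ceiling ``base_u`` (linear/quadratic in scaled
  covariates, floored at a small positive yield);
* a ceiling trajectory ``ceiling_ut = base_u · g(t)`` with
  ``g(t) = 1 + r (t − 2000)`` (default r = 1% yr⁻¹ of the year-2000
  level) for growing-ceiling scenarios and ``g ≡ 1`` for flat ceilings;
* a scenario-controlled floor (expected actual yield) trajectory; and
* actual yields ``y_ut = ceiling_ut × attainment`` with an attainment
  mechanism placing ≈5% of harvested area strictly above the ceiling.

Scenarios (per unit):

``steady_growth``
    ceiling and floor both grow, yield gap widens slowly.
``stalled_floor``
    ceiling grows, floor is flat, gap widens.
``ceiling_pressure_gapclose``
    ceiling grows but the gap shrinks linearly (floor catches up).
``ceiling_pressure_flatceiling``
    ceiling and floor both flat (gap static under a static ceiling).

Attainment families:

``beta`` (default)
    non-exceeder units draw attainment from a Beta distribution with the
    scenario's mean trajectory; a persistent 5% of units are "exceeders"
    whose yields sit just above the ceiling (Uniform(1.0, 1.1) × ceiling)
    every year, so ≈5% of harvested area lies above the surface.
``lognormal``
    per-record attainment ``exp(σ(Z − z_τ))`` with Z standard normal, so
    the conditional τ-quantile of yield equals the ceiling *exactly* with
    continuous density there — the family used for calibration and
    bootstrap-coverage studies.
``exact``
    attainment ≡ 1 (degenerate, for noiseless fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ingest import COVARIATE_COLUMNS, SCHEMA_COLUMNS

__all__ = ["ScenarioConfig", "GroundTruth", "generate_panel", "inject_decoy_covariate"]

SCENARIOS = (
    "steady_growth",
    "stalled_floor",
    "ceiling_pressure_gapclose",
    "ceiling_pressure_flatceiling",
)

#: (center, halfwidth) used to scale raw covariates into [-1, 1] for the
#: true-ceiling linear form; fixed constants, independent of any sample.
COVARIATE_SCALE: dict[str, tuple[float, float]] = {
    "gdd": (4750.0, 3250.0),
    "map": (1350.0, 1150.0),
    "pci": (24.5, 15.5),
    "irr": (0.5, 0.5),
    "awc": (125.0, 75.0),
    "soc": (45.0, 35.0),
    "ph": (6.5, 2.0),
    "slope30": (0.5, 0.5),
    "vf": (0.5, 0.5),
}

#: default true-ceiling coefficients on scaled covariates (t/ha); a mild
#: concave climate response with irrigation and soil effects.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "1": 6.0,
    "gdd": 1.2,
    "map": 0.8,
    "gdd^2": -0.6,
    "map^2": -0.4,
    "pci": -0.3,
    "irr": 0.8,
    "irr*map": -0.4,
    "soc": 0.3,
    "ph": 0.2,
    "slope30": -0.4,
}

DEFAULT_SCENARIO_MIX: dict[str, float] = {
    "steady_growth": 0.5,
    "stalled_floor": 0.2,
    "ceiling_pressure_gapclose": 0.2,
    "ceiling_pressure_flatceiling": 0.1,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic panel."""

    n_units: int = 500
    year_start: int = 1973
    year_end: int = 2012
    seed: int = 0
    crop: str = "maize"
    archetype: str = "default"  # "wheat" adds the VF covariate to the truth
    scenario_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_MIX)
    )
    tau: float = 0.95
    growth_rate: float = 0.01  # ceiling growth, fraction of year-2000 level per year
    gap_close_rate: float = 0.02  # gap shrink rate for gapclose units, per year
    attainment_family: str = "beta"
    attainment_mean_range: tuple[float, float] = (0.5, 0.8)
    attainment_concentration: float = 200.0  # Beta κ: higher = less yearly noise
    attainment_sigma: float = 0.25  # lognormal family spread
    exceeder_prob: float = 0.05
    exceeder_range: tuple[float, float] = (1.0, 1.1)
    area_log_mu: float = 7.0  # harvested areas ~ LogNormal(7, 1.5) ha
    area_log_sigma: float = 1.5
    floor_min: float = 0.5  # smallest admissible true ceiling, t/ha
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be at least 1")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.attainment_family not in ("beta", "lognormal", "exact"):
            raise ValueError(f"unknown attainment family {self.attainment_family!r}")
        bad = set(self.scenario_mix) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios in mix: {sorted(bad)}")
        total = sum(self.scenario_mix.values())
        if not total > 0:
            raise ValueError("scenario mix weights must have positive total")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: true ceilings, floors, slopes and labels.

    ``records``: one row per unit-year with ``true_attainable`` and
    ``true_floor`` (expected actual yield, t/ha).
    ``units``: one row per unit with scenario label, exceeder flag, base
    ceiling, mean attainment and the analytic ceiling/floor/gap slopes
    (t/ha yr⁻¹) valid over the trend window.
    """

    records: pd.DataFrame
    units: pd.DataFrame
    config: ScenarioConfig


def _largest_remainder_counts(weights: np.ndarray, n: int) -> np.ndarray:
    """Apportion n units to scenario shares exactly (largest-remainder)."""
    raw = weights / weights.sum() * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    return counts


def _draw_covariates(rng: np.random.Generator, n: int, archetype: str) -> pd.DataFrame:
    cov = pd.DataFrame(
        {
            "gdd": rng.uniform(1500.0, 8000.0, n),
            "map": rng.uniform(200.0, 2500.0, n),
            "pci": rng.uniform(9.0, 40.0, n),
            "irr": rng.beta(0.8, 2.5, n),
            "awc": rng.uniform(50.0, 200.0, n),
            "soc": rng.uniform(10.0, 80.0, n),
            "ph": rng.uniform(4.5, 8.5, n),
            "slope30": rng.beta(1.0, 15.0, n),
            "vf": (rng.random(n) < 0.4).astype(float) if archetype == "wheat" else np.zeros(n),
        }
    )
    return cov


def _true_base_ceiling(cov: pd.DataFrame, coefficients: Mapping[str, float], floor_min: float) -> np.ndarray:
    base = np.zeros(len(cov))
    for term, beta in coefficients.items():
        if term == "1":
            base = base + beta
            continue
        col = np.ones(len(cov))
        for piece in term.split("*"):
            var, power = (piece.split("^") + ["1"])[:2] if "^" in piece else (piece, "1")
            center, half = COVARIATE_SCALE[var]
            col = col * ((cov[var].to_numpy(float) - center) / half) ** int(power)
        base = base + beta * col
    return np.maximum(base, floor_min)


def _floor_trajectory(
    scenario: str, base: float, mu0: float, years: np.ndarray, g: np.ndarray, close_rate: float
) -> np.ndarray:
    """Expected actual yield per year for one unit under its scenario."""
    if scenario == "steady_growth":
        return base * g * mu0
    if scenario == "stalled_floor":
        return np.full_like(g, base * mu0)
    if scenario == "ceiling_pressure_gapclose":
        gap = base * (1.0 - mu0) * np.maximum(1.0 - close_rate * (years - 2000.0), 0.05)
        return base * g - gap
    # ceiling_pressure_flatceiling: both flat
    return np.full_like(g, base * mu0)


def generate_panel(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a census-style panel: records, per-unit covariates, truth.

    The records table is in the exact ingest schema; regenerating with the
    same config is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    n, years = config.n_units, config.years
    n_years = len(years)

    cov = _draw_covariates(rng, n, config.archetype)
    unit_ids = np.array([f"U{i:05d}" for i in range(n)])
    base = _true_base_ceiling(cov, config.true_coefficients, config.floor_min)

    mix_names = [s for s in SCENARIOS if config.scenario_mix.get(s, 0.0) > 0]
    mix_w = np.array([config.scenario_mix[s] for s in mix_names], dtype=float)
    counts = _largest_remainder_counts(mix_w, n)
    scenario = np.repeat(mix_names, counts)
    scenario = scenario[rng.permutation(n)]

    lo, hi = config.attainment_mean_range
    mu0 = rng.uniform(lo, hi, n)
    # stalled floors must stay attainable back to the panel start, where the
    # growing ceiling was lowest
    g_min = 1.0 + config.growth_rate * (config.year_start - 2000.0)
    if g_min <= 0:
        raise ValueError("infeasible scenario mix: ceiling trajectory crosses zero in-panel")
    stalled = scenario == "stalled_floor"
    mu0[stalled] = np.minimum(mu0[stalled], 0.95 * g_min)
    gapclose = scenario == "ceiling_pressure_gapclose"
    mu0[gapclose] = np.maximum(mu0[gapclose], 0.6)

    exceeder = rng.random(n) < config.exceeder_prob

    area0 = rng.lognormal(config.area_log_mu, config.area_log_sigma, n)
    area_drift = rng.normal(0.0, 0.005, n)
    area_fraction = rng.uniform(0.1, 1.2, n)

    grows = np.isin(scenario, ("steady_growth", "stalled_floor", "ceiling_pressure_gapclose"))
    rec_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    t_rel = years - 2000.0
    for u in range(n):
        g = 1.0 + config.growth_rate * t_rel if grows[u] else np.ones(n_years)
        ceiling = base[u] * g
        floor = _floor_trajectory(
            scenario[u], base[u], mu0[u], years.astype(float), g, config.gap_close_rate
        )
        floor = np.clip(floor, 0.02 * base[u], 0.98 * ceiling)
        mu_rel = floor / ceiling

        if config.attainment_family == "exact":
            y = ceiling.copy()
            floor_true = ceiling.copy()
        elif config.attainment_family == "lognormal":
            z = rng.standard_normal(n_years)
            sig = config.attainment_sigma
            y = ceiling * np.exp(sig * (z - norm.ppf(config.tau)))
            floor_true = ceiling * np.exp(sig**2 / 2 - sig * norm.ppf(config.tau))
        elif exceeder[u]:
            y = ceiling * rng.uniform(*config.exceeder_range, n_years)
            floor_true = ceiling * np.mean(config.exceeder_range)
        else:
            kappa = config.attainment_concentration
            attain = rng.beta(mu_rel * kappa, (1.0 - mu_rel) * kappa)
            y = ceiling * attain
            floor_true = floor

        area = area0[u] * np.clip(1.0 + area_drift[u] * t_rel, 0.05, None)
        rec_rows.append(
            pd.DataFrame(
                {
                    "unit_id": unit_ids[u],
                    "crop": config.crop,
                    "year": years,
                    "yield_t_ha": y,
                    "area_ha": area,
                    "area_fraction": area_fraction[u],
                    **{c: cov[c].iloc[u] for c in COVARIATE_COLUMNS},
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "unit_id": unit_ids[u],
                    "year": years,
                    "true_attainable": ceiling,
                    "true_floor": floor_true,
                    "scenario": scenario[u],
                }
            )
        )

    records = pd.concat(rec_rows, ignore_index=True)[SCHEMA_COLUMNS]
    truth_records = pd.concat(truth_rows, ignore_index=True)

    ceiling_slope = np.where(grows, base * config.growth_rate, 0.0)
    floor_slope = np.where(
        scenario == "steady_growth",
        base * config.growth_rate * mu0,
        np.where(
            gapclose, base * (config.growth_rate + config.gap_close_rate * (1.0 - mu0)), 0.0
        ),
    )
    # exceeder units track the ceiling regardless of scenario floor
    floor_slope = np.where(exceeder, ceiling_slope * np.mean(config.exceeder_range), floor_slope)
    units = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "scenario": scenario,
            "exceeder": exceeder,
            "base_ceiling": base,
            "mu0": mu0,
            "area_ha_2000": area0,
            "ceiling_slope": ceiling_slope,
            "floor_slope": floor_slope,
            "gap_slope": ceiling_slope - floor_slope,
        }
    )
    unit_cov = cov.copy()
    unit_cov.insert(0, "unit_id", unit_ids)
    return records, unit_cov, GroundTruth(records=truth_records, units=units, config=config)


def inject_decoy_covariate(
    records: pd.DataFrame,
    unit_covariates: pd.DataFrame,
    seed: int,
    name: str = "decoy",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add a covariate with zero true effect (per-unit standard normal).

    The decoy is statistically independent of yield by construction; its
    ground-truth coefficient is zero.  Raises on a column-name collision.
    """
    if name in records.columns or name in unit_covariates.columns:
        raise ValueError(f"covariate name collision: {name!r} already present")
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        {"unit_id": unit_covariates["unit_id"], name: rng.standard_normal(len(unit_covariates))}
    )
    return (
        records.merge(values, on="unit_id", how="left"),
        unit_covariates.merge(values, on="unit_id", how="left"),
    )
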