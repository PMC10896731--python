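"""Biophysical covariate derivation from monthly climate and irrigation inputs.

The attainable-yield model regresses census yields on a small set of
biophysical predictors.  Four of them are derived rather than measured:

* GDD   — growing degree days, the annual heat sum above a 0 °C base,
  computed from monthly mean temperatures (``max(T̄_m, 0) × days_m`` summed
  over the twelve months).
* PCI   — Oliver's precipitation concentration index,
  ``100 · Σ p_m² / (Σ p_m)²``, which is 100/12 ≈ 8.33 for perfectly uniform
  rainfall and 100 when all rain falls in a single month.
* VF    — a binary vernalization factor for winter wheat: 1 when the mean
  temperature of the coldest month falls in a cold-but-survivable band.
* IRR   — the irrigated fraction of harvested area, anchored at a base-year
  value and scaled through time by the ratio of area equipped for
  irrigation (AEI), clamped to [0, 1].

Soil covariates (AWC, SOC, PH, SLOPE30) are consumed as precomputed
per-unit values and have no derivation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimate",
    "IrrigationSeries",
    "compute_gdd",
    "compute_pci",
    "compute_vf",
    "scale_irrigation",
    "derive_climate_covariates",
]

#: days per month of a non-leap year, used to weight monthly temperatures
DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: default vernalization band (°C) on the coldest-month mean temperature
VF_BAND_DEFAULT = (-8.0, 5.0)
#: alternative convention: any coldest month at or below 8 °C vernalizes
VF_BAND_ALTERNATE = (-np.inf, 8.0)


@dataclass(frozen=True)
class MonthlyClimate:
    """Twelve monthly mean temperatures (°C) and precipitation totals (mm)."""

    temperature: np.ndarray
    precipitation: np.ndarray
    days: np.ndarray = field(default_factory=lambda: DAYS_PER_MONTH.copy())

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        p = np.asarray(self.precipitation, dtype=float)
        d = np.asarray(self.days, dtype=float)
        if t.shape != (12,) or p.shape != (12,) or d.shape != (12,):
            raise ValueError("MonthlyClimate requires exactly 12 monthly values per field")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(p)):
            raise ValueError("MonthlyClimate contains missing or non-finite months")
        if np.any(p < 0):
            raise ValueError("monthly precipitation must be non-negative")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "precipitation", p)
        object.__setattr__(self, "days", d)


@dataclass(frozen=True)
class IrrigationSeries:
    """Base-year irrigated fraction plus an AEI time series to scale it by.

    ``irr0`` is the irrigated fraction of harvested area in ``base_year``
    (circa 2000 in the source data); ``aei`` maps calendar years to area
    equipped for irrigation in any consistent unit.
    """

    irr0: float
    base_year: int
    aei: dict[int, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.irr0 <= 1.0:
            raise ValueError("irr0 must lie in [0, 1]")
        if any(v < 0 for v in self.aei.values()):
            raise ValueError("AEI values must be non-negative")
        if self.base_year not in self.aei:
            raise ValueError(f"AEI missing for base year {self.base_year}")


def compute_gdd(climate: MonthlyClimate) -> float:
    """Annual growing degree days above a 0 °C base from monthly means."""
    return float(np.sum(np.maximum(climate.temperature, 0.0) * climate.days))


def compute_pci(monthly_precip: Sequence[float]) -> float:
    """Oliver's annual precipitation concentration index.

    ``PCI = 100 · Σ p_m² / (Σ p_m)²``; bounded in [100/12, 100].
    Raises when the annual total is zero (the index is undefined).
    """
    p = np.asarray(monthly_precip, dtype=float)
    if p.shape != (12,):
        raise ValueError("PCI requires exactly 12 monthly precipitation values")
    if np.any(p < 0):
        raise ValueError("monthly precipitation must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("PCI undefined: all-zero precipitation")
    return float(100.0 * np.sum(p**2) / total**2)


def compute_vf(climate: MonthlyClimate, band: tuple[float, float] = VF_BAND_DEFAULT) -> int:
    """Binary vernalization factor from the coldest-month mean temperature.

    Returns 1 when the coldest month lies inside the closed ``band``
    (default −8 to 5 °C). Pass :data:`VF_BAND_ALTERNATE` for the
    "at or below 8 °C" convention.
    """
    coldest = float(np.min(climate.temperature))
    lo, hi = band
    return int(lo <= coldest <= hi)


def _aei_at(series: IrrigationSeries, year: int) -> float:
    years = np.array(sorted(series.aei), dtype=float)
    values = np.array([series.aei[int(y)] for y in years], dtype=float)
    if year <= years[-1]:
        # linear interpolation inside the record, constant before its start
        return float(np.interp(year, years, values))
    if len(years) < 2:
        return float(values[-1])
    # extrapolate from the last two observations
    slope = (values[-1] - values[-2]) / (years[-1] - years[-2])
    return float(values[-1] + slope * (year - years[-1]))


def scale_irrigation(series: IrrigationSeries, year: int) -> float:
    """Irrigated fraction for ``year``: IRR₀ scaled by AEI ratio, clamped to [0, 1].

    AEI beyond the last observation is extrapolated linearly from the final
    two observations; a negative extrapolated AEI is treated as zero.
    """
    aei_base = series.aei[series.base_year]
    if aei_base == 0:
        if series.irr0 > 0:
            raise ValueError("AEI at base year is zero but irr0 > 0: ratio undefined")
        return 0.0
    aei_year = max(_aei_at(series, year), 0.0)
    return float(np.clip(series.irr0 * aei_year / aei_base, 0.0, 1.0))


def derive_climate_covariates(
    climate_table: pd.DataFrame, vf_band: tuple[float, float] = VF_BAND_DEFAULT
) -> pd.DataFrame:
    """Derive GDD, MAP, PCI and VF per unit from a monthly climate table.

    ``climate_table`` is keyed by ``unit_id`` with columns ``t01..t12`` and
    ``p01..p12`` (monthly mean temperature °C, monthly precipitation mm).
    """
    t_cols = [f"t{m:02d}" for m in range(1, 13)]
    p_cols = [f"p{m:02d}" for m in range(1, 13)]
    missing = [c for c in t_cols + p_cols + ["unit_id"] if c not in climate_table.columns]
    if missing:
        raise ValueError(f"climate table missing columns: {missing}")
    rows = []
    for _, row in climate_table.iterrows():
        clim = MonthlyClimate(row[t_cols].to_numpy(float), row[p_cols].to_numpy(float))
        rows.append(
            {
                "unit_id": row["unit_id"],
                "gdd": compute_gdd(clim),
                "map": float(clim.precipitation.sum()),
                "pci": compute_pci(clim.precipitation),
                "vf": compute_vf(clim, band=vf_band),
            }
        )
    return pd.DataFrame(rows)
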