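"""Yield-gap series, trends, time-to-closure and aggregate change tables.

The yield gap of a unit-year is attainable minus actual yield (t/ha); the
relative gap is the percentage of the attainable yield achieved.  All the
statistics here are computed per bootstrap realization of the attainable
surface and summarized through percentile bounds across realizations:

* ``windowed_value`` — the ±2-year, harvested-area-weighted average that
  defines every "circa year" quantity;
* ``linear_gap_trend`` — per-realization OLS of annual gaps on year over a
  15-year window (default 1998–2012, origin at the window start);
* ``time_to_closure`` — the projected crossing of the actual- and
  attainable-yield trends, expressed in years relative to 2010
  (``t_close = −x0/x1 − 12`` per realization; median reported), with
  ``no_trend`` and ``widen`` categories;
* ``area_fraction_significant`` — the share of harvested area whose
  endpoint change in a quantity has a given significant sign;
* ``global_average_change`` — per-year linear change of the global
  area-weighted series as a percentage of its base-year value;
* ``fixed_area_counterfactual`` — the same global series with every
  unit's weight frozen at a baseline year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEnsemble, percentile_ci, significant_sign
from .ingest import zscore
from .quantile import RESPONSE, build_design

__all__ = [
    "GapSeries",
    "TrendResult",
    "gap_series_from_records",
    "windowed_value",
    "linear_gap_trend",
    "time_to_closure",
    "area_fraction_significant",
    "global_average_change",
    "fixed_area_counterfactual",
]


@dataclass
class GapSeries:
    """Aligned actual/attainable arrays for a set of units and years.

    ``actual`` and ``area`` are (U, T); ``attainable`` is (B, U, T) with
    one slice per surface realization (B = 1 for a point fit).  Missing
    unit-years are NaN in ``actual``/``area``.
    """

    unit_ids: np.ndarray
    years: np.ndarray
    actual: np.ndarray
    attainable: np.ndarray
    area: np.ndarray
    crop: str = ""

    def __post_init__(self) -> None:
        U, T = len(self.unit_ids), len(self.years)
        if self.actual.shape != (U, T) or self.area.shape != (U, T):
            raise ValueError("actual/area must be (units, years)")
        if self.attainable.ndim != 3 or self.attainable.shape[1:] != (U, T):
            raise ValueError("attainable must be (realizations, units, years)")

    @property
    def n_realizations(self) -> int:
        return int(self.attainable.shape[0])

    @property
    def gap(self) -> np.ndarray:
        """(B, U, T) yield gap, attainable − actual; negative values retained."""
        return self.attainable - self.actual[None, :, :]

    @property
    def relative_gap_achieved(self) -> np.ndarray:
        """% of attainable achieved, capped into [0, 100] for reporting."""
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * self.actual[None, :, :] / self.attainable
        return np.clip(pct, 0.0, 100.0)

    def series(self, quantity: str) -> np.ndarray:
        if quantity == "gap":
            return self.gap
        if quantity == "attainable":
            return self.attainable
        if quantity == "actual":
            return np.broadcast_to(self.actual[None, :, :], self.gap.shape)
        raise ValueError(f"unknown quantity {quantity!r}")


def gap_series_from_records(
    records: pd.DataFrame, ensembles: dict[int, BootstrapEnsemble]
) -> GapSeries:
    """Assemble a :class:`GapSeries` from census records and per-year ensembles.

    Attainable yields are predicted for every record's covariates under
    each coefficient realization of that year's ensemble (all ensembles
    must share one spec and factor convention; factors are taken from the
    records via the first ensemble's spec covariates).
    """
    years = np.array(sorted(ensembles))
    unit_ids = np.array(sorted(records["unit_id"].unique()))
    uidx = {u: i for i, u in enumerate(unit_ids)}
    if not ensembles:
        raise ValueError("no ensembles supplied (were all years skipped for lack of records?)")
    if len({tuple(e.spec.terms) for e in ensembles.values()}) != 1:
        raise ValueError("all ensembles must share one model spec")
    spec = next(iter(ensembles.values())).spec
    B = min(e.n_replicates for e in ensembles.values())
    _, factors = zscore(records, columns=spec.covariates + [RESPONSE])

    U, T = len(unit_ids), len(years)
    actual = np.full((U, T), np.nan)
    area = np.full((U, T), np.nan)
    attain = np.full((B, U, T), np.nan)
    for tj, year in enumerate(years):
        sub = records.loc[records["year"] == year]
        rows = np.array([uidx[u] for u in sub["unit_id"]])
        actual[rows, tj] = sub["yield_t_ha"].to_numpy(float)
        area[rows, tj] = sub["area_ha"].to_numpy(float)
        norm, _ = zscore(sub, columns=[c for c in factors.columns if c in sub.columns],
                         factors=factors)
        X = build_design(norm, spec)
        q_z = X @ ensembles[year].coef[:B].T  # (n, B)
        q = q_z * factors.sds[RESPONSE] + factors.means[RESPONSE]
        attain[:, rows, tj] = np.maximum(q.T, 0.0)
    crop = str(records["crop"].iloc[0]) if "crop" in records.columns else ""
    return GapSeries(unit_ids=unit_ids, years=years, actual=actual,
                     attainable=attain, area=area, crop=crop)


def windowed_value(years, values, areas, year: int, half_window: int = 2) -> float:
    """±2-year, area-weighted average of a series around ``year``.

    Years absent from the window are simply not averaged; an entirely
    empty window yields NaN.  Weights are each year's harvested area, so
    the value is invariant to splitting a unit into sub-units with the
    same totals.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    areas = np.asarray(areas, dtype=float)
    mask = (years >= year - half_window) & (years <= year + half_window)
    mask &= np.isfinite(values) & np.isfinite(areas)
    if not mask.any() or not areas[mask].sum() > 0:
        return float("nan")
    return float(np.average(values[mask], weights=areas[mask]))


@dataclass
class TrendResult:
    """Per-unit linear trend of a gap (or yield) series across realizations."""

    unit_id: str
    x0: float  # fitted value at the window start (median across realizations)
    x1: float  # slope, t/ha per year (median across realizations)
    x0s: np.ndarray  # per-realization intercepts
    x1s: np.ndarray  # per-realization slopes
    significance: str  # "positive" | "negative" | "none"
    origin_year: int
    insufficient: bool = False

    @classmethod
    def insufficient_data(cls, unit_id: str, origin_year: int) -> "TrendResult":
        nanarr = np.array([np.nan, np.nan])
        return cls(unit_id=unit_id, x0=np.nan, x1=np.nan, x0s=nanarr, x1s=nanarr,
                   significance="none", origin_year=origin_year, insufficient=True)


def _ols_by_realization(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS of y (B, T) on t (T,): returns intercepts, slopes."""
    tbar = t.mean()
    ybar = y.mean(axis=1)
    st = np.sum((t - tbar) ** 2)
    slopes = (y - ybar[:, None]) @ (t - tbar) / st
    intercepts = ybar - slopes * tbar
    return intercepts, slopes


def linear_gap_trend(
    gs: GapSeries,
    unit_id: str,
    period: tuple[int, int] = (1998, 2012),
    quantity: str = "gap",
    level: float = 0.95,
    min_years: int = 8,
) -> TrendResult:
    """Per-realization OLS trend of a unit's series over ``period``.

    Years are centred on the window start so ``x0`` is the fitted value at
    the first period year.  Units with fewer than ``min_years`` observed
    years in the window are flagged insufficient.
    """
    u = int(np.flatnonzero(gs.unit_ids == unit_id)[0])
    in_window = (gs.years >= period[0]) & (gs.years <= period[1])
    series = gs.series(quantity)[:, u, :][:, in_window]
    t = gs.years[in_window].astype(float) - period[0]
    present = np.isfinite(series).all(axis=0) & np.isfinite(gs.actual[u, in_window])
    if present.sum() < min_years:
        return TrendResult.insufficient_data(unit_id, period[0])
    x0s, x1s = _ols_by_realization(t[present], series[:, present])
    if len(x1s) >= 2:
        sig = significant_sign(x1s, level)
    else:
        sig = "none"
    return TrendResult(unit_id=unit_id, x0=float(np.median(x0s)), x1=float(np.median(x1s)),
                       x0s=x0s, x1s=x1s, significance=sig, origin_year=period[0])


def single_series_trend(
    years, values, origin_year: int, level: float = 0.95, min_years: int = 8
) -> TrendResult:
    """OLS trend of one observed series with a t-interval significance call.

    Used for quantities with no bootstrap ensemble (the actual-yield
    "floor"), where the only uncertainty is residual noise around the
    linear fit.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < min_years:
        return TrendResult.insufficient_data("", origin_year)
    t = years[ok] - origin_year
    y = values[ok]
    (x0,), (x1,) = _ols_by_realization(t, y[None, :])
    resid = y - (x0 + x1 * t)
    dof = len(y) - 2
    st = np.sum((t - t.mean()) ** 2)
    se = np.sqrt(np.sum(resid**2) / dof / st) if dof > 0 else np.inf
    from scipy.stats import t as t_dist

    half = t_dist.ppf(1 - (1 - level) / 2, dof) * se if dof > 0 else np.inf
    lo, hi = x1 - half, x1 + half
    sig = "positive" if lo > 0 else ("negative" if hi < 0 else "none")
    return TrendResult(unit_id="", x0=float(x0), x1=float(x1),
                       x0s=np.array([x0]), x1s=np.array([x1]),
                       significance=sig, origin_year=origin_year)


def time_to_closure(trend: TrendResult, offset_years: int = 12) -> tuple[str, float]:
    """Years to gap closure relative to 2010 (``t_close = −x0/x1 − 12``).

    Computed per realization from the trend fitted at the 1998 origin; the
    −12-year offset re-references the zero crossing to 2010.  Returns
    ``("no_trend", nan)`` when the slope's percentile bounds differ in
    sign, ``("widen", median)`` when the crossing lies before 2010 (the
    gap and its trend are diverging), else ``("years", median)``.
    """
    if trend.insufficient:
        return "insufficient", float("nan")
    if trend.significance == "none":
        return "no_trend", float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        t_close = -trend.x0s / trend.x1s - offset_years
    t_close = t_close[np.isfinite(t_close)]
    if t_close.size == 0:
        return "no_trend", float("nan")
    med = float(np.median(t_close))
    if med < 0:
        return "widen", med
    return "years", med


def area_fraction_significant(
    gs: GapSeries,
    quantity: str,
    direction: str,
    period: tuple[int, int],
    reference_year: int,
    level: float = 0.95,
    mode: str = "endpoint",
) -> float:
    """% of reference-year harvested area with a significant change.

    ``mode="endpoint"`` (default) tests, per realization, the difference
    between the ±2-year windowed values of the quantity at the period's
    end and start; ``mode="slope"`` tests the per-realization OLS slope.
    Significance is a same-sign call on the percentile bounds.  Area is
    measured in ``reference_year`` (±2-year window); units without any
    reference-year area are excluded with a warning.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    want = "positive" if direction == "increase" else "negative"
    series = gs.series(quantity)
    total_area, hit_area, skipped = 0.0, 0.0, 0
    for u, unit in enumerate(gs.unit_ids):
        ref_area = windowed_value(gs.years, gs.area[u], gs.area[u], reference_year)
        if not np.isfinite(ref_area):
            skipped += 1
            continue
        if mode == "endpoint":
            changes = np.array(
                [
                    windowed_value(gs.years, series[b, u], gs.area[u], period[1])
                    - windowed_value(gs.years, series[b, u], gs.area[u], period[0])
                    for b in range(gs.n_realizations)
                ]
            )
            changes = changes[np.isfinite(changes)]
            sig = significant_sign(changes, level) if changes.size >= 2 else "none"
        else:
            trend = linear_gap_trend(gs, unit, period=period, quantity=quantity, level=level)
            sig = trend.significance
        total_area += ref_area
        if sig == want:
            hit_area += ref_area
    if skipped:
        warnings.warn(f"{skipped} units lacked reference-year area and were excluded")
    if not total_area > 0:
        return float("nan")
    return 100.0 * hit_area / total_area


def global_series(gs: GapSeries, quantity: str) -> np.ndarray:
    """(B, T) global area-weighted average of a quantity, NaN-aware."""
    series = gs.series(quantity)
    area = gs.area
    out = np.full((gs.n_realizations, len(gs.years)), np.nan)
    for tj in range(len(gs.years)):
        w = area[:, tj]
        ok = np.isfinite(w) & np.isfinite(series[:, :, tj]).all(axis=0)
        if ok.any() and w[ok].sum() > 0:
            out[:, tj] = series[:, ok, tj] @ w[ok] / w[ok].sum()
    return out


def global_average_change(
    gs: GapSeries,
    quantity: str,
    period: tuple[int, int],
    base_year: int = 2000,
    level: float = 0.95,
    outlier_sd: float = 4.0,
    one_sided_outliers: bool = False,
) -> dict:
    """Per-year % change of the global series relative to its base-year value.

    Per realization: OLS slope of the global area-weighted series over
    ``period`` divided by the realization's ±2-year windowed base-year
    value, ×100.  Realizations with a non-positive base value are
    rejected (near-zero gaps make relative rates blow up); remaining
    rates outside mean ± ``outlier_sd`` s.d. are rejected (above only,
    when one-sided).  Returns the surviving mean, percentile CI, the
    significance call and rejection count.
    """
    glob = global_series(gs, quantity)
    in_window = (gs.years >= period[0]) & (gs.years <= period[1])
    t = gs.years[in_window].astype(float)
    total_area = np.nansum(np.nan_to_num(gs.area), axis=0)  # per-year global weights
    rates = []
    rejected = 0
    for b in range(gs.n_realizations):
        y = glob[b, in_window]
        ok = np.isfinite(y)
        base = windowed_value(gs.years, glob[b], total_area, base_year)
        if not np.isfinite(base) or base <= 0 or ok.sum() < 3:
            rejected += 1
            continue
        _, (slope,) = _ols_by_realization(t[ok], y[None, ok])
        rates.append(100.0 * slope / base)
    rates = np.asarray(rates, dtype=float)
    if rates.size:
        mu, sd = rates.mean(), rates.std(ddof=1) if rates.size > 1 else 0.0
        if sd > 0:
            keep = rates <= mu + outlier_sd * sd
            if not one_sided_outliers:
                keep &= rates >= mu - outlier_sd * sd
            rejected += int((~keep).sum())
            rates = rates[keep]
    if rates.size == 0:
        return {"rate": float("nan"), "ci": (float("nan"), float("nan")),
                "significance": "none", "n_rejected": rejected}
    ci = percentile_ci(rates, level) if rates.size >= 2 else (float(rates[0]), float(rates[0]))
    sig = significant_sign(rates, level) if rates.size >= 2 else "none"
    return {"rate": float(rates.mean()), "ci": ci, "significance": sig, "n_rejected": rejected}


def fixed_area_counterfactual(
    gs: GapSeries, baseline_year: int, quantity: str = "attainable"
) -> pd.DataFrame:
    """Global series with unit weights frozen at their baseline-year area.

    Units without a baseline-year observation are excluded from both arms
    (a paired comparison).  Returns per-year factual and counterfactual
    realization-mean values plus their difference.
    """
    tb = int(np.flatnonzero(gs.years == baseline_year)[0])
    base_w = gs.area[:, tb]
    included = np.isfinite(base_w)
    if not included.any():
        raise ValueError(f"no units observed in baseline year {baseline_year}")
    series = gs.series(quantity)
    rows = []
    for tj, year in enumerate(gs.years):
        w_now = gs.area[:, tj]
        ok = included & np.isfinite(w_now) & np.isfinite(series[:, :, tj]).all(axis=0)
        if not ok.any():
            continue
        factual = (series[:, ok, tj] @ w_now[ok] / w_now[ok].sum()).mean()
        counter = (series[:, ok, tj] @ base_w[ok] / base_w[ok].sum()).mean()
        rows.append({"year": int(year), "factual": float(factual),
                     "counterfactual": float(counter),
                     "difference": float(factual - counter)})
    return pd.DataFrame(rows)
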