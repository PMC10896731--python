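"""Yield-gap typologies, piecewise stagnation detection and risk ratios.

Three mutually exclusive trajectories partition the units:

``steady_growth``
    attainable yield (ceiling) and actual yield (floor) both rising — the
    gap may widen, but both series benefit from ongoing improvement;
``stalled_floor``
    the ceiling rises but the floor does not — best-in-class management
    is not being adopted, so the gap widens;
``ceiling_pressure``
    the gap is significantly closing and/or the ceiling has stagnated —
    yields are approaching their biophysical ceiling and further growth
    requires raising it.

The classification cascade (ceiling_pressure → stalled_floor →
steady_growth) is exhaustive over units with determinate trends.

Stagnation is a plateau after a period of growth: a value-continuous
piecewise ("broken-stick") regression over 1986–2012 with a slope break
at 2000 flags a unit stagnant when the 1986–2000 slope's 95% interval is
entirely positive while the 2000–2012 slope's lower limit is negative.
The stagnation risk ratio quantifies how much more likely stagnation
after 2000 is among units whose 1986–2000 gap trend projected closure
within a 30-year horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .trends import GapSeries, TrendResult, linear_gap_trend, single_series_trend

__all__ = [
    "StagnationResult",
    "TYPOLOGY_LABELS",
    "piecewise_stagnation",
    "classify_typology",
    "classify_units",
    "typology_area_table",
    "closing_within",
    "stagnation_risk_ratio",
]

TYPOLOGY_LABELS = ("steady_growth", "stalled_floor", "ceiling_pressure")


@dataclass(frozen=True)
class StagnationResult:
    """Broken-stick slopes around the 2000 break with their 95% intervals."""

    pre_slope: float
    pre_ci: tuple[float, float]
    post_slope: float
    post_ci: tuple[float, float]
    stagnant: bool
    indeterminate: bool = False

    @classmethod
    def indeterminate_result(cls) -> "StagnationResult":
        nan = float("nan")
        return cls(nan, (nan, nan), nan, (nan, nan), stagnant=False, indeterminate=True)


def piecewise_stagnation(
    years,
    values,
    break_year: int = 2000,
    start_year: int = 1986,
    end_year: int = 2012,
    level: float = 0.95,
    min_years_per_side: int = 10,
) -> StagnationResult:
    """Fit a value-continuous broken-stick and test for a growth plateau.

    Model: ``y = b0 + b1·(t − start) + b2·max(t − break, 0)`` — continuous
    in value with a single discontinuity in slope.  The pre-break slope is
    ``b1``, the post-break slope ``b1 + b2``; both get ordinary
    least-squares t-intervals.  Stagnant means the pre-break interval is
    entirely positive and the post-break lower limit is negative (growth,
    then a slope no longer distinguishable from flat-or-falling).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = (years >= start_year) & (years <= end_year) & np.isfinite(values)
    years, values = years[keep], values[keep]
    n_pre = int(((years >= start_year) & (years <= break_year)).sum())
    n_post = int(((years >= break_year) & (years <= end_year)).sum())
    if n_pre < min_years_per_side or n_post < min_years_per_side:
        return StagnationResult.indeterminate_result()
    X = np.column_stack(
        [np.ones_like(years), years - start_year, np.maximum(years - break_year, 0.0)]
    )
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    dof = len(values) - 3
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tcrit = t_dist.ppf(1.0 - (1.0 - level) / 2.0, dof)
    pre = float(beta[1])
    pre_se = float(np.sqrt(cov[1, 1]))
    post = float(beta[1] + beta[2])
    post_se = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]))
    pre_ci = (pre - tcrit * pre_se, pre + tcrit * pre_se)
    post_ci = (post - tcrit * post_se, post + tcrit * post_se)
    stagnant = pre_ci[0] > 0 and post_ci[0] < 0
    return StagnationResult(pre, pre_ci, post, post_ci, stagnant)


def classify_typology(ceiling_sig: str, floor_sig: str, gap_sig: str) -> str:
    """Decision cascade from the three trend significance calls.

    ``ceiling_pressure`` when the gap is significantly decreasing or the
    ceiling is not significantly increasing; otherwise ``stalled_floor``
    when the floor is not significantly increasing; otherwise
    ``steady_growth``.  Exhaustive and mutually exclusive by construction.
    """
    for sig in (ceiling_sig, floor_sig, gap_sig):
        if sig not in ("positive", "negative", "none"):
            raise ValueError(f"invalid significance call {sig!r}")
    if gap_sig == "negative" or ceiling_sig != "positive":
        return "ceiling_pressure"
    if floor_sig != "positive":
        return "stalled_floor"
    return "steady_growth"


def classify_units(
    gs: GapSeries,
    period: tuple[int, int] = (1998, 2012),
    level: float = 0.95,
) -> pd.DataFrame:
    """Label every unit with its typology over the analysis window.

    Ceiling and gap significances come from the surface-realization
    ensemble; floor significance comes from an OLS t-interval on the
    unit's observed actual-yield series (the floor has no ensemble).
    Units with insufficient data get label ``"indeterminate"`` and are
    excluded from area tables.
    """
    rows = []
    for u, unit in enumerate(gs.unit_ids):
        ceiling = linear_gap_trend(gs, unit, period=period, quantity="attainable", level=level)
        gap = linear_gap_trend(gs, unit, period=period, quantity="gap", level=level)
        in_window = (gs.years >= period[0]) & (gs.years <= period[1])
        floor = single_series_trend(
            gs.years[in_window], gs.actual[u, in_window], origin_year=period[0], level=level
        )
        if ceiling.insufficient or gap.insufficient or floor.insufficient:
            label = "indeterminate"
        else:
            label = classify_typology(ceiling.significance, floor.significance, gap.significance)
        area2000 = gs.area[u][np.isfinite(gs.area[u])]
        rows.append(
            {
                "unit_id": unit,
                "label": label,
                "ceiling_sig": ceiling.significance,
                "floor_sig": floor.significance,
                "gap_sig": gap.significance,
                "ceiling_slope": ceiling.x1,
                "floor_slope": floor.x1,
                "gap_slope": gap.x1,
                "area_ha": float(area2000.mean()) if area2000.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def typology_area_table(labels: pd.DataFrame, area_col: str = "area_ha") -> pd.DataFrame:
    """Harvested-area share (%) per typology; shares sum to 100 over labeled units."""
    labeled = labels.loc[labels["label"].isin(TYPOLOGY_LABELS)]
    total = labeled[area_col].sum()
    rows = []
    for label in TYPOLOGY_LABELS:
        area = labeled.loc[labeled["label"] == label, area_col].sum()
        rows.append({"label": label, "area_share_pct": 100.0 * area / total if total > 0 else 0.0})
    return pd.DataFrame(rows)


def closing_within(trend: TrendResult, horizon_end_year: int = 2030) -> bool:
    """Whether a gap trend projects significant closure by ``horizon_end_year``.

    Requires a significantly negative slope; the median projected crossing
    year, ``origin − x0/x1`` across realizations, must not exceed the
    horizon.  Used with the 1986–2000 conditioning window and a 30-year
    horizon from 2000 for the stagnation risk ratio.
    """
    if trend.insufficient or trend.significance != "negative":
        return False
    with np.errstate(divide="ignore", invalid="ignore"):
        crossing = trend.origin_year - trend.x0s / trend.x1s
    crossing = crossing[np.isfinite(crossing)]
    if crossing.size == 0:
        return False
    return bool(np.median(crossing) <= horizon_end_year)


def _conditional_ratio(stagnant: np.ndarray, exposed: np.ndarray) -> dict:
    n11 = int((stagnant & exposed).sum())
    n10 = int((~stagnant & exposed).sum())
    n01 = int((stagnant & ~exposed).sum())
    n00 = int((~stagnant & ~exposed).sum())
    p_exposed = n11 / (n11 + n10) if (n11 + n10) else float("nan")
    p_other = n01 / (n01 + n00) if (n01 + n00) else float("nan")
    if not np.isfinite(p_exposed) or not np.isfinite(p_other):
        ratio = float("nan")
    elif p_other == 0:
        ratio = float("inf") if p_exposed > 0 else 0.0
    else:
        ratio = p_exposed / p_other
    return {
        "ratio": ratio,
        "p_stagnant_given_closing": p_exposed,
        "p_stagnant_otherwise": p_other,
        "counts": {"closing_stagnant": n11, "closing_not": n10,
                   "other_stagnant": n01, "other_not": n00},
    }


def stagnation_risk_ratio(units: pd.DataFrame) -> dict:
    """Risk ratio of post-2000 stagnation given pre-2000 gap closure.

    ``units`` needs boolean columns ``stagnant`` (2000–2012 plateau after
    growth) and ``closing30`` (1986–2000 gap trend significantly closing
    with projected closure within 30 years of 2000), and optionally a
    ``growth_rate`` column (pre-2000 yield growth) for the
    reversion-to-the-mean controls: the same ratio restricted to the top
    yield-growth quartile and to the third quartile.
    """
    stagnant = units["stagnant"].to_numpy(bool)
    exposed = units["closing30"].to_numpy(bool)
    out = {"overall": _conditional_ratio(stagnant, exposed)}
    if stagnant.any() is False:  # pragma: no cover - informational only
        out["warning"] = "zero stagnant units"
    if "growth_rate" in units.columns:
        g = units["growth_rate"].to_numpy(float)
        q50, q75 = np.nanpercentile(g, [50, 75])
        top = g >= q75
        third = (g >= q50) & (g < q75)
        out["top_quartile"] = _conditional_ratio(stagnant[top], exposed[top])
        out["third_quartile"] = _conditional_ratio(stagnant[third], exposed[third])
    return out
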