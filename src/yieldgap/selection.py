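"""Two-phase term selection with temporal leave-one-layer-out validation.

Phase 1 prunes terms whose bootstrap confidence intervals overlap zero,
removing at each step the term whose interval most centrally overlaps
zero, until every remaining (unprotected) term is significant.  Phase 2
generates "child" models by deleting one deletable term at a time and
scores each child by leave-one-layer-out cross-validation over eight
half-decadal layers: fit on seven layers, predict the held-out layer,
accumulate the area-weighted pinball loss, and sum across layers.  The
child with the lowest summed loss becomes the next parent; the search
stops one generation past the first non-improving generation (guarding
against a local minimum at the stopping point).

Protected terms — the intercept, the irrigation fraction, the
irrigation × precipitation cross term and (while present) the linear and
quadratic time terms — are never deleted in either phase.

Layers are built by averaging each unit's records, area-weighted, over a
central year ±2; the layers tile the panel without overlap, and each
pseudo-record carries the layer's central year as its time covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import percentile_ci
from .ingest import NormalizationFactors, zscore
from .quantile import (
    RESPONSE,
    ModelSpec,
    build_design,
    fit_weighted_quantile_lp,
    quantile_loss,
)

__all__ = [
    "HalfDecadeLayer",
    "SelectionTrace",
    "build_layers",
    "prune_nonsignificant",
    "cv_loss",
    "select_model",
    "strip_time_terms",
]


@dataclass(frozen=True)
class HalfDecadeLayer:
    """One smoothed fold: per-unit area-weighted averages over a ±2 year window."""

    central_year: int
    records: pd.DataFrame
    index: int


@dataclass
class SelectionTrace:
    """Every (spec, summed CV loss, action) step of a selection run."""

    steps: list[dict] = field(default_factory=list)
    selected: ModelSpec | None = None

    def log(self, generation: int, spec: ModelSpec, loss: float, action: str) -> None:
        self.steps.append(
            {"generation": generation, "terms": "+".join(spec.terms), "cv_loss": loss,
             "action": action}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def build_layers(
    records: pd.DataFrame,
    central_years: list[int] | None = None,
    half_window: int = 2,
) -> list[HalfDecadeLayer]:
    """Collapse a panel into non-overlapping half-decadal layers.

    Default central years start two years into the panel and step by the
    window width (1975, 1980, …, 2010 for a 1973–2012 panel).  Within each
    window, every unit contributes one pseudo-record: the area-weighted
    mean of its yield and covariates, with the mean harvested area as its
    weight and the central year as its time value.  Units absent from a
    window are omitted from that layer.
    """
    years = records["year"].to_numpy(int)
    if central_years is None:
        width = 2 * half_window + 1
        start = int(years.min()) + half_window
        central_years = list(range(start, int(years.max()) - half_window + 1, width))
    layers: list[HalfDecadeLayer] = []
    value_cols = [
        c for c in records.columns
        if c not in ("unit_id", "crop", "year", "area_ha") and pd.api.types.is_numeric_dtype(records[c])
    ]
    for idx, cy in enumerate(central_years):
        window = records.loc[(years >= cy - half_window) & (years <= cy + half_window)]
        if window.empty:
            continue
        grouped = window.groupby("unit_id", sort=True)
        areas = grouped["area_ha"].mean()
        w = window["area_ha"].to_numpy(float)
        agg = {}
        for col in value_cols:
            num = (window[col].to_numpy(float) * w)
            agg[col] = pd.Series(num, index=window.index).groupby(window["unit_id"]).sum() / (
                pd.Series(w, index=window.index).groupby(window["unit_id"]).sum()
            )
        pseudo = pd.DataFrame(agg)
        pseudo.insert(0, "unit_id", pseudo.index)
        pseudo["area_ha"] = areas
        pseudo["t"] = float(cy)
        layers.append(HalfDecadeLayer(central_year=int(cy), records=pseudo.reset_index(drop=True), index=idx))
    return layers


def _pooled(layers: list[HalfDecadeLayer]) -> pd.DataFrame:
    return pd.concat([layer.records for layer in layers], ignore_index=True)


def _fit_columns(spec: ModelSpec) -> list[str]:
    return spec.covariates + [RESPONSE]


def _fit_pooled(
    pooled: pd.DataFrame, spec: ModelSpec, tau: float, factors: NormalizationFactors | None = None
) -> tuple[np.ndarray, NormalizationFactors]:
    if factors is None:
        _, factors = zscore(pooled, columns=_fit_columns(spec))
    norm, _ = zscore(pooled, columns=_fit_columns(spec), factors=factors)
    X = build_design(norm, spec)
    beta = fit_weighted_quantile_lp(X, norm[RESPONSE].to_numpy(float),
                                    pooled["area_ha"].to_numpy(float), tau)
    return beta, factors


def prune_nonsignificant(
    spec: ModelSpec,
    layers: list[HalfDecadeLayer],
    tau: float = 0.95,
    ci_level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> ModelSpec:
    """Iteratively drop the term whose bootstrap CI most centrally overlaps zero.

    Coefficient intervals come from a case-resampling bootstrap of the
    pooled layer records at a fixed seed.  Centrality of overlap is
    ``|lo + hi| / (hi − lo)`` (interval midpoint distance from zero,
    relative to width); protected terms are never dropped.  Terminates
    because the term count strictly decreases.
    """
    pooled = _pooled(layers)
    n = len(pooled)
    step = 0
    while True:
        _, factors = _fit_pooled(pooled, spec, tau)
        rng = np.random.default_rng([seed, step])
        coefs = np.empty((n_boot, spec.n_terms))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sample = pooled.iloc[idx]
            try:
                coefs[b], _ = _fit_pooled(sample, spec, tau, factors=factors)
            except (ValueError, RuntimeError):
                coefs[b] = np.nan
        coefs = coefs[~np.isnan(coefs).any(axis=1)]
        worst_term, worst_centrality = None, np.inf
        for j, term in enumerate(spec.terms):
            if term in spec.protected:
                continue
            lo, hi = percentile_ci(coefs[:, j], level=ci_level)
            if lo > 0 or hi < 0:
                continue  # significant
            width = hi - lo
            centrality = abs(lo + hi) / width if width > 0 else 0.0
            if centrality < worst_centrality:
                worst_term, worst_centrality = term, centrality
        if worst_term is None:
            return spec
        spec = spec.drop(worst_term)
        step += 1


def cv_loss(spec: ModelSpec, layers: list[HalfDecadeLayer], tau: float = 0.95) -> float:
    """Summed leave-one-layer-out pinball loss of a candidate spec.

    For each held-out layer the model is fitted (unregularized, exact LP)
    on the remaining layers pooled, the held-out yields are predicted, and
    the area-weighted pinball loss is evaluated in physical units; the
    eight per-layer losses are summed.  A failed fold disqualifies the
    spec (returns +inf).
    """
    if len(layers) < 2:
        raise ValueError("cross-validation needs at least 2 layers")
    total = 0.0
    for held in layers:
        train = _pooled([l for l in layers if l.index != held.index])
        if train["unit_id"].nunique() < 2 or held.records["unit_id"].nunique() < 2:
            raise ValueError("insufficient data: single-unit layers cannot be cross-validated")
        try:
            beta, factors = _fit_pooled(train, spec, tau)
        except (ValueError, RuntimeError):
            return float("inf")
        norm, _ = zscore(held.records, columns=_fit_columns(spec), factors=factors)
        q_z = build_design(norm, spec) @ beta
        q = q_z * factors.sds[RESPONSE] + factors.means[RESPONSE]
        total += quantile_loss(
            held.records[RESPONSE].to_numpy(float), q, held.records["area_ha"].to_numpy(float), tau
        )
    return total


def select_model(
    start_spec: ModelSpec,
    layers: list[HalfDecadeLayer],
    tau: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
    prune_first: bool = True,
) -> SelectionTrace:
    """Stepwise child-model search, one generation past the loss minimum.

    Each generation scores every child obtained by deleting one deletable
    term from the parent; the lowest-loss child is adopted (ties delete
    the term appearing later in spec order).  When a generation fails to
    improve on the best loss seen, one further generation is explored
    before the best spec overall is returned.
    """
    trace = SelectionTrace()
    spec = start_spec
    if prune_first:
        spec = prune_nonsignificant(spec, layers, tau=tau, n_boot=n_boot, seed=seed)
        trace.log(0, spec, float("nan"), "pruned")
    best_spec = spec
    best_loss = cv_loss(spec, layers, tau=tau)
    trace.log(0, spec, best_loss, "parent")
    generation, extended = 0, False
    parent = spec
    while parent.deletable_terms():
        generation += 1
        child_best: tuple[float, int, ModelSpec] | None = None
        for j, term in enumerate(parent.terms):
            if term in parent.protected:
                continue
            child = parent.drop(term)
            try:
                loss = cv_loss(child, layers, tau=tau)
            except ValueError:
                loss = float("inf")
            trace.log(generation, child, loss, f"child (−{term})")
            # ties delete the later-ordered term: <= prefers the later child
            if child_best is None or loss <= child_best[0]:
                child_best = (loss, j, child)
        if child_best is None or not np.isfinite(child_best[0]):
            break
        loss, _, child = child_best
        parent = child
        if loss < best_loss:
            best_loss, best_spec, extended = loss, child, False
            trace.log(generation, child, loss, "adopted (improved)")
        elif not extended:
            extended = True
            trace.log(generation, child, loss, "adopted (exploring past minimum)")
        else:
            trace.log(generation, child, loss, "stop (no improvement)")
            break
    trace.selected = best_spec
    return trace


def strip_time_terms(spec: ModelSpec) -> ModelSpec:
    """Remove t and t² ahead of per-year fitting; order otherwise preserved."""
    stripped = spec.without_time()
    if stripped.terms == spec.terms:
        warnings.warn("spec carries no time terms; returned unchanged")
    return stripped
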