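"""Bootstrap ensembles of surface coefficients and percentile intervals.

Every confidence interval and significance call downstream of the fits is
read from an ensemble of coefficient realizations obtained by refitting
the regularized quantile surface on case-resampled census records (the
resampling unit is the individual unit-year record with its area weight,
within the fit year).  The production default is B = 1000 realizations.

Seeding follows a ladder — master seed → per-year substream →
per-replicate substream — so any single replicate can be reproduced in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import NormalizationFactors, zscore
from .quantile import RESPONSE, LossConfig, ModelSpec, build_design, fit_quantile

__all__ = ["BootstrapEnsemble", "bootstrap_fit", "percentile_ci", "significant_sign"]


@dataclass(frozen=True)
class BootstrapEnsemble:
    """B coefficient realizations for one crop-year surface."""

    crop: str
    year: int
    spec: ModelSpec
    coef: np.ndarray  # (B, n_terms)
    seed: int

    def __post_init__(self) -> None:
        if self.coef.ndim != 2 or self.coef.shape[1] != self.spec.n_terms:
            raise ValueError("ensemble coefficients must be (B, n_terms)")
        if self.coef.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 realizations")

    @property
    def n_replicates(self) -> int:
        return int(self.coef.shape[0])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.coef, columns=list(self.spec.terms))
        frame.insert(0, "replicate", np.arange(self.n_replicates))
        frame.insert(0, "year", self.year)
        frame.insert(0, "crop", self.crop)
        return frame


def bootstrap_fit(
    records: pd.DataFrame,
    spec: ModelSpec,
    year: int,
    B: int = 1000,
    seed: int = 0,
    config: LossConfig | None = None,
    factors: NormalizationFactors | None = None,
) -> BootstrapEnsemble:
    """Refit the regularized surface on B resamples of one year's records.

    Normalization factors are computed once from the full data (or passed
    in) and reused for every replicate, mirroring the single factor table
    kept per crop.  A replicate whose resample yields a degenerate design
    is redrawn up to three times; more than 5% irrecoverable failures
    aborts the ensemble.
    """
    if config is None:
        config = LossConfig()
    sub = records.loc[records["year"] == year].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no records for year {year}")
    if factors is None:
        _, factors = zscore(records, columns=spec.covariates + [RESPONSE])
    norm, _ = zscore(sub, columns=[c for c in factors.columns if c in sub.columns], factors=factors)
    X = build_design(norm, spec)
    y = norm[RESPONSE].to_numpy(float)
    a = sub["area_ha"].to_numpy(float)
    n = len(sub)
    intercept_idx = spec.terms.index("1")
    crop = str(sub["crop"].iloc[0]) if "crop" in sub.columns else ""

    coefs = np.empty((B, spec.n_terms))
    failures = 0
    for b in range(B):
        rng = np.random.default_rng([seed, int(year), b])  # seed ladder leaf
        for attempt in range(4):
            idx = rng.integers(0, n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta, _ = fit_quantile(X[idx], y[idx], a[idx], config, intercept_idx)
                coefs[b] = beta
                break
            except (ValueError, RuntimeError):
                continue
        else:
            failures += 1
            coefs[b] = np.nan
    if failures > 0.05 * B:
        raise RuntimeError(f"bootstrap failed: {failures}/{B} replicates irrecoverable")
    if failures:
        warnings.warn(f"{failures} bootstrap replicates failed and were dropped")
        coefs = coefs[~np.isnan(coefs).any(axis=1)]
    return BootstrapEnsemble(crop=crop, year=int(year), spec=spec, coef=coefs, seed=seed)


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("percentile interval needs at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(v, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def significant_sign(values, level: float = 0.95) -> str:
    """Sign call from percentile bounds: both > 0, both < 0, or neither.

    Returns ``"positive"``, ``"negative"`` or ``"none"``; a zero bound is
    treated as straddling (not significant).
    """
    lo, hi = percentile_ci(values, level)
    if lo > 0 and hi > 0:
        return "positive"
    if lo < 0 and hi < 0:
        return "negative"
    return "none"
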