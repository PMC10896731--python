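"""Area-weighted quantile-regression surfaces for attainable yield.

The attainable yield of a census unit is modelled as the τ = 0.95
conditional quantile of observed yields given the unit's biophysical
covariates.  The fitting criterion is the area-weighted pinball (check)
loss

    LF_τ = [ Σ_i w_i |y_i − q_i| a_i ] / Σ_i a_i,
    w_i = τ if y_i > q_i else (1 − τ),

where ``a_i`` is harvested area.  Because this loss only weakly constrains
the share of harvested area below the surface, a calibration penalty

    λ = s.d.(y) · Σ_i a_i · | Σ_{j: q_j > y_j} a_j / Σ a  −  τ |

is added for the per-year production fits; the regularized fit drives the
area-weighted under-surface fraction to τ by adjusting the intercept of
the exact linear-programming solution (the fraction is monotone
non-decreasing in the intercept, so the adjustment that minimizes λ given
the fitted slopes is the weighted τ-quantile of the residuals).

All fitting is done on z-scored covariates and response, so coefficients
are unitless; :class:`AnnualFit` carries the normalization factors needed
to map predictions back to t/ha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .ingest import NormalizationFactors, weighted_quantile, zscore

__all__ = [
    "LossConfig",
    "ModelSpec",
    "AnnualFit",
    "quantile_loss",
    "lambda_penalty",
    "build_design",
    "fit_weighted_quantile_lp",
    "fit_quantile",
    "predict_attainable",
    "fit_annual_series",
    "under_surface_fraction",
]

#: Core model terms for all crops other than wheat (quadratic climate
#: response, rainfall concentration, irrigation and its precipitation and
#: concentration interactions, soil and terrain).
BASE_TERMS = (
    "1", "gdd", "map", "gdd^2", "map^2", "gdd*map",
    "pci", "pci*map", "irr", "irr*map", "irr*pci",
    "awc", "soc", "slope30", "ph",
)
#: Wheat adds a vernalization indicator and its climate interactions.
WHEAT_TERMS = BASE_TERMS + ("vf", "vf*gdd", "vf*map")

#: Terms never removed by pruning or child-model deletion.
PROTECTED_ALWAYS = frozenset({"1", "irr", "irr*map"})
#: Additional protections while time terms are in play (model selection).
PROTECTED_SELECTION = PROTECTED_ALWAYS | {"t", "t^2"}

TIME_TERMS = ("t", "t^2")

RESPONSE = "yield_t_ha"


@dataclass(frozen=True)
class LossConfig:
    """Quantile level and regularization settings for a fit."""

    tau: float = 0.95
    regularized: bool = True
    sd_y: float | None = None  # s.d.(y) entering λ; computed from data when None
    calibration_tol: float = 1e-3  # acceptable |achieved fraction − τ|

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("quantile level tau must lie in (0, 1)")


def _parse_term(term: str) -> list[tuple[str, int]]:
    """``"gdd^2"`` → [("gdd", 2)]; ``"irr*map"`` → [("irr", 1), ("map", 1)]."""
    if term == "1":
        return []
    factors = []
    for piece in term.split("*"):
        if "^" in piece:
            var, power = piece.split("^")
            factors.append((var, int(power)))
        else:
            factors.append((piece, 1))
    return factors


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of regression terms with protected-term flags.

    Terms are products of powers of covariate names (``"gdd^2"``,
    ``"irr*map"``) plus the intercept ``"1"`` and optional time terms
    ``"t"``/``"t^2"``.  Protected terms survive every pruning and
    child-model deletion step.
    """

    terms: tuple[str, ...]
    protected: frozenset[str] = field(default_factory=lambda: PROTECTED_ALWAYS)

    def __post_init__(self) -> None:
        if "1" not in self.terms:
            raise ValueError("model spec must contain the intercept term '1'")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")

    @classmethod
    def for_crop(cls, archetype: str = "default", time_terms: bool = False) -> "ModelSpec":
        """Starting spec for a crop archetype (``"wheat"`` adds VF terms)."""
        terms = WHEAT_TERMS if archetype == "wheat" else BASE_TERMS
        if time_terms:
            return cls(terms + TIME_TERMS, protected=PROTECTED_SELECTION)
        return cls(terms, protected=PROTECTED_ALWAYS)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def covariates(self) -> list[str]:
        names: list[str] = []
        for term in self.terms:
            for var, _ in _parse_term(term):
                if var not in names:
                    names.append(var)
        return names

    def deletable_terms(self) -> list[str]:
        return [t for t in self.terms if t not in self.protected]

    def drop(self, term: str) -> "ModelSpec":
        if term in self.protected:
            raise ValueError(f"cannot drop protected term {term!r}")
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def without_time(self) -> "ModelSpec":
        """Remove t and t² (order of the remaining terms preserved)."""
        return ModelSpec(
            terms=tuple(t for t in self.terms if t not in TIME_TERMS),
            protected=frozenset(self.protected - set(TIME_TERMS)),
        )


@dataclass(frozen=True)
class AnnualFit:
    """Coefficients of one year's attainable-yield surface in z-score space."""

    year: int
    spec: ModelSpec
    coef: np.ndarray
    factors: NormalizationFactors
    loss: float
    under_fraction: float  # achieved area-weighted fraction with y on/below surface

    def __post_init__(self) -> None:
        if len(self.coef) != self.spec.n_terms:
            raise ValueError("coefficient vector length must equal number of terms")


def _check_weights(a: np.ndarray) -> None:
    if np.any(a < 0):
        raise ValueError("area weights must be non-negative")
    if not a.sum() > 0:
        raise ValueError("total harvested area must be positive")


def quantile_loss(y, q, a, tau: float) -> float:
    """Area-weighted pinball loss of predictions ``q`` against yields ``y``."""
    y, q, a = (np.asarray(x, dtype=float) for x in (y, q, a))
    _check_weights(a)
    w = np.where(y > q, tau, 1.0 - tau)
    return float(np.sum(w * np.abs(y - q) * a) / a.sum())


def under_surface_fraction(y, q, a, strict: bool = False, atol: float = 1e-9) -> float:
    """Area-weighted fraction of records below the surface.

    ``strict=False`` (the package-wide tie convention) counts records on
    the surface as below, matching the ``y ≤ q`` branch of the loss;
    ``strict=True`` counts only ``y < q``.  ``atol`` absorbs solver-level
    float fuzz when records sit exactly on a fitted surface.
    """
    y, q, a = (np.asarray(x, dtype=float) for x in (y, q, a))
    _check_weights(a)
    below = (y < q - atol) if strict else (y <= q + atol)
    return float(a[below].sum() / a.sum())


def lambda_penalty(y, q, a, tau: float, sd_y: float, ties_below: bool = True) -> float:
    """Calibration penalty λ: zero iff the under-surface area share is τ.

    The under-surface share counts on-surface records as encompassed by
    default, the tie convention used throughout; ``ties_below=False``
    counts strictly-below records only.
    """
    y, q, a = (np.asarray(x, dtype=float) for x in (y, q, a))
    _check_weights(a)
    frac = under_surface_fraction(y, q, a, strict=not ties_below)
    return float(sd_y * a.sum() * abs(frac - tau))


def build_design(covariates: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Design matrix with one column per spec term, evaluated on z-scores."""
    n = len(covariates)
    cols = []
    for term in spec.terms:
        col = np.ones(n)
        for var, power in _parse_term(term):
            if var not in covariates.columns:
                raise ValueError(f"missing covariate {var!r} required by term {term!r}")
            col = col * covariates[var].to_numpy(float) ** power
        cols.append(col)
    return np.column_stack(cols)


def fit_weighted_quantile_lp(X: np.ndarray, y: np.ndarray, a: np.ndarray, tau: float) -> np.ndarray:
    """Exact minimizer of the area-weighted pinball loss, by linear programming.

    Splits each residual into its positive and negative parts
    (y = Xβ + u − v, u, v ≥ 0) and minimizes Σ a_i (τ u_i + (1−τ) v_i),
    which equals the loss numerator.  Solved with the HiGHS LP solver on a
    sparse constraint matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"underdetermined fit: {n} rows for {p} coefficients")
    _check_weights(a)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    eye = sp.eye(n, format="csc")
    A_eq = sp.hstack([sp.csc_matrix(X), eye, -eye], format="csc")
    c = np.concatenate([np.zeros(p), tau * a, (1.0 - tau) * a])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if res.status != 0:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"quantile LP failed to converge: {res.message}")
    return res.x[:p]


def _calibrate_intercept(
    X: np.ndarray, y: np.ndarray, a: np.ndarray, beta: np.ndarray, tau: float, intercept_idx: int
) -> np.ndarray:
    """Shift the intercept so the on/below-surface area share is closest to τ.

    The share is a monotone non-decreasing step function of the intercept,
    so the λ-minimizing shift (slopes held fixed) is attained at a residual
    order statistic: the weighted τ-quantile of the residuals reaches a
    share ≥ τ, and the preceding distinct residual gives the largest share
    below τ.  The candidate with the share nearer τ wins; ties go to the
    smaller shift.
    """
    r = y - X @ beta
    a_tot = a.sum()
    c_hi = weighted_quantile(r, a, tau)

    def frac_at(c: float) -> float:
        return float(a[r <= c + 1e-9].sum() / a_tot)

    candidates = [(c_hi, frac_at(c_hi)), (0.0, frac_at(0.0))]
    lower = r[r < c_hi]
    if lower.size:
        c_lo = float(np.max(lower))
        candidates.append((c_lo, frac_at(c_lo)))
    candidates.sort(key=lambda cf: (abs(cf[1] - tau), abs(cf[0])))
    c_best = candidates[0][0]
    beta = beta.copy()
    beta[intercept_idx] += c_best
    return beta


#: tilt magnitudes (z-score units) tried by the refinement pass
_TILT_GRID = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2)


def _tilt_refinement(
    X: np.ndarray, y: np.ndarray, a: np.ndarray, beta: np.ndarray, tau: float,
    intercept_idx: int, tol: float,
) -> np.ndarray:
    """One refinement pass when intercept calibration alone is too coarse.

    The achievable under-surface fractions are partial sums of area
    weights in residual order; when a heavy record sits exactly at the τ
    boundary the nearest achievable fraction can be far from τ.  A small
    tilt of one slope coefficient reorders the residuals, letting lighter
    records cross the surface instead.  The pass scans a fixed grid of
    signed tilts per slope (re-calibrating the intercept each time, which
    is cheap) and adopts the first-best fraction improvement; it is
    deterministic and leaves β untouched when no tilt helps.
    """
    def calibrated_frac(b: np.ndarray) -> tuple[np.ndarray, float]:
        b2 = _calibrate_intercept(X, y, a, b, tau, intercept_idx)
        return b2, under_surface_fraction(y, X @ b2, a)

    best_beta, best_frac = calibrated_frac(beta)
    if abs(best_frac - tau) <= tol:
        return best_beta
    for j in range(X.shape[1]):
        if j == intercept_idx:
            continue
        for mag in _TILT_GRID:
            for sign in (1.0, -1.0):
                trial = beta.copy()
                trial[j] += sign * mag
                cand_beta, cand_frac = calibrated_frac(trial)
                if abs(cand_frac - tau) < abs(best_frac - tau) - 1e-12:
                    best_beta, best_frac = cand_beta, cand_frac
                if abs(best_frac - tau) <= tol:
                    return best_beta
    return best_beta


def fit_quantile(
    X: np.ndarray,
    y: np.ndarray,
    a: np.ndarray,
    config: LossConfig,
    intercept_idx: int = 0,
) -> tuple[np.ndarray, dict]:
    """Fit the quantile surface; returns coefficients plus diagnostics.

    The unregularized path is the exact LP solution of the weighted
    pinball loss.  The regularized path additionally recalibrates the
    intercept so the area-weighted on/below-surface share is as close to τ
    as the data allow, which minimizes the λ penalty given the slopes.
    Diagnostics report the achieved loss, share and λ.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    beta = fit_weighted_quantile_lp(X, y, a, config.tau)
    if config.regularized:
        beta = _tilt_refinement(
            X, y, a, beta, config.tau, intercept_idx, config.calibration_tol
        )
    q = X @ beta
    sd_y = config.sd_y if config.sd_y is not None else float(np.std(y, ddof=1))
    frac = under_surface_fraction(y, q, a)
    diag = {
        "loss": quantile_loss(y, q, a, config.tau),
        "under_fraction": frac,
        "lambda": lambda_penalty(y, q, a, config.tau, sd_y),
        "calibrated": abs(frac - config.tau),
    }
    if config.regularized and diag["calibrated"] > max(config.calibration_tol, np.max(a) / a.sum()):
        warnings.warn(
            f"calibration residual {diag['calibrated']:.4f} exceeds tolerance; "
            "a single record may dominate the area distribution"
        )
    return beta, diag


def fit_year(
    records: pd.DataFrame,
    spec: ModelSpec,
    factors: NormalizationFactors,
    year: int,
    config: LossConfig,
) -> AnnualFit:
    """Fit one year's records (z-scoring via shared ``factors``)."""
    sub = records.loc[records["year"] == year]
    norm, _ = zscore(sub, columns=[c for c in factors.columns if c in sub.columns], factors=factors)
    X = build_design(norm, spec)
    y = norm[RESPONSE].to_numpy(float)
    a = sub["area_ha"].to_numpy(float)
    beta, diag = fit_quantile(X, y, a, config, intercept_idx=spec.terms.index("1"))
    return AnnualFit(
        year=int(year), spec=spec, coef=beta, factors=factors,
        loss=diag["loss"], under_fraction=diag["under_fraction"],
    )


def fit_annual_series(
    records: pd.DataFrame,
    spec: ModelSpec,
    years: list[int] | None = None,
    config: LossConfig | None = None,
    factors: NormalizationFactors | None = None,
) -> dict[int, AnnualFit]:
    """One regularized fit per year, each on that year's records only.

    The spec must carry no time terms (they are removed before annual
    fitting); normalization factors are computed once over all records so
    coefficients are comparable across years.  Years with fewer than five
    records per term are skipped with a warning.
    """
    if config is None:
        config = LossConfig()
    if any(t in spec.terms for t in TIME_TERMS):
        raise ValueError("annual fits require a spec without time terms; call without_time()")
    if factors is None:
        _, factors = zscore(records, columns=spec.covariates + [RESPONSE])
    if years is None:
        years = sorted(records["year"].unique())
    fits: dict[int, AnnualFit] = {}
    for year in years:
        n_year = int((records["year"] == year).sum())
        if n_year < 5 * spec.n_terms:
            warnings.warn(f"year {year}: only {n_year} records for {spec.n_terms} terms; skipped")
            continue
        fits[int(year)] = fit_year(records, spec, factors, int(year), config)
    return fits


def predict_attainable(fit: AnnualFit, covariates: pd.DataFrame) -> np.ndarray:
    """Attainable yields (t/ha) for raw-unit covariates, floored at zero.

    Covariates are mapped to z-space with the fit's stored factors; values
    more than six factor standard deviations from the training mean raise
    an extrapolation warning rather than an error.
    """
    cov_cols = [c for c in fit.factors.columns if c != RESPONSE and c in covariates.columns]
    norm, _ = zscore(covariates, columns=cov_cols, factors=fit.factors)
    zmax = max((np.max(np.abs(norm[c].to_numpy(float))) for c in cov_cols), default=0.0)
    if zmax > 6.0:
        warnings.warn(f"covariates up to {zmax:.1f} s.d. outside training support")
    X = build_design(norm, fit.spec)
    y_z = X @ fit.coef
    y_phys = y_z * fit.factors.sds[RESPONSE] + fit.factors.means[RESPONSE]
    if np.any(y_phys < 0):
        warnings.warn("negative attainable-yield predictions floored at 0 t/ha")
    return np.maximum(y_phys, 0.0)
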