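"""Census-table ingest: schema, quality control, aggregation and z-scoring.

The unit of observation is one (administrative unit, crop, year) census
record carrying actual yield in tonnes per harvested hectare, harvested
area in hectares (the area weight ``a_i`` used throughout the pipeline),
the harvested-area fraction of unit land area (a multicropping index when
above 1) and the biophysical covariates.

Tables are plain :class:`pandas.DataFrame` objects in the column layout of
:data:`SCHEMA_COLUMNS`; delimited-text round-trip helpers are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "COVARIATE_COLUMNS",
    "NormalizationFactors",
    "weighted_quantile",
    "qc_filter",
    "aggregate_to_unit",
    "zscore",
    "denormalize",
    "read_census_table",
    "write_census_table",
]

COVARIATE_COLUMNS = ["gdd", "map", "pci", "irr", "awc", "soc", "ph", "slope30", "vf"]
SCHEMA_COLUMNS = [
    "unit_id",
    "crop",
    "year",
    "yield_t_ha",
    "area_ha",
    "area_fraction",
    *COVARIATE_COLUMNS,
]

#: multicropping index above which a record is rejected (harvested area > 300%)
MAX_AREA_FRACTION = 3.0


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-column mean and standard deviation backing the z-score transform.

    One factor set is stored per crop so that coefficients fitted in
    different years remain directly comparable.  Standard deviations use
    the population (ddof=0) convention and must be strictly positive.
    """

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for col, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"zero-variance column in normalization factors: {col!r}")

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.columns,
             "mean": [self.means[c] for c in self.columns],
             "sd": [self.sds[c] for c in self.columns]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormalizationFactors":
        return cls(
            means=dict(zip(frame["column"], frame["mean"].astype(float))),
            sds=dict(zip(frame["column"], frame["sd"].astype(float))),
        )


def weighted_quantile(values, weights, q: float) -> float:
    """Quantile of the left-continuous weighted empirical CDF.

    Returns the smallest observed value ``x`` whose cumulative weight
    reaches ``q`` of the total.  Ties are resolved by value order, so the
    result is always one of the observed values and is deterministic.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_quantile of empty data")
    if np.any(w < 0) or not w.sum() > 0:
        raise ValueError("weights must be non-negative with positive total")
    if not 0 < q <= 1:
        raise ValueError("quantile level must lie in (0, 1]")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, q * cw[-1] - 1e-12 * cw[-1]))
    idx = min(idx, v.size - 1)
    return float(v[order][idx])


def qc_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-filter census records per crop-year group.

    Two screens are applied simultaneously within each (crop, year) group:

    * multicropping: ``area_fraction`` above 3 (harvested area over 300% of
      unit land area) rejects the record;
    * yield outliers: yields above the area-weighted 97.5th-percentile
      yield of the group plus twice the group's (unweighted, ddof=1)
      yield standard deviation reject the record.

    Returns the kept records plus a rejection log (one row per reject with
    a ``qc_reason``).  The kept table carries ``qc_flag = "pass"``.
    """
    if records["area_ha"].isna().any():
        raise ValueError("missing harvested-area weights; cannot compute weighted percentile")
    kept_parts: list[pd.DataFrame] = []
    log_parts: list[pd.DataFrame] = []
    for (crop, year), group in records.groupby(["crop", "year"], sort=True):
        if group.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty crop-year group ({crop}, {year}) passed through")
            continue
        multicrop = group["area_fraction"].to_numpy(float) > MAX_AREA_FRACTION
        y = group["yield_t_ha"].to_numpy(float)
        a = group["area_ha"].to_numpy(float)
        if a.sum() > 0:
            p975 = weighted_quantile(y, a, 0.975)
        else:
            p975 = float(np.max(y))
        sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
        outlier = y > p975 + 2.0 * sd
        reject = multicrop | outlier
        kept = group.loc[~reject].copy()
        kept["qc_flag"] = "pass"
        kept["qc_reason"] = ""
        kept_parts.append(kept)
        if reject.any():
            log = group.loc[reject].copy()
            reasons = np.where(
                multicrop[reject], "multicropping > 3", "yield > weighted 97.5th pct + 2 s.d."
            )
            log["qc_flag"] = "reject"
            log["qc_reason"] = reasons
            log_parts.append(log)
    kept_all = (
        pd.concat(kept_parts, ignore_index=True) if kept_parts
        else records.iloc[0:0].assign(qc_flag="pass", qc_reason="")
    )
    log_all = (
        pd.concat(log_parts, ignore_index=True) if log_parts
        else records.iloc[0:0].assign(qc_flag="reject", qc_reason="")
    )
    return kept_all, log_all


def aggregate_to_unit(subrecords: pd.DataFrame, weight_col: str = "area_ha") -> pd.Series:
    """Collapse sub-records into one row by harvested-area-weighted averaging.

    Every numeric column except the weight itself becomes the weighted mean
    of the sub-records; the weight column becomes the total.  Weighted
    means are invariant to uniform rescaling of the weights and to how the
    sub-records are partitioned before merging.
    """
    w = subrecords[weight_col].to_numpy(float)
    if np.any(w < 0):
        raise ValueError("harvested-area weights must be non-negative")
    total = w.sum()
    if not total > 0:
        raise ValueError("no harvested area: all weights are zero")
    out: dict[str, object] = {}
    for col in subrecords.columns:
        if col == weight_col:
            out[col] = float(total)
        elif pd.api.types.is_numeric_dtype(subrecords[col]):
            out[col] = float(np.average(subrecords[col].to_numpy(float), weights=w))
        else:
            vals = subrecords[col].unique()
            if len(vals) > 1:
                raise ValueError(f"non-numeric column {col!r} not constant within aggregate")
            out[col] = vals[0]
    return pd.Series(out)


def zscore(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    factors: NormalizationFactors | None = None,
) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Z-score the given columns, computing or reusing normalization factors.

    With ``factors=None`` (fit path) the mean and population standard
    deviation of each column are computed from ``table``; supplying
    ``factors`` (prediction path) reuses them unchanged.  The transform is
    exactly invertible through :func:`denormalize`.
    """
    if columns is None:
        columns = [c for c in COVARIATE_COLUMNS if c in table.columns]
    if factors is None:
        means, sds = {}, {}
        for col in columns:
            x = table[col].to_numpy(float)
            mu, sd = float(np.mean(x)), float(np.std(x, ddof=0))
            if not sd > 0:
                raise ValueError(f"zero-variance covariate cannot be z-scored: {col!r}")
            means[col], sds[col] = mu, sd
        factors = NormalizationFactors(means, sds)
    out = table.copy()
    for col in columns:
        if col not in factors.means:
            raise ValueError(f"no normalization factors for column {col!r}")
        out[col] = (table[col].to_numpy(float) - factors.means[col]) / factors.sds[col]
    return out, factors


def denormalize(table: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """Invert :func:`zscore` for every factor column present in ``table``."""
    out = table.copy()
    for col in factors.columns:
        if col in out.columns:
            out[col] = out[col].to_numpy(float) * factors.sds[col] + factors.means[col]
    return out


def read_census_table(path, covariate_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a delimited census table, optionally joining covariates on unit_id.

    Validates the schema and the basic record invariants (non-negative
    yields and areas, unique (unit_id, crop, year) keys).
    """
    table = pd.read_csv(path)
    if covariate_table is not None:
        table = table.merge(covariate_table, on="unit_id", how="left", validate="many_to_one")
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    if (table["yield_t_ha"] < 0).any() or (table["area_ha"] < 0).any():
        raise ValueError("yield and harvested area must be non-negative")
    if table.duplicated(["unit_id", "crop", "year"]).any():
        raise ValueError("duplicate (unit_id, crop, year) records")
    return table


def write_census_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
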