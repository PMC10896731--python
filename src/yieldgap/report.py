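"""End-to-end pipeline orchestration and report tables.

``run_pipeline`` sequences the full analysis — ingest (or simulate) → QC →
model selection → per-year regularized fits → bootstrap ensembles → gap
trends → typology and stagnation — and writes delimited report tables:
area-with-growth and gap-change tables per period, global average change
rates, per-unit time-to-closure and typology labels, and the selection
trace.  Every output carries a header block with the serialized run
configuration hash and master seed, so a run can be reproduced from any
of its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bootstrap as bt
from . import ingest, selection, simulate, trends, typology
from .quantile import LossConfig, ModelSpec, fit_annual_series

log = logging.getLogger("yieldgap")

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_PERIODS = {
    "entire": ((1975, 2010), 2000),
    "first_decade": ((1975, 1985), 1975),
    "last_decade": ((2000, 2010), 2000),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, serialized into every output."""

    output_dir: str = "yieldgap_out"
    input_path: str | None = None  # census CSV; None → simulate
    crop_archetype: str = "default"  # "wheat" enables the VF terms
    n_units: int = 200  # simulated panel size when input_path is None
    tau: float = 0.95
    n_bootstrap: int = 50
    n_boot_prune: int = 50
    ci_level: float = 0.95
    seed: int = 0
    select: bool = False  # run the (expensive) model-selection phase
    trend_period: tuple[int, int] = (1998, 2012)
    periods: dict = field(default_factory=lambda: dict(DEFAULT_PERIODS))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# yieldgap run config_hash={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the bundle of result tables.

    Any stage failure after the first outputs leaves a partial bundle on
    disk together with a machine-readable ``error_manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "init"
    t0 = time.time()
    try:
        stage = "ingest"
        if config.input_path is None:
            scen = simulate.ScenarioConfig(
                n_units=config.n_units, seed=config.seed, archetype=config.crop_archetype
            )
            records, _, truth = simulate.generate_panel(scen)
            bundle["ground_truth_units"] = truth.units
            _write(truth.units, out / "ground_truth_units.csv", config)
        else:
            records = ingest.read_census_table(config.input_path)
        records, rejects = ingest.qc_filter(records)
        _write(rejects, out / "qc_rejects.csv", config)
        log.info("ingest: %d records kept, %d rejected (%.1fs)",
                 len(records), len(rejects), time.time() - t0)

        stage = "selection"
        start = ModelSpec.for_crop(config.crop_archetype, time_terms=True)
        if config.select:
            layers = selection.build_layers(records)
            trace = selection.select_model(
                start, layers, tau=config.tau, n_boot=config.n_boot_prune, seed=config.seed
            )
            spec = selection.strip_time_terms(trace.selected)
            _write(trace.to_frame(), out / "selection_trace.csv", config)
        else:
            spec = start.without_time()
        log.info("selection: spec has %d terms (%.1fs)", spec.n_terms, time.time() - t0)

        stage = "annual_fits"
        loss_cfg = LossConfig(tau=config.tau)
        fits = fit_annual_series(records, spec, config=loss_cfg)
        coef_rows = [
            {"year": yr, "term": term, "estimate": fit.coef[j],
             "under_fraction": fit.under_fraction}
            for yr, fit in fits.items() for j, term in enumerate(spec.terms)
        ]
        _write(pd.DataFrame(coef_rows), out / "annual_coefficients.csv", config)
        if fits:
            factors = next(iter(fits.values())).factors
            _write(factors.to_frame(), out / "normalization_factors.csv", config)
        log.info("annual fits: %d years (%.1fs)", len(fits), time.time() - t0)

        stage = "bootstrap"
        ensembles = {
            yr: bt.bootstrap_fit(records, spec, yr, B=config.n_bootstrap,
                                 seed=config.seed, config=loss_cfg)
            for yr in fits
        }
        log.info("bootstrap: %d ensembles of B=%d (%.1fs)",
                 len(ensembles), config.n_bootstrap, time.time() - t0)

        stage = "trends"
        gs = trends.gap_series_from_records(records, ensembles)
        period_rows = []
        for name, (period, ref_year) in config.periods.items():
            row = {"period": name, "start": period[0], "end": period[1],
                   "reference_year": ref_year}
            row["attainable_growth_area_pct"] = trends.area_fraction_significant(
                gs, "attainable", "increase", period, ref_year, level=config.ci_level)
            row["gap_growth_area_pct"] = trends.area_fraction_significant(
                gs, "gap", "increase", period, ref_year, level=config.ci_level)
            row["gap_decrease_area_pct"] = trends.area_fraction_significant(
                gs, "gap", "decrease", period, ref_year, level=config.ci_level)
            for quantity in ("attainable", "gap"):
                change = trends.global_average_change(
                    gs, quantity, period, base_year=ref_year, level=config.ci_level)
                row[f"{quantity}_change_pct_per_yr"] = change["rate"]
                row[f"{quantity}_change_lo"], row[f"{quantity}_change_hi"] = change["ci"]
            period_rows.append(row)
        _write(pd.DataFrame(period_rows), out / "period_tables.csv", config)

        closure_rows = []
        for unit in gs.unit_ids:
            tr = trends.linear_gap_trend(gs, unit, period=config.trend_period,
                                         level=config.ci_level)
            category, value = trends.time_to_closure(tr)
            closure_rows.append({"unit_id": unit, "category": category,
                                 "t_close": value, "slope": tr.x1})
        _write(pd.DataFrame(closure_rows), out / "time_to_closure.csv", config)
        log.info("trends (%.1fs)", time.time() - t0)

        stage = "typology"
        labels = typology.classify_units(gs, period=config.trend_period, level=config.ci_level)
        _write(labels, out / "typology_labels.csv", config)
        _write(typology.typology_area_table(labels), out / "typology_area_table.csv", config)

        stag_rows = []
        for u, unit in enumerate(gs.unit_ids):
            res = typology.piecewise_stagnation(gs.years, gs.actual[u])
            pre_trend = trends.linear_gap_trend(gs, unit, period=(1986, 2000),
                                                level=config.ci_level)
            growth = trends.single_series_trend(
                gs.years[(gs.years >= 1986) & (gs.years <= 2000)],
                gs.actual[u, (gs.years >= 1986) & (gs.years <= 2000)], 1986)
            stag_rows.append({
                "unit_id": unit, "stagnant": res.stagnant,
                "indeterminate": res.indeterminate,
                "pre_slope": res.pre_slope, "post_slope": res.post_slope,
                "closing30": typology.closing_within(pre_trend, horizon_end_year=2030),
                "growth_rate": growth.x1,
            })
        stag = pd.DataFrame(stag_rows)
        _write(stag, out / "stagnation.csv", config)
        risk = typology.stagnation_risk_ratio(stag)
        with open(out / "stagnation_risk.json", "w") as fh:
            json.dump({"config_hash": config.digest(), "seed": config.seed, **risk}, fh, indent=2)
        bundle.update({"records": records, "fits": fits, "gap_series": gs,
                       "labels": labels, "stagnation": stag, "risk": risk,
                       "periods": pd.DataFrame(period_rows)})
        log.info("pipeline complete (%.1fs)", time.time() - t0)
        return bundle
    except Exception as exc:
        manifest = {"stage": stage, "error": repr(exc), "config_hash": config.digest()}
        with open(out / "error_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
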