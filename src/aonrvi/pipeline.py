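"""End-to-end orchestration: simulate -> VIs -> clean -> regress -> fit -> assess.

A run is fully determined by a :class:`RunConfig` (simulator block plus
analysis thresholds) and writes every stage's inputs and outputs to a run
directory, together with a design-enumeration report and a JSON log of the
seed, thresholds and library versions. Re-running with the same configuration
and seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .aonr_accuracy import build_pairs, standard_summaries
from .config import SimConfig, default_study_design, simconfig_from_dict
from .response_models import (
    R2_THRESHOLD,
    retention_summary,
    run_curve_battery,
)
from .synthetic_field import (
    TrialDesign,
    TrueField,
    generate_trial,
    generate_yield_points,
    render_scene,
)
from .vi_core import ALL_VIS, zonal_vi_table
from .vi_yield_regression import (
    P_SIGNIFICANT,
    heatmap_table,
    run_regression_battery,
    summarize_battery,
)
from .yield_cleaning import CleaningThresholds, clean_yield_points, subplot_yield_table


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Thresholds default to the protocol's published values (p < 0.10
    significance, R^2 > 0.50 curve screen, the yield-monitor bounds); any
    override is echoed into the run log.
    """

    sim: SimConfig
    cleaning: CleaningThresholds = field(default_factory=CleaningThresholds)
    p_threshold: float = P_SIGNIFICANT
    r2_threshold: float = R2_THRESHOLD
    vis: Tuple[str, ...] = ALL_VIS
    curve_timings: Tuple[int, ...] = (1, 2, 3)
    regression_timings: Optional[Tuple[int, ...]] = None  # None = full calendar
    write_scenes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = simconfig_from_dict(doc.get("sim", {}))
        cleaning = CleaningThresholds(**doc.get("cleaning", {}))
        kw = {
            k: v
            for k, v in doc.items()
            if k in ("p_threshold", "r2_threshold", "write_scenes")
        }
        if "vis" in doc:
            kw["vis"] = tuple(doc["vis"])
        if "curve_timings" in doc:
            kw["curve_timings"] = tuple(int(t) for t in doc["curve_timings"])
        if "regression_timings" in doc:
            kw["regression_timings"] = tuple(
                int(t) for t in doc["regression_timings"]
            )
        return cls(sim=sim, cleaning=cleaning, **kw)


def enumerate_design(
    designs: Dict[str, TrialDesign],
    timings: Sequence[int],
    vis: Sequence[str],
    curve_timings: Sequence[int] = (1, 2, 3),
) -> dict:
    """Pure design arithmetic: how many models/curves the run will evaluate.

    Independent of any data values; the counts must match the row counts of
    the corresponding stage outputs (flagged placeholders included).
    """
    n_fields = len(designs)
    n_vis = len(vis)
    periods = {}
    for d in designs.values():
        for t in timings:
            periods[t] = d.period(t)
        break
    veg = [t for t in timings if periods.get(t) == "vegetative"]
    rep = [t for t in timings if periods.get(t) == "reproductive"]
    transects = sum(len(d.transect_ids) for d in designs.values())
    per_field_curves = {
        tid: len(d.transect_ids) * len(curve_timings) * n_vis
        for tid, d in designs.items()
    }
    return {
        "n_fields": n_fields,
        "n_vis": n_vis,
        "n_timings": len(timings),
        "n_transects": transects,
        "regressions_total": n_fields * len(timings) * n_vis,
        "regressions_vegetative": n_fields * len(veg) * n_vis,
        "regressions_reproductive": n_fields * len(rep) * n_vis,
        "curves_total": transects * len(curve_timings) * n_vis,
        "curves_per_field": per_field_curves,
        "curves_per_vi": transects * len(curve_timings),
        "yield_curves": transects,
    }


def run_all(config: RunConfig, outdir: str | Path) -> Dict[str, pd.DataFrame]:
    """Execute the full pipeline and write all stage outputs under ``outdir``.

    Returns the in-memory tables keyed by stage name. Raises with a
    stage-labeled error on failure; outputs written before the failure are
    preserved for inspection.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    cfg.validate()

    stage = "simulate"
    try:
        designs: Dict[str, TrialDesign] = {}
        truths: Dict[str, TrueField] = {}
        zones_frames: List[pd.DataFrame] = []
        points_frames: List[pd.DataFrame] = []
        zonal_frames: List[pd.DataFrame] = []
        for i, trial in enumerate(cfg.trials):
            design, truth = generate_trial(cfg, i)
            designs[design.trial_id] = design
            truths[design.trial_id] = truth
            zones = truth.zone_table(design)
            zones_frames.append(zones)
            _io.write_design_json(design, out / f"design_{design.trial_id}.json")
            pts = generate_yield_points(design, truth, cfg)
            points_frames.append(pts)
            stage = "compute-vi"
            for timing in sorted(cfg.timing_calendar):
                scene = render_scene(design, truth, timing, cfg)
                if config.write_scenes:
                    _io.write_scene_geotiff(
                        scene, out / f"scene_{design.trial_id}_t{timing}.tif"
                    )
                zt = zonal_vi_table(scene, zones, vis=config.vis)
                zonal_frames.append(zt)
            stage = "simulate"
        zones_all = pd.concat(zones_frames, ignore_index=True)
        points_all = pd.concat(points_frames, ignore_index=True)
        zonal = pd.concat(zonal_frames, ignore_index=True)
        _io.write_csv(zones_all, out / "zones.csv")
        _io.write_csv(points_all, out / "yield_points.csv")
        _io.write_csv(zonal, out / "zonal_vi.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "clean-yield"
    try:
        cleaned, audit = clean_yield_points(
            points_all, zones_all, config.cleaning, cfg.pixel_size_m
        )
        yields = subplot_yield_table(cleaned, zones_all)
        _io.write_csv(cleaned, out / "yield_points_cleaned.csv")
        _io.write_csv(yields, out / "subplot_yield.csv")
        (out / "cleaning_audit.json").write_text(json.dumps(audit, indent=1))
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "regress"
    try:
        regressions = run_regression_battery(
            zonal,
            yields,
            designs,
            timings=config.regression_timings,
            vis=config.vis,
            p_threshold=config.p_threshold,
        )
        reg_summary = summarize_battery(regressions)
        _io.write_csv(regressions, out / "regressions.csv")
        _io.write_csv(reg_summary, out / "regression_summary.csv")
        _io.write_csv(heatmap_table(regressions), out / "regression_heatmap.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "fit-response"
    try:
        decisions = run_curve_battery(
            zonal,
            yields,
            designs,
            timings=config.curve_timings,
            vis=config.vis,
            r2_threshold=config.r2_threshold,
        )
        _io.write_csv(decisions, out / "curve_decisions.csv")
        vi_dec = decisions[decisions["vi_name"] != "yield"]
        _io.write_csv(
            retention_summary(vi_dec, by=("trial_id", "timing")),
            out / "retention_by_field_timing.csv",
        )
        _io.write_csv(
            retention_summary(vi_dec, by=("vi_group", "vi_name", "timing")),
            out / "retention_by_vi_timing.csv",
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "assess"
    try:
        pairs = build_pairs(decisions)
        _io.write_csv(pairs, out / "aonr_pairs.csv")
        summaries = standard_summaries(pairs)
        for name, df in summaries.items():
            _io.write_csv(df, out / f"agreement_{name}.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    stage = "report"
    try:
        timings_reg = config.regression_timings or tuple(
            sorted(cfg.timing_calendar)
        )
        report = enumerate_design(
            designs, timings_reg, config.vis, config.curve_timings
        )
        report["regressions_rows"] = int(len(regressions))
        report["curves_rows"] = int(
            len(decisions[decisions["vi_name"] != "yield"])
        )
        report["yield_curve_rows"] = int(
            len(decisions[decisions["vi_name"] == "yield"])
        )
        report["curves_usable"] = int(
            decisions[decisions["vi_name"] != "yield"]["usable"].sum()
        )
        report["n_pairs"] = int(len(pairs))
        (out / "enumeration_report.json").write_text(json.dumps(report, indent=1))
        (out / "run_log.json").write_text(json.dumps(_run_log(config), indent=1))
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    return {
        "zones": zones_all,
        "points": points_all,
        "zonal": zonal,
        "cleaned": cleaned,
        "yields": yields,
        "regressions": regressions,
        "regression_summary": reg_summary,
        "decisions": decisions,
        "pairs": pairs,
        "agreement_all": summaries["all"],
        "report": pd.DataFrame([
            {k: v for k, v in report.items() if not isinstance(v, dict)}
        ]),
    }


def _run_log(config: RunConfig) -> dict:
    from importlib.metadata import version

    import scipy
    import tifffile

    cfg_repr = repr(config).encode()
    return {
        "seed": config.sim.seed,
        "p_threshold": config.p_threshold,
        "r2_threshold": config.r2_threshold,
        "cleaning": config.cleaning.as_dict(),
        "config_sha1": hashlib.sha1(cfg_repr).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
            "click": version("click"),
        },
    }


def default_run_config(seed: int = 0, **sim_overrides) -> RunConfig:
    """RunConfig for the default three-trial study design."""
    return RunConfig(sim=default_study_design(seed=seed, **sim_overrides))
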