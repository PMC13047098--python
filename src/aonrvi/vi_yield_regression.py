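"""Field-level VI-yield screening regressions.

For every (field x image timing x VI) combination, a simple ordinary
least-squares regression of subplot grain yield (dependent) on the subplot
mean VI (independent) is fitted and summarized by its coefficient of
determination R^2 = 1 - RSS/TSS, RMSE, and normalized RMSE (RMSE divided by
the range of observed yields, making sites with different yield ranges
comparable). Models with a two-sided slope-test p below 0.10 are counted as
significant; for a simple regression this t-test coincides with the model
F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vi_core import ALL_VIS, vi_group

P_SIGNIFICANT = 0.10


@dataclass
class RegressionResult:
    """One fitted VI-yield regression."""

    trial_id: str
    timing: int
    vi_name: str
    n_obs: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    rmse: float
    nrmse: float
    significant: bool
    period: str = ""
    valid: bool = True  # False for degenerate input (constant x, too few obs)


def fit_vi_yield(
    x: Sequence[float],
    y: Sequence[float],
    trial_id: str = "",
    timing: int = 0,
    vi_name: str = "",
    period: str = "",
    p_threshold: float = P_SIGNIFICANT,
) -> RegressionResult:
    """OLS of yield on one VI; flags degenerate inputs instead of raising.

    Requires at least 3 paired finite observations and non-constant x for a
    valid result; otherwise a flagged placeholder is returned so battery
    enumeration counts are preserved.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return RegressionResult(
            trial_id, timing, vi_name, n, np.nan, np.nan, np.nan, np.nan,
            np.nan, np.nan, False, period, valid=False,
        )
    fit = stats.linregress(x, y)
    pred = fit.intercept + fit.slope * x
    rss = float(((y - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    rmse = float(np.sqrt(rss / n))
    nrmse = rmse / float(np.ptp(y))
    return RegressionResult(
        trial_id=trial_id,
        timing=timing,
        vi_name=vi_name,
        n_obs=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        p_value=float(fit.pvalue),
        rmse=rmse,
        nrmse=nrmse,
        significant=bool(fit.pvalue < p_threshold),
        period=period,
        valid=True,
    )


def results_to_frame(results: Iterable[RegressionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "trial_id": r.trial_id,
                "timing": r.timing,
                "period": r.period,
                "vi_name": r.vi_name,
                "vi_group": vi_group(r.vi_name) if r.vi_name in ALL_VIS else "",
                "n_obs": r.n_obs,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "rmse": r.rmse,
                "nrmse": r.nrmse,
                "significant": r.significant,
                "valid": r.valid,
            }
        )
    return pd.DataFrame(rows)


def run_regression_battery(
    zonal: pd.DataFrame,
    yields: pd.DataFrame,
    designs: Dict[str, "TrialDesign"],
    timings: Optional[Sequence[int]] = None,
    vis: Optional[Sequence[str]] = None,
    p_threshold: float = P_SIGNIFICANT,
) -> pd.DataFrame:
    """One regression per (trial x timing x VI); the subplot is the unit.

    Exactly |trials| x |timings| x |VIs| rows come back regardless of data
    quality: degenerate cells are flagged placeholders, preserving the
    enumeration. Timings default to each design's full calendar.
    """
    vis = tuple(vis or ALL_VIS)
    results: List[RegressionResult] = []
    for trial_id, design in designs.items():
        ztrial = zonal[zonal["trial_id"] == trial_id]
        ytrial = yields[yields["trial_id"] == trial_id][
            ["subplot_id", "yield_mg_ha"]
        ]
        trial_timings = timings or sorted(design.timing_calendar)
        for timing in trial_timings:
            if timing not in design.timing_calendar:
                raise ValueError(
                    f"timing {timing} missing from {trial_id} calendar"
                )
            period = design.period(timing)
            zt = ztrial[ztrial["timing"] == timing]
            for vi in vis:
                zv = zt[zt["vi_name"] == vi]
                merged = zv.merge(ytrial, on="subplot_id", how="inner")
                results.append(
                    fit_vi_yield(
                        merged["mean_value"].to_numpy()
                        if len(merged)
                        else np.empty(0),
                        merged["yield_mg_ha"].to_numpy()
                        if len(merged)
                        else np.empty(0),
                        trial_id=trial_id,
                        timing=timing,
                        vi_name=vi,
                        period=period,
                        p_threshold=p_threshold,
                    )
                )
    return results_to_frame(results)


def _summary_row(sub: pd.DataFrame, period: str, group: str, fld: str) -> dict:
    sig = sub[sub["significant"] & sub["valid"]]
    return {
        "period": period,
        "vi_group": group,
        "field": fld,
        "models": int(len(sub)),
        "significant_models": int(len(sig)),
        "min_r2": float(sig["r_squared"].min()) if len(sig) else np.nan,
        "max_r2": float(sig["r_squared"].max()) if len(sig) else np.nan,
        "min_nrmse": float(sig["nrmse"].min()) if len(sig) else np.nan,
        "max_nrmse": float(sig["nrmse"].max()) if len(sig) else np.nan,
    }


def summarize_battery(results: pd.DataFrame) -> pd.DataFrame:
    """Period x VI-group x field summary of the regression battery.

    For each period (vegetative/reproductive), spectral group (ALL/NIR/RGB)
    and field (ALL plus each trial): models evaluated, significant count, and
    the R^2 / nRMSE ranges over significant models only.
    """
    rows = []
    for period in ("vegetative", "reproductive"):
        per = results[results["period"] == period]
        if not len(per):
            continue
        for group in ("ALL", "NIR", "RGB"):
            gsub = per if group == "ALL" else per[per["vi_group"] == group]
            rows.append(_summary_row(gsub, period, group, "ALL"))
            if group != "ALL":
                for fld in sorted(per["trial_id"].unique()):
                    rows.append(
                        _summary_row(
                            gsub[gsub["trial_id"] == fld], period, group, fld
                        )
                    )
    return pd.DataFrame(rows)


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format (trial, timing, VI, R^2, significant) table for heatmaps."""
    return results[
        ["trial_id", "timing", "vi_name", "vi_group", "r_squared", "significant"]
    ].copy()
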