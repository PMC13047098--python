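"""Agreement between VI-derived and yield-derived optimum N rates.

Every retained VI-N curve contributes one comparison pair: its AONRvi against
the same transect's AONRy (so a transect can contribute one pair per usable
VI x timing). Accuracy metrics:

* signed percent difference, (AONRvi - AONRy) / AONRy * 100 — negative means
  the VI underestimates the yield-based optimum;
* R^2 as the squared Pearson correlation of the paired values;
* RMSE and MAE in kg N/ha.

Undefined correlations (fewer than two pairs, or zero variance in either
variable) are reported as missing, never as zero.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


def percent_difference(aonr_vi: float, aonr_y: float) -> float:
    """Signed percent difference of an estimate vs the yield-based optimum."""
    if aonr_y <= 0:
        raise ValueError("aonr_y must be positive")
    return (aonr_vi - aonr_y) / aonr_y * 100.0


def build_pairs(decisions: pd.DataFrame) -> pd.DataFrame:
    """Pair each usable VI-N decision with its transect's usable yield AONR.

    ``decisions`` is the curve-battery frame (VI rows plus ``vi_name ==
    "yield"`` rows). Transects whose yield-N curve failed screening contribute
    no pairs.
    """
    yrows = decisions[(decisions["vi_name"] == "yield") & decisions["usable"]]
    aonr_y = {
        (r.trial_id, r.transect_id): float(r.aonr) for r in yrows.itertuples()
    }
    virows = decisions[(decisions["vi_name"] != "yield") & decisions["usable"]]
    rows = []
    for r in virows.itertuples():
        key = (r.trial_id, r.transect_id)
        if key not in aonr_y:
            continue
        ay = aonr_y[key]
        rows.append(
            {
                "trial_id": r.trial_id,
                "transect_id": r.transect_id,
                "timing": int(r.timing),
                "vi_name": r.vi_name,
                "vi_group": r.vi_group,
                "aonr_vi": float(r.aonr),
                "aonr_y": ay,
                "pct_diff": percent_difference(float(r.aonr), ay),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "transect_id", "timing", "vi_name", "vi_group",
            "aonr_vi", "aonr_y", "pct_diff",
        ],
    )


def _stats_one(sub: pd.DataFrame) -> dict:
    est = sub["aonr_vi"].to_numpy(dtype=float)
    obs = sub["aonr_y"].to_numpy(dtype=float)
    n = len(sub)
    err = est - obs
    rec = {
        "n_pairs": n,
        "mean_pct_diff": float(sub["pct_diff"].mean()) if n else np.nan,
        "rmse": float(np.sqrt((err**2).mean())) if n else np.nan,
        "mae": float(np.abs(err).mean()) if n else np.nan,
    }
    if n >= 2 and np.ptp(est) > 0 and np.ptp(obs) > 0:
        r = float(np.corrcoef(obs, est)[0, 1])
        rec["r_squared"] = r * r
    else:
        rec["r_squared"] = np.nan
    return rec


def agreement_stats(
    pairs: pd.DataFrame, by: Sequence[str] = ()
) -> pd.DataFrame:
    """Accuracy summary over all pairs or per grouping keys.

    With no keys a single "All" row is returned; otherwise one row per group
    (unweighted over its pairs) with n, mean percent difference, Pearson-based
    R^2, RMSE and MAE.
    """
    if not by:
        rec = _stats_one(pairs)
        rec["group"] = "All"
        return pd.DataFrame([rec])[
            ["group", "n_pairs", "mean_pct_diff", "r_squared", "rmse", "mae"]
        ]
    rows = []
    for keys, sub in pairs.groupby(list(by), dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rec = dict(zip(by, keys))
        rec.update(_stats_one(sub))
        rows.append(rec)
    cols = list(by) + ["n_pairs", "mean_pct_diff", "r_squared", "rmse", "mae"]
    return pd.DataFrame(rows)[cols]


def standard_summaries(pairs: pd.DataFrame) -> dict:
    """The package's standard accuracy breakdowns, keyed by name."""
    return {
        "all": agreement_stats(pairs),
        "by_field": agreement_stats(pairs, by=("trial_id",)),
        "by_timing": agreement_stats(pairs, by=("timing",)),
        "by_vi": agreement_stats(pairs, by=("vi_name",)),
        "by_group_timing": agreement_stats(pairs, by=("vi_group", "timing")),
        "by_field_vi_timing": agreement_stats(
            pairs, by=("trial_id", "vi_name", "timing")
        ),
    }
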