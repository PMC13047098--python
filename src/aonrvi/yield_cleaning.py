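"""Yield-monitor cleaning and moisture standardization.

The cleaning protocol for combine yield-monitor streams:

1. remove points outside the study area (not inside any subplot zone);
2. remove points with abnormal combine heading (further than a configurable
   tolerance, default 30 degrees, from the pass's circular median heading);
3. remove grain moisture outside [10%, 33%];
4. remove travel speed outside [0.7, 8.2] mph;
5. remove points whose speed changed by more than 15% from the previous
   reading in the same pass;
6. standardize retained yields to 150 g kg^-1 (15%) moisture;
7. remove extreme outliers beyond +/- 3 standard deviations from the
   treatment mean (single pass, on the standardized yield).

Flags are assigned in that fixed order and all applicable flags are recorded
per point; a point carries an ``adjusted_yield`` only if its flag set is
empty. The speed-jump rule compares each reading against the immediately
preceding reading of the acquisition sequence (flagged or not); across a gap
in the sequence there is no previous reading and the rule does not apply,
which makes the filter idempotent on its own retained output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

STANDARD_MOISTURE_PCT = 15.0

REMOVAL_REASONS = (
    "outside_area",
    "heading",
    "moisture_range",
    "speed_range",
    "speed_jump",
    "treatment_outlier",
)

REQUIRED_COLUMNS = (
    "x",
    "y",
    "pass_id",
    "seq",
    "heading_deg",
    "speed_mph",
    "moisture_pct",
    "wet_yield",
)


@dataclass
class CleaningThresholds:
    """Cleaning-rule thresholds (defaults are the protocol's published values)."""

    moisture_min_pct: float = 10.0
    moisture_max_pct: float = 33.0
    speed_min_mph: float = 0.7
    speed_max_mph: float = 8.2
    speed_jump_frac: float = 0.15
    heading_tol_deg: float = 30.0
    outlier_sd: float = 3.0
    outlier_scope: str = "field"  # "field" or "transect"

    def as_dict(self) -> dict:
        return {
            "moisture_min_pct": self.moisture_min_pct,
            "moisture_max_pct": self.moisture_max_pct,
            "speed_min_mph": self.speed_min_mph,
            "speed_max_mph": self.speed_max_mph,
            "speed_jump_frac": self.speed_jump_frac,
            "heading_tol_deg": self.heading_tol_deg,
            "outlier_sd": self.outlier_sd,
            "outlier_scope": self.outlier_scope,
        }


def standardize_moisture(
    wet_yield: np.ndarray | float, moisture_pct: np.ndarray | float
) -> np.ndarray | float:
    """Adjust wet yield to the 15% standard moisture basis.

    adjusted = wet * (1 - moisture/100) / (1 - 0.15). Moisture must lie in
    [0, 100); at exactly 15% the yield is unchanged.
    """
    m = np.asarray(moisture_pct, dtype=float)
    if np.any(m < 0) or np.any(m >= 100):
        raise ValueError("moisture must be in [0, 100) percent")
    out = np.asarray(wet_yield, dtype=float) * (1.0 - m / 100.0) / (
        1.0 - STANDARD_MOISTURE_PCT / 100.0
    )
    return out if out.ndim else float(out)


def circular_median_deg(headings: np.ndarray) -> float:
    """Circular median: the observed heading minimizing summed angular distance.

    Ties resolve to the first minimizer in input order. O(n^2), adequate for
    per-pass streams.
    """
    h = np.asarray(headings, dtype=float) % 360.0
    if h.size == 0:
        raise ValueError("empty heading array")
    diff = np.abs(((h[:, None] - h[None, :]) + 180.0) % 360.0 - 180.0)
    return float(h[int(np.argmin(diff.sum(axis=1)))])


def _angular_dist(a: np.ndarray, b: float) -> np.ndarray:
    return np.abs(((a - b) + 180.0) % 360.0 - 180.0)


def filter_points(
    points: pd.DataFrame,
    zones: Optional[pd.DataFrame] = None,
    thresholds: Optional[CleaningThresholds] = None,
    pixel_size_m: float = 3.0,
) -> pd.DataFrame:
    """Assign removal flags; returns a copy with ``flags`` and ``retained``.

    ``zones`` is the pixel->subplot membership table (columns subplot_id,
    row, col); when given, each point is mapped to the zone of the pixel
    containing it (center-point grid rule) into a ``subplot_id`` column, and
    unassigned points are flagged ``outside_area``. Points must be ordered by
    acquisition sequence within each pass (``seq`` strictly increasing).
    """
    th = thresholds or CleaningThresholds()
    missing = [c for c in REQUIRED_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"points table missing required columns: {missing}")
    df = points.copy()
    for pid, g in df.groupby("pass_id", sort=False):
        if not g["seq"].is_monotonic_increasing:
            raise ValueError(f"pass {pid!r} is not ordered by acquisition sequence")

    flags: List[List[str]] = [[] for _ in range(len(df))]

    # 1. outside the study area. Each trial has its own pixel grid, so the
    # lookup is keyed by trial when both tables carry a trial_id.
    if zones is not None:
        per_trial = "trial_id" in df.columns and "trial_id" in zones.columns
        if per_trial:
            owner = {
                (str(t), int(r), int(c)): str(s)
                for t, r, c, s in zip(
                    zones["trial_id"], zones["row"], zones["col"],
                    zones["subplot_id"],
                )
            }
        else:
            owner = {
                (int(r), int(c)): str(s)
                for r, c, s in zip(zones["row"], zones["col"], zones["subplot_id"])
            }
        rows = np.floor(df["y"].to_numpy() / pixel_size_m).astype(int)
        cols = np.floor(df["x"].to_numpy() / pixel_size_m).astype(int)
        if per_trial:
            assigned = [
                owner.get((str(t), r, c), "")
                for t, r, c in zip(df["trial_id"], rows, cols)
            ]
        else:
            assigned = [owner.get((r, c), "") for r, c in zip(rows, cols)]
        df["subplot_id"] = assigned
        for i, sid in enumerate(assigned):
            if not sid:
                flags[i].append("outside_area")

    # 2. abnormal heading relative to the pass's circular median
    pos = {idx: i for i, idx in enumerate(df.index)}
    for _, g in df.groupby("pass_id", sort=False):
        med = circular_median_deg(g["heading_deg"].to_numpy())
        dev = _angular_dist(g["heading_deg"].to_numpy(), med)
        for idx, d in zip(g.index, dev):
            if d > th.heading_tol_deg:
                flags[pos[idx]].append("heading")

    # 3. moisture range
    m = df["moisture_pct"].to_numpy()
    for i in np.flatnonzero((m < th.moisture_min_pct) | (m > th.moisture_max_pct)):
        flags[i].append("moisture_range")

    # 4. speed range
    v = df["speed_mph"].to_numpy()
    for i in np.flatnonzero((v < th.speed_min_mph) | (v > th.speed_max_mph)):
        flags[i].append("speed_range")

    # 5. speed jump vs the immediately preceding reading in the pass. The
    # comparison applies only between consecutive readings of the original
    # acquisition sequence (seq difference of 1): on a stream with readings
    # already removed there is no "previous reading" across a gap, which
    # also makes the filter idempotent on its own output.
    for _, g in df.groupby("pass_id", sort=False):
        gv = g["speed_mph"].to_numpy()
        gseq = g["seq"].to_numpy()
        rel = np.abs(np.diff(gv)) / np.where(gv[:-1] > 0, gv[:-1], np.nan)
        adjacent = np.diff(gseq) == 1
        for idx, r, adj in zip(g.index[1:], rel, adjacent):
            if adj and np.isfinite(r) and r > th.speed_jump_frac:
                flags[pos[idx]].append("speed_jump")

    df["flags"] = [";".join(f) for f in flags]
    df["retained"] = df["flags"] == ""
    df["adjusted_yield"] = np.where(
        df["retained"],
        standardize_moisture(df["wet_yield"].to_numpy(), df["moisture_pct"].to_numpy()),
        np.nan,
    )
    return df


def remove_treatment_outliers(
    df: pd.DataFrame,
    value_col: str = "adjusted_yield",
    group_cols: Iterable[str] = ("treatment",),
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """Flag values beyond k standard deviations from their treatment mean.

    Single pass: the mean and (sample) standard deviation are computed on the
    group before any removal. Groups with fewer than two finite values pass
    through untouched. Adds/extends ``flags`` with ``treatment_outlier`` and
    updates ``retained`` / ``adjusted_yield`` consistently.
    """
    out = df.copy()
    if "flags" not in out.columns:
        out["flags"] = ""
    vals = out[value_col].to_numpy(dtype=float)
    flag_new = np.zeros(len(out), dtype=bool)
    for _, g in out.groupby(list(group_cols), sort=False, dropna=False):
        idx = g.index.to_numpy()
        gv = vals[[out.index.get_loc(i) for i in idx]]
        ok = np.isfinite(gv)
        if ok.sum() < 2:
            continue
        mean = float(gv[ok].mean())
        sd = float(gv[ok].std(ddof=1))
        if sd == 0.0:
            continue
        bad = ok & (np.abs(gv - mean) > k_sd * sd)
        for i, b in zip(idx, bad):
            if b:
                flag_new[out.index.get_loc(i)] = True
    old = out["flags"].to_numpy(dtype=object)
    out["flags"] = [
        (f + ";" if f else "") + "treatment_outlier" if b else f
        for f, b in zip(old, flag_new)
    ]
    out["retained"] = out["flags"] == ""
    if value_col in out.columns:
        out.loc[~out["retained"], value_col] = np.nan
    return out


def clean_yield_points(
    points: pd.DataFrame,
    zones: pd.DataFrame,
    thresholds: Optional[CleaningThresholds] = None,
    pixel_size_m: float = 3.0,
) -> Tuple[pd.DataFrame, dict]:
    """Full cleaning chain: range filters -> standardization -> outlier filter.

    Returns the flagged point table and an audit report (counts per removal
    reason, thresholds used, retention). Counts satisfy
    retained + flagged = input.
    """
    th = thresholds or CleaningThresholds()
    df = filter_points(points, zones, th, pixel_size_m)
    field_col = ["trial_id"] if "trial_id" in df.columns else []
    if th.outlier_scope == "transect" and "subplot_id" in df.columns:
        sub_meta = zones.drop_duplicates("subplot_id")[
            ["subplot_id", "transect_id", "treatment"]
        ]
        df = df.merge(sub_meta, on="subplot_id", how="left")
        group_cols = field_col + ["transect_id", "treatment"]
    else:
        sub_meta = zones.drop_duplicates("subplot_id")[["subplot_id", "treatment"]]
        df = df.merge(sub_meta, on="subplot_id", how="left")
        group_cols = field_col + ["treatment"]
    df = remove_treatment_outliers(
        df, value_col="adjusted_yield", group_cols=group_cols, k_sd=th.outlier_sd
    )
    reason_counts = {r: 0 for r in REMOVAL_REASONS}
    for f in df["flags"]:
        for r in f.split(";") if f else []:
            reason_counts[r] += 1
    audit = {
        "n_input": int(len(df)),
        "n_retained": int(df["retained"].sum()),
        "n_flagged": int((~df["retained"]).sum()),
        "reason_counts": reason_counts,
        "thresholds": th.as_dict(),
    }
    return df, audit


def subplot_yield_table(cleaned: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    """Mean cleaned yield per subplot, joined to subplot metadata.

    Subplots with no retained points appear with NaN yield and n_points 0, so
    downstream batteries can preserve their enumeration slots.
    """
    meta_cols = [
        c
        for c in ("trial_id", "transect_id", "subplot_id", "treatment", "n_rate")
        if c in zones.columns
    ]
    meta = zones.drop_duplicates("subplot_id")[meta_cols]
    kept = cleaned[cleaned["retained"]]
    agg = (
        kept.groupby("subplot_id")["adjusted_yield"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "yield_mg_ha", "count": "n_points"})
        .reset_index()
    )
    out = meta.merge(agg, on="subplot_id", how="left")
    out["n_points"] = out["n_points"].fillna(0).astype(int)
    return out
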