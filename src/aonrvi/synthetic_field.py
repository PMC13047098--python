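"""Virtual on-farm N-rate strip trials with known ground truth.

Generates complete field trials — transect/subplot layout, per-transect true
optimum N rates, plateau-type yield responses, multi-date 4-band reflectance
scenes, and yield-monitor point streams with injected artifacts — so the
downstream analysis (VI extraction, cleaning, regression, dose-response
fitting, AONR agreement) can be exercised end-to-end with every answer known.

Scenes are rendered by per-pixel linear spectral mixing:

    reflectance = f * canopy + (1 - f) * (r * residue + (1 - r) * soil) + noise

where ``f`` is the subplot's canopy fraction at the image timing and ``r`` the
trial's residue cover fraction (tillage scenario). Pixels outside any subplot
get the background mixture (f = 0). Canopy fraction grows logistically with
timing and is scaled by N sufficiency, so mean VI increases with applied N at
vegetative timings and saturates beyond the transect's true AONR.

Random streams are separated by purpose (truth, scene noise, harvest stream,
artifact injection), each seeded from ``(seed, trial_index, stream)``, so the
same configuration and seed reproduce byte-identical outputs regardless of
call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ARTIFACT_CLASSES, BANDS, SimConfig, TrialSpec
from .vi_core import SCALE, SpectralScene

# generator artifact class -> removal reason the cleaning stage should assign
EXPECTED_FLAG: Dict[str, str] = {
    "moisture_low": "moisture_range",
    "moisture_high": "moisture_range",
    "speed_low": "speed_range",
    "speed_high": "speed_range",
    "speed_jump": "speed_jump",
    "heading": "heading",
    "yield_outlier": "treatment_outlier",
}

_STREAM_TRUTH = 0
_STREAM_SCENE = 1000  # + timing
_STREAM_HARVEST = 2000
_STREAM_ARTIFACT = 3000


@dataclass(frozen=True)
class Subplot:
    subplot_id: str
    transect_id: str
    treatment: str
    n_rate: float
    x0: float
    y0: float
    length_m: float
    width_m: float


@dataclass
class TrialDesign:
    """Treatments, transects, subplot geometry and timing calendar of a trial."""

    trial_id: str
    trial_index: int
    fnr: float
    treatments: Tuple[Tuple[str, float, int], ...]  # (label, rate, replications)
    transect_ids: Tuple[str, ...]
    subplots: Tuple[Subplot, ...]
    timing_calendar: Dict[int, Tuple[str, str]]
    max_n_rate: float

    def subplot_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": self.trial_id,
                    "transect_id": s.transect_id,
                    "subplot_id": s.subplot_id,
                    "treatment": s.treatment,
                    "n_rate": s.n_rate,
                }
                for s in self.subplots
            ]
        )

    def period(self, timing: int) -> str:
        return self.timing_calendar[timing][1]

    def stage(self, timing: int) -> str:
        return self.timing_calendar[timing][0]

    def validate(self) -> None:
        labels = [t[0] for t in self.treatments]
        for tid in self.transect_ids:
            got = sorted(
                s.treatment for s in self.subplots if s.transect_id == tid
            )
            if got != sorted(labels):
                raise ValueError(
                    f"{self.trial_id}/{tid}: transect must contain every "
                    f"treatment exactly once (got {got})"
                )
        if self.max_n_rate != max(t[1] for t in self.treatments):
            raise ValueError("max_n_rate must equal the largest treatment rate")


@dataclass
class TrueField:
    """Hidden ground truth for one simulated trial."""

    trial_id: str
    aonr: Dict[str, float]  # transect_id -> true AONR
    plateau_yield: Dict[str, float]  # transect_id -> yield plateau (Mg/ha)
    expected_yield: Dict[str, float]  # subplot_id -> expected yield (Mg/ha)
    canopy_fraction: Dict[Tuple[str, int], float]  # (subplot_id, timing) -> f
    zone_pixels: Dict[str, Tuple[np.ndarray, np.ndarray]]  # subplot -> (rows, cols)
    scene_shape: Tuple[int, int]
    pixel_size_m: float

    def zone_table(self, design: TrialDesign) -> pd.DataFrame:
        """Pixel -> subplot membership table (center-point rule)."""
        meta = {s.subplot_id: s for s in design.subplots}
        frames = []
        for subplot_id, (rows, cols) in self.zone_pixels.items():
            s = meta[subplot_id]
            frames.append(
                pd.DataFrame(
                    {
                        "trial_id": self.trial_id,
                        "transect_id": s.transect_id,
                        "subplot_id": subplot_id,
                        "treatment": s.treatment,
                        "n_rate": s.n_rate,
                        "row": rows,
                        "col": cols,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# plateau response families (shared by yield truth and refitting tests)
# ---------------------------------------------------------------------------

def plateau_response(
    n: np.ndarray | float,
    family: str,
    y_at_zero: float,
    plateau: float,
    join: float,
) -> np.ndarray | float:
    """Expected response at N rate(s) ``n`` for a rise-then-plateau curve.

    ``family`` is ``"quadratic_plateau"`` (smooth vertex at ``join``) or
    ``"linear_plateau"``; the curve passes through ``y_at_zero`` at N = 0 and
    is constant at ``plateau`` for N >= ``join``.
    """
    n = np.asarray(n, dtype=float)
    nn = np.minimum(n, join)
    if family == "quadratic_plateau":
        k = (plateau - y_at_zero) / join**2
        out = plateau - k * (join - nn) ** 2
    elif family == "linear_plateau":
        b = (plateau - y_at_zero) / join
        out = y_at_zero + b * nn
    else:
        raise ValueError(f"unknown plateau family {family!r}")
    return out if out.ndim else float(out)


def _plateau_shape(n: float, family: str, join: float) -> float:
    """Normalized plateau shape: 0 at N = 0, 1 at and beyond the join."""
    return float(plateau_response(n, family, 0.0, 1.0, join))


def _canopy_fmax(cfg: SimConfig, timing: int) -> float:
    z = cfg.canopy_logistic_rate * (timing - cfg.canopy_logistic_midpoint)
    return 1.0 / (1.0 + math.exp(-z))


def canopy_fraction(cfg: SimConfig, n_rate: float, aonr: float, timing: int) -> float:
    """Canopy cover fraction for a subplot at an image timing.

    Logistic growth in timing index sets the stage ceiling; the N effect is
    either a diminishing-returns sufficiency factor ``min(1, N/AONR)**gamma``
    (default) or the yield plateau family normalized to [rel0, 1]
    (``canopy_response="plateau"``).
    """
    fmax = _canopy_fmax(cfg, timing)
    if cfg.canopy_response == "logistic":
        s = min(1.0, n_rate / aonr) ** cfg.canopy_gamma
    else:
        rel0 = cfg.canopy_rel_at_zero
        s = rel0 + (1.0 - rel0) * _plateau_shape(n_rate, cfg.yield_family, aonr)
    return fmax * s


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _rng(cfg: SimConfig, trial_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, trial_index, stream])
    )


def _pixel_range(start: float, extent: float, px: float) -> np.ndarray:
    """Indices whose pixel centers fall in the half-open [start, start+extent)."""
    lo = math.ceil(start / px - 0.5)
    hi = math.ceil((start + extent) / px - 0.5)
    return np.arange(max(lo, 0), max(hi, 0), dtype=int)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled normal draw truncated to (lo, hi]."""
    if sd == 0:
        return float(min(max(mean, np.nextafter(lo, hi)), hi))
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return float(v)
    raise RuntimeError("truncated normal sampling failed; check mean/sd vs bounds")


def generate_trial(cfg: SimConfig, trial_index: int) -> Tuple[TrialDesign, TrueField]:
    """Generate one trial's design and hidden truth.

    Treatments are assigned to subplot positions in a per-transect random
    order; the true AONR is drawn per transect from the configured normal
    distribution truncated to (0, max tested rate].
    """
    cfg.validate()
    if not 0 <= trial_index < len(cfg.trials):
        raise IndexError(f"trial_index {trial_index} out of range")
    trial = cfg.trials[trial_index]
    rng = _rng(cfg, trial_index, _STREAM_TRUTH)
    px = cfg.pixel_size_m

    n_treat = len(trial.treatments)
    n_tr = cfg.transects_per_trial
    length, width = trial.subplot_length_m, trial.plot_width_m

    x_extent = 2 * cfg.margin_m + n_treat * length + (n_treat - 1) * cfg.buffer_consecutive_m
    y_extent = 2 * cfg.margin_m + n_tr * width + (n_tr - 1) * cfg.buffer_adjacent_m
    shape = (math.ceil(y_extent / px), math.ceil(x_extent / px))

    transect_ids = tuple(f"T{k + 1}" for k in range(n_tr))
    subplots: List[Subplot] = []
    zone_pixels: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    aonr: Dict[str, float] = {}
    plateau_yield: Dict[str, float] = {}
    expected_yield: Dict[str, float] = {}
    canopy: Dict[Tuple[str, int], float] = {}

    for k, tid in enumerate(transect_ids):
        order = rng.permutation(n_treat)
        aonr[tid] = _truncated_normal(
            rng, cfg.aonr_mean, cfg.aonr_sd, 0.0, trial.max_n_rate
        )
        plateau_yield[tid] = max(
            2.0, float(rng.normal(cfg.plateau_yield_mean, cfg.plateau_yield_sd))
        )
        y0 = cfg.margin_m + k * (width + cfg.buffer_adjacent_m)
        prows = _pixel_range(y0, width, px)
        for j, ti in enumerate(order):
            label, rate = trial.treatments[ti]
            x0 = cfg.margin_m + j * (length + cfg.buffer_consecutive_m)
            sid = f"{trial.trial_id}-{tid}-S{j + 1}"
            subplots.append(
                Subplot(sid, tid, label, rate, x0, y0, length, width)
            )
            pcols = _pixel_range(x0, length, px)
            rr, cc = np.meshgrid(prows, pcols, indexing="ij")
            zone_pixels[sid] = (rr.ravel(), cc.ravel())
            y_zero = cfg.rel_yield_at_zero * plateau_yield[tid]
            expected_yield[sid] = float(
                plateau_response(
                    rate, cfg.yield_family, y_zero, plateau_yield[tid], aonr[tid]
                )
            )
            for timing in cfg.timing_calendar:
                canopy[(sid, timing)] = canopy_fraction(cfg, rate, aonr[tid], timing)

    design = TrialDesign(
        trial_id=trial.trial_id,
        trial_index=trial_index,
        fnr=trial.fnr,
        treatments=tuple(
            (label, rate, trial.replications) for label, rate in trial.treatments
        ),
        transect_ids=transect_ids,
        subplots=tuple(subplots),
        timing_calendar=dict(cfg.timing_calendar),
        max_n_rate=trial.max_n_rate,
    )
    design.validate()
    truth = TrueField(
        trial_id=trial.trial_id,
        aonr=aonr,
        plateau_yield=plateau_yield,
        expected_yield=expected_yield,
        canopy_fraction=canopy,
        zone_pixels=zone_pixels,
        scene_shape=shape,
        pixel_size_m=px,
    )
    return design, truth


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def mixture_reflectance(
    cfg: SimConfig, trial: TrialSpec, f: float | np.ndarray, band: str
) -> float | np.ndarray:
    """Linear canopy/soil/residue mixture for one band at canopy fraction f."""
    r = trial.residue_fraction
    bg = (
        r * cfg.endmembers["residue"][band]
        + (1.0 - r) * cfg.endmembers["soil"][band]
    )
    return f * cfg.endmembers["canopy"][band] + (1.0 - np.asarray(f)) * bg


def render_scene(
    design: TrialDesign, truth: TrueField, timing: int, cfg: SimConfig
) -> SpectralScene:
    """Render one acquisition as a scaled-integer (x10,000) 4-band scene."""
    if timing not in design.timing_calendar:
        raise ValueError(
            f"timing {timing} not in calendar {sorted(design.timing_calendar)}"
        )
    trial = cfg.trials[design.trial_index]
    rng = _rng(cfg, design.trial_index, _STREAM_SCENE + timing)
    shape = truth.scene_shape
    bands: Dict[str, np.ndarray] = {}
    for band in BANDS:
        grid = np.full(shape, mixture_reflectance(cfg, trial, 0.0, band), dtype=float)
        for s in design.subplots:
            f = truth.canopy_fraction[(s.subplot_id, timing)]
            rows, cols = truth.zone_pixels[s.subplot_id]
            grid[rows, cols] = mixture_reflectance(cfg, trial, f, band)
        if cfg.noise_sd_reflectance > 0:
            grid = grid + rng.normal(0.0, cfg.noise_sd_reflectance, shape)
        scaledg = np.clip(grid, 0.0, 1.0) * SCALE
        if cfg.quantize_scenes:
            bands[band] = np.round(scaledg).astype(np.uint16)
        else:
            bands[band] = scaledg
    return SpectralScene(
        blue=bands["blue"],
        green=bands["green"],
        red=bands["red"],
        nir=bands["nir"],
        timing=timing,
        stage=design.stage(timing),
        trial_id=design.trial_id,
        pixel_size_m=cfg.pixel_size_m,
        x_origin=0.0,
        y_origin=0.0,
        scaled=True,
    )


# ---------------------------------------------------------------------------
# yield-monitor stream
# ---------------------------------------------------------------------------

STANDARD_MOISTURE = 15.0  # % wet basis


def _wet_from_adjusted(adjusted: np.ndarray, moisture: np.ndarray) -> np.ndarray:
    """Invert the 15%-moisture standardization: wet = adj * 0.85 / (1 - m/100)."""
    return adjusted * (1.0 - STANDARD_MOISTURE / 100.0) / (1.0 - moisture / 100.0)


def generate_yield_points(
    design: TrialDesign, truth: TrueField, cfg: SimConfig
) -> pd.DataFrame:
    """Simulate combine passes along each transect with labeled artifacts.

    One serpentine pass per transect; points are spaced so each subplot
    receives ``cfg.points_per_subplot`` readings, with extra readings falling
    in the between-subplot buffers (those are outside any zone and should be
    removed by the area filter). A configurable fraction of in-subplot points
    carries an injected artifact; the hidden truth label is in ``artifact``
    ("" for clean points) and the assigned subplot in ``true_subplot``
    ("" outside).

    Speeds for clean points follow a small-step random walk; after any
    injected speed artifact the stream ramps back toward its baseline at
    <= 13% per reading, so only injected points violate the 15% jump rule.
    """
    trial = cfg.trials[design.trial_index]
    rng = _rng(cfg, design.trial_index, _STREAM_HARVEST)
    rng_a = _rng(cfg, design.trial_index, _STREAM_ARTIFACT)
    px = truth.pixel_size_m
    length = trial.subplot_length_m
    step = length / cfg.points_per_subplot

    # pixel -> subplot lookup (the same center-point zones the analysis uses)
    pixel_owner: Dict[Tuple[int, int], str] = {}
    for sid, (rows, cols) in truth.zone_pixels.items():
        for r_, c_ in zip(rows.tolist(), cols.tolist()):
            pixel_owner[(r_, c_)] = sid

    by_transect: Dict[str, List[Subplot]] = {}
    for s in design.subplots:
        by_transect.setdefault(s.transect_id, []).append(s)

    records: List[dict] = []
    for k, tid in enumerate(design.transect_ids):
        subs = sorted(by_transect[tid], key=lambda s: s.x0)
        x_start = subs[0].x0
        x_end = subs[-1].x0 + subs[-1].length_m
        y_c = subs[0].y0 + subs[0].width_m / 2.0
        xs = np.arange(x_start + step / 2.0, x_end, step)
        heading_base = 90.0 if k % 2 == 0 else 270.0
        if k % 2 == 1:
            xs = xs[::-1]
        n = len(xs)
        headings = (heading_base + rng.normal(0.0, 3.0, n)) % 360.0
        moisture = np.clip(
            rng.normal(cfg.nominal_moisture_pct, 1.2, n), 12.0, 30.0
        )
        # baseline speed: bounded random walk with steps well below 15%
        v = np.empty(n)
        v[0] = cfg.nominal_speed_mph
        steps = rng.normal(0.0, 0.08, n - 1) if n > 1 else np.empty(0)
        for i in range(1, n):
            v[i] = float(
                np.clip(v[i - 1] + steps[i - 1], 4.0, 6.0)
            )
        pass_id = f"{design.trial_id}-{tid}"
        for i, x in enumerate(xs):
            row = int(math.floor(y_c / px))
            col = int(math.floor(x / px))
            sid = pixel_owner.get((row, col), "")
            if sid:
                adj = truth.expected_yield[sid]
            else:
                adj = 0.45 * cfg.plateau_yield_mean
            if cfg.noise_sd_yield > 0:
                adj += float(rng.normal(0.0, cfg.noise_sd_yield))
            records.append(
                {
                    "trial_id": design.trial_id,
                    "x": float(x),
                    "y": float(y_c),
                    "pass_id": pass_id,
                    "seq": i,
                    "heading_deg": float(headings[i]),
                    "speed_mph": float(v[i]),
                    "moisture_pct": float(moisture[i]),
                    "adjusted_true": max(adj, 0.1),
                    "true_subplot": sid,
                    "artifact": "",
                }
            )

    df = pd.DataFrame(records)

    # --- artifact injection (separate stream; labels recorded) -------------
    n_artifacts = int(round(cfg.artifact_fraction * len(df)))
    if n_artifacts > 0:
        eligible = df.index[(df["true_subplot"] != "") & (df["seq"] >= 2)].to_numpy()
        order = rng_a.permutation(eligible)
        chosen: List[int] = []
        for idx in order:
            if len(chosen) >= n_artifacts:
                break
            if all(abs(int(idx) - c) >= 8 for c in chosen):
                chosen.append(int(idx))
        classes = list(ARTIFACT_CLASSES)
        start = int(rng_a.integers(len(classes)))
        for m, idx in enumerate(sorted(chosen)):
            df.loc[idx, "artifact"] = classes[(start + m) % len(classes)]

    # apply non-speed artifacts
    art = df["artifact"]
    df.loc[art == "moisture_low", "moisture_pct"] = 7.0
    df.loc[art == "moisture_high", "moisture_pct"] = 36.0
    df.loc[art == "heading", "heading_deg"] = (
        df.loc[art == "heading", "heading_deg"] + 75.0
    ) % 360.0
    df.loc[art == "yield_outlier", "adjusted_true"] *= 2.5

    # apply speed artifacts with ramp-back, per pass in reading order
    base = df["speed_mph"].to_numpy().copy()
    final = base.copy()
    for _, g in df.groupby("pass_id", sort=False):
        idxs = g.index.to_numpy()  # already in reading order
        for pos in range(1, len(idxs)):
            i = idxs[pos]
            prev = final[idxs[pos - 1]]
            a = df.at[i, "artifact"]
            if a == "speed_low":
                final[i] = 0.65
            elif a == "speed_high":
                final[i] = 9.0
            elif a == "speed_jump":
                final[i] = prev * 1.25
            else:
                final[i] = float(np.clip(base[i], prev / 1.13, prev * 1.13))
    df["speed_mph"] = final

    df["wet_yield"] = _wet_from_adjusted(
        df["adjusted_true"].to_numpy(), df["moisture_pct"].to_numpy()
    )
    df = df.drop(columns=["adjusted_true"])
    return df


def transect_yield_table(
    points: pd.DataFrame, design: TrialDesign
) -> pd.DataFrame:
    """Mean adjusted yield per subplot from *clean* labeled points.

    Convenience for tests that bypass the cleaning stage; production code
    derives subplot yields from :mod:`aonrvi.yield_cleaning` output instead.
    """
    clean = points[(points["artifact"] == "") & (points["true_subplot"] != "")]
    adj = clean["wet_yield"] * (1.0 - clean["moisture_pct"] / 100.0) / 0.85
    tab = (
        pd.DataFrame({"subplot_id": clean["true_subplot"], "adjusted_yield": adj})
        .groupby("subplot_id", as_index=False)
        .mean()
    )
    meta = design.subplot_table()
    return meta.merge(tab, on="subplot_id", how="left")
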