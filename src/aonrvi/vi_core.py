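"""Vegetation-index computation from 4-band (B/G/R/NIR) reflectance scenes.

Implements the 16 indices used throughout the package — 8 visible-band (RGB)
and 8 near-infrared (NIR) indices — plus scaled-integer rescaling and
per-subplot zonal means. Surface-reflectance rasters arrive in the scaled
integer convention (reflectance x 10,000, 0-10000 in 16-bit) and are divided
by 10,000 before any index is computed.

Pixels where an index's denominator vanishes are set to NaN (a missing-value
sentinel) and counted, so downstream zonal means stay finite.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import BANDS

SCALE = 10_000.0

RGB = "RGB"
NIR = "NIR"


@dataclass
class SpectralScene:
    """One acquisition's 4-band grid plus timing metadata.

    ``scaled=True`` means bands hold scaled integers (reflectance x 10,000);
    after :func:`rescale_reflectance` they hold unitless reflectance in [0, 1].
    ``x_origin``/``y_origin`` anchor the grid's top-left corner in field
    coordinates (meters); pixel (row, col) covers the half-open square
    [origin + index*size, origin + (index+1)*size).
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    timing: int = 0
    stage: str = ""
    trial_id: str = ""
    acquisition_date: Optional[_dt.date] = None
    pixel_size_m: float = 3.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    scaled: bool = True
    clip_warnings: int = 0

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.blue, self.green, self.red, self.nir)}
        if len(shapes) != 1:
            raise ValueError(f"all four bands must share one shape, got {shapes}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.blue.shape

    def band(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown band {name!r}; expected one of {BANDS}")

    def bands(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in BANDS}


def rescale_band(scaled: np.ndarray) -> Tuple[np.ndarray, int]:
    """Divide a scaled-integer band by 10,000.

    Returns the reflectance grid and the count of values above 10,000 that
    were clipped to 1.0. Negative inputs raise, since surface reflectance in
    this convention is non-negative.
    """
    arr = np.asarray(scaled, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scaled reflectance values must be >= 0")
    n_clipped = int(np.count_nonzero(arr > SCALE))
    out = np.minimum(arr, SCALE) / SCALE
    return out, n_clipped


def rescale_reflectance(scene: SpectralScene) -> SpectralScene:
    """Rescale a scaled-integer scene to unit reflectance.

    Values above 10,000 are clipped to 1.0; the number of clipped pixels is
    recorded on ``clip_warnings``. A scene already in reflectance units is
    returned unchanged.
    """
    if not scene.scaled:
        return scene
    rescaled = {}
    n_clipped = 0
    for name in BANDS:
        out, n = rescale_band(scene.band(name))
        rescaled[name] = out
        n_clipped += n
    return SpectralScene(
        blue=rescaled["blue"],
        green=rescaled["green"],
        red=rescaled["red"],
        nir=rescaled["nir"],
        timing=scene.timing,
        stage=scene.stage,
        trial_id=scene.trial_id,
        acquisition_date=scene.acquisition_date,
        pixel_size_m=scene.pixel_size_m,
        x_origin=scene.x_origin,
        y_origin=scene.y_origin,
        scaled=False,
        clip_warnings=n_clipped,
    )


@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation index: spectral group plus a band expression."""

    name: str
    group: str  # RGB or NIR
    full_name: str
    func: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Element-wise num/den with zero denominators mapped to NaN."""
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _exg(b, g, r, n):
    return 2.0 * g - r - b


def _exr(b, g, r, n):
    return 1.4 * r - b


def _vdvi(b, g, r, n):
    return _ratio(2.0 * g - b - r, 2.0 * g + b + r)


def _pprb(b, g, r, n):
    return _ratio(g - b, g + b)


def _vari(b, g, r, n):
    return _ratio(g - r, g + r - b)


def _vig(b, g, r, n):
    return _ratio(g - r, g + r)


def _dvi(b, g, r, n):
    # Green-Red Difference Vegetation Index. NOTE: despite the acronym, this
    # is the visible-band difference G - R, not the classic NIR - R DVI.
    return g - r


def _green(b, g, r, n):
    return np.array(g, dtype=float, copy=True)


def _ndvi(b, g, r, n):
    return _ratio(n - r, n + r)


def _gndvi(b, g, r, n):
    return _ratio(n - g, n + g)


def _osavi(b, g, r, n):
    return _ratio(n - r, n + r + 0.16)


def _savi(b, g, r, n):
    # (1 + L) * (NIR - R) / (NIR + R + L), L = 0.5
    return 1.5 * _ratio(n - r, n + r + 0.5)


def _cvi(b, g, r, n):
    return _ratio(n, g) * _ratio(r, g)


def _rdvi(b, g, r, n):
    s = np.asarray(n + r, dtype=float)
    root = np.sqrt(np.where(s > 0, s, np.nan))
    return _ratio(n - r, np.where(s > 0, root, 0.0))


def _gari(b, g, r, n):
    # Normalized ratio (NIR - X)/(NIR + X) with X = G - 1.7*(B - R).
    x = g - 1.7 * (b - r)
    return _ratio(n - x, n + x)


def _evi2(b, g, r, n):
    return _ratio(2.5 * (n - r), n + 2.4 * r + 1.0)


VI_REGISTRY: Dict[str, VIDefinition] = {
    d.name: d
    for d in (
        VIDefinition("EXG", RGB, "Excess Greenness Index", _exg),
        VIDefinition("EXR", RGB, "Excess Red Index", _exr),
        VIDefinition("VDVI", RGB, "Visible-band Difference Vegetation Index", _vdvi),
        VIDefinition("PPRB", RGB, "Plant Pigment Ratio", _pprb),
        VIDefinition("VARI", RGB, "Visible Atmospherically Resistant Index", _vari),
        VIDefinition("VIG", RGB, "Vegetation Index Green", _vig),
        VIDefinition("DVI", RGB, "Green-Red Difference Vegetation Index", _dvi),
        VIDefinition("GREEN", RGB, "Green spectral band", _green),
        VIDefinition("NDVI", NIR, "Normalized Difference Vegetation Index", _ndvi),
        VIDefinition("GNDVI", NIR, "Green Normalized Difference Vegetation Index", _gndvi),
        VIDefinition("OSAVI", NIR, "Optimized Soil-Adjusted Vegetation Index", _osavi),
        VIDefinition("SAVI", NIR, "Soil-Adjusted Vegetation Index", _savi),
        VIDefinition("CVI", NIR, "Chlorophyll Vegetation Index", _cvi),
        VIDefinition("RDVI", NIR, "Renormalized Difference Vegetation Index", _rdvi),
        VIDefinition("GARI", NIR, "Green Atmospherically Resistant Vegetation Index", _gari),
        VIDefinition("EVI2", NIR, "Two-Band Enhanced Vegetation Index", _evi2),
    )
}

ALL_VIS: Tuple[str, ...] = tuple(VI_REGISTRY)
RGB_VIS: Tuple[str, ...] = tuple(n for n, d in VI_REGISTRY.items() if d.group == RGB)
NIR_VIS: Tuple[str, ...] = tuple(n for n, d in VI_REGISTRY.items() if d.group == NIR)

#: VIs that are affine functions of band reflectance. Under linear spectral
#: mixing these respond to canopy fraction exactly linearly, so their
#: N-response inherits the canopy model's functional family unchanged.
AFFINE_VIS: Tuple[str, ...] = ("EXG", "EXR", "DVI", "GREEN")

assert len(RGB_VIS) == 8 and len(NIR_VIS) == 8


def vi_group(name: str) -> str:
    return VI_REGISTRY[name].group


def compute_vi(scene: SpectralScene, vi: str) -> np.ndarray:
    """Evaluate one vegetation index over a rescaled scene.

    Returns a float grid; pixels with an undefined value (zero denominator)
    are NaN. Raises KeyError for unknown index names and ValueError if the
    scene has not been rescaled to reflectance units.
    """
    if vi not in VI_REGISTRY:
        raise KeyError(
            f"unknown vegetation index {vi!r}; known: {sorted(VI_REGISTRY)}"
        )
    if scene.scaled:
        raise ValueError("scene must be rescaled to [0, 1] reflectance first")
    d = VI_REGISTRY[vi]
    with np.errstate(invalid="ignore", divide="ignore"):
        return d.func(scene.blue, scene.green, scene.red, scene.nir)


def compute_all_vis(
    scene: SpectralScene, vis: Optional[Sequence[str]] = None
) -> Dict[str, np.ndarray]:
    return {name: compute_vi(scene, name) for name in (vis or ALL_VIS)}


def zonal_means(
    grid: np.ndarray, zones: pd.DataFrame, value_name: str = "mean_value"
) -> pd.DataFrame:
    """Arithmetic mean of a grid over pixel-index zones.

    ``zones`` must carry integer ``row``/``col`` columns plus the identifying
    columns (subplot_id and any metadata); one output row is produced per
    subplot_id over non-NaN pixels. Zones whose pixels are all NaN are
    omitted (their loss is visible through the returned frame's length).
    Raises ValueError on an empty zone table or out-of-bounds pixel indices.
    """
    if len(zones) == 0:
        raise ValueError("empty zone table")
    rows = zones["row"].to_numpy()
    cols = zones["col"].to_numpy()
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= grid.shape[0]
        or cols.max() >= grid.shape[1]
    ):
        raise ValueError("zone table references pixels outside the grid")
    values = grid[rows, cols]
    meta_cols = [
        c for c in zones.columns if c not in ("row", "col")
    ]
    df = zones[meta_cols].copy()
    df["_value"] = values
    grouped = df.groupby("subplot_id", sort=True)
    out = []
    for subplot_id, g in grouped:
        vals = g["_value"].to_numpy()
        ok = ~np.isnan(vals)
        if not ok.any():
            continue  # all-missing zone: omitted
        rec = {c: g[c].iloc[0] for c in meta_cols}
        rec[value_name] = float(vals[ok].mean())
        rec["pixel_count"] = int(ok.sum())
        out.append(rec)
    return pd.DataFrame(out)


def zonal_vi_table(
    scene: SpectralScene,
    zones: pd.DataFrame,
    vis: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long-format zonal table: one row per (subplot, VI) for one scene.

    The scene is rescaled if still in scaled-integer form. Columns:
    the zone metadata plus timing, stage, vi_name, vi_group, mean_value,
    pixel_count.
    """
    scene = rescale_reflectance(scene)
    frames = []
    for name in (vis or ALL_VIS):
        grid = compute_vi(scene, name)
        zm = zonal_means(grid, zones)
        zm["vi_name"] = name
        zm["vi_group"] = vi_group(name)
        zm["timing"] = scene.timing
        zm["stage"] = scene.stage
        frames.append(zm)
    return pd.concat(frames, ignore_index=True)
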