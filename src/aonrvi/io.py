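"""File I/O: GeoTIFF scenes, zone tables, trial-design JSON, yield CSVs.

Scenes are written as single-file multiband GeoTIFFs — band order Blue,
Green, Red, NIR, unsigned 16-bit, scaled-integer convention (reflectance x
10,000) — with ModelPixelScale/ModelTiepoint tags carrying the affine
transform and a JSON ImageDescription holding timing metadata. Reading back
reproduces pixel values exactly (uint16 is lossless).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import BANDS
from .synthetic_field import Subplot, TrialDesign
from .vi_core import SpectralScene

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_scene_geotiff(scene: SpectralScene, path: str | Path) -> None:
    """Write a scaled-integer scene as a 4-band uint16 GeoTIFF (B, G, R, NIR)."""
    if not scene.scaled:
        raise ValueError("write the scaled-integer form, not rescaled reflectance")
    # the file format is whole counts; unquantized float scenes are rounded
    stack = np.stack(
        [np.round(scene.band(b)).astype(np.uint16) for b in BANDS]
    )
    meta = {
        "bands": list(BANDS),
        "timing": scene.timing,
        "stage": scene.stage,
        "trial_id": scene.trial_id,
        "pixel_size_m": scene.pixel_size_m,
        "x_origin": scene.x_origin,
        "y_origin": scene.y_origin,
        "scale": 10000,
    }
    px = float(scene.pixel_size_m)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(scene.x_origin), float(scene.y_origin), 0.0),
        ),
    ]
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_scene_geotiff(
    path: str | Path, band_order: Sequence[str] = BANDS
) -> SpectralScene:
    """Read a 4-band scaled-integer GeoTIFF written by this package (or any
    generic 4-band file, with ``band_order`` naming its band sequence)."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        page = tif.pages[0]
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_MODEL_TIEPOINT)
        scale_value = tuple(scale_tag.value) if scale_tag is not None else None
        tie_value = tuple(tie_tag.value) if tie_tag is not None else None
    if stack.ndim != 3 or stack.shape[0] != 4:
        raise ValueError(f"expected a 4-band scene, got shape {stack.shape}")
    order = list(meta.get("bands", band_order))
    if sorted(order) != sorted(BANDS):
        raise ValueError(f"band order {order} does not cover {BANDS}")
    grids = {name: stack[i] for i, name in enumerate(order)}
    pixel_size = float(meta.get("pixel_size_m", 0.0))
    x_origin = float(meta.get("x_origin", 0.0))
    y_origin = float(meta.get("y_origin", 0.0))
    if scale_value is not None:
        pixel_size = float(scale_value[0])
    if tie_value is not None:
        x_origin, y_origin = float(tie_value[3]), float(tie_value[4])
    return SpectralScene(
        blue=grids["blue"],
        green=grids["green"],
        red=grids["red"],
        nir=grids["nir"],
        timing=int(meta.get("timing", 0)),
        stage=str(meta.get("stage", "")),
        trial_id=str(meta.get("trial_id", "")),
        pixel_size_m=pixel_size or 3.0,
        x_origin=x_origin,
        y_origin=y_origin,
        scaled=True,
    )


def write_design_json(design: TrialDesign, path: str | Path) -> None:
    doc = {
        "trial_id": design.trial_id,
        "trial_index": design.trial_index,
        "fnr": design.fnr,
        "treatments": [list(t) for t in design.treatments],
        "transect_ids": list(design.transect_ids),
        "max_n_rate": design.max_n_rate,
        "timing_calendar": {
            str(k): list(v) for k, v in design.timing_calendar.items()
        },
        "subplots": [
            {
                "subplot_id": s.subplot_id,
                "transect_id": s.transect_id,
                "treatment": s.treatment,
                "n_rate": s.n_rate,
                "x0": s.x0,
                "y0": s.y0,
                "length_m": s.length_m,
                "width_m": s.width_m,
            }
            for s in design.subplots
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_design_json(path: str | Path) -> TrialDesign:
    doc = json.loads(Path(path).read_text())
    return TrialDesign(
        trial_id=doc["trial_id"],
        trial_index=int(doc["trial_index"]),
        fnr=float(doc["fnr"]),
        treatments=tuple(
            (str(lbl), float(rate), int(rep)) for lbl, rate, rep in doc["treatments"]
        ),
        transect_ids=tuple(doc["transect_ids"]),
        subplots=tuple(
            Subplot(
                subplot_id=s["subplot_id"],
                transect_id=s["transect_id"],
                treatment=s["treatment"],
                n_rate=float(s["n_rate"]),
                x0=float(s["x0"]),
                y0=float(s["y0"]),
                length_m=float(s["length_m"]),
                width_m=float(s["width_m"]),
            )
            for s in doc["subplots"]
        ),
        timing_calendar={
            int(k): (v[0], v[1]) for k, v in doc["timing_calendar"].items()
        },
        max_n_rate=float(doc["max_n_rate"]),
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), keep_default_na=True)
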