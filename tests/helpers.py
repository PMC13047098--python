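"""Shared independent oracles and scene builders for the test suite."""

import math

import numpy as np
from scipy import optimize

from aonrvi.response_models import _lp_rss_at
from aonrvi.vi_core import SpectralScene


def scalar_vi(name: str, b: float, g: float, r: float, n: float) -> float:
    """Independent per-pixel VI evaluator, written as plain scalar arithmetic."""
    if name == "EXG":
        return 2 * g - r - b
    if name == "EXR":
        return 1.4 * r - b
    if name == "VDVI":
        d = 2 * g + b + r
        return (2 * g - b - r) / d if d else math.nan
    if name == "PPRB":
        d = g + b
        return (g - b) / d if d else math.nan
    if name == "VARI":
        d = g + r - b
        return (g - r) / d if d else math.nan
    if name == "VIG":
        d = g + r
        return (g - r) / d if d else math.nan
    if name == "DVI":
        return g - r
    if name == "GREEN":
        return g
    if name == "NDVI":
        d = n + r
        return (n - r) / d if d else math.nan
    if name == "GNDVI":
        d = n + g
        return (n - g) / d if d else math.nan
    if name == "OSAVI":
        return (n - r) / (n + r + 0.16)
    if name == "SAVI":
        return (1 + 0.5) * (n - r) / (n + r + 0.5)
    if name == "CVI":
        return (n / g) * (r / g) if g else math.nan
    if name == "RDVI":
        s = n + r
        return (n - r) / math.sqrt(s) if s > 0 else math.nan
    if name == "GARI":
        xx = g - 1.7 * (b - r)
        d = n + xx
        return (n - xx) / d if d else math.nan
    if name == "EVI2":
        return 2.5 * (n - r) / (n + 2.4 * r + 1)
    raise KeyError(name)


def random_scene(rng, shape=(16, 16)) -> SpectralScene:
    bands = {k: rng.uniform(0.0, 1.0, shape) for k in ("blue", "green", "red", "nir")}
    return SpectralScene(**bands, scaled=False)


def uniform_scene(b, g, r, n, shape=(4, 4)) -> SpectralScene:
    return SpectralScene(
        blue=np.full(shape, b),
        green=np.full(shape, g),
        red=np.full(shape, r),
        nir=np.full(shape, n),
        scaled=False,
    )


def oracle_lp_rss(x: np.ndarray, y: np.ndarray, n_dense: int = 2001) -> float:
    """Exhaustive linear-plateau profiling oracle: a dense join grid, the
    data breakpoints (kink locations of the profile), and a bounded search
    within every smooth piece, each solved by conditional OLS."""
    cands = np.unique(
        np.concatenate([np.linspace(x.min(), x.max(), n_dense), np.unique(x)])
    )
    best = min(_lp_rss_at(x, y, g)[2] for g in cands)
    ux = np.unique(x)
    for lo, hi in zip(ux[:-1], ux[1:]):
        r = optimize.minimize_scalar(
            lambda t: _lp_rss_at(x, y, t)[2],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(best, float(r.fun))
    return best
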