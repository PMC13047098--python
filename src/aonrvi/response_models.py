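"""Linear-plateau and quadratic-plateau dose-response fitting and selection.

Both families rise to a join point x0 and are constant beyond it; the join
point is the agronomic optimum N rate (AONR) candidate:

* linear-plateau:     y = a + b * min(x, x0)
* quadratic-plateau:  y = a + b*x + c*x^2  for x < x0,  constant for x >= x0,
  with the smooth join at the vertex x0 = -b / (2c) and plateau value
  a - b^2 / (4c).

Fitting is least squares. For a *fixed* join point both families are linear
in their remaining coefficients, so the optimizer profiles x0 over a grid
(21 candidates across the tested N range), solves the conditional ordinary
least squares problem at each, refines the best brackets with bounded scalar
minimization, and finishes with a bounded Levenberg-type polish. This makes
the fit reproducible and provably near the global optimum on the small
(~5-point) transect datasets it is designed for.

Screening and selection for a response curve:
convergence -> R^2 > 0.50 -> agronomic plausibility (positive slope for the
linear-plateau, concave-down for the quadratic-plateau); among the survivors
the lower AIC wins, with exact ties going to the quadratic-plateau. A
selected curve whose AONR exceeds the maximum tested N rate is discarded
(its optimum is unobserved, not estimated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .vi_core import vi_group

LINEAR_PLATEAU = "linear_plateau"
QUADRATIC_PLATEAU = "quadratic_plateau"

SCREEN_REASONS = (
    "no_convergence",
    "low_r2",
    "nonpositive_slope",
    "not_concave_down",
)

R2_THRESHOLD = 0.50
AIC_TIE_TOL = 1e-9


@dataclass
class PlateauFit:
    """One fitted plateau curve with its diagnostics."""

    family: str
    a: float
    b: float
    c: Optional[float]  # quadratic coefficient; None for the linear-plateau
    join_x0: float  # kg N/ha; NaN when the quadratic is not concave-down
    plateau_value: float
    rss: float
    tss: float
    r_squared: float
    aic: float
    n_obs: int
    converged: bool = True

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.family == LINEAR_PLATEAU:
            out = self.a + self.b * np.minimum(x, self.join_x0)
        else:
            out = _qp_predict(x, self.a, self.b, self.c)
        return out if out.ndim else float(out)


@dataclass
class CurveDecision:
    """Screening verdicts and the selected fit for one response curve."""

    trial_id: str
    transect_id: str
    timing: Optional[int]
    vi_name: str  # a VI name, or "yield" for the yield-N curve
    lp: Optional[PlateauFit]
    qp: Optional[PlateauFit]
    lp_reasons: Tuple[str, ...]
    qp_reasons: Tuple[str, ...]
    selected: Optional[str]  # family name or None
    aonr: Optional[float]
    discarded_exceeds_max: bool = False
    degenerate: bool = False  # placeholder row for missing/degenerate input

    @property
    def usable(self) -> bool:
        return self.aonr is not None


def _conditional_ols(design: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _lp_rss_at(x: np.ndarray, y: np.ndarray, x0: float) -> Tuple[float, float, float]:
    """Conditional OLS of the linear-plateau at a fixed join; (a, b, rss)."""
    design = np.column_stack([np.ones_like(x), np.minimum(x, x0)])
    coef, rss = _conditional_ols(design, y)
    return float(coef[0]), float(coef[1]), rss


def _qp_predict(x: np.ndarray, a: float, b: float, c: Optional[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if c is None or c == 0:
        return a + b * x
    if c < 0:
        x0 = -b / (2.0 * c)
        xx = np.minimum(x, x0)
        return a + b * xx + c * xx**2
    # convex: no plateau; the raw quadratic (screened out later)
    return a + b * x + c * x**2


def _qp_rss_at(
    x: np.ndarray, y: np.ndarray, x0: float
) -> Tuple[float, float, float, float]:
    """Conditional OLS of the smooth-join quadratic-plateau at fixed x0.

    With the join constrained to x0, b = -2*c*x0, so the model is linear in
    (a, c): y = a + c * (x^2 - 2*x0*x) for x < x0 and a - c*x0^2 beyond.
    Returns (a, b, c, rss).
    """
    z = np.where(x < x0, x**2 - 2.0 * x0 * x, -(x0**2))
    design = np.column_stack([np.ones_like(x), z])
    coef, rss = _conditional_ols(design, y)
    a, c = float(coef[0]), float(coef[1])
    return a, -2.0 * c * x0, c, rss


def _local_minima(values: np.ndarray) -> List[int]:
    """Indices of all local minima of a 1-D profile (endpoints included)."""
    n = len(values)
    out = []
    for i in range(n):
        left = values[i - 1] if i > 0 else np.inf
        right = values[i + 1] if i < n - 1 else np.inf
        if values[i] <= left and values[i] <= right:
            out.append(i)
    return out


def _join_candidates(x: np.ndarray, n_grid: int) -> np.ndarray:
    """Candidate join points: a global grid stratified by the data's segments.

    The profiled RSS is piecewise smooth with breakpoints at the observed x
    values, and a segment between two close observations can be narrower than
    a uniform grid step, so each inter-point segment contributes its own
    candidates in addition to the uniform grid.
    """
    lo, hi = float(x.min()), float(x.max())
    pieces = [np.linspace(lo, hi, n_grid)]
    ux = np.unique(x)
    for a, b in zip(ux[:-1], ux[1:]):
        pieces.append(np.linspace(a, b, 5))
    return np.unique(np.concatenate(pieces))


def _refine_brackets(
    grid: np.ndarray, rss_grid: np.ndarray, x: np.ndarray
) -> List[Tuple[float, float]]:
    """Brackets worth a bounded scalar search: around every grid local
    minimum, plus every inter-observation segment (the profile's smooth
    pieces, whose interior minima can hide between grid points)."""
    brackets: List[Tuple[float, float]] = []
    for i in _local_minima(rss_grid):
        left = float(grid[max(i - 1, 0)])
        right = float(grid[min(i + 1, len(grid) - 1)])
        if right > left:
            brackets.append((left, right))
    ux = np.unique(x)
    for a, b in zip(ux[:-1], ux[1:]):
        if b > a:
            brackets.append((float(a), float(b)))
    return brackets


def _check_inputs(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    return x, y


def _tss(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def aic_least_squares(rss: float, n_obs: int, n_params: int) -> float:
    """AIC for a least-squares fit: n*ln(rss/n) + 2*(p + 1).

    The +1 counts the error variance as an estimated parameter. A perfect
    fit (rss = 0) returns -inf so it always wins a comparison.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        return -math.inf
    return n_obs * math.log(rss / n_obs) + 2.0 * (n_params + 1)


def _finish(
    family: str,
    a: float,
    b: float,
    c: Optional[float],
    x0: float,
    rss: float,
    x: np.ndarray,
    y: np.ndarray,
    converged: bool = True,
) -> PlateauFit:
    tss = _tss(y)
    rss = max(rss, 0.0)
    # numerically perfect fits: rounding can leave rss ~ 1e-30 instead of an
    # exact 0, which must not break the equal-AIC tie rule
    if tss > 0 and rss <= 1e-12 * tss:
        rss = 0.0
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    if family == QUADRATIC_PLATEAU and c is not None and c < 0:
        plateau = a - b**2 / (4.0 * c)
    elif family == LINEAR_PLATEAU:
        plateau = a + b * x0
    else:
        plateau = math.nan
    return PlateauFit(
        family=family,
        a=a,
        b=b,
        c=c,
        join_x0=x0,
        plateau_value=plateau,
        rss=rss,
        tss=tss,
        r_squared=r2,
        aic=aic_least_squares(rss, len(y), 3),
        n_obs=len(y),
        converged=converged,
    )


def fit_linear_plateau(
    x: Sequence[float], y: Sequence[float], n_grid: int = 21
) -> PlateauFit:
    """Least-squares linear-plateau fit with the join profiled over [min x, max x]."""
    x, y = _check_inputs(np.asarray(x), np.asarray(y))
    lo, hi = float(x.min()), float(x.max())
    grid = _join_candidates(x, n_grid)
    rss_grid = np.array([_lp_rss_at(x, y, g)[2] for g in grid])
    best_x0 = float(grid[int(np.argmin(rss_grid))])
    best = float(rss_grid.min())
    # refine every local basin of the profile (the profile is piecewise
    # smooth with breakpoints at the data x's, so basins can be narrow)
    for left, right in _refine_brackets(grid, rss_grid, x):
        res = optimize.minimize_scalar(
            lambda t: _lp_rss_at(x, y, t)[2],
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if float(res.fun) < best:
            best, best_x0 = float(res.fun), float(res.x)
    a, b, rss = _lp_rss_at(x, y, best_x0)

    # bounded least-squares polish over (a, b, x0)
    def resid(p):
        return p[0] + p[1] * np.minimum(x, p[2]) - y

    try:
        sol = optimize.least_squares(
            resid,
            x0=[a, b, best_x0],
            bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        rss_p = float(sol.fun @ sol.fun)
        if sol.success and rss_p < rss:
            a, b, best_x0, rss = sol.x[0], sol.x[1], float(sol.x[2]), rss_p
        converged = True
    except Exception:
        converged = False
    return _finish(LINEAR_PLATEAU, float(a), float(b), None, float(best_x0), rss, x, y,
                   converged=converged)


def fit_quadratic_plateau(
    x: Sequence[float], y: Sequence[float], n_grid: int = 21
) -> PlateauFit:
    """Least-squares quadratic-plateau fit (smooth join at the vertex).

    Candidates: the profiled smooth-join fit over a 21-point x0 grid within
    the tested range, plus the unconstrained quadratic OLS fit (which covers
    joins beyond the tested range and convex data). The winner is polished
    with bounded least squares on (a, b, c).
    """
    x, y = _check_inputs(np.asarray(x), np.asarray(y))
    lo, hi = float(x.min()), float(x.max())
    grid = _join_candidates(x, n_grid)
    grid = grid[grid > 0] if lo <= 0 else grid
    if len(grid) == 0:
        grid = np.array([max(hi, 1e-9)])
    profile = [_qp_rss_at(x, y, g) for g in grid]
    rss_grid = np.array([p[3] for p in profile])

    candidates: List[Tuple[float, float, Optional[float], float]] = [
        profile[int(np.argmin(rss_grid))][:4]
    ]
    for left, right in _refine_brackets(grid, rss_grid, x):
        res = optimize.minimize_scalar(
            lambda t: _qp_rss_at(x, y, t)[3],
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-10},
        )
        candidates.append(_qp_rss_at(x, y, float(res.x)))
    # unconstrained quadratic (join outside the range, or convex response)
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, _ = _conditional_ols(design, y)
    aq, bq, cq = (float(v) for v in coef)
    rq = float(((_qp_predict(x, aq, bq, cq) - y) ** 2).sum())
    candidates.append((aq, bq, cq, rq))

    a, b, c, rss = min(candidates, key=lambda t: t[3])

    def resid(p):
        return _qp_predict(x, p[0], p[1], p[2]) - y

    converged = True
    try:
        sol = optimize.least_squares(
            resid, x0=[a, b, c if c not in (None, 0.0) else -1e-9],
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss_p = float(sol.fun @ sol.fun)
        if sol.success and rss_p < rss:
            a, b, c, rss = float(sol.x[0]), float(sol.x[1]), float(sol.x[2]), rss_p
    except Exception:
        converged = False

    if c is not None and c < 0:
        x0 = -b / (2.0 * c)
    else:
        x0 = math.nan
    return _finish(QUADRATIC_PLATEAU, a, b, c, x0, rss, x, y, converged=converged)


def screen_fit(fit: Optional[PlateauFit], r2_threshold: float = R2_THRESHOLD
               ) -> Tuple[str, ...]:
    """Screening verdicts for one fit, in fixed order; empty tuple = pass."""
    if fit is None or not fit.converged:
        return ("no_convergence",)
    reasons: List[str] = []
    if not (np.isfinite(fit.r_squared) and fit.r_squared > r2_threshold):
        reasons.append("low_r2")
    if fit.family == LINEAR_PLATEAU:
        if not fit.b > 0:
            reasons.append("nonpositive_slope")
    else:
        if not (fit.c is not None and fit.c < 0):
            reasons.append("not_concave_down")
    return tuple(reasons)


def screen_and_select(
    lp: Optional[PlateauFit],
    qp: Optional[PlateauFit],
    max_n_rate: float,
    trial_id: str = "",
    transect_id: str = "",
    timing: Optional[int] = None,
    vi_name: str = "",
    r2_threshold: float = R2_THRESHOLD,
) -> CurveDecision:
    """Apply the screens to both candidate fits and select by AIC.

    A fit failing any screen is never selected regardless of AIC. Among
    passers the lower AIC wins; an exact tie (|delta AIC| < 1e-9, including
    both perfect fits) prefers the quadratic-plateau. A selected join at the
    maximum tested rate is allowed; strictly beyond it the decision is
    discarded and carries no AONR.
    """
    lp_reasons = screen_fit(lp, r2_threshold)
    qp_reasons = screen_fit(qp, r2_threshold)
    passers = []
    if not lp_reasons:
        passers.append(lp)
    if not qp_reasons:
        passers.append(qp)
    selected: Optional[str] = None
    aonr: Optional[float] = None
    discarded = False
    if passers:
        if len(passers) == 2:
            both_perfect = math.isinf(lp.aic) and math.isinf(qp.aic)
            if both_perfect or abs(lp.aic - qp.aic) < AIC_TIE_TOL:
                chosen = qp
            else:
                chosen = lp if lp.aic < qp.aic else qp
        else:
            chosen = passers[0]
        selected = chosen.family
        aonr = float(chosen.join_x0)
        if aonr > max_n_rate + 1e-9:
            discarded = True
            aonr = None
    return CurveDecision(
        trial_id=trial_id,
        transect_id=transect_id,
        timing=timing,
        vi_name=vi_name,
        lp=lp,
        qp=qp,
        lp_reasons=lp_reasons,
        qp_reasons=qp_reasons,
        selected=selected,
        aonr=aonr,
        discarded_exceeds_max=discarded,
    )


def fit_and_screen(
    x: Sequence[float],
    y: Sequence[float],
    max_n_rate: float,
    r2_threshold: float = R2_THRESHOLD,
    **ids,
) -> CurveDecision:
    """Fit both families to one (N, response) set and run the selection."""
    try:
        lp = fit_linear_plateau(x, y)
    except (ValueError, np.linalg.LinAlgError):
        lp = None
    try:
        qp = fit_quadratic_plateau(x, y)
    except (ValueError, np.linalg.LinAlgError):
        qp = None
    if lp is None and qp is None:
        return CurveDecision(
            trial_id=ids.get("trial_id", ""),
            transect_id=ids.get("transect_id", ""),
            timing=ids.get("timing"),
            vi_name=ids.get("vi_name", ""),
            lp=None,
            qp=None,
            lp_reasons=("no_convergence",),
            qp_reasons=("no_convergence",),
            selected=None,
            aonr=None,
            degenerate=True,
        )
    return screen_and_select(
        lp, qp, max_n_rate, r2_threshold=r2_threshold, **ids
    )


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

def decisions_to_frame(decisions: Iterable[CurveDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "trial_id": d.trial_id,
                "transect_id": d.transect_id,
                "timing": d.timing,
                "vi_name": d.vi_name,
                "vi_group": (
                    "yield" if d.vi_name == "yield" else vi_group(d.vi_name)
                ),
                "selected": d.selected or "",
                "aonr": d.aonr if d.aonr is not None else np.nan,
                "usable": d.usable,
                "discarded_exceeds_max": d.discarded_exceeds_max,
                "degenerate": d.degenerate,
                "lp_reasons": ";".join(d.lp_reasons),
                "qp_reasons": ";".join(d.qp_reasons),
                "lp_r2": d.lp.r_squared if d.lp else np.nan,
                "qp_r2": d.qp.r_squared if d.qp else np.nan,
                "lp_aic": d.lp.aic if d.lp else np.nan,
                "qp_aic": d.qp.aic if d.qp else np.nan,
                "lp_x0": d.lp.join_x0 if d.lp else np.nan,
                "qp_x0": d.qp.join_x0 if d.qp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_curve_battery(
    zonal: pd.DataFrame,
    yields: pd.DataFrame,
    designs: Dict[str, "TrialDesign"],
    timings: Sequence[int] = (1, 2, 3),
    vis: Optional[Sequence[str]] = None,
    r2_threshold: float = R2_THRESHOLD,
) -> pd.DataFrame:
    """Fit/screen every (transect x timing x VI) VI-N curve plus one
    yield-N curve per transect.

    ``zonal`` is the long-format zonal VI table; ``yields`` the per-subplot
    cleaned yield table. Every enumeration slot yields exactly one row;
    combinations with degenerate input appear as flagged placeholder rows so
    the design bookkeeping is preserved. Yield-N rows carry ``vi_name ==
    "yield"`` and ``timing`` NaN.
    """
    from .synthetic_field import TrialDesign  # local import to avoid cycle

    if vis is None:
        from .vi_core import ALL_VIS

        vis = ALL_VIS
    decisions: List[CurveDecision] = []
    for trial_id, design in designs.items():
        ymeta = yields[yields["trial_id"] == trial_id]
        ztrial = zonal[zonal["trial_id"] == trial_id]
        for transect_id in design.transect_ids:
            ytr = ymeta[ymeta["transect_id"] == transect_id]
            xy = ytr[["n_rate", "yield_mg_ha"]].dropna()
            decisions.append(
                fit_and_screen(
                    xy["n_rate"].to_numpy(),
                    xy["yield_mg_ha"].to_numpy(),
                    design.max_n_rate,
                    r2_threshold=r2_threshold,
                    trial_id=trial_id,
                    transect_id=transect_id,
                    timing=None,
                    vi_name="yield",
                )
                if len(xy) >= 4
                else _degenerate(trial_id, transect_id, None, "yield")
            )
            ztr = ztrial[ztrial["transect_id"] == transect_id]
            for timing in timings:
                zt = ztr[ztr["timing"] == timing]
                for vi in vis:
                    zv = zt[zt["vi_name"] == vi]
                    merged = zv.merge(
                        ytr[["subplot_id", "yield_mg_ha"]], on="subplot_id",
                        how="left",
                    )
                    sub = merged[["n_rate", "mean_value"]].dropna()
                    if len(sub) >= 4 and sub["n_rate"].nunique() >= 3:
                        decisions.append(
                            fit_and_screen(
                                sub["n_rate"].to_numpy(),
                                sub["mean_value"].to_numpy(),
                                design.max_n_rate,
                                r2_threshold=r2_threshold,
                                trial_id=trial_id,
                                transect_id=transect_id,
                                timing=timing,
                                vi_name=vi,
                            )
                        )
                    else:
                        decisions.append(
                            _degenerate(trial_id, transect_id, timing, vi)
                        )
    return decisions_to_frame(decisions)


def _degenerate(
    trial_id: str, transect_id: str, timing: Optional[int], vi_name: str
) -> CurveDecision:
    return CurveDecision(
        trial_id=trial_id,
        transect_id=transect_id,
        timing=timing,
        vi_name=vi_name,
        lp=None,
        qp=None,
        lp_reasons=("no_convergence",),
        qp_reasons=("no_convergence",),
        selected=None,
        aonr=None,
        degenerate=True,
    )


def retention_summary(
    decisions: pd.DataFrame, by: Sequence[str] = ()
) -> pd.DataFrame:
    """Percent of VI-N curves usable for AONR, overall or by grouping keys.

    Yield-N rows are excluded; the denominator is every evaluated VI-N curve
    (degenerate placeholders included), so percentages over any partition
    reaggregate exactly to the overall percentage.
    """
    vi_rows = decisions[decisions["vi_name"] != "yield"]
    if not by:
        n = len(vi_rows)
        usable = int(vi_rows["usable"].sum())
        return pd.DataFrame(
            [{"n_curves": n, "n_usable": usable,
              "pct_usable": 100.0 * usable / n if n else np.nan}]
        )
    g = vi_rows.groupby(list(by), dropna=False)
    out = g["usable"].agg(["count", "sum"]).reset_index()
    out = out.rename(columns={"count": "n_curves", "sum": "n_usable"})
    out["n_usable"] = out["n_usable"].astype(int)
    out["pct_usable"] = 100.0 * out["n_usable"] / out["n_curves"]
    return out
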