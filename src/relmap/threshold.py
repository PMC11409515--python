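"""Dynamic thresholding of unreliability against MI.

The dependence of the unreliability score on MI falls steeply at low
intensity and then stabilises.  A smoothed curve (a Gaussian generalized
additive model with a single penalized-spline smooth, i.e. a P-spline)
is fitted to the per-probe (MI, unreliability) scatter, and the
"critical point" is the grid point maximizing the second derivative of
the fitted curve — the elbow where the steep decline flattens out.
Probes with MI strictly below the critical MI are flagged unreliable.

Smoothing uses a cubic B-spline basis on equally spaced knots with an
Eilers–Marx second-order difference penalty and natural boundary
conditions (second derivative zero at both ends, as in cubic smoothing
splines and mgcv's cubic regression splines); the penalty weight is
chosen by generalized cross-validation over a log-spaced grid unless
fixed explicitly.  The natural boundary condition matters: without it
the clamped basis concentrates spurious curvature at the left edge of a
steeply decaying curve and the second-derivative maximum degenerates to
the boundary instead of the elbow.  The evaluation grid spans [min MI,
99th percentile of MI] to avoid edge effects from stray extreme-MI
probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .data_model import ProbeType, ValidationError

__all__ = [
    "SmoothingParams",
    "SmoothedCurve",
    "ThresholdResult",
    "fit_smoothed_curve",
    "find_critical_point",
    "flag_unreliable",
    "dynamic_threshold",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Tunables for the penalized-spline fit.

    ``df``: number of B-spline basis functions (equally spaced knots).
    ``lam``: penalty weight; ``None`` selects it by GCV.
    ``n_grid``: dense evaluation grid size (uniform in MI).
    ``upper_quantile``: MI quantile bounding the grid on the right.
    """

    df: int = 35
    degree: int = 3
    lam: float | None = None
    n_grid: int = 512
    upper_quantile: float = 0.99


@dataclass
class SmoothedCurve:
    mi_grid: np.ndarray
    values: np.ndarray
    params: SmoothingParams
    lam_used: float


@dataclass
class ThresholdResult:
    type_channel: ProbeType
    curve: SmoothedCurve
    critical_mi: float
    critical_unreliability: float
    flagged_probes: set[str]
    smoothing_params: SmoothingParams


def _knots(lo: float, hi: float, params: SmoothingParams) -> np.ndarray:
    k = params.degree
    n_inner = params.df - k + 1
    if n_inner < 2:
        raise ValidationError("df too small for the spline degree")
    inner = np.linspace(lo, hi, n_inner)
    return np.r_[[lo] * k, inner, [hi] * k]


def _design_matrix(x: np.ndarray, t: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = t[degree], t[-degree - 1]
    xc = np.clip(x, lo, np.nextafter(hi, lo))
    return BSpline.design_matrix(xc, t, degree).toarray()


def _penalty(df: int) -> np.ndarray:
    d = np.diff(np.eye(df), n=2, axis=0)
    return d.T @ d


def _natural_nullspace(t: np.ndarray, degree: int, df: int) -> np.ndarray:
    """Basis of coefficient vectors whose spline has zero second
    derivative at both boundaries (natural boundary conditions)."""
    from scipy.linalg import null_space

    lo, hi = t[degree], t[-degree - 1]
    eye = np.eye(df)
    pts = (lo, np.nextafter(hi, lo))
    constraints = np.array(
        [[BSpline(t, eye[j], degree)(p, nu=2) for j in range(df)] for p in pts]
    )
    return null_space(constraints)


def fit_smoothed_curve(
    mi: np.ndarray,
    unreliability: np.ndarray,
    params: SmoothingParams | None = None,
) -> SmoothedCurve:
    """Penalized-spline fit of unreliability on MI on a dense uniform grid.

    Duplicate (MI, unreliability) rows are aggregated into weights
    normalized to mean 1, so replicating the whole input leaves the fit
    unchanged.  Deterministic given the parameters.
    """
    params = params or SmoothingParams()
    x = np.asarray(mi, dtype=float)
    y = np.asarray(unreliability, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 50:
        raise ValidationError("need at least 50 probes to fit the curve")
    if np.ptp(x) == 0:
        raise ValidationError("MI values are constant; cannot fit a curve")

    # aggregate exact duplicates into weights
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    new = np.r_[True, (np.diff(xs) != 0) | (np.diff(ys) != 0)]
    idx = np.cumsum(new) - 1
    n_unique = idx[-1] + 1
    w = np.bincount(idx, minlength=n_unique).astype(float)
    xu = xs[new]
    yu = ys[new]
    w /= w.mean()

    lo = float(xu.min())
    hi = float(np.quantile(x, params.upper_quantile))
    if hi <= lo:
        hi = float(xu.max())
    if hi <= lo:
        raise ValidationError("degenerate MI range after quantile trimming")
    # probes beyond the trimmed range are outside the evaluated domain and
    # are excluded from the fit so extreme-MI outliers cannot perturb it
    inside = xu <= hi
    xu, yu, w = xu[inside], yu[inside], w[inside]
    w /= w.mean()

    t = _knots(lo, hi, params)
    b = _design_matrix(xu, t, params.degree)
    p = _penalty(params.df)
    nspace = _natural_nullspace(t, params.degree, params.df)
    bw = b * w[:, None]
    btb = b.T @ bw
    bty = bw.T @ yu
    n = float(w.sum())
    btb_n = nspace.T @ btb @ nspace
    bty_n = nspace.T @ bty
    p_n = nspace.T @ p @ nspace

    def solve(lam: float) -> tuple[np.ndarray, float]:
        a = btb_n + lam * p_n
        coef = nspace @ np.linalg.solve(a, bty_n)
        # effective dof = tr(H) = tr((B'WB + lam P)^-1 B'WB) in the null space
        edof = float(np.trace(np.linalg.solve(a, btb_n)))
        return coef, edof

    if params.lam is not None:
        lam_used = float(params.lam)
        coef, _ = solve(lam_used)
    else:
        scale = np.trace(btb) / max(np.trace(p), 1e-300)
        best = None
        for lam in scale * np.logspace(-8, 4, 49):
            coef, edof = solve(lam)
            resid = yu - b @ coef
            rss = float(w @ resid**2)
            denom = max(n - edof, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef)
        _, lam_used, coef = best

    grid = np.linspace(lo, hi, params.n_grid)
    bg = _design_matrix(grid, t, params.degree)
    fitted = bg @ coef
    return SmoothedCurve(mi_grid=grid, values=fitted, params=params, lam_used=float(lam_used))


def find_critical_point(curve: SmoothedCurve) -> tuple[float, float]:
    """Grid point maximizing the second derivative of the fitted curve.

    The second derivative is taken by central finite differences on the
    uniform grid, and the search is restricted to the declining limb —
    strictly right of the curve's global maximum — so that the returned
    point marks where the steep decline of unreliability with MI
    flattens out.
    """
    y = np.asarray(curve.values, dtype=float)
    x = np.asarray(curve.mi_grid, dtype=float)
    if y.size < 16:
        raise ValidationError("curve must have at least 16 grid points")
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise ValidationError("no critical point: curve is flat")
    h = x[1] - x[0]
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2 * y[1:-1] + y[:-2]) / h**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    i_max = int(np.argmax(y))
    lo = max(i_max + 1, 1)
    hi = y.size - 1
    if lo >= hi:
        raise ValidationError("no critical point: no declining limb right of the maximum")
    region = slice(lo, hi)
    j = lo + int(np.argmax(d2[region]))
    return float(x[j]), float(y[j])


def flag_unreliable(mi_table: pd.DataFrame, critical_mi: float) -> set[str]:
    """Probes with MI strictly below the critical MI."""
    mask = mi_table["mi"] < critical_mi
    return set(mi_table.loc[mask, "probe_id"])


def dynamic_threshold(
    mi_table: pd.DataFrame,
    unreliability_table: pd.DataFrame,
    ptype: ProbeType,
    params: SmoothingParams | None = None,
    flag_by: Literal["mi", "unreliability"] = "mi",
) -> ThresholdResult:
    """Fit the curve, locate the critical point and flag probes.

    ``flag_by="mi"`` (default) flags probes with MI below the critical
    MI; ``flag_by="unreliability"`` flags probes whose unreliability
    exceeds the critical unreliability instead.
    """
    params = params or SmoothingParams()
    merged = mi_table.merge(
        unreliability_table[["probe_id", "unreliability"]], on="probe_id"
    ).dropna(subset=["mi", "unreliability"])
    curve = fit_smoothed_curve(
        merged["mi"].to_numpy(), merged["unreliability"].to_numpy(), params
    )
    critical_mi, critical_unrel = find_critical_point(curve)
    if flag_by == "mi":
        flagged = flag_unreliable(merged, critical_mi)
    else:
        flagged = set(merged.loc[merged["unreliability"] > critical_unrel, "probe_id"])
    return ThresholdResult(
        type_channel=ptype,
        curve=curve,
        critical_mi=critical_mi,
        critical_unreliability=critical_unrel,
        flagged_probes=flagged,
        smoothing_params=params,
    )
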