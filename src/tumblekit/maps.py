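"""Phenotype-map statistics over (log10 CheR, log10 CheB) protein numbers.

Local linear (LOESS-style) regression surfaces of the mean tumble bias
and of the residual standard deviation, a global log-linear fit

    TB = a + b * log10(N_R / N_B^c),

and contour-orientation diagnostics quantifying whether two surfaces
depend on the protein numbers in the same direction.

Smoothing conventions: degree-1 weighted least squares over the nearest
``bandwidth`` fraction of the data (default 20%), tricube weights,
Euclidean distances after standardizing each log axis by its SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PhenotypeMap",
    "LogLinearFit",
    "local_linear_mean",
    "local_residual_sd",
    "loess_predict",
    "fit_loglinear",
    "contour_orientation",
    "angular_separation",
]


@dataclass
class PhenotypeMap:
    """A surface on a rectangular grid in (log10 N_R, log10 N_B)."""

    grid_logR: np.ndarray  # (nx,)
    grid_logB: np.ndarray  # (ny,)
    values: np.ndarray  # (ny, nx), NaN off support
    support_mask: np.ndarray  # (ny, nx) bool
    bandwidth: float
    kind: str = "mean_tb"  # or "resid_sd"
    n_points: int = 0
    n_fallback: int = 0  # grid nodes where the local design was singular

    def __post_init__(self) -> None:
        ny, nx = len(self.grid_logB), len(self.grid_logR)
        if self.values.shape != (ny, nx):
            raise ValueError("values shape must be (len(grid_logB), len(grid_logR))")
        if not 0 < self.bandwidth <= 1:
            raise ValueError("bandwidth must be in (0, 1]")


@dataclass
class LogLinearFit:
    """Global fit TB = a + b*(log10 N_R - c*log10 N_B)."""

    a: float
    b: float
    c: float
    ci: dict = field(default_factory=dict)  # {"a": (lo, hi), ...}
    n_cells: int = 0
    residual_sd: float = np.nan

    def predict(self, NR: np.ndarray, NB: np.ndarray) -> np.ndarray:
        return self.a + self.b * (np.log10(NR) - self.c * np.log10(NB))


def _standardize(x: np.ndarray, y: np.ndarray):
    sx = np.std(x) or 1.0
    sy = np.std(y) or 1.0
    return x / sx, y / sy, sx, sy


def loess_predict(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    x_eval: np.ndarray,
    y_eval: np.ndarray,
    bandwidth: float = 0.2,
    min_neighbors: int = 10,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Degree-1 tricube local regression at arbitrary evaluation points.

    Returns (predictions, supported, n_fallback); ``supported`` marks
    evaluation points whose neighborhood holds >= ``min_neighbors`` points.
    Collinear neighborhoods fall back to the local weighted mean.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 data points")
    k = max(int(np.ceil(bandwidth * n)), 3)
    xs, ys, sx, sy = _standardize(x, y)
    xe, ye = np.asarray(x_eval, float) / sx, np.asarray(y_eval, float) / sy

    preds = np.full(len(xe), np.nan)
    supported = np.zeros(len(xe), dtype=bool)
    n_fallback = 0
    for i in range(len(xe)):
        d = np.hypot(xs - xe[i], ys - ye[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            preds[i] = z[idx].mean()
            supported[i] = k >= min_neighbors
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        dx = xs[idx] - xe[i]
        dy = ys[idx] - ye[i]
        X = np.column_stack([np.ones(k), dx, dy])
        WX = X * w[:, None]
        G = X.T @ WX
        rhs = WX.T @ z[idx]
        try:
            beta = np.linalg.solve(G, rhs)
            if not np.all(np.isfinite(beta)):
                raise np.linalg.LinAlgError
            preds[i] = beta[0]
        except np.linalg.LinAlgError:
            preds[i] = np.average(z[idx], weights=w) if w.sum() > 0 else z[idx].mean()
            n_fallback += 1
        supported[i] = k >= min_neighbors
    return preds, supported, n_fallback


def _default_grid(logR: np.ndarray, logB: np.ndarray, n_grid: int):
    return (
        np.linspace(logR.min(), logR.max(), n_grid),
        np.linspace(logB.min(), logB.max(), n_grid),
    )


def local_linear_mean(
    NR: np.ndarray,
    NB: np.ndarray,
    TB: np.ndarray,
    bandwidth: float = 0.2,
    grid: Optional[tuple[np.ndarray, np.ndarray]] = None,
    n_grid: int = 50,
) -> PhenotypeMap:
    """Local-linear-regression surface of mean tumble bias.

    ``grid`` is (grid_logR, grid_logB); default 50x50 over the observed
    bounding box in log10 space.
    """
    NR, NB, TB = map(np.asarray, (NR, NB, TB))
    ok = np.isfinite(TB) & (NR > 0) & (NB > 0)
    logR, logB, tb = np.log10(NR[ok]), np.log10(NB[ok]), TB[ok]
    if len(tb) < 30:
        raise ValueError(f"need >= 30 points, got {len(tb)}")
    if grid is None:
        grid = _default_grid(logR, logB, n_grid)
    gx, gy = grid
    GX, GY = np.meshgrid(gx, gy)
    preds, supp, n_fb = loess_predict(
        logR, logB, tb, GX.ravel(), GY.ravel(), bandwidth=bandwidth
    )
    values = preds.reshape(GX.shape)
    mask = supp.reshape(GX.shape)
    values[~mask] = np.nan
    return PhenotypeMap(
        grid_logR=gx, grid_logB=gy, values=values, support_mask=mask,
        bandwidth=bandwidth, kind="mean_tb", n_points=len(tb), n_fallback=n_fb,
    )


def local_residual_sd(
    NR: np.ndarray,
    NB: np.ndarray,
    TB: np.ndarray,
    bandwidth: float = 0.2,
    grid: Optional[tuple[np.ndarray, np.ndarray]] = None,
    n_grid: int = 50,
) -> PhenotypeMap:
    """Residual-SD surface after subtracting the local-linear mean.

    Residuals are computed against the smoother's prediction at each data
    point; their squares are smoothed with the same degree-1 machinery and
    the map reports sqrt(max(0, fitted variance)).
    """
    NR, NB, TB = map(np.asarray, (NR, NB, TB))
    ok = np.isfinite(TB) & (NR > 0) & (NB > 0)
    logR, logB, tb = np.log10(NR[ok]), np.log10(NB[ok]), TB[ok]
    if grid is None:
        grid = _default_grid(logR, logB, n_grid)
    fitted, _, _ = loess_predict(logR, logB, tb, logR, logB, bandwidth=bandwidth)
    r2 = (tb - fitted) ** 2
    gx, gy = grid
    GX, GY = np.meshgrid(gx, gy)
    preds, supp, n_fb = loess_predict(
        logR, logB, r2, GX.ravel(), GY.ravel(), bandwidth=bandwidth
    )
    clipped = int(np.sum(preds < 0))
    values = np.sqrt(np.maximum(preds, 0.0)).reshape(GX.shape)
    mask = supp.reshape(GX.shape)
    values[~mask] = np.nan
    pm = PhenotypeMap(
        grid_logR=gx, grid_logB=gy, values=values, support_mask=mask,
        bandwidth=bandwidth, kind="resid_sd", n_points=len(tb), n_fallback=n_fb,
    )
    pm.n_clipped = clipped
    return pm


def fit_loglinear(
    NR: np.ndarray,
    NB: np.ndarray,
    TB: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    fix_c: Optional[float] = None,
) -> LogLinearFit:
    """Nonlinear least squares of TB = a + b*(log10 N_R - c*log10 N_B).

    Confidence intervals by nonparametric bootstrap over cells.  With
    ``fix_c`` the exponent is held fixed and the fit reduces to ordinary
    least squares on log10(N_R / N_B^c).
    """
    NR, NB, TB = map(lambda v: np.asarray(v, float), (NR, NB, TB))
    ok = np.isfinite(TB) & (NR > 0) & (NB > 0)
    lr, lb, tb = np.log10(NR[ok]), np.log10(NB[ok]), TB[ok]
    if len(np.unique(np.round(lr, 12) + 1j * np.round(lb, 12))) < 3:
        raise ValueError("need >= 3 distinct (N_R, N_B) supports")
    if np.std(lb) < 1e-12:
        raise ValueError("c is not identifiable: N_B has no spread")

    def solve(lr_, lb_, tb_):
        if fix_c is not None:
            X = np.column_stack([np.ones(len(lr_)), lr_ - fix_c * lb_])
            beta, *_ = np.linalg.lstsq(X, tb_, rcond=None)
            p = np.array([beta[0], beta[1], fix_c])
            return p, X @ beta - tb_

        def resid(p):
            a, b, c = p
            return a + b * (lr_ - c * lb_) - tb_

        # OLS on log-ratio (c=1) provides the starting point
        X = np.column_stack([np.ones(len(lr_)), lr_ - lb_])
        beta, *_ = np.linalg.lstsq(X, tb_, rcond=None)
        sol = least_squares(resid, [beta[0], beta[1] if beta[1] != 0 else 0.05, 1.0])
        return sol.x, sol.fun

    p_hat, res = solve(lr, lb, tb)
    ci = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 3))
        n = len(tb)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[i], _ = solve(lr[idx], lb[idx], tb[idx])
        alpha = (1.0 - ci_level) / 2.0
        for j, name in enumerate(("a", "b", "c")):
            lo, hi = np.quantile(boots[:, j], [alpha, 1.0 - alpha])
            ci[name] = (float(lo), float(hi))
    return LogLinearFit(
        a=float(p_hat[0]), b=float(p_hat[1]), c=float(p_hat[2]),
        ci=ci, n_cells=int(len(tb)), residual_sd=float(np.std(res)),
    )


def contour_orientation(pm: PhenotypeMap) -> tuple[float, float]:
    """Mean gradient axis of the map (degrees) and circular dispersion.

    The gradient direction is axial (contours have no sign), so statistics
    use doubled angles: returns (axis_angle_deg in [-90, 90), dispersion
    in [0, 1] with 0 = perfectly aligned gradients).  Angle 0 means the
    map varies along log N_R only; +/-90 along log N_B only.
    """
    vals = pm.values
    if not np.any(np.isfinite(vals)):
        raise ValueError("empty support")
    gy, gx = np.gradient(vals, pm.grid_logB, pm.grid_logR)
    ok = np.isfinite(gx) & np.isfinite(gy)
    mag = np.hypot(gx[ok], gy[ok])
    if not np.any(mag > 0):
        raise ValueError("flat map: orientation undefined")
    ang = np.arctan2(gy[ok], gx[ok])
    w = mag  # weight by gradient magnitude
    c2 = np.average(np.cos(2 * ang), weights=w)
    s2 = np.average(np.sin(2 * ang), weights=w)
    axis = 0.5 * np.arctan2(s2, c2)
    R = np.hypot(c2, s2)
    axis_deg = np.degrees(axis)
    if axis_deg >= 90.0:
        axis_deg -= 180.0
    elif axis_deg < -90.0:
        axis_deg += 180.0
    return float(axis_deg), float(1.0 - R)


def angular_separation(pm1: PhenotypeMap, pm2: PhenotypeMap) -> float:
    """Separation of the two maps' mean gradient axes, degrees in [0, 90]."""
    a1, _ = contour_orientation(pm1)
    a2, _ = contour_orientation(pm2)
    d = abs(a1 - a2) % 180.0
    return float(min(d, 180.0 - d))
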