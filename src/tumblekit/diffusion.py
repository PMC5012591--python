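"""Effective diffusion coefficients from trajectory correlation curves.

The velocity autocorrelation and mean-square displacement of a planar
trajectory are jointly fitted with

    Cv(t)  = v0^2 * exp(-t/tau) * cos(omega*t)
    MSD(t) = 2t * int_0^t Cv(u) du - 2 * int_0^t u*Cv(u) du

where the MSD form follows from integrating the velocity autocorrelation
in two dimensions (Green-Kubo).  Writing z = 1/tau - i*omega the double
integral has the closed form

    MSD(t) = 2 v0^2 Re[ t(1 - e^(-zt))/z - (1 - (1+zt) e^(-zt))/z^2 ].

tau captures directional persistence, omega the circular swimming induced
by the glass surface.  The effective diffusion coefficient D_eff =
v0^2 * tau / d removes the circling effect; D_apx = v^2 T / (d (1-theta))
approximates it from the mean run time T and mean tumble-angle cosine
theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .simulate import Trajectory

__all__ = [
    "CorrelationCurves",
    "MotilityFit",
    "correlation_curves",
    "cv_model",
    "msd_model",
    "fit_motility_model",
    "approx_diffusion",
]


@dataclass
class CorrelationCurves:
    """Velocity autocorrelation and MSD on a shared lag grid."""

    lags: np.ndarray  # s, starting at 0
    Cv: np.ndarray  # um^2/s^2
    MSD: np.ndarray  # um^2
    counts: np.ndarray  # averaging pairs per lag (Cv convention)
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.lags) == len(self.Cv) == len(self.MSD) == len(self.counts)):
            raise ValueError("curve arrays must share one lag grid")


@dataclass
class MotilityFit:
    """Joint Cv/MSD fit result for one cell."""

    v0: float  # um/s
    tau_persist: float  # s
    omega: float  # rad/s
    D_eff: float  # um^2/s
    D_apx: float = np.nan  # um^2/s, filled in by the pipeline when run stats exist
    d: int = 2
    fit_quality: float = np.nan  # residual norm of the joint fit
    converged: bool = True
    cell_id: str = ""
    diagnostics: dict = field(default_factory=dict)


def correlation_curves(traj: Trajectory, max_lag: Optional[float] = None) -> CorrelationCurves:
    """Time-averaged velocity autocorrelation and MSD of one trajectory.

    ``max_lag`` defaults to min(10 s, duration/4).  All available pairs at
    each lag are averaged.
    """
    n = len(traj)
    if n < 3:
        raise ValueError("need >= 3 samples")
    dts = np.diff(traj.t)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * max(1.0, abs(dt)):
        raise ValueError("non-uniform sampling grid")
    duration = traj.duration
    if max_lag is None:
        max_lag = min(10.0, duration / 4.0)
    if max_lag >= duration:
        raise ValueError(f"max_lag ({max_lag}) must be < duration ({duration})")

    K = int(np.floor(max_lag / dt))
    vx = np.diff(traj.x) / dt
    vy = np.diff(traj.y) / dt
    m = n - 1  # number of velocity vectors
    Cv = np.empty(K + 1)
    MSD = np.empty(K + 1)
    counts = np.empty(K + 1, dtype=int)
    for k in range(K + 1):
        Cv[k] = np.mean(vx[: m - k] * vx[k:] + vy[: m - k] * vy[k:])
        if k == 0:
            MSD[k] = 0.0
        else:
            ddx = traj.x[k:] - traj.x[:-k]
            ddy = traj.y[k:] - traj.y[:-k]
            MSD[k] = np.mean(ddx**2 + ddy**2)
        counts[k] = m - k
    return CorrelationCurves(
        lags=np.arange(K + 1) * dt, Cv=Cv, MSD=MSD, counts=counts, dt=dt
    )


def cv_model(t: np.ndarray, v0: float, tau: float, omega: float) -> np.ndarray:
    """Closed-form velocity autocorrelation."""
    t = np.asarray(t, dtype=float)
    return v0**2 * np.exp(-t / tau) * np.cos(omega * t)


def msd_model(t: np.ndarray, v0: float, tau: float, omega: float) -> np.ndarray:
    """Closed-form MSD: 2t*int_0^t Cv - 2*int_0^t u*Cv(u) du."""
    t = np.asarray(t, dtype=float)
    z = 1.0 / tau - 1j * omega
    ezt = np.exp(-z * t)
    val = t * (1.0 - ezt) / z - (1.0 - (1.0 + z * t) * ezt) / z**2
    return 2.0 * v0**2 * np.real(val)


def fit_motility_model(
    curves: CorrelationCurves,
    d: int = 2,
    cell_id: str = "",
) -> MotilityFit:
    """Jointly fit (v0, tau, omega) to the Cv and MSD curves.

    Residuals of the two curves are normalized by Cv(0) and MSD(max_lag)
    so neither dominates.  Starting values: v0 from sqrt(Cv(0)), tau from
    the first lag where Cv drops below Cv(0)/e, omega from the first zero
    crossing of Cv (held at 0 when Cv never crosses zero).  D_eff =
    v0^2 tau / d.
    """
    lags, Cv, MSD = curves.lags, curves.Cv, curves.MSD
    cv0 = Cv[0]
    if not np.isfinite(cv0) or cv0 <= 0:
        # stationary cell: no kinetic energy, nothing to fit
        return MotilityFit(
            v0=0.0, tau_persist=0.0, omega=0.0, D_eff=0.0, d=d,
            fit_quality=0.0, converged=True, cell_id=cell_id,
            diagnostics={"reason": "degenerate Cv(0) <= 0"},
        )
    msd_scale = max(MSD[-1], 1e-12)

    v0_init = float(np.sqrt(cv0))
    below = np.flatnonzero(Cv < cv0 / np.e)
    tau_init = float(lags[below[0]]) if below.size else float(lags[-1])
    tau_init = max(tau_init, curves.dt)
    crossings = np.flatnonzero((Cv[:-1] > 0) & (Cv[1:] <= 0))
    if crossings.size:
        # quarter period at the first zero crossing
        omega_init = float(np.pi / (2.0 * lags[crossings[0] + 1]))
        fit_omega = True
    else:
        omega_init = 0.0
        fit_omega = False
    omega_max = np.pi / curves.dt  # aliasing bound

    def residuals(p):
        if fit_omega:
            v0, tau, omega = p
        else:
            v0, tau = p
            omega = 0.0
        r1 = (cv_model(lags, v0, tau, omega) - Cv) / cv0
        r2 = (msd_model(lags, v0, tau, omega) - MSD) / msd_scale
        return np.concatenate([r1, r2])

    if fit_omega:
        x0 = [v0_init, tau_init, omega_init]
        bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, omega_max])
    else:
        x0 = [v0_init, tau_init]
        bounds = ([0.0, 1e-6], [np.inf, np.inf])
    sol = least_squares(residuals, x0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if fit_omega:
        v0, tau, omega = sol.x
    else:
        (v0, tau), omega = sol.x, 0.0
    return MotilityFit(
        v0=float(v0),
        tau_persist=float(tau),
        omega=float(abs(omega)),
        D_eff=float(v0**2 * tau / d),
        d=d,
        fit_quality=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        cell_id=cell_id,
        diagnostics={"status": int(sol.status), "nfev": int(sol.nfev)},
    )


def approx_diffusion(
    mean_speed: float,
    mean_run_time: float,
    mean_cos_turn: float,
    d: int = 2,
) -> float:
    """Run-time approximation D_apx = v^2 T / (d (1 - theta)).

    theta is the mean cosine of tumble angles and must be < 1.
    """
    if mean_cos_turn >= 1.0:
        raise ValueError(f"mean_cos_turn must be < 1, got {mean_cos_turn}")
    return mean_speed**2 * mean_run_time / (d * (1.0 - mean_cos_turn))
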