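"""Chemotaxis signaling model with CheB-dependent receptor deamidation.

State variables (concentrations, uM):

    Q    glutamine residues on receptors (immature methylation sites)
    M    methylated glutamate residues
    A_P  phosphorylated CheA
    B_P  phosphorylated CheB
    Y_P  phosphorylated CheY

Dynamics (no attractant; receptor cluster activity ``a`` is an algebraic
function of M and Q):

    dQ/dt   = -a kQ B_P Q/(K_B+Q) + 2 r T_tot - r Q
    dM/dt   = (1-a) kR R (4T-M-Q)/(K_R+4T-M-Q) - a kB B_P M/(K_B+M) - r M
    dA_P/dt = a aP (A-A_P) - aB A_P (B-B_P) - aY A_P (Y-Y_P)
    dB_P/dt = aB A_P (B-B_P) - dB B_P
    dY_P/dt = aY A_P (Y-Y_P) - dZ Z Y_P

    a = 1 / (1 + exp(eps0 + eps1*2N*(M/T)/4 + eps2*2N*(Q/T)/4))

Receptors are synthesized in the QEQE configuration: growth at rate ``r``
adds two glutamines per new receptor (the ``2 r T_tot`` source) and
dilutes Q and M.  A glutamine contributes half the free-energy change of
a methylated glutamate (eps2 = eps1/2 by default).

Parameter values are shipped defaults assembled from the antecedent
pathway-modeling literature and measured mean copy numbers (CheB ~240,
CheR ~140 molecules/cell); every value can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .simulate import (
    MotorParams,
    adaptive_motor,
    single_motor_cw_bias,
    tumble_bias_theoretical,
)

__all__ = [
    "PathwayParams",
    "CellState",
    "SteadyStateError",
    "receptor_activity",
    "pathway_derivatives",
    "steady_state",
    "tumble_bias_from_Yp",
    "steady_state_tumble_bias",
    "adaptation_transient",
    "GROWTH_RATE_DOUBLING_1H",
]

#: growth rate for a doubling time of 1 h (exponential-growth reading)
GROWTH_RATE_DOUBLING_1H = math.log(2.0) / 3600.0

AVOGADRO_PER_FL_UM = 602.214  # molecules per (uM * fL)


class SteadyStateError(RuntimeError):
    """No stable equilibrium could be located."""


@dataclass(frozen=True)
class PathwayParams:
    """Rate constants, free energies, and totals of the signaling model.

    Units: first-order rates in 1/s, second-order rates in 1/(uM s),
    concentrations in uM, free energies in kBT.
    """

    # (de)methylation and deamidation
    k_R: float = 0.04  # CheR methylation turnover, 1/s
    k_B: float = 1.28  # CheB-P demethylation turnover, 1/s
    k_Q: float = 0.64  # CheB-P deamidation turnover, 1/s (= k_B/2)
    K_R: float = 0.25  # Michaelis constant of CheR-receptor binding, uM
    K_B: float = 0.1  # Michaelis constant of CheB-receptor binding, uM
    # phospho-relay
    a_P: float = 50.0  # active CheA autophosphorylation, 1/s
    a_B: float = 10.0  # CheA-P -> CheB phosphotransfer, 1/(uM s)
    a_Y: float = 100.0  # CheA-P -> CheY phosphotransfer, 1/(uM s)
    d_B: float = 3.0  # CheB-P dephosphorylation, 1/s
    d_Z: float = 7.94  # CheZ-mediated CheY-P dephosphorylation, 1/(uM s)
    # MWC receptor cluster: eps0 = 3 makes a freshly synthesized QEQE
    # receptor (2 glutamines) exactly semi-active, the property that lets
    # incomplete deamidation raise the tumble bias
    eps0: float = 3.0  # baseline free energy, kBT
    eps1: float = -1.0  # per methylated-glutamate free energy, kBT
    eps2: float = -0.5  # per glutamine free energy, kBT (eps1/2)
    N: int = 6  # MWC complex size
    # growth
    r: float = GROWTH_RATE_DOUBLING_1H  # 1/s
    # totals, uM (defaults: measured mean copy numbers in a 1.4 fL cell)
    CheA_Tot: float = 7.95
    CheB_Tot: float = 0.285
    CheY_Tot: float = 9.73
    CheZ: float = 3.80
    CheR: float = 0.166
    T_Tot: float = 17.8
    # conversion
    volume: float = 1.4  # fL
    cheZ_scale: float = 1.0  # multiplier on CheZ (documented tuning knob)
    deamidation: bool = True  # False: Q pinned to 0 (model ablation)

    def __post_init__(self) -> None:
        for name in (
            "k_R", "k_B", "k_Q", "K_R", "K_B", "a_P", "a_B", "a_Y",
            "d_B", "d_Z", "r", "CheA_Tot", "CheB_Tot", "CheY_Tot",
            "CheZ", "CheR", "T_Tot",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N < 1 or self.N != int(self.N):
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def molecules_per_uM(self) -> float:
        return AVOGADRO_PER_FL_UM * self.volume

    def concentration(self, n_molecules: float) -> float:
        """Copy number -> concentration (uM) at this cell volume."""
        return n_molecules / self.molecules_per_uM

    def molecules(self, conc: float) -> float:
        return conc * self.molecules_per_uM

    def with_numbers(
        self,
        cheR: Optional[float] = None,
        cheB: Optional[float] = None,
        cheA: Optional[float] = None,
        cheY: Optional[float] = None,
        cheZ: Optional[float] = None,
        receptors: Optional[float] = None,
    ) -> "PathwayParams":
        """Copy of the parameters with totals set from molecule numbers."""
        kw = {}
        if cheR is not None:
            kw["CheR"] = self.concentration(cheR)
        if cheB is not None:
            kw["CheB_Tot"] = self.concentration(cheB)
        if cheA is not None:
            kw["CheA_Tot"] = self.concentration(cheA)
        if cheY is not None:
            kw["CheY_Tot"] = self.concentration(cheY)
        if cheZ is not None:
            kw["CheZ"] = self.concentration(cheZ)
        if receptors is not None:
            kw["T_Tot"] = self.concentration(receptors)
        return replace(self, **kw)

    def without_deamidation(self) -> "PathwayParams":
        """Model ablation: no glutamine pool, no growth (classic ratio model)."""
        return replace(self, deamidation=False, r=0.0)


@dataclass
class CellState:
    """Concentrations (uM) of the five dynamic species."""

    Q: float
    M: float
    A_P: float
    B_P: float
    Y_P: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Q, self.M, self.A_P, self.B_P, self.Y_P])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CellState":
        return cls(*(float(v) for v in x))

    def activity(self, p: PathwayParams) -> float:
        return receptor_activity(self.M, self.Q, p)

    def validate(self, p: PathwayParams, tol: float = 1e-9) -> None:
        if self.Q < -tol or self.M < -tol:
            raise ValueError("Q and M must be >= 0")
        if self.Q + self.M > 4.0 * p.T_Tot * (1 + 1e-9) + tol:
            raise ValueError("Q + M exceeds the 4*T_Tot site budget")
        for val, tot, name in (
            (self.A_P, p.CheA_Tot, "A_P"),
            (self.B_P, p.CheB_Tot, "B_P"),
            (self.Y_P, p.CheY_Tot, "Y_P"),
        ):
            if val < -tol or val > tot * (1 + 1e-9) + tol:
                raise ValueError(f"{name}={val} outside [0, total={tot}]")


def qeqe_state(p: PathwayParams) -> CellState:
    """Initial condition: all receptors freshly synthesized (QEQE), no phospho."""
    q0 = 2.0 * p.T_Tot if p.deamidation else 0.0
    return CellState(Q=q0, M=0.0, A_P=0.0, B_P=0.0, Y_P=0.0)


def receptor_activity(M: float, Q: float, p: PathwayParams) -> float:
    """MWC receptor-cluster activity in [0, 1].

    a = (1 + exp[eps0 + eps1*2N*(M/T_Tot)/4 + eps2*2N*(Q/T_Tot)/4])^-1

    i.e. the cluster free energy is eps0 plus (N/2) * (eps1 * methyls-per-
    receptor + eps2 * glutamines-per-receptor); with eps2 = eps1/2 one
    methyl equals two glutamines in free energy.
    """
    if M < 0 or Q < 0:
        raise ValueError("M and Q must be >= 0")
    if M + Q > 4.0 * p.T_Tot * (1.0 + 1e-9):
        raise ValueError(
            f"M + Q = {M + Q} exceeds 4*T_Tot = {4 * p.T_Tot}"
        )
    expo = (
        p.eps0
        + p.eps1 * 2.0 * p.N * (M / p.T_Tot) / 4.0
        + p.eps2 * 2.0 * p.N * (Q / p.T_Tot) / 4.0
    )
    # guard overflow; activity saturates anyway
    expo = min(max(expo, -500.0), 500.0)
    return 1.0 / (1.0 + math.exp(expo))


def _derivs(x: np.ndarray, p: PathwayParams) -> np.ndarray:
    Q, M, A_P, B_P, Y_P = x
    Qc = max(Q, 0.0)
    Mc = max(M, 0.0)
    a = receptor_activity(min(Mc, 4 * p.T_Tot), min(Qc, max(4 * p.T_Tot - Mc, 0.0)), p)
    if p.deamidation:
        dQ = (
            -a * p.k_Q * B_P * Qc / (p.K_B + Qc)
            + 2.0 * p.r * p.T_Tot
            - p.r * Qc
        )
    else:
        dQ = 0.0
    free_sites = max(4.0 * p.T_Tot - Mc - Qc, 0.0)
    dM = (
        (1.0 - a) * p.k_R * p.CheR * free_sites / (p.K_R + free_sites)
        - a * p.k_B * B_P * Mc / (p.K_B + Mc)
        - p.r * Mc
    )
    Z = p.CheZ * p.cheZ_scale
    dA = (
        a * p.a_P * (p.CheA_Tot - A_P)
        - p.a_B * A_P * (p.CheB_Tot - B_P)
        - p.a_Y * A_P * (p.CheY_Tot - Y_P)
    )
    dB = p.a_B * A_P * (p.CheB_Tot - B_P) - p.d_B * B_P
    dY = p.a_Y * A_P * (p.CheY_Tot - Y_P) - p.d_Z * Z * Y_P
    return np.array([dQ, dM, dA, dB, dY])


def pathway_derivatives(s: CellState, p: PathwayParams) -> CellState:
    """Time derivatives of (Q, M, A_P, B_P, Y_P), uM/s."""
    s.validate(p)
    return CellState.from_array(_derivs(s.as_array(), p))


def active_indices(p: PathwayParams) -> np.ndarray:
    """Indices of dynamic species: Q is frozen when deamidation is disabled."""
    return np.arange(5) if p.deamidation else np.arange(1, 5)


def jacobian(x: np.ndarray, p: PathwayParams, eps: float = 1e-7) -> np.ndarray:
    """Numerical Jacobian of the five-species dynamics at ``x``."""
    x = np.asarray(x, dtype=float)
    f0 = _derivs(x, p)
    J = np.empty((5, 5))
    for j in range(5):
        h = eps * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (_derivs(xp, p) - f0) / h
    return J


def _integrate_to_rest(
    p: PathwayParams, x0: np.ndarray, t_max: float = 2e5
) -> np.ndarray:
    sol = solve_ivp(
        lambda t, x: _derivs(x, p),
        (0.0, t_max),
        x0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise SteadyStateError(f"long-time integration failed: {sol.message}")
    return sol.y[:, -1]


def steady_state(
    p: PathwayParams,
    guess: Optional[CellState] = None,
    tol: float = 1e-10,
    require_stable: bool = True,
) -> CellState:
    """Stable equilibrium of the pathway.

    Root solve (hybr) from ``guess`` (default: the long-time integration of
    the QEQE initial condition), verified by derivative residuals below
    ``tol`` in relative units and negative real parts of the Jacobian
    eigenvalues.
    """
    if guess is None:
        x0 = _integrate_to_rest(p, qeqe_state(p).as_array())
    else:
        x0 = guess.as_array()
    sol = root(lambda x: _derivs(x, p), x0, method="hybr", tol=1e-13)
    x = sol.x
    scale = np.maximum(np.abs(x), 1e-3)
    ok = sol.success and np.all(np.abs(_derivs(x, p)) / scale < tol)
    if not ok:
        # fallback: integrate longer, then re-solve
        x0 = _integrate_to_rest(p, x0 if np.all(np.isfinite(x)) else qeqe_state(p).as_array())
        sol = root(lambda x: _derivs(x, p), x0, method="hybr", tol=1e-13)
        x = sol.x
        scale = np.maximum(np.abs(x), 1e-3)
        if not (sol.success and np.all(np.abs(_derivs(x, p)) / scale < tol)):
            raise SteadyStateError(
                f"no equilibrium found (residual {np.max(np.abs(_derivs(x, p))):g})"
            )
    x = np.maximum(x, 0.0)
    if require_stable:
        act = active_indices(p)
        lam = np.linalg.eigvals(jacobian(x, p)[np.ix_(act, act)])
        if np.max(lam.real) >= 0:
            raise SteadyStateError(
                f"equilibrium unstable: max Re(lambda) = {np.max(lam.real):g}"
            )
    st = CellState.from_array(x)
    st.validate(p)
    return st


def tumble_bias_from_Yp(
    Yp: float,
    mp: MotorParams = MotorParams(),
    n_flagella: int = 1,
    rule: str = "any-cw",
) -> float:
    """Motor-level tumble bias at CheY-P concentration ``Yp`` (uM)."""
    return tumble_bias_theoretical(Yp, mp, n_flagella=n_flagella, rule=rule)


def steady_state_tumble_bias(
    p: PathwayParams,
    mp: Optional[MotorParams] = None,
    n_flagella: int = 1,
    rule: str = "any-cw",
    guess: Optional[CellState] = None,
) -> tuple[float, CellState]:
    """Solve the pathway at equilibrium and read out the tumble bias.

    The default readout uses the adaptive-motor steady-state curve
    (reduced gain); pass an explicit ``mp`` for the raw switching motor.
    """
    if mp is None:
        mp = adaptive_motor()
    st = steady_state(p, guess=guess)
    return tumble_bias_from_Yp(st.Y_P, mp, n_flagella=n_flagella, rule=rule), st


def adaptation_transient(
    p: PathwayParams,
    duration: float = 3600.0,
    n_out: int = 200,
    mp: Optional[MotorParams] = None,
    growth_rate: float = GROWTH_RATE_DOUBLING_1H,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tumble-bias relaxation after growth arrest.

    The model is solved at steady state with growth rate ``growth_rate``
    (doubling time 1 h by default), then integrated with r = 0 (transfer
    from growth medium to chemotaxis buffer).  Returns (t, TB(t), states)
    where ``states`` has one row per output time.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if mp is None:
        mp = adaptive_motor()
    p_grow = replace(p, r=growth_rate)
    x0 = steady_state(p_grow).as_array()
    p_stop = replace(p, r=0.0)
    t_eval = np.linspace(0.0, duration, n_out)
    sol = solve_ivp(
        lambda t, x: _derivs(x, p_stop),
        (0.0, duration),
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-11,
    )
    if not sol.success:
        raise SteadyStateError(f"transient integration failed: {sol.message}")
    tb = np.array([single_motor_cw_bias(max(yp, 0.0), mp) for yp in sol.y[4]])
    return sol.t, tb, sol.y.T
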