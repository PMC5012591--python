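"""Population-level stochastic machinery.

Three noise layers link protein numbers to behavioral variability:

* cell-to-cell expression noise — correlated lognormal protein numbers
  with a shared extrinsic factor per operon group and independent
  intrinsic factors per protein;
* signaling noise — stationary fluctuations of the pathway species from
  the linear noise approximation (LNA): with stoichiometry S and
  propensity vector v at the fixed point, the diffusion matrix is
  B^T B = S diag(v) S^T (per unit volume in concentration units) and the
  stationary covariance C solves the Lyapunov equation
  A C + C A^T + B^T B = 0;
* temporal averaging — an observed tumble bias averages over
  n_eff = round(T_obs / tau) independent excursions of the slow cluster
  dynamics, tau = -1/max Re lambda(A).

A Gillespie stochastic-simulation routine over the same reaction list is
provided as an exact oracle for validating the LNA variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import solve_continuous_lyapunov

from .pathway import (
    CellState,
    PathwayParams,
    SteadyStateError,
    active_indices,
    jacobian,
    receptor_activity,
    steady_state,
)
from .simulate import MotorParams, adaptive_motor, tumble_bias_theoretical

__all__ = [
    "NoiseSpec",
    "LNASystem",
    "sample_protein_numbers",
    "pathway_reactions",
    "lna_covariance",
    "solve_lyapunov_system",
    "effective_Yp",
    "simulate_population_phenotypes",
    "variance_explained",
    "gillespie_variance",
]

PROTEINS = ("cheR", "cheB", "cheA", "cheY", "cheZ", "receptors")

#: measured mean copy numbers per cell (CheR ~140, CheB ~240, and the
#: major pathway proteins), matching the pathway defaults at 1.4 fL
DEFAULT_MEANS = {
    "cheR": 140.0,
    "cheB": 240.0,
    "cheA": 6700.0,
    "cheY": 8200.0,
    "cheZ": 3200.0,
    "receptors": 15000.0,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Lognormal expression-noise specification.

    ``eta_int``/``eta_ext`` are ln-space standard deviations for the
    intrinsic (per-protein) and extrinsic (shared within an operon group)
    noise of CheR and CheB; every other protein has both reduced by
    ``reduction`` (default a tenth).
    """

    eta_int: float = 0.125
    eta_ext: float = 0.26
    means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    operon_groups: tuple = (("cheR", "cheB"),)
    reduction: float = 0.1

    def __post_init__(self) -> None:
        if self.eta_int < 0 or self.eta_ext < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if any(v <= 0 for v in self.means.values()):
            raise ValueError("mean copy numbers must be > 0")

    def protein_eta(self, protein: str) -> tuple[float, float]:
        """(eta_int, eta_ext) applying to one protein."""
        scale = 1.0 if protein in ("cheR", "cheB") else self.reduction
        return self.eta_int * scale, self.eta_ext * scale

    def group_of(self, protein: str) -> int:
        for gi, grp in enumerate(self.operon_groups):
            if protein in grp:
                return gi
        return -1  # own independent extrinsic factor


def sample_protein_numbers(
    spec: NoiseSpec, n_cells: int, seed: int
) -> pd.DataFrame:
    """Correlated lognormal protein numbers for ``n_cells`` cells.

    Each cell draws one extrinsic deviate per operon group (shared by the
    group's proteins) and one intrinsic deviate per protein; copy number
    = mean * exp(eta_ext * Z_group + eta_int * Z_protein).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_groups = len(spec.operon_groups)
    z_group = rng.standard_normal((n_cells, n_groups))
    data = {}
    for prot in PROTEINS:
        mean = spec.means[prot]
        eta_i, eta_e = spec.protein_eta(prot)
        gi = spec.group_of(prot)
        z_ext = z_group[:, gi] if gi >= 0 else rng.standard_normal(n_cells)
        z_int = rng.standard_normal(n_cells)
        data[prot] = mean * np.exp(eta_e * z_ext + eta_i * z_int)
    return pd.DataFrame(data)


def sample_panel_numbers(
    spec: NoiseSpec,
    n_cells: int,
    seed: int,
    logR_range: tuple[float, float] = (1.2, 3.5),
    logB_range: tuple[float, float] = (1.2, 3.5),
) -> pd.DataFrame:
    """Panel covering the full (CheR, CheB) range: uniform in log10 copy
    number for CheR and CheB, lognormal expression noise for the rest."""
    rng = np.random.default_rng(seed)
    df = sample_protein_numbers(spec, n_cells, seed)
    df["cheR"] = 10.0 ** rng.uniform(*logR_range, n_cells)
    df["cheB"] = 10.0 ** rng.uniform(*logB_range, n_cells)
    return df


@dataclass
class LNASystem:
    """Stoichiometry, propensities, and stationary covariance at a fixed point."""

    S: np.ndarray  # (species, reactions)
    v: np.ndarray  # propensities at the fixed point, uM/s
    A: np.ndarray  # Jacobian of the deterministic rates
    B2: np.ndarray  # diffusion matrix B^T B (concentration units)
    C: np.ndarray  # stationary covariance, uM^2
    tau_adapt: float  # s, slowest relaxation time
    T_obs: float = 100.0  # s, observation window
    species: tuple = ("Q", "M", "A_P", "B_P", "Y_P")

    @property
    def n_eff(self) -> int:
        return max(1, int(round(self.T_obs / self.tau_adapt)))

    @property
    def var_Yp(self) -> float:
        return float(self.C[4, 4])


def pathway_reactions(
    s: CellState, p: PathwayParams
) -> tuple[np.ndarray, np.ndarray]:
    """Elementary-reaction stoichiometry S and propensities v at state ``s``.

    Species order (Q, M, A_P, B_P, Y_P); propensities in uM/s mirror the
    deterministic equations term for term (Michaelis-Menten steps treated
    as single events at their reduced rates).
    """
    Q, M, A_P, B_P, Y_P = s.Q, s.M, s.A_P, s.B_P, s.Y_P
    a = receptor_activity(M, Q, p)
    free = max(4.0 * p.T_Tot - M - Q, 0.0)
    Z = p.CheZ * p.cheZ_scale
    cols = []  # (stoich 5-vector, propensity)
    if p.deamidation:
        cols += [
            ((-1, 0, 0, 0, 0), a * p.k_Q * B_P * Q / (p.K_B + Q)),
            ((+2, 0, 0, 0, 0), p.r * p.T_Tot),  # QEQE synthesis
            ((-1, 0, 0, 0, 0), p.r * Q),  # dilution
        ]
    cols += [
        ((0, +1, 0, 0, 0), (1.0 - a) * p.k_R * p.CheR * free / (p.K_R + free)),
        ((0, -1, 0, 0, 0), a * p.k_B * B_P * M / (p.K_B + M)),
        ((0, -1, 0, 0, 0), p.r * M),
        ((0, 0, +1, 0, 0), a * p.a_P * (p.CheA_Tot - A_P)),
        ((0, 0, -1, +1, 0), p.a_B * A_P * (p.CheB_Tot - B_P)),
        ((0, 0, -1, 0, +1), p.a_Y * A_P * (p.CheY_Tot - Y_P)),
        ((0, 0, 0, -1, 0), p.d_B * B_P),
        ((0, 0, 0, 0, -1), p.d_Z * Z * Y_P),
    ]
    S = np.array([c[0] for c in cols], dtype=float).T
    v = np.array([c[1] for c in cols], dtype=float)
    return S, v


def solve_lyapunov_system(
    A: np.ndarray, S: np.ndarray, v: np.ndarray, omega: float
) -> np.ndarray:
    """Stationary covariance from A C + C A^T + S diag(v) S^T / omega = 0.

    ``omega`` converts concentration to molecule numbers (system size);
    the returned covariance is in (concentration)^2 units.
    """
    lam = np.linalg.eigvals(A)
    lead = lam[np.argmax(lam.real)]
    if lead.real >= 0:
        raise SteadyStateError(
            f"Jacobian not stable: leading eigenvalue {lead:g}"
        )
    B2 = S @ np.diag(v) @ S.T / omega
    C = solve_continuous_lyapunov(A, -B2)
    return 0.5 * (C + C.T)  # enforce exact symmetry


def lna_covariance(
    s: CellState, p: PathwayParams, T_obs: float = 100.0
) -> LNASystem:
    """Linear-noise-approximation covariance of the pathway at ``s``.

    ``s`` must be a stable fixed point.  Raises if the Jacobian has a
    non-negative leading eigenvalue.
    """
    S, v = pathway_reactions(s, p)
    A_full = jacobian(s.as_array(), p)
    act = active_indices(p)
    A = A_full[np.ix_(act, act)]
    S_act = S[act]
    C_act = solve_lyapunov_system(A, S_act, v, p.molecules_per_uM)
    C = np.zeros((5, 5))
    C[np.ix_(act, act)] = C_act
    lam = np.linalg.eigvals(A)
    tau = -1.0 / float(np.max(lam.real))
    return LNASystem(S=S, v=v, A=A_full,
                     B2=S @ np.diag(v) @ S.T / p.molecules_per_uM,
                     C=C, tau_adapt=tau, T_obs=T_obs)


def effective_Yp(
    Yp_ss: float,
    varYp: float,
    n_eff: int,
    rng: np.random.Generator,
) -> float:
    """One effective CheY-P draw: mean of ``n_eff`` Gaussian samples.

    Equivalent to a single draw with variance varYp / n_eff; negative
    draws are clipped to 0.
    """
    if varYp < 0:
        raise ValueError("varYp must be >= 0")
    n_eff = max(1, int(n_eff))
    draw = rng.normal(Yp_ss, math.sqrt(varYp / n_eff))
    return max(draw, 0.0)


def simulate_population_phenotypes(
    spec: NoiseSpec,
    p: PathwayParams,
    n_cells: int,
    seed: int,
    with_lna: bool = True,
    mp: Optional[MotorParams] = None,
    n_flagella: int = 1,
    rule: str = "any-cw",
    T_obs: float = 100.0,
    numbers: Optional[pd.DataFrame] = None,
    progress: Optional[Callable[[int], None]] = None,
) -> pd.DataFrame:
    """Per-cell phenotypes for a simulated population.

    For each cell: sample protein numbers (or take the rows of ``numbers``,
    e.g. from :func:`sample_panel_numbers`), solve the pathway steady
    state, optionally add an LNA-based effective CheY-P fluctuation, and
    read out the tumble bias.  Cells whose steady state cannot be found
    are recorded with NaN phenotypes (count in ``df.attrs["n_failed"]``).
    """
    if mp is None:
        mp = adaptive_motor()
    if numbers is None:
        numbers = sample_protein_numbers(spec, n_cells, seed)
    else:
        n_cells = len(numbers)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xEFF)))
    rows = []
    n_failed = 0
    for i in range(n_cells):
        rec = {
            "cell_id": f"pop_{i:05d}",
            "N_R": numbers.cheR[i],
            "N_B": numbers.cheB[i],
            "N_A": numbers.cheA[i],
            "N_Y": numbers.cheY[i],
            "N_Z": numbers.cheZ[i],
            "N_T": numbers.receptors[i],
        }
        pc = p.with_numbers(
            cheR=numbers.cheR[i],
            cheB=numbers.cheB[i],
            cheA=numbers.cheA[i],
            cheY=numbers.cheY[i],
            cheZ=numbers.cheZ[i],
            receptors=numbers.receptors[i],
        )
        try:
            st = steady_state(pc)
            rec["Yp_ss"] = st.Y_P
            if with_lna:
                sys = lna_covariance(st, pc, T_obs=T_obs)
                rec["varYp"] = sys.var_Yp
                rec["tau_adapt"] = sys.tau_adapt
                rec["n_eff"] = sys.n_eff
                rec["Yp_eff"] = effective_Yp(st.Y_P, sys.var_Yp, sys.n_eff, rng)
            else:
                rec["varYp"] = 0.0
                rec["tau_adapt"] = np.nan
                rec["n_eff"] = 1
                rec["Yp_eff"] = st.Y_P
            rec["tb"] = tumble_bias_theoretical(
                rec["Yp_eff"], mp, n_flagella=n_flagella, rule=rule
            )
        except SteadyStateError:
            n_failed += 1
            rec.update(
                Yp_ss=np.nan, varYp=np.nan, tau_adapt=np.nan,
                n_eff=0, Yp_eff=np.nan, tb=np.nan,
            )
        rows.append(rec)
        if progress is not None:
            progress(i)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    df.attrs["seed"] = int(seed)
    df.attrs["with_lna"] = bool(with_lna)
    return df


def variance_explained(
    tb_surface: Callable[[np.ndarray, np.ndarray], np.ndarray],
    spec: NoiseSpec,
    observed_var: float,
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Fraction of observed tumble-bias variance explained by expression noise.

    Samples wild-type (N_R, N_B) pairs from ``spec``, pushes them through
    the tumble-bias surface, and ratios the resulting variance to
    ``observed_var``.
    """
    if observed_var <= 0:
        raise ValueError("observed_var must be > 0")
    numbers = sample_protein_numbers(spec, n_samples, seed)
    tb = np.asarray(tb_surface(numbers.cheR.values, numbers.cheB.values), dtype=float)
    if np.any(~np.isfinite(tb)):
        raise ValueError(
            f"{int(np.sum(~np.isfinite(tb)))} sampled points fell outside "
            "the surface support"
        )
    return float(np.var(tb) / observed_var)


@njit(cache=True)
def _gillespie_pathway(
    x0: np.ndarray,  # counts (Q, M, A_P, B_P, Y_P)
    deam: int,
    kQ: float,
    kR_R: float,  # k_R * n_CheR (molecules of CheR, fixed)
    kB: float,
    KR_n: float,
    KB_n: float,
    aP: float,
    aB_w: float,  # a_B / omega
    aY_w: float,
    dB: float,
    dZZ: float,
    r: float,
    synth: float,  # r * T_Tot * omega
    A_n: float,
    B_n: float,
    Y_n: float,
    T4_n: float,  # 4 * T_Tot * omega
    eps0: float,
    cM: float,  # free-energy per M molecule
    cQ: float,
    t_total: float,
    t_burn: float,
    track: int,
    seed: int,
):  # pragma: no cover - exercised through gillespie_variance
    np.random.seed(seed)
    nQ, nM, nA, nB, nY = x0[0], x0[1], x0[2], x0[3], x0[4]
    t = 0.0
    w_sum = 0.0
    m1 = 0.0
    m2 = 0.0
    props = np.empty(11)
    # activity cache: recompute only when M or Q changes (slow reactions)
    expo = eps0 + cM * nM + cQ * nQ
    if expo > 500.0:
        expo = 500.0
    elif expo < -500.0:
        expo = -500.0
    a = 1.0 / (1.0 + math.exp(expo))
    xs = np.array([nQ, nM, nA, nB, nY])
    while t < t_total:
        nQ, nM, nA, nB, nY = xs[0], xs[1], xs[2], xs[3], xs[4]
        free = T4_n - nM - nQ
        if free < 0.0:
            free = 0.0
        if deam == 1:
            props[0] = a * kQ * nB * nQ / (KB_n + nQ)
            props[1] = synth
            props[2] = r * nQ
        else:
            props[0] = 0.0
            props[1] = 0.0
            props[2] = 0.0
        props[3] = (1.0 - a) * kR_R * free / (KR_n + free)
        props[4] = a * kB * nB * nM / (KB_n + nM)
        props[5] = r * nM
        props[6] = a * aP * (A_n - nA)
        props[7] = aB_w * nA * (B_n - nB)
        props[8] = aY_w * nA * (Y_n - nY)
        props[9] = dB * nB
        props[10] = dZZ * nY
        tot = 0.0
        for j in range(11):
            if props[j] < 0.0:
                props[j] = 0.0
            tot += props[j]
        if tot <= 0.0:
            break
        dt = np.random.exponential(1.0 / tot)
        t_new = t + dt
        # accumulate dwell-weighted moments of the tracked species
        lo = t if t > t_burn else t_burn
        hi = t_new if t_new < t_total else t_total
        if hi > lo:
            w = hi - lo
            val = xs[track]
            w_sum += w
            m1 += w * val
            m2 += w * val * val
        t = t_new
        if t >= t_total:
            break
        u = np.random.uniform(0.0, tot)
        acc = 0.0
        j_sel = 10
        for j in range(11):
            acc += props[j]
            if u <= acc:
                j_sel = j
                break
        if j_sel == 0:
            xs[0] -= 1.0
        elif j_sel == 1:
            xs[0] += 2.0
        elif j_sel == 2:
            xs[0] -= 1.0
        elif j_sel == 3:
            xs[1] += 1.0
        elif j_sel == 4:
            xs[1] -= 1.0
        elif j_sel == 5:
            xs[1] -= 1.0
        elif j_sel == 6:
            xs[2] += 1.0
        elif j_sel == 7:
            xs[2] -= 1.0
            xs[3] += 1.0
        elif j_sel == 8:
            xs[2] -= 1.0
            xs[4] += 1.0
        elif j_sel == 9:
            xs[3] -= 1.0
        else:
            xs[4] -= 1.0
        if j_sel <= 5:  # M or Q changed: refresh activity
            expo = eps0 + cM * xs[1] + cQ * xs[0]
            if expo > 500.0:
                expo = 500.0
            elif expo < -500.0:
                expo = -500.0
            a = 1.0 / (1.0 + math.exp(expo))
    mean = m1 / w_sum
    var = m2 / w_sum - mean * mean
    return mean, var


def gillespie_variance(
    s: CellState,
    p: PathwayParams,
    t_total: float = 3000.0,
    t_burn: float = 300.0,
    seed: int = 0,
    track_species: str = "Y_P",
) -> tuple[float, float]:
    """Exact stochastic-simulation oracle for the stationary moments.

    Simulates the same elementary reactions as the LNA in molecule units,
    with the receptor activity re-evaluated from the instantaneous (M, Q)
    counts, and returns the dwell-time-averaged (mean, variance) of
    ``track_species`` in uM units, started from the fixed point ``s``.
    """
    omega = p.molecules_per_uM
    Z = p.CheZ * p.cheZ_scale
    x0 = np.round(s.as_array() * omega)
    # per-molecule free-energy increments of the cluster exponent
    cM = p.eps1 * 2.0 * p.N / (4.0 * p.T_Tot * omega)
    cQ = p.eps2 * 2.0 * p.N / (4.0 * p.T_Tot * omega)
    track = {"Q": 0, "M": 1, "A_P": 2, "B_P": 3, "Y_P": 4}[track_species]
    mean_n, var_n = _gillespie_pathway(
        x0,
        1 if p.deamidation else 0,
        p.k_Q,
        p.k_R * p.CheR * omega,
        p.k_B,
        p.K_R * omega,
        p.K_B * omega,
        p.a_P,
        p.a_B / omega,
        p.a_Y / omega,
        p.d_B,
        p.d_Z * Z,
        p.r,
        p.r * p.T_Tot * omega,
        p.CheA_Tot * omega,
        p.CheB_Tot * omega,
        p.CheY_Tot * omega,
        4.0 * p.T_Tot * omega,
        p.eps0,
        cM,
        cQ,
        float(t_total),
        float(t_burn),
        track,
        int(seed) % (2**31 - 1),
    )
    return mean_n / omega, var_n / omega**2
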