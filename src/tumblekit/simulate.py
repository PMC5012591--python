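"""Run-and-tumble trajectory simulation under the two-state motor switch.

A cell carries one (or more) flagellar motors that switch stochastically
between counter-clockwise (CCW, run) and clockwise (CW, tumble) rotation.
CheY-P concentration sets the switching rates

    k+ = eps * exp(-h),   k- = eps * exp(+h),
    h  = (g/2) * (1/2 - Yp / (Yp + K_D)),

with k+ the CCW->CW rate.  The exponent signs are assigned so that CW bias
*increases* with Yp (CheY-P binding promotes tumbling); the literal printed
form with the opposite assignment would invert the biology.  The product
k+ * k- = eps**2 for every Yp either way.

Swimming rules: constant speed along a 3D heading subject to rotational
diffusion during runs, zero displacement during tumbles, a fresh heading
drawn uniformly on the sphere at every tumble->run transition, reflecting
boundaries in z, and 2D-projected output positions on a fixed sampling
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "MotorParams",
    "ADAPTIVE_MOTOR_GAIN",
    "adaptive_motor",
    "SwimParams",
    "Trajectory",
    "motor_switch_rates",
    "single_motor_cw_bias",
    "tumble_bias_theoretical",
    "simulate_trajectory",
    "simulate_cells",
    "cell_seed",
    "yp_for_bias",
]

RUN_LABEL = "run"
TUMBLE_LABEL = "tumble"

#: Coordination rules for multiple flagella.  "single" uses the first motor
#: only; "any-cw" declares a tumble whenever at least one independent motor
#: rotates CW (an approximation -- the original coordination model is not
#: described in the source material for this pipeline).
COORDINATION_RULES = ("single", "any-cw")

#: Effective gain of the *adaptive* motor steady-state readout.  The g=40
#: switching gain describes fast motor kinetics; on the minutes timescale
#: motor remodeling partially adapts the switch point to the prevailing
#: CheY-P level, flattening the steady-state bias-vs-CheY-P curve.  The
#: reduced-gain logistic is the package's surrogate for that steady-state
#: function and is the default readout for pathway-model tumble biases.
ADAPTIVE_MOTOR_GAIN = 8.0


@dataclass(frozen=True)
class MotorParams:
    """Two-state flagellar motor switching parameters."""

    epsilon: float = 1.3  # base switching rate, 1/s
    g: float = 40.0  # dimensionless gain
    K_D: float = 3.06  # CheY-P dissociation constant, uM

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.g <= 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if self.K_D <= 0:
            raise ValueError(f"K_D must be > 0, got {self.K_D}")


@dataclass(frozen=True)
class SwimParams:
    """Swimming and sampling parameters for the trajectory integrator."""

    speed: float = 20.0  # run speed, um/s
    D_rot: float = 0.062  # rotational diffusion coefficient, rad^2/s
    depth: float = 10.0  # chamber z-extent, um
    dt_sample: float = 0.1  # output sampling interval, s
    dt_internal: float = 0.01  # integration step, s
    n_flagella: int = 1
    #: SD of additive Gaussian localization noise on the output (x, y)
    #: samples, um.  0 gives noise-free positions (the physical path);
    #: ~0.1 um emulates sub-pixel tracking error and is used when
    #: validating the state classifier against ground truth.
    loc_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError(f"speed must be >= 0, got {self.speed}")
        if self.loc_noise < 0:
            raise ValueError(f"loc_noise must be >= 0, got {self.loc_noise}")
        if self.D_rot < 0:
            raise ValueError(f"D_rot must be >= 0, got {self.D_rot}")
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        if self.dt_internal > self.dt_sample:
            raise ValueError(
                f"dt_internal ({self.dt_internal}) must be <= dt_sample "
                f"({self.dt_sample})"
            )
        if self.n_flagella < 1:
            raise ValueError(f"n_flagella must be >= 1, got {self.n_flagella}")


@dataclass
class Trajectory:
    """Time-stamped planar positions of one cell.

    ``truth_state`` holds per-sample ground-truth labels (``"run"`` /
    ``"tumble"``) when the trajectory comes from the simulator, else None.
    """

    t: np.ndarray  # s
    x: np.ndarray  # um
    y: np.ndarray  # um
    truth_state: Optional[np.ndarray] = None
    cell_id: str = "cell"
    z: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")
        if self.truth_state is not None:
            self.truth_state = np.asarray(self.truth_state, dtype=object)
            if len(self.truth_state) != len(self.t):
                raise ValueError("truth_state length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def truth_tumble_fraction(self) -> float:
        if self.truth_state is None:
            raise ValueError("trajectory carries no ground-truth labels")
        return float(np.mean(self.truth_state == TUMBLE_LABEL))


def adaptive_motor(mp: MotorParams = None) -> MotorParams:
    """Motor parameters for the adaptive steady-state readout (reduced gain)."""
    base = mp or MotorParams()
    return MotorParams(epsilon=base.epsilon, g=ADAPTIVE_MOTOR_GAIN, K_D=base.K_D)


def motor_switch_rates(
    Yp: float, mp: MotorParams = MotorParams()
) -> tuple[float, float]:
    """CCW->CW and CW->CCW switching rates (1/s) at CheY-P level ``Yp`` (uM).

    Returns ``(k_to_CW, k_to_CCW)``.  ``k_to_CW`` increases with Yp;
    ``k_to_CW * k_to_CCW == epsilon**2`` for every Yp.
    """
    if Yp < 0:
        raise ValueError(f"Yp must be >= 0, got {Yp}")
    h = 0.5 * mp.g * (0.5 - Yp / (Yp + mp.K_D))
    return mp.epsilon * math.exp(-h), mp.epsilon * math.exp(h)


def single_motor_cw_bias(Yp: float, mp: MotorParams = MotorParams()) -> float:
    """Stationary CW (tumble) probability of a single motor.

    Closed form ``1 / (1 + exp(g * (1/2 - Yp/(Yp + K_D))))``; monotone
    non-decreasing in Yp, 0.5 at Yp == K_D.
    """
    if Yp < 0:
        raise ValueError(f"Yp must be >= 0, got {Yp}")
    return 1.0 / (1.0 + math.exp(mp.g * (0.5 - Yp / (Yp + mp.K_D))))


def tumble_bias_theoretical(
    Yp: float,
    mp: MotorParams = MotorParams(),
    n_flagella: int = 1,
    rule: str = "any-cw",
) -> float:
    """Cell tumble bias from the single-motor CW bias and a coordination rule.

    With ``rule="any-cw"`` the cell tumbles whenever any of ``n_flagella``
    independent motors is CW: TB = 1 - (1 - b)**n.  ``rule="single"``
    ignores all but one motor.
    """
    if n_flagella < 1:
        raise ValueError(f"n_flagella must be >= 1, got {n_flagella}")
    if rule not in COORDINATION_RULES:
        raise ValueError(
            f"unknown coordination rule {rule!r}; valid: {COORDINATION_RULES}"
        )
    b = single_motor_cw_bias(Yp, mp)
    if rule == "single" or n_flagella == 1:
        return b
    return 1.0 - (1.0 - b) ** n_flagella


def yp_for_bias(bias: float, mp: MotorParams = MotorParams()) -> float:
    """Invert ``single_motor_cw_bias``: CheY-P level giving a target bias."""
    if not 0.0 < bias < 1.0:
        raise ValueError(f"bias must be in (0, 1), got {bias}")
    # logit(bias) = -g*(1/2 - f), f = Yp/(Yp+K_D)
    f = 0.5 + math.log(bias / (1.0 - bias)) / mp.g
    if not 0.0 < f < 1.0:
        raise ValueError(f"bias {bias} unreachable with gain g={mp.g}")
    return mp.K_D * f / (1.0 - f)


@njit(cache=True)
def _simulate_core(
    k_cw: float,
    k_ccw: float,
    speed: float,
    d_rot: float,
    depth: float,
    dt: float,
    steps_per_sample: int,
    n_samples: int,
    start_tumbling: int,
    seed: int,
):  # pragma: no cover - exercised through simulate_trajectory
    np.random.seed(seed)
    x = 0.0
    y = 0.0
    z = np.random.uniform(0.0, depth)
    # heading uniform on the sphere
    hz = np.random.uniform(-1.0, 1.0)
    phi = np.random.uniform(0.0, 2.0 * np.pi)
    s = math.sqrt(max(0.0, 1.0 - hz * hz))
    hx = s * math.cos(phi)
    hy = s * math.sin(phi)

    tumbling = start_tumbling == 1
    if tumbling:
        t_switch = np.random.exponential(1.0 / k_ccw)
    else:
        t_switch = np.random.exponential(1.0 / k_cw)

    xs = np.empty(n_samples + 1)
    ys = np.empty(n_samples + 1)
    zs = np.empty(n_samples + 1)
    states = np.empty(n_samples + 1, dtype=np.int8)
    xs[0] = x
    ys[0] = y
    zs[0] = z
    states[0] = 1 if tumbling else 0

    sig = math.sqrt(2.0 * d_rot * dt)
    for i in range(1, n_samples + 1):
        for _ in range(steps_per_sample):
            rem = dt
            while t_switch <= rem:
                if not tumbling:
                    x += speed * t_switch * hx
                    y += speed * t_switch * hy
                    z += speed * t_switch * hz
                rem -= t_switch
                if tumbling:
                    # tumble -> run: fresh heading, uniform on sphere
                    tumbling = False
                    hz = np.random.uniform(-1.0, 1.0)
                    phi = np.random.uniform(0.0, 2.0 * np.pi)
                    s = math.sqrt(max(0.0, 1.0 - hz * hz))
                    hx = s * math.cos(phi)
                    hy = s * math.sin(phi)
                    t_switch = np.random.exponential(1.0 / k_cw)
                else:
                    tumbling = True
                    t_switch = np.random.exponential(1.0 / k_ccw)
            t_switch -= rem
            if not tumbling:
                x += speed * rem * hx
                y += speed * rem * hy
                z += speed * rem * hz
                # rotational diffusion: two orthogonal angular kicks
                if d_rot > 0.0:
                    # orthonormal frame (e1, e2) perpendicular to heading
                    if abs(hx) < 0.9:
                        e1x, e1y, e1z = 0.0, hz, -hy
                    else:
                        e1x, e1y, e1z = -hz, 0.0, hx
                    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                    e1x /= n1
                    e1y /= n1
                    e1z /= n1
                    e2x = hy * e1z - hz * e1y
                    e2y = hz * e1x - hx * e1z
                    e2z = hx * e1y - hy * e1x
                    g1 = sig * np.random.standard_normal()
                    g2 = sig * np.random.standard_normal()
                    hx += g1 * e1x + g2 * e2x
                    hy += g1 * e1y + g2 * e2y
                    hz += g1 * e1z + g2 * e2z
                    nh = math.sqrt(hx * hx + hy * hy + hz * hz)
                    hx /= nh
                    hy /= nh
                    hz /= nh
            # reflecting z boundaries (flip heading z-component too)
            if z < 0.0:
                z = -z
                hz = -hz
            elif z > depth:
                z = 2.0 * depth - z
                hz = -hz
        xs[i] = x
        ys[i] = y
        zs[i] = z
        states[i] = 1 if tumbling else 0
    return xs, ys, zs, states


def cell_seed(seed: int, cell_index: int) -> int:
    """Deterministic per-cell substream seed from (root seed, cell index)."""
    ss = np.random.SeedSequence((int(seed), int(cell_index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_trajectory(
    Yp: float,
    mp: MotorParams = MotorParams(),
    sp: SwimParams = SwimParams(),
    duration: float = 300.0,
    seed: int = 0,
    cell_id: str = "cell",
) -> Trajectory:
    """Simulate one cell for ``duration`` seconds at CheY-P level ``Yp`` (uM).

    Motor switching uses exact exponential event sampling; heading updates
    (rotational diffusion) happen every ``sp.dt_internal``.  Positions are
    projected to (x, y) on the ``sp.dt_sample`` grid; ground-truth motor
    state at each sample instant is recorded in ``truth_state``.  Identical
    (inputs, seed) give bit-identical output.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    k_cw, k_ccw = motor_switch_rates(Yp, mp)
    bias = single_motor_cw_bias(Yp, mp)

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EED)))
    start_tumbling = int(rng.random() < bias)
    core_seed = int(
        np.random.SeedSequence((int(seed), 0xC0DE)).generate_state(
            1, dtype=np.uint32
        )[0]
    )

    steps_per_sample = max(1, round(sp.dt_sample / sp.dt_internal))
    dt = sp.dt_sample / steps_per_sample
    n_samples = int(round(duration / sp.dt_sample))
    xs, ys, zs, states = _simulate_core(
        k_cw,
        k_ccw,
        sp.speed,
        sp.D_rot,
        sp.depth,
        dt,
        steps_per_sample,
        n_samples,
        start_tumbling,
        core_seed,
    )
    if sp.loc_noise > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence((int(seed), 0x0B5))
        )
        xs = xs + noise_rng.normal(0.0, sp.loc_noise, xs.shape)
        ys = ys + noise_rng.normal(0.0, sp.loc_noise, ys.shape)
    t = np.arange(n_samples + 1) * sp.dt_sample
    labels = np.where(states == 1, TUMBLE_LABEL, RUN_LABEL).astype(object)
    return Trajectory(t=t, x=xs, y=ys, truth_state=labels, cell_id=cell_id, z=zs)


def simulate_cells(
    Yp: float | Sequence[float],
    n_cells: int,
    duration: float,
    seed: int,
    mp: MotorParams = MotorParams(),
    sp: SwimParams = SwimParams(),
    id_prefix: str = "sim",
) -> list[Trajectory]:
    """Simulate a panel of cells with per-cell substreams from one root seed.

    ``Yp`` may be a scalar (shared) or a sequence of per-cell levels.
    """
    yps = np.broadcast_to(np.asarray(Yp, dtype=float), (n_cells,))
    out = []
    for i in range(n_cells):
        out.append(
            simulate_trajectory(
                float(yps[i]),
                mp=mp,
                sp=sp,
                duration=duration,
                seed=cell_seed(seed, i),
                cell_id=f"{id_prefix}_{i:05d}",
            )
        )
    return out
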