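"""Kinematics, behavioral-state classification, and motility summaries.

Per-frame kinematic features are computed from a uniformly sampled planar
trajectory:

    v_i     = |r_{i+1} - r_i| / dt                       (speed of step i)
    a_i     = (v_{i+1} - v_i) / dt                       (acceleration)
    theta_i = signed turn between velocity vectors i-1, i (rad)
    alpha_i = ((theta_{i+1}-theta_i) - (theta_i-theta_{i-1})) / dt^2

A mixture of three trivariate Gaussians over (normalized speed, normalized
acceleration, angular acceleration) represents the swimming (S), tumbling
(T), and intermediate (I, recovering from a tumble) states.  Fitting
alternates per-cell speed normalization (initialized at the 95th speed
percentile, then the mean speed while in the swimming state) with mixture
re-estimation until the fraction of frames changing state drops below a
tolerance (default 1%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .simulate import Trajectory

__all__ = [
    "KinematicsSeries",
    "BehaviorModel",
    "StateAnnotation",
    "MotilitySummary",
    "ShortTrajectoryError",
    "DegenerateDataError",
    "compute_kinematics",
    "fit_behavior_model",
    "fit_feature_mixture",
    "annotate_states",
    "summarize_motility",
    "STATE_ORDER",
]

logger = logging.getLogger(__name__)

#: Canonical state order; also the tie-break order on equal posteriors.
STATE_ORDER = ("S", "I", "T")

TIME_TOLERANCE = 1e-6  # relative tolerance on sampling-grid uniformity


class ShortTrajectoryError(ValueError):
    """Trajectory shorter than the minimum analyzable duration."""


class DegenerateDataError(ValueError):
    """Pooled features carry no variance; the mixture is unidentifiable."""


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(-np.asarray(a) + np.pi, 2.0 * np.pi)
    return -(w - np.pi)


@dataclass
class KinematicsSeries:
    """Per-frame kinematics, NaN-padded so every array has one entry per frame.

    Offsets: ``v[i]`` and the velocity vector refer to the step i -> i+1
    (defined for i in [0, n-2]); ``a[i]`` for i in [0, n-3]; ``theta[i]``
    is the turn arriving at step i (defined for i in [1, n-2]);
    ``alpha[i]`` for i in [2, n-3].
    """

    v: np.ndarray  # um/s
    a: np.ndarray  # um/s^2
    alpha: np.ndarray  # rad/s^2
    theta: np.ndarray  # rad
    vx: np.ndarray
    vy: np.ndarray
    dt: float

    @property
    def feature_mask(self) -> np.ndarray:
        """Frames where (v, a, alpha) are all defined."""
        return np.isfinite(self.v) & np.isfinite(self.a) & np.isfinite(self.alpha)


def compute_kinematics(traj: Trajectory) -> KinematicsSeries:
    """Speeds, accelerations, turn angles, and angular accelerations.

    Requires >= 4 samples on a uniform time grid.
    """
    n = len(traj)
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    dts = np.diff(traj.t)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > TIME_TOLERANCE * max(1.0, abs(dt)):
        raise ValueError("non-uniform sampling grid")

    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    vx[: n - 1] = np.diff(traj.x) / dt
    vy[: n - 1] = np.diff(traj.y) / dt
    v = np.full(n, np.nan)
    v[: n - 1] = np.hypot(vx[: n - 1], vy[: n - 1])

    a = np.full(n, np.nan)
    a[: n - 2] = (v[1 : n - 1] - v[: n - 2]) / dt

    phi = np.arctan2(vy[: n - 1], vx[: n - 1])  # direction of each step
    theta = np.full(n, np.nan)
    theta[1 : n - 1] = _wrap_angle(np.diff(phi))

    alpha = np.full(n, np.nan)
    if n >= 5:
        dtheta = _wrap_angle(np.diff(theta[1 : n - 1]))
        alpha[2 : n - 2] = _wrap_angle(np.diff(dtheta)) / dt**2

    return KinematicsSeries(v=v, a=a, alpha=alpha, theta=theta, vx=vx, vy=vy, dt=dt)


@dataclass
class BehaviorModel:
    """Three-state trivariate Gaussian mixture over kinematic features."""

    weights: np.ndarray  # (3,)
    means: np.ndarray  # (3, 3) in (v_norm, a_norm, alpha) space
    covariances: np.ndarray  # (3, 3, 3), each symmetric positive-definite
    state_names: tuple[str, ...] = STATE_ORDER
    norm_stats: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        for c in self.covariances:
            if not np.allclose(c, c.T):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("covariances must be positive-definite")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def log_posterior(self, X: np.ndarray) -> np.ndarray:
        """Log posterior responsibilities, rows normalized."""
        X = np.atleast_2d(X)
        logp = np.empty((X.shape[0], 3))
        for k in range(3):
            diff = X - self.means[k]
            L = np.linalg.cholesky(self.covariances[k])
            sol = np.linalg.solve(L, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            logp[:, k] = (
                np.log(self.weights[k])
                - 0.5 * (maha + logdet + X.shape[1] * np.log(2.0 * np.pi))
            )
        return logp - logsumexp(logp, axis=1, keepdims=True)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_posterior(X))

    def classify(self, X: np.ndarray) -> np.ndarray:
        """State indices (into ``state_names``); ties break toward S < I < T."""
        return np.argmax(self.posterior(X), axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "state_names": list(self.state_names),
                "norm_stats": self.norm_stats,
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BehaviorModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            state_names=tuple(d["state_names"]),
            norm_stats=d.get("norm_stats", {}),
            diagnostics=d.get("diagnostics", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "BehaviorModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class StateAnnotation:
    """Per-frame state labels and posteriors for one trajectory."""

    state: np.ndarray  # per-frame label in {"S", "I", "T"}
    posterior: np.ndarray  # (n, 3) ordered as STATE_ORDER
    norm_factor: float = np.nan

    def __len__(self) -> int:
        return len(self.state)


@dataclass
class MotilitySummary:
    cell_id: str
    tumble_bias: float
    mean_run_time: float  # s
    mean_speed: float  # um/s
    mean_cos_turn: float
    n_frames: int
    duration: float  # s
    n_tumbles: int = 0


def _init_norm(kin: KinematicsSeries) -> float:
    v = kin.v[np.isfinite(kin.v)]
    return float(np.percentile(v, 95)) if v.size else np.nan


def _features(kin: KinematicsSeries, norm: float) -> np.ndarray:
    m = kin.feature_mask
    return np.column_stack(
        [kin.v[m] / norm, kin.a[m] / norm, kin.alpha[m]]
    )


def fit_feature_mixture(
    X: np.ndarray, seed: int = 0, reg_covar: float = 1e-6
) -> GaussianMixture:
    """EM fit of the 3-component trivariate mixture on feature rows.

    Structured start: swim near normalized speed 1 with a tight
    angular-acceleration spread, tumble near 0 with a wide one, the
    intermediate component between them.  A blind k-means start tends to
    split on the sign of the angular acceleration instead of run/tumble
    structure.
    """
    var = np.maximum(X.var(axis=0), 1e-12)
    means_init = np.array([[1.0, 0.0, 0.0], [0.6, 0.0, 0.0], [0.1, 0.0, 0.0]])
    covs_init = [
        np.diag([0.02, var[1], 0.05 * var[2]]),
        np.diag([0.03, var[1], 0.5 * var[2]]),
        np.diag([0.04, var[1], 2.0 * var[2]]),
    ]
    return GaussianMixture(
        n_components=3,
        covariance_type="full",
        reg_covar=reg_covar,
        random_state=seed,
        weights_init=np.array([0.7, 0.15, 0.15]),
        means_init=means_init,
        precisions_init=np.array([np.linalg.inv(c) for c in covs_init]),
        n_init=1,
        max_iter=200,
    ).fit(X)


def _order_components(gm: GaussianMixture) -> np.ndarray:
    """Map raw mixture components to (S, I, T) by decreasing mean speed."""
    order = np.argsort(-gm.means_[:, 0])  # S fastest, T slowest
    return np.array([order[0], order[2], order[1]])  # -> indices for S, T, I


def fit_behavior_model(
    trajs: Iterable[Trajectory],
    tol: float = 0.01,
    max_iter: int = 20,
    seed: int = 0,
    max_fit_points: int = 500_000,
    reg_covar: float = 1e-6,
) -> BehaviorModel:
    """Fit the three-state behavioral mixture on pooled kinematic features.

    Outer loop: normalize each cell's speed (95th percentile at first, then
    its mean speed in the swimming state), refit the mixture, re-assign
    states; stop when fewer than ``tol`` of the frames change state.

    Non-convergence after ``max_iter`` iterations is reported through
    ``model.diagnostics["converged"]`` rather than raised.
    """
    trajs = list(trajs)
    kins = [compute_kinematics(tr) for tr in trajs]
    norms = np.array([_init_norm(k) for k in kins])
    if np.any(~np.isfinite(norms)) or np.any(norms <= 0):
        raise DegenerateDataError("some cells have no positive speeds")

    pooled_check = np.concatenate([k.v[k.feature_mask] for k in kins])
    n_params = 3 * (1 + 3 + 6)  # weights + means + covariance entries
    if pooled_check.size < 30 * n_params:
        raise ValueError(
            f"too few pooled feature frames ({pooled_check.size}) to fit "
            f"3 components"
        )

    rng = np.random.default_rng(seed)
    prev_labels = None
    change_history: list[float] = []
    converged = False
    gm = None
    comp_map = None

    for it in range(max_iter):
        X = np.vstack([_features(k, n) for k, n in zip(kins, norms)])
        if np.allclose(np.ptp(X, axis=0), 0.0):
            raise DegenerateDataError("features have zero variance")
        if X.shape[0] > max_fit_points:
            idx = rng.choice(X.shape[0], max_fit_points, replace=False)
            X_fit = X[idx]
        else:
            X_fit = X
        gm = fit_feature_mixture(X_fit, seed=seed, reg_covar=reg_covar)
        comp_map = _order_components(gm)  # raw component index for S, T, I
        raw_post = gm.predict_proba(X)
        # reorder columns to STATE_ORDER = (S, I, T)
        post = raw_post[:, [comp_map[0], comp_map[2], comp_map[1]]]
        labels = np.argmax(post, axis=1)

        if prev_labels is not None:
            change = float(np.mean(labels != prev_labels))
            change_history.append(change)
            if change < tol:
                converged = True
                prev_labels = labels
                break
        prev_labels = labels

        # update per-cell normalization: mean speed in swimming state
        offset = 0
        for i, k in enumerate(kins):
            m = k.feature_mask
            nk = int(m.sum())
            cell_labels = labels[offset : offset + nk]
            swim = cell_labels == 0
            if swim.any():
                norms[i] = float(np.mean(k.v[m][swim]))
            offset += nk

    if not converged:
        logger.warning(
            "behavior model did not converge below tol=%g in %d iterations",
            tol,
            max_iter,
        )

    weights = gm.weights_[[comp_map[0], comp_map[2], comp_map[1]]]
    means = gm.means_[[comp_map[0], comp_map[2], comp_map[1]]]
    covs = gm.covariances_[[comp_map[0], comp_map[2], comp_map[1]]]
    return BehaviorModel(
        weights=weights / weights.sum(),
        means=means,
        covariances=covs,
        norm_stats={
            "per_cell_norm": {
                tr.cell_id: float(n) for tr, n in zip(trajs, norms)
            }
        },
        diagnostics={
            "converged": converged,
            "n_outer_iterations": len(change_history) + 1,
            "state_change_fraction": change_history,
            "n_frames_pooled": int(pooled_check.size),
        },
    )


def annotate_states(
    traj: Trajectory,
    model: BehaviorModel,
    max_norm_iter: int = 10,
    tol: float = 0.01,
) -> StateAnnotation:
    """Per-frame posteriors and argmax state labels under a fitted model.

    The per-cell speed normalization is re-derived for the new trajectory
    (95th-percentile start, then mean swimming-state speed, iterated to
    stability).  Edge frames lacking features inherit the nearest interior
    label and a matching one-hot posterior.
    """
    kin = compute_kinematics(traj)
    n = len(traj)
    m = kin.feature_mask
    if not m.any():
        raise ValueError("trajectory has no frames with complete features")

    norm = _init_norm(kin)
    labels = None
    for _ in range(max_norm_iter):
        post = model.posterior(_features(kin, norm))
        new_labels = np.argmax(post, axis=1)
        swim = new_labels == 0
        if swim.any():
            new_norm = float(np.mean(kin.v[m][swim]))
            if new_norm > 0:
                norm = new_norm
        if labels is not None and np.mean(new_labels != labels) < tol:
            labels = new_labels
            break
        labels = new_labels
    post = model.posterior(_features(kin, norm))
    labels = np.argmax(post, axis=1)

    full_state = np.empty(n, dtype=object)
    full_post = np.zeros((n, 3))
    idx = np.flatnonzero(m)
    full_post[idx] = post
    names = np.array(model.state_names, dtype=object)
    full_state[idx] = names[labels]
    # edge frames inherit the nearest interior label
    missing = np.flatnonzero(~m)
    nearest = idx[np.argmin(np.abs(missing[:, None] - idx[None, :]), axis=1)]
    full_state[missing] = full_state[nearest]
    for j, src in zip(missing, nearest):
        full_post[j] = full_post[src]
    return StateAnnotation(state=full_state, posterior=full_post, norm_factor=norm)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index intervals where ``mask`` is True."""
    out = []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    for s, e in zip(starts, stops):
        out.append((int(s), int(e)))
    return out


def summarize_motility(
    traj: Trajectory,
    annotation: StateAnnotation,
    min_duration: float = 10.0,
    count_intermediate_as_tumble: bool = False,
    boundary_correction: bool = True,
) -> MotilitySummary:
    """Tumble bias, run statistics, and turn-angle summary for one cell.

    Tumble bias is the fraction of frames labeled T (optionally T or I).
    With ``boundary_correction`` (default) one extra frame per maximal
    tumble block is credited: the two partially covered frame intervals at
    the edges of a tumble carry on average one frame's worth of tumbling
    but are classified by their mixed kinematics, so plain frame counting
    under-reports tumble time by ~1 frame per tumble.  Set False for the
    raw frame fraction.

    Run time averages the durations of maximal swimming intervals; the
    mean cosine of tumble angles compares the heading just before and just
    after each maximal tumble block.
    """
    if traj.duration < min_duration:
        raise ShortTrajectoryError(
            f"{traj.cell_id}: duration {traj.duration:.2f}s < {min_duration}s"
        )
    kin = compute_kinematics(traj)
    state = annotation.state
    n = len(state)

    tumble_mask = state == "T"
    if count_intermediate_as_tumble:
        tumble_mask |= state == "I"
    n_blocks = len(_runs_of(tumble_mask))
    tumble_count = float(tumble_mask.sum())
    if boundary_correction:
        tumble_count = min(tumble_count + n_blocks, float(n))
    tumble_bias = tumble_count / n

    dt = kin.dt
    run_blocks = _runs_of(state == "S")
    mean_run_time = (
        float(np.mean([(e - s) * dt for s, e in run_blocks]))
        if run_blocks
        else 0.0
    )

    swim_v = kin.v[(state == "S") & np.isfinite(kin.v)]
    mean_speed = float(np.mean(swim_v)) if swim_v.size else np.nan

    # turn angle across each maximal tumble block: heading of last valid
    # step before vs first valid step after
    cosines = []
    tumble_blocks = _runs_of(state == "T")
    for s, e in tumble_blocks:
        pre = s - 1
        while pre >= 0 and not (np.isfinite(kin.vx[pre]) and kin.v[pre] > 0):
            pre -= 1
        post = e
        while post < n and not (np.isfinite(kin.vx[post]) and kin.v[post] > 0):
            post += 1
        if pre >= 0 and post < n:
            u = np.array([kin.vx[pre], kin.vy[pre]])
            w = np.array([kin.vx[post], kin.vy[post]])
            denom = np.linalg.norm(u) * np.linalg.norm(w)
            if denom > 0:
                cosines.append(float(np.dot(u, w) / denom))
    mean_cos_turn = float(np.mean(cosines)) if cosines else np.nan

    return MotilitySummary(
        cell_id=traj.cell_id,
        tumble_bias=tumble_bias,
        mean_run_time=mean_run_time,
        mean_speed=mean_speed,
        mean_cos_turn=mean_cos_turn,
        n_frames=n,
        duration=traj.duration,
        n_tumbles=len(tumble_blocks),
    )
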