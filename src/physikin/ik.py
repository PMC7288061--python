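"""Per-frame least-squares inverse kinematics over the skeleton.

Serves two purposes: initializing the filter state (angles, root and
segment lengths) from the first frames of a measurement stream, and
producing reference joint-angle trajectories from clean joint-center data
as a lightweight stand-in for a full multibody kinematic optimization.

Several rotations (e.g. hip or shoulder internal/external rotation with
the adjacent joint extended) are unobservable from joint-center positions
alone; a tiny quadratic pull toward the initial guess keeps the solution
unique without affecting observable angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from physikin.cekf import FilterState
from physikin.data import MeasurementSeries
from physikin.skeleton import (
    JCP_INDEX,
    LENGTH_NAMES,
    N_LEN,
    N_STATE,
    N_THETA,
    S_LEN,
    S_ROOT,
    S_THETA,
    SEGMENT_PAIRS,
    SkeletonModel,
    fk_with_jacobian,
)

logger = logging.getLogger(__name__)

REG_WEIGHT = 1e-6  # quadratic pull toward theta_init for unobservable DOFs
LENGTH_BOUND_FRACTION = 0.2  # +-20% bounds around the initial estimate


@dataclass
class IKResult:
    theta: np.ndarray  # (22,) rad
    root: np.ndarray  # (3,) m
    residual: float  # RMS point distance, m
    converged: bool


def estimate_initial_lengths(
    frames: MeasurementSeries | np.ndarray,
    model: SkeletonModel,
    n_frames: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment lengths from noise-corrected mean inter-center distances.

    The raw mean Euclidean distance between two noisy centers is biased
    upward (strongly so for short segments such as the pelvis), since
    ``E[|d + n|^2] = L^2 + 2 * sum(axis variances)``.  The per-axis noise
    variance is estimated from frame-to-frame position differences over
    the init window (trials start at quiet standing, so true motion is
    negligible there) and subtracted from the mean squared distance.
    Returns ``(lengths, lo, hi)`` with ``lo = 0.8 * lengths`` and
    ``hi = 1.2 * lengths``.
    """
    if isinstance(frames, MeasurementSeries):
        pos = frames.positions[:n_frames]
        valid = frames.validity[:n_frames]
    else:
        pos = np.asarray(frames, dtype=float)[:n_frames]
        valid = np.ones(pos.shape[:2], dtype=bool)
    if pos.shape[0] < 1:
        raise ValueError("need at least one frame")

    noise_var = 0.0  # sum over the three axes
    if pos.shape[0] >= 3:
        pair_ok = valid[1:] & valid[:-1]
        steps = (pos[1:] - pos[:-1])[pair_ok]
        if steps.shape[0] >= 10:
            # var of a difference of two i.i.d. noises is twice the noise var
            noise_var = float(np.sum(steps.var(axis=0) / 2.0))

    lengths = np.empty(N_LEN)
    for k, name in enumerate(LENGTH_NAMES):
        sq = []
        for a, b in SEGMENT_PAIRS[name]:
            ia, ib = JCP_INDEX[a], JCP_INDEX[b]
            ok = valid[:, ia] & valid[:, ib]
            if ok.any():
                sq.append(np.sum((pos[ok, ia] - pos[ok, ib]) ** 2, axis=1))
        if not sq:
            raise ValueError(
                f"segment {name!r}: no frame with both endpoints valid")
        mean_sq = float(np.concatenate(sq).mean())
        # keep a positive floor in case the noise estimate overshoots
        lengths[k] = np.sqrt(max(mean_sq - 2.0 * noise_var, 0.04 * mean_sq))
    lo = (1.0 - LENGTH_BOUND_FRACTION) * lengths
    hi = (1.0 + LENGTH_BOUND_FRACTION) * lengths
    return lengths, lo, hi


def ik_frame(
    model: SkeletonModel,
    frame: np.ndarray,
    lengths: np.ndarray,
    theta_init: np.ndarray,
    root_init: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    *,
    limit_clip: bool = True,
    reg_weight: float = REG_WEIGHT,
) -> IKResult:
    """Bounded least-squares fit of (theta, root) to one frame's centers.

    Deterministic given the initial guess; the returned ``converged`` flag
    mirrors the solver status and the best iterate is returned regardless.
    """
    frame = np.asarray(frame, dtype=float).reshape(15, 3)
    if valid is None:
        valid = np.isfinite(frame).all(axis=1)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() < 6:
        raise ValueError("need at least 6 valid joints for IK")
    rows = np.flatnonzero(np.repeat(valid, 3))
    z = frame.ravel()[rows]
    theta_init = np.asarray(theta_init, dtype=float)
    if root_init is None:
        # the spine base coincides with the root origin
        root_init = (frame[JCP_INDEX["spine_base"]]
                     if valid[JCP_INDEX["spine_base"]]
                     else frame[valid].mean(axis=0))
    sqrt_w = np.sqrt(reg_weight)

    lo, hi = model.limits
    if limit_clip:
        lb = np.concatenate([lo, np.full(3, -10.0)])
        ub = np.concatenate([hi, np.full(3, 10.0)])
    else:
        lb, ub = -np.inf, np.inf
    x0 = np.concatenate([np.clip(theta_init, lo + 1e-9, hi - 1e-9),
                         root_init])

    def fun(x):
        p, _, _ = fk_with_jacobian(model, x[:N_THETA], lengths, x[N_THETA:])
        return np.concatenate([p.ravel()[rows] - z,
                               sqrt_w * (x[:N_THETA] - theta_init)])

    def jac(x):
        _, j_theta, _ = fk_with_jacobian(model, x[:N_THETA], lengths)
        top = np.hstack([j_theta[rows],
                         np.tile(np.eye(3), (15, 1))[rows]])
        reg = np.hstack([sqrt_w * np.eye(N_THETA),
                         np.zeros((N_THETA, 3))])
        return np.vstack([top, reg])

    sol = least_squares(fun, x0, jac=jac, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    point_res = sol.fun[:rows.size].reshape(-1, 3)
    rms = float(np.sqrt(np.mean(np.sum(point_res**2, axis=1))))
    return IKResult(theta=sol.x[:N_THETA], root=sol.x[N_THETA:],
                    residual=rms, converged=bool(sol.status > 0))


@dataclass
class IKTrajectory:
    t: np.ndarray
    theta: np.ndarray  # (T, 22)
    root: np.ndarray  # (T, 3)
    residual: np.ndarray  # (T,)
    converged: np.ndarray  # (T,) bool


def mko_reference(
    series: MeasurementSeries,
    model: SkeletonModel,
    lengths: np.ndarray,
    theta0: np.ndarray | None = None,
) -> IKTrajectory:
    """Per-frame IK over a whole series with fixed segment lengths.

    Each frame is warm-started from the previous solution, emulating the
    constant-length reference reconstruction used for marker data.
    """
    n = series.n_frames
    theta = np.empty((n, N_THETA))
    root = np.empty((n, 3))
    residual = np.empty(n)
    converged = np.empty(n, dtype=bool)
    guess = np.zeros(N_THETA) if theta0 is None else np.asarray(theta0)
    root_guess = None
    for i in range(n):
        res = ik_frame(model, series.positions[i], lengths, guess,
                       root_init=root_guess, valid=series.validity[i])
        theta[i], root[i] = res.theta, res.root
        residual[i], converged[i] = res.residual, res.converged
        if not res.converged:
            logger.warning("IK frame %d did not converge "
                           "(residual %.3e m)", i, res.residual)
        guess, root_guess = res.theta, res.root
    return IKTrajectory(t=series.t.copy(), theta=theta, root=root,
                        residual=residual, converged=converged)


def initialize_state(
    series: MeasurementSeries,
    model: SkeletonModel,
    n_length_frames: int = 30,
    p0: np.ndarray | None = None,
) -> tuple[FilterState, np.ndarray, np.ndarray]:
    """Filter initialization from the first frames of a stream.

    Lengths are averaged over ``n_length_frames`` frames, angles and root
    come from IK on the first valid frame, velocities and accelerations
    start at zero, and P0 defaults to the identity.  Returns the state and
    the +-20% length bounds ``(lo, hi)``.
    """
    lengths, l_lo, l_hi = estimate_initial_lengths(
        series, model, n_frames=n_length_frames)
    # trials start at quiet standing: averaging the init window suppresses
    # the measurement noise before the one-frame IK fit
    window = series.positions[:n_length_frames]
    w_valid = series.validity[:n_length_frames]
    counts = w_valid.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("a joint is never valid in the init window")
    mean_pos = np.einsum("tjc,tj->jc", np.where(
        w_valid[..., None], window, 0.0), w_valid.astype(float))
    mean_pos /= counts[:, None]
    # stronger neutral pull than the per-frame default: at quiet standing
    # the axial rotations are unobservable and should start at neutral
    res = ik_frame(model, mean_pos, lengths, np.zeros(N_THETA),
                   reg_weight=1e-3)
    x = np.zeros(N_STATE)
    x[S_THETA] = res.theta
    x[S_LEN] = lengths
    x[S_ROOT] = res.root
    p = np.eye(N_STATE) if p0 is None else p0
    return FilterState(x=x, P=p.copy()), l_lo, l_hi
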