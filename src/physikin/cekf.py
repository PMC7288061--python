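"""Constrained extended Kalman filter with a restricted gain.

The filter tracks an 84-dimensional state -- 22 joint angles with their
velocities and accelerations, 12 segment lengths, and a 3-D root translation
with its velocity -- against the 45 stacked coordinates of the 15 measured
joint centers.  The state transition is linear (constant-acceleration model
for the angles, constant-velocity for the root, constant segment lengths);
the measurement model is the forward-kinematics map of the skeleton.

Physical consistency (joint limits, bounded segment lengths) is enforced at
every update by correcting the Kalman gain on the active inequality rows,
so that the posterior satisfies ``C x <= d`` componentwise.  With the
single-component constraint rows used here the gain correction moves only
the offending components, i.e. it clamps them onto their bound.  The error
covariance is propagated in Joseph form, by default with the standard
(pre-correction) gain so the correction acts as a covariance-neutral
projection; a direct componentwise clamp remains as a logged safety net
for the degenerate case of a vanishing innovation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from physikin.skeleton import (
    N_JCP,
    N_LEN,
    N_ROOT,
    N_STATE,
    N_THETA,
    S_DDTHETA,
    S_DTHETA,
    S_LEN,
    S_ROOT,
    S_ROOTV,
    S_THETA,
    SkeletonModel,
    fk_with_jacobian,
    forward_kinematics,
)

logger = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-9


@dataclass
class FilterState:
    """State estimate and its error covariance."""

    x: np.ndarray  # (84,)
    P: np.ndarray  # (84, 84)

    @property
    def theta(self) -> np.ndarray:
        return self.x[S_THETA]

    @property
    def theta_dot(self) -> np.ndarray:
        return self.x[S_DTHETA]

    @property
    def theta_ddot(self) -> np.ndarray:
        return self.x[S_DDTHETA]

    @property
    def lengths(self) -> np.ndarray:
        return self.x[S_LEN]

    @property
    def root(self) -> np.ndarray:
        return self.x[S_ROOT]


@dataclass
class ConstraintSet:
    """Inequality constraints ``sign * x[idx] <= bound`` (one row each).

    Rows cover both bounds of every joint angle and segment length; the
    dense ``C`` / ``d`` form of the constraint system is exposed for tests
    and oracles.
    """

    idx: np.ndarray  # (m,) state indices
    sign: np.ndarray  # (m,) +-1
    bound: np.ndarray  # (m,)

    @classmethod
    def from_model(cls, model: SkeletonModel, length_lo: np.ndarray,
                   length_hi: np.ndarray) -> "ConstraintSet":
        lo, hi = model.limits
        if np.any(length_lo <= 0):
            raise ValueError("lower length bounds must be positive")
        idx, sign, bound = [], [], []
        for j in range(model.n_joints):
            idx += [j, j]
            sign += [-1.0, 1.0]
            bound += [-lo[j], hi[j]]
        for k in range(model.n_lengths):
            i = S_LEN.start + k
            idx += [i, i]
            sign += [-1.0, 1.0]
            bound += [-length_lo[k], length_hi[k]]
        out = cls(np.array(idx), np.array(sign), np.array(bound))
        if not np.all(np.isfinite(out.bound)):
            raise ValueError("constraint bounds must be finite")
        return out

    @property
    def C(self) -> np.ndarray:
        c = np.zeros((len(self.idx), N_STATE))
        c[np.arange(len(self.idx)), self.idx] = self.sign
        return c

    @property
    def d(self) -> np.ndarray:
        return self.bound.copy()

    def violations(self, x: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Indices of rows with ``sign * x[idx] > bound - tol``."""
        return np.flatnonzero(self.sign * x[self.idx] > self.bound - tol)

    def clamp(self, x: np.ndarray) -> np.ndarray:
        """Project the constrained components onto their bounds."""
        out = x.copy()
        viol = self.violations(out)
        out[self.idx[viol]] = self.sign[viol] * self.bound[viol]
        return out

    def satisfied(self, x: np.ndarray, tol: float = _BOUNDARY_TOL) -> bool:
        return self.violations(x, tol=-tol).size == 0


@dataclass
class FilterMatrices:
    F: np.ndarray  # (84, 84)
    Q: np.ndarray  # (84, 84)
    R: np.ndarray  # (45, 45)
    dt: float


def build_transition(dt: float, n_theta: int = N_THETA,
                     n_lengths: int = N_LEN, n_root: int = N_ROOT,
                     ) -> np.ndarray:
    """Linear transition: angles integrate a constant-acceleration model,
    segment lengths are constant, the root follows a constant-velocity
    model."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = 3 * n_theta + n_lengths + 2 * n_root
    f = np.eye(n)
    i = np.arange(n_theta)
    f[i, i + n_theta] = dt
    f[i, i + 2 * n_theta] = 0.5 * dt * dt
    f[i + n_theta, i + 2 * n_theta] = dt
    r0 = 3 * n_theta + n_lengths
    j = np.arange(n_root)
    f[r0 + j, r0 + n_root + j] = dt
    return f


def predict(state: FilterState, f: np.ndarray, q: np.ndarray) -> FilterState:
    """Time update: ``x- = F x``, ``P- = F P F' + Q`` (symmetrized)."""
    x = f @ state.x
    p = f @ state.P @ f.T + q
    return FilterState(x=x, P=0.5 * (p + p.T))


def _masked_rows(valid: np.ndarray | None) -> np.ndarray:
    if valid is None:
        return np.arange(3 * N_JCP)
    return np.flatnonzero(np.repeat(np.asarray(valid, dtype=bool), 3))


def _solve_spd(s: np.ndarray, b: np.ndarray):
    """Cholesky solve with a logged jitter fallback for near-singular S."""
    try:
        return cho_solve(cho_factor(s), b), s
    except np.linalg.LinAlgError:
        jitter = 1e-9 * np.trace(s) / s.shape[0]
        logger.warning("innovation covariance near singular; "
                       "adding jitter %.3e", jitter)
        s = s + jitter * np.eye(s.shape[0])
        return cho_solve(cho_factor(s), b), s


def correct_gain(
    k: np.ndarray,
    nu: np.ndarray,
    sinv_nu: np.ndarray,
    x_unc: np.ndarray,
    c_act: np.ndarray,
    d_act: np.ndarray,
    x_prior: np.ndarray | None = None,
    residual_from: str = "posterior",
) -> np.ndarray:
    """Constraint-corrected Kalman gain for the active rows.

    ``K_R = K - C'(CC')^-1 (C x - d) (nu' S^-1 nu)^-1 nu' S^-1`` with the
    constraint residual evaluated at the unconstrained posterior
    (default) or at the prior.  System-agnostic: used by the filter and
    directly testable on low-dimensional toy problems.
    """
    nsn = float(nu @ sinv_nu)
    ref = x_unc if residual_from == "posterior" else x_prior
    resid = c_act @ ref - d_act
    corr = c_act.T @ np.linalg.solve(c_act @ c_act.T, resid)
    return k - np.outer(corr, sinv_nu) / nsn


def restricted_update(
    x_prior: np.ndarray,
    p_prior: np.ndarray,
    z: np.ndarray,
    model: SkeletonModel,
    r: np.ndarray,
    constraints: ConstraintSet,
    valid: np.ndarray | None = None,
    *,
    residual_from: str = "posterior",
    joseph: bool = True,
    p_gain: str = "standard",
) -> tuple[FilterState, dict]:
    """Measurement update with a constraint-corrected (restricted) gain.

    When no constraint row is active this is the textbook EKF update.
    Otherwise the gain is corrected with the active rows of ``C``/``d`` so
    the posterior lands on the violated bounds; a residual componentwise
    clamp (logged) guards the degenerate vanishing-innovation case.

    ``residual_from`` selects whether the constraint residual is evaluated
    at the unconstrained posterior (default; guarantees the bound is met)
    or at the prior (the literal gain-correction formula).

    ``p_gain`` selects the gain used in the covariance update:
    ``"standard"`` (default) treats the constraint correction as a
    projection that leaves the error covariance untouched -- a clamped
    component keeps its uncertainty and can move off its bound once the
    data pull it back; ``"restricted"`` propagates the corrected gain into
    the covariance, which freezes components that were clamped while
    poorly observed.

    Returns the posterior state and an info dict (active row count,
    innovation, whether clamping was needed).
    """
    z = np.asarray(z, dtype=float).ravel()
    rows = _masked_rows(valid)
    p, j_theta, j_len = fk_with_jacobian(
        model, x_prior[S_THETA], x_prior[S_LEN], x_prior[S_ROOT])
    h_full = p.ravel()
    hmat = np.zeros((3 * N_JCP, N_STATE))
    hmat[:, S_THETA] = j_theta
    hmat[:, S_LEN] = j_len
    hmat[:, S_ROOT] = np.tile(np.eye(3), (N_JCP, 1))
    hmat = hmat[rows]
    nu = z[rows] - h_full[rows]
    if not np.all(np.isfinite(nu)):
        raise ValueError("non-finite measurement on valid joints")
    ph_t = p_prior @ hmat.T
    s = hmat @ ph_t + r[np.ix_(rows, rows)]
    s = 0.5 * (s + s.T)
    sinv_nu_and_kt, s = _solve_spd(s, np.column_stack([nu, ph_t.T]))
    sinv_nu = sinv_nu_and_kt[:, 0]
    k = sinv_nu_and_kt[:, 1:].T  # P H' S^-1
    x_unc = x_prior + k @ nu

    info = {"n_active": 0, "clamped": False, "innovation_rms": float(
        np.sqrt(np.mean(nu**2)))}
    active = constraints.violations(x_unc, tol=_BOUNDARY_TOL)
    k_restricted = k
    if active.size == 0:
        x_post = x_unc
    else:
        info["n_active"] = int(active.size)
        nsn = float(nu @ sinv_nu)
        if nsn < 1e-12:
            # (nu' S^-1 nu)^-1 undefined: fall back to clamping.
            logger.warning("vanishing innovation with %d active constraints;"
                           " clamping", active.size)
            x_post = constraints.clamp(x_unc)
            info["clamped"] = True
        else:
            c_act = np.zeros((active.size, N_STATE))
            c_act[np.arange(active.size),
                  constraints.idx[active]] = constraints.sign[active]
            d_act = constraints.bound[active]
            k_restricted = correct_gain(
                k, nu, sinv_nu, x_unc, c_act, d_act,
                x_prior=x_prior, residual_from=residual_from)
            x_post = x_prior + k_restricted @ nu
            if not constraints.satisfied(x_post):
                logger.debug("post-hoc clamp after restricted gain")
                x_post = constraints.clamp(x_post)
                info["clamped"] = True

    k_used = k if p_gain == "standard" else k_restricted
    if joseph:
        a = np.eye(N_STATE) - k_used @ hmat
        p_post = a @ p_prior @ a.T + k_used @ r[np.ix_(rows, rows)] @ k_used.T
    else:
        p_post = (np.eye(N_STATE) - k_used @ hmat) @ p_prior
    p_post = 0.5 * (p_post + p_post.T)
    return FilterState(x=x_post, P=p_post), info


@dataclass
class FilterResult:
    """Per-frame posterior trajectory of a filtering run."""

    t: np.ndarray  # (T,)
    theta: np.ndarray  # (T, 22) rad
    theta_dot: np.ndarray  # (T, 22) rad/s
    theta_ddot: np.ndarray  # (T, 22) rad/s^2
    lengths: np.ndarray  # (T, 12) m
    root: np.ndarray  # (T, 3) m
    n_active: np.ndarray  # (T,) active constraint rows per frame
    predicted_only: np.ndarray  # (T,) bool, frames with no valid joints
    innovation_rms: np.ndarray  # (T,) m
    p_diag: np.ndarray  # (T, 84) posterior variance diagonal
    final_state: FilterState = field(repr=False, default=None)


def run_filter(
    measurements,
    model: SkeletonModel,
    matrices: FilterMatrices,
    constraints: ConstraintSet,
    init: FilterState,
    *,
    residual_from: str = "posterior",
    joseph: bool = True,
    p_gain: str = "standard",
) -> FilterResult:
    """Run the CEKF causally over a full trial (single forward pass).

    ``measurements`` needs attributes ``t`` (T,), ``positions`` (T, 15, 3)
    and ``validity`` (T, 15).  Frames with no valid joint get a
    prediction-only step (constraints still enforced by clamping, flagged
    in the output).
    """
    t = np.asarray(measurements.t, dtype=float)
    if t.size >= 2:
        steps = np.diff(t)
        if steps.min() <= 0:
            raise ValueError("measurement timestamps must be increasing")
        if steps.max() / steps.min() > 1.01:
            raise ValueError("measurement rate not uniform within 1%")
    n = t.size
    state = FilterState(x=init.x.copy(), P=init.P.copy())
    out = FilterResult(
        t=t,
        theta=np.empty((n, N_THETA)),
        theta_dot=np.empty((n, N_THETA)),
        theta_ddot=np.empty((n, N_THETA)),
        lengths=np.empty((n, N_LEN)),
        root=np.empty((n, 3)),
        n_active=np.zeros(n, dtype=int),
        predicted_only=np.zeros(n, dtype=bool),
        innovation_rms=np.full(n, np.nan),
        p_diag=np.empty((n, N_STATE)),
    )
    for i in range(n):
        prior = predict(state, matrices.F, matrices.Q)
        valid = np.asarray(measurements.validity[i], dtype=bool)
        if not valid.any():
            logger.info("frame %d: no valid joints, prediction-only", i)
            x = constraints.clamp(prior.x)
            state = FilterState(x=x, P=prior.P)
            out.predicted_only[i] = True
        else:
            state, info = restricted_update(
                prior.x, prior.P, measurements.positions[i].ravel(),
                model, matrices.R, constraints,
                valid=None if valid.all() else valid,
                residual_from=residual_from, joseph=joseph, p_gain=p_gain)
            out.n_active[i] = info["n_active"]
            out.innovation_rms[i] = info["innovation_rms"]
        out.theta[i] = state.theta
        out.theta_dot[i] = state.theta_dot
        out.theta_ddot[i] = state.theta_ddot
        out.lengths[i] = state.lengths
        out.root[i] = state.root
        out.p_diag[i] = np.diag(state.P)
    out.final_state = state
    return out
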