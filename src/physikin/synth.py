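"""Synthetic motion generator and depth-camera noise model.

Four scripted rehabilitation tasks (deep squat with lateral arm
extensions, stepping in place, sagittal trunk tilt, frontal trunk tilt)
are generated as smooth raised-cosine joint trajectories: every repetition
starts and ends at the resting posture (standing, arms along the body,
facing the camera) and stays strictly inside the physiological joint
limits.  Trajectory generation is fully deterministic; randomness enters
only when the rendered joint centers are corrupted with the measurement
noise model.

The noise model is white Gaussian per axis with the empirical depth-camera
moments (x: mean -0.06 m, var 0.0019 m^2; y: 0.06, 0.0050; z: -0.003,
0.0009; pooled: 0.00, 0.0052), plus optional outlier jumps and dropouts.
Real depth-sensor error is pose-dependent and structured; the white model
is a documented fidelity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from physikin.data import MeasurementSeries, MotionTruth
from physikin.skeleton import (
    DEFAULT_ANTHROPOMETRY,
    N_LEN,
    N_THETA,
    SkeletonModel,
    build_default_skeleton,
    forward_kinematics,
)

_D2R = np.pi / 180.0

# Per-axis empirical measurement-noise moments (m, m^2).
AXIS_NOISE_MEAN = np.array([-0.06, 0.06, -0.003])
AXIS_NOISE_VAR = np.array([0.0019, 0.0050, 0.0009])
POOLED_NOISE_VAR = 0.0052
OUTLIER_JUMP = 0.3  # m


@dataclass(frozen=True)
class Move:
    """One scripted degree of freedom.

    ``dof`` is a joint name or ``root_x`` / ``root_y`` / ``root_z``;
    ``amplitude`` is in radians (meters for root); ``profile`` selects a
    full-repetition raised cosine ('cycle') or one active only during the
    first/second half of each repetition ('half1' / 'half2').
    """

    dof: str
    amplitude: float
    profile: str = "cycle"


@dataclass(frozen=True)
class TaskScript:
    task_id: str
    moves: tuple[Move, ...]
    reps: int = 10
    period: float = 4.0  # s per repetition
    lead_in: float = 2.0  # s of quiet standing before the first repetition
    angles_of_interest: tuple[int, ...] = ()


def _deg(x: float) -> float:
    return x * _D2R


TASKS: dict[str, TaskScript] = {
    "squat_lateral_arms": TaskScript(
        task_id="squat_lateral_arms",
        moves=(
            Move("hip_r_flex", _deg(80)), Move("hip_l_flex", _deg(80)),
            Move("knee_r", _deg(100)), Move("knee_l", _deg(100)),
            Move("trunk", _deg(15)),
            Move("sh_r_abd", _deg(80)), Move("sh_l_abd", _deg(80)),
            Move("elbow_r", _deg(10)), Move("elbow_l", _deg(10)),
            Move("root_y", -0.38),
        ),
        angles_of_interest=tuple(range(3, 11)) + (13, 14, 15, 16,
                                                  18, 19, 20, 21),
    ),
    "stepping": TaskScript(
        task_id="stepping",
        moves=(
            Move("hip_r_flex", _deg(50), "half1"),
            Move("knee_r", _deg(70), "half1"),
            Move("hip_l_flex", _deg(50), "half2"),
            Move("knee_l", _deg(70), "half2"),
            Move("root_x", 0.02, "half1"), Move("root_x", -0.02, "half2"),
        ),
        angles_of_interest=tuple(range(3, 11)),
    ),
    "trunk_tilt_sagittal": TaskScript(
        task_id="trunk_tilt_sagittal",
        moves=(
            Move("trunk", _deg(40)),
            Move("hip_r_flex", _deg(15)), Move("hip_l_flex", _deg(15)),
            Move("root_z", -0.04),
        ),
        angles_of_interest=(3, 4, 7, 8, 11),
    ),
    "trunk_tilt_frontal": TaskScript(
        task_id="trunk_tilt_frontal",
        moves=(
            Move("base_roll", _deg(20)),
            Move("hip_r_abd", -_deg(18)), Move("hip_l_abd", _deg(18)),
            Move("root_x", 0.05),
        ),
        angles_of_interest=(3, 4, 7, 8, 11),
    ),
}


def _profile(u: np.ndarray, kind: str, period: float):
    """Raised-cosine activation s(u) in [0, 1] and ds/dt for u in [0, 1)."""
    s = np.zeros_like(u)
    ds = np.zeros_like(u)
    if kind == "cycle":
        s = 0.5 * (1.0 - np.cos(2 * np.pi * u))
        ds = (np.pi / period) * np.sin(2 * np.pi * u)
    elif kind in ("half1", "half2"):
        mask = u < 0.5 if kind == "half1" else u >= 0.5
        v = (u[mask] if kind == "half1" else u[mask] - 0.5) * 2.0
        s[mask] = 0.5 * (1.0 - np.cos(2 * np.pi * v))
        ds[mask] = (2 * np.pi / period) * np.sin(2 * np.pi * v)
    else:
        raise ValueError(f"unknown profile {kind!r}")
    return s, ds


def generate_task(
    script: TaskScript | str,
    anthropometry: np.ndarray | None = None,
    dt: float = 1.0 / 30.0,
    seed: int | None = None,
    *,
    reps: int | None = None,
    model: SkeletonModel | None = None,
) -> MotionTruth:
    """Ground-truth angle/root trajectories for a scripted task.

    Generation is deterministic: ``seed`` is accepted for interface
    symmetry with :func:`corrupt` but has no effect.  Raises when the
    scripted amplitudes would leave the joint limits.
    """
    if isinstance(script, str):
        try:
            script = TASKS[script]
        except KeyError:
            raise ValueError(f"unknown task id {script!r}") from None
    if reps is not None:
        script = replace(script, reps=reps)
    if model is None:
        model = build_default_skeleton(anthropometry)
    lengths = (model.default_lengths if anthropometry is None
               else np.asarray(anthropometry, dtype=float))

    frames_per_rep = int(round(script.period / dt))
    lead = int(round(script.lead_in / dt))
    n = lead + frames_per_rep * script.reps
    t = np.arange(n) * dt
    t_move = np.maximum(t - script.lead_in, 0.0)
    u = (t_move % script.period) / script.period
    u[:lead] = 0.0

    theta = np.zeros((n, N_THETA))
    theta_dot = np.zeros((n, N_THETA))
    root = np.zeros((n, 3))
    root_vel = np.zeros((n, 3))
    root_axis = {"root_x": 0, "root_y": 1, "root_z": 2}
    for mv in script.moves:
        s, ds = _profile(u, mv.profile, script.period)
        if mv.dof in root_axis:
            root[:, root_axis[mv.dof]] += mv.amplitude * s
            root_vel[:, root_axis[mv.dof]] += mv.amplitude * ds
        else:
            j = model.joint_index(mv.dof)
            theta[:, j] += mv.amplitude * s
            theta_dot[:, j] += mv.amplitude * ds

    lo, hi = model.limits
    if np.any(theta <= lo) or np.any(theta >= hi):
        bad = np.flatnonzero((theta.min(0) <= lo) | (theta.max(0) >= hi))
        names = ", ".join(model.joints[j].name for j in bad)
        raise ValueError(f"scripted amplitudes leave joint limits: {names}")

    rep_bounds = lead + np.arange(script.reps + 1) * frames_per_rep
    return MotionTruth(
        t=t, theta=theta, theta_dot=theta_dot, root=root, root_vel=root_vel,
        lengths=lengths, rep_bounds=rep_bounds, task_id=script.task_id,
        angles_of_interest=script.angles_of_interest)


def render_joint_centers(model: SkeletonModel,
                         truth: MotionTruth) -> MeasurementSeries:
    """Noise-free joint-center stream via forward kinematics."""
    n = truth.t.size
    pos = np.empty((n, 15, 3))
    for i in range(n):
        pos[i] = forward_kinematics(model, truth.theta[i], truth.lengths,
                                    truth.root[i])
    return MeasurementSeries(t=truth.t, positions=pos,
                             meta={"task": truth.task_id, "noise": "none"})


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement-noise model for rendered joint centers."""

    bias: np.ndarray = field(default_factory=lambda: AXIS_NOISE_MEAN.copy())
    var: np.ndarray = field(default_factory=lambda: AXIS_NOISE_VAR.copy())
    outlier_rate: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias",
                           np.broadcast_to(np.asarray(self.bias, float),
                                           (3,)).copy())
        object.__setattr__(self, "var",
                           np.broadcast_to(np.asarray(self.var, float),
                                           (3,)).copy())
        if np.any(self.var < 0):
            raise ValueError("noise variance must be non-negative")
        for r in (self.outlier_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def per_axis(cls, **kw) -> "NoiseModel":
        return cls(bias=AXIS_NOISE_MEAN, var=AXIS_NOISE_VAR, **kw)

    @classmethod
    def pooled(cls, **kw) -> "NoiseModel":
        return cls(bias=np.zeros(3), var=np.full(3, POOLED_NOISE_VAR), **kw)


def corrupt(clean: MeasurementSeries, noise: NoiseModel,
            seed: int) -> MeasurementSeries:
    """Corrupt a clean joint-center stream (reproducible given seed)."""
    if not np.all(np.isfinite(clean.positions)):
        raise ValueError("clean series must be finite")
    rng = np.random.default_rng(seed)
    shape = clean.positions.shape
    pos = clean.positions.copy()
    if np.any(noise.var > 0):
        pos += rng.normal(0.0, np.sqrt(noise.var), size=shape)
    pos += noise.bias
    validity = clean.validity.copy()
    if noise.outlier_rate > 0:
        hits = rng.random(shape[:2]) < noise.outlier_rate
        direction = rng.normal(size=shape)
        direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
        pos[hits] += OUTLIER_JUMP * direction[hits]
    if noise.dropout_rate > 0:
        validity &= rng.random(shape[:2]) >= noise.dropout_rate
    meta = dict(clean.meta, noise="gaussian", seed=seed,
                bias=noise.bias.tolist(), var=noise.var.tolist(),
                outlier_rate=noise.outlier_rate,
                dropout_rate=noise.dropout_rate)
    return MeasurementSeries(t=clean.t.copy(), positions=pos,
                             validity=validity, meta=meta)


def sample_anthropometry(seed: int, spread: float = 0.10) -> np.ndarray:
    """Draw a subject's 12 segment lengths within +-spread of the default,
    keeping left/right symmetry."""
    rng = np.random.default_rng(seed)
    base = DEFAULT_ANTHROPOMETRY.copy()
    factors = rng.uniform(1.0 - spread, 1.0 + spread, size=N_LEN)
    # mirror-symmetric subjects: tie paired segments
    pairs = [(1, 2), (3, 4), (8, 9), (10, 11)]
    for a, b in pairs:
        factors[b] = factors[a]
    return base * factors
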