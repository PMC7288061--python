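"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MeasurementSeries:
    """Timestamped joint-center observations in the camera frame.

    ``positions`` is (T, 15, 3) in meters; ``validity`` flags joints that
    were actually observed in each frame (dropouts are False).
    """

    t: np.ndarray
    positions: np.ndarray
    validity: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.validity is None:
            self.validity = np.ones(self.positions.shape[:2], dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
        if not np.all(np.isfinite(self.positions[self.validity])):
            raise ValueError("positions must be finite where valid")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class MotionTruth:
    """Ground-truth whole-body motion of a synthetic trial."""

    t: np.ndarray  # (T,)
    theta: np.ndarray  # (T, 22) rad
    theta_dot: np.ndarray  # (T, 22) rad/s
    root: np.ndarray  # (T, 3) m
    root_vel: np.ndarray  # (T, 3) m/s
    lengths: np.ndarray  # (12,) m
    rep_bounds: np.ndarray  # (reps + 1,) frame indices
    task_id: str
    angles_of_interest: tuple[int, ...]  # 0-based joint indices

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))
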