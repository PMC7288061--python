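"""Kinematic chain of the whole-body biomechanical model.

The locomotor system is modeled as a tree of 22 revolute joints spanning 12
rigid segments, rooted at the pelvis (spine base).  Every joint rotates about
its *local Z axis*; an arbitrary anatomical rotation axis is obtained by a
fixed pre-rotation of the joint frame, so spherical joints (hips, shoulders,
base link) are stacks of three co-located revolute Z joints realizing an
intrinsic Euler sequence.  Fixed translations between frames are affine in
the 12 segment lengths, which makes joint-center positions affine in the
lengths for a fixed posture -- a property the analytic Jacobian exploits.

The measurement model ``h`` maps a posture (22 angles, 12 lengths, 3 root
translations) to the 15 tracked joint-center positions (camera frame,
meters): spine base / mid / shoulder plus left and right shoulder, elbow,
wrist, hip, knee and ankle.  Units are radians and meters throughout;
degrees appear only at I/O boundaries.

Joint indexing is 0-based internally; ``JOINT_NAMES[i]`` corresponds to the
conventional numbering theta_(i+1) (theta_1..theta_3 base link,
theta_4..theta_7 right leg, theta_8..theta_11 left leg, theta_12 trunk,
theta_13/theta_18 clavicles, theta_14..theta_17 right arm,
theta_19..theta_22 left arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

N_THETA = 22
N_LEN = 12
N_JCP = 15
N_ROOT = 3

# State-vector layout shared by the filter and the measurement Jacobian:
# [theta (22), theta_dot (22), theta_ddot (22), lengths (12),
#  root position (3), root velocity (3)]
S_THETA = slice(0, N_THETA)
S_DTHETA = slice(N_THETA, 2 * N_THETA)
S_DDTHETA = slice(2 * N_THETA, 3 * N_THETA)
S_LEN = slice(3 * N_THETA, 3 * N_THETA + N_LEN)
S_ROOT = slice(3 * N_THETA + N_LEN, 3 * N_THETA + N_LEN + 3)
S_ROOTV = slice(3 * N_THETA + N_LEN + 3, 3 * N_THETA + N_LEN + 6)
N_STATE = 3 * N_THETA + N_LEN + 6  # 84

LENGTH_NAMES = (
    "pelvis",
    "thigh_r",
    "thigh_l",
    "shank_r",
    "shank_l",
    "trunk_lower",
    "trunk_upper",
    "clavicle",
    "upper_arm_r",
    "upper_arm_l",
    "forearm_r",
    "forearm_l",
)

JCP_NAMES = (
    "spine_base",
    "spine_mid",
    "spine_shoulder",
    "shoulder_r",
    "elbow_r",
    "wrist_r",
    "shoulder_l",
    "elbow_l",
    "wrist_l",
    "hip_r",
    "knee_r",
    "ankle_r",
    "hip_l",
    "knee_l",
    "ankle_l",
)


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# Fixed rotations carrying the local Z axis onto a signed world axis.
_AXIS_ROT = {
    "+z": np.eye(3),
    "-z": _rx(np.pi),
    "+x": _ry(np.pi / 2),
    "-x": _ry(-np.pi / 2),
    "+y": _rx(-np.pi / 2),
    "-y": _rx(np.pi / 2),
}


@dataclass(frozen=True)
class JointSpec:
    """One revolute joint: fixed transform from parent, then Rz(theta).

    ``t_const`` and the direction vectors in ``t_lengths`` are expressed in
    the parent frame; ``t_lengths`` holds ``(length_index, direction)``
    terms so the offset is ``t_const + sum(L[i] * d_i)``.
    """

    name: str
    parent: int  # -1 for the root joint
    axis: str  # signed world axis of rotation at the reference posture
    r_pre: np.ndarray
    t_const: np.ndarray
    t_lengths: tuple[tuple[int, np.ndarray], ...]
    limit_lo: float  # rad
    limit_hi: float  # rad
    group: str  # leg / arm / base / trunk
    tuning_key: str  # process-noise sharing key, e.g. "leg.flex"


@dataclass(frozen=True)
class JcpSpec:
    """A tracked joint center: a fixed offset in one joint's frame."""

    name: str
    joint: int
    off_const: np.ndarray
    off_lengths: tuple[tuple[int, np.ndarray], ...]


@dataclass
class SkeletonModel:
    joints: list[JointSpec]
    jcp_map: list[JcpSpec]
    default_lengths: np.ndarray  # (12,) m, reference anthropometry
    length_names: tuple[str, ...] = LENGTH_NAMES
    # ancestors[i, k] is True when joint k is joint i or one of its ancestors
    ancestors: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.joints)
        anc = np.zeros((n, n), dtype=bool)
        for i, js in enumerate(self.joints):
            if js.parent >= 0:
                anc[i] = anc[js.parent]
            anc[i, i] = True
        self.ancestors = anc
        # dense structure arrays for the vectorized kinematics kernels
        nl = len(self.length_names)
        self._parents = np.array([js.parent for js in self.joints])
        self._r_pre = np.stack([js.r_pre for js in self.joints])
        self._t_const = np.stack([js.t_const for js in self.joints])
        t_len = np.zeros((n, 3, nl))
        for i, js in enumerate(self.joints):
            for k, d in js.t_lengths:
                t_len[i, :, k] += d
        self._t_len = t_len
        self._jcp_joint = np.array([s.joint for s in self.jcp_map])
        self._jcp_const = np.stack([s.off_const for s in self.jcp_map])
        jcp_len = np.zeros((len(self.jcp_map), 3, nl))
        for m, s in enumerate(self.jcp_map):
            for k, d in s.off_lengths:
                jcp_len[m, :, k] += d
        self._jcp_len = jcp_len
        self._jcp_anc = anc[self._jcp_joint].astype(float)  # (15, 22)

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def n_lengths(self) -> int:
        return len(self.length_names)

    @property
    def limits(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([j.limit_lo for j in self.joints])
        hi = np.array([j.limit_hi for j in self.joints])
        return lo, hi

    def joint_index(self, name: str) -> int:
        for i, js in enumerate(self.joints):
            if js.name == name:
                return i
        raise KeyError(name)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for js in self.joints:
            sizes[js.group] = sizes.get(js.group, 0) + 1
        return sizes


# --------------------------------------------------------------------------
# Default model definition.
#
# World frame at the reference posture (standing, arms along the body,
# facing the camera): X to the subject's right, Y up, Z forward (toward the
# camera).  All joint frames coincide with the world orientation at the
# reference posture, so offsets and rotation axes below are written directly
# in world coordinates.  Positive angle conventions: flexion forward,
# abduction lateral, elevation up -- mirrored axes on the left side keep the
# signs side-symmetric.
# --------------------------------------------------------------------------

# Unit direction from the spine base to each hip (lateral and slightly down).
_HIP_DIR = np.array([2.0, -1.0, 0.0]) / np.sqrt(5.0)
_DOWN = np.array([0.0, -1.0, 0.0])
_UP = np.array([0.0, 1.0, 0.0])

_L = {name: i for i, name in enumerate(LENGTH_NAMES)}

# Physiological joint limits in degrees (conservative ranges from standard
# goniometry tables; base-link orientation is unbounded in practice).
_LIMITS_DEG = {
    "base": (-180.0, 180.0),
    "hip_flex": (-30.0, 130.0),
    "hip_abd": (-50.0, 50.0),
    "hip_rot": (-45.0, 45.0),
    "knee": (-3.0, 150.0),
    "trunk": (-30.0, 90.0),
    "clav": (-40.0, 40.0),
    "sh_flex": (-90.0, 180.0),
    "sh_abd": (-45.0, 180.0),
    "sh_rot": (-90.0, 90.0),
    "elbow": (-3.0, 150.0),
}


def _default_joint_table() -> list[dict]:
    """World-frame joint definitions in theta_1..theta_22 order."""

    def j(name, parent, axis, limits, group, key, terms=()):
        return dict(name=name, parent=parent, axis=axis, limits=limits,
                    group=group, key=key, terms=terms)

    t = []
    # Base link: three co-located rotations at the spine base (yaw about the
    # vertical, then pitch, then roll).
    t.append(j("base_yaw", -1, "+y", "base", "base", "base.rot"))
    t.append(j("base_pitch", 0, "+x", "base", "base", "base.rot"))
    t.append(j("base_roll", 1, "+z", "base", "base", "base.rot"))
    # Right leg (theta_4..theta_7).
    t.append(j("hip_r_flex", 2, "-x", "hip_flex", "leg", "leg.flex",
               ((_L["pelvis"], _HIP_DIR * np.array([1.0, 1.0, 1.0])),)))
    t.append(j("hip_r_abd", 3, "+z", "hip_abd", "leg", "leg.abd"))
    t.append(j("hip_r_rot", 4, "-y", "hip_rot", "leg", "leg.rot"))
    t.append(j("knee_r", 5, "+x", "knee", "leg", "leg.knee",
               ((_L["thigh_r"], _DOWN),)))
    # Left leg (theta_8..theta_11); lateral axes mirrored.
    t.append(j("hip_l_flex", 2, "-x", "hip_flex", "leg", "leg.flex",
               ((_L["pelvis"], _HIP_DIR * np.array([-1.0, 1.0, 1.0])),)))
    t.append(j("hip_l_abd", 7, "-z", "hip_abd", "leg", "leg.abd"))
    t.append(j("hip_l_rot", 8, "+y", "hip_rot", "leg", "leg.rot"))
    t.append(j("knee_l", 9, "+x", "knee", "leg", "leg.knee",
               ((_L["thigh_l"], _DOWN),)))
    # Trunk flexion/extension (theta_12) at the spine base.
    t.append(j("trunk", 2, "-x", "trunk", "trunk", "trunk"))
    # Right clavicle + arm (theta_13..theta_17).
    _sternum = ((_L["trunk_lower"], _UP), (_L["trunk_upper"], _UP))
    # Shoulder sequence: abduction, then flexion, then axial rotation.
    # The middle angle (flexion) stays far from the 90 deg singularity in
    # rehabilitation tasks even during full lateral arm raises, and the
    # poorly observable axial rotation sits last in the chain where an
    # erroneous value cannot corrupt the direction-setting axes.
    t.append(j("clav_r", 11, "+z", "clav", "trunk", "trunk", _sternum))
    t.append(j("sh_r_abd", 12, "+z", "sh_abd", "arm", "arm.abd",
               ((_L["clavicle"], np.array([1.0, 0.0, 0.0])),)))
    t.append(j("sh_r_flex", 13, "-x", "sh_flex", "arm", "arm.flex"))
    t.append(j("sh_r_rot", 14, "-y", "sh_rot", "arm", "arm.rot"))
    t.append(j("elbow_r", 15, "-x", "elbow", "arm", "arm.elbow",
               ((_L["upper_arm_r"], _DOWN),)))
    # Left clavicle + arm (theta_18..theta_22).
    t.append(j("clav_l", 11, "-z", "clav", "trunk", "trunk", _sternum))
    t.append(j("sh_l_abd", 17, "-z", "sh_abd", "arm", "arm.abd",
               ((_L["clavicle"], np.array([-1.0, 0.0, 0.0])),)))
    t.append(j("sh_l_flex", 18, "-x", "sh_flex", "arm", "arm.flex"))
    t.append(j("sh_l_rot", 19, "+y", "sh_rot", "arm", "arm.rot"))
    t.append(j("elbow_l", 20, "-x", "elbow", "arm", "arm.elbow",
               ((_L["upper_arm_l"], _DOWN),)))
    return t


def _default_jcp_table() -> list[dict]:
    def c(name, joint, terms=()):
        return dict(name=name, joint=joint, terms=terms)

    return [
        c("spine_base", "base_roll"),
        c("spine_mid", "trunk", ((_L["trunk_lower"], _UP),)),
        c("spine_shoulder", "trunk",
          ((_L["trunk_lower"], _UP), (_L["trunk_upper"], _UP))),
        c("shoulder_r", "sh_r_abd"),
        c("elbow_r", "elbow_r"),
        c("wrist_r", "elbow_r", ((_L["forearm_r"], _DOWN),)),
        c("shoulder_l", "sh_l_abd"),
        c("elbow_l", "elbow_l"),
        c("wrist_l", "elbow_l", ((_L["forearm_l"], _DOWN),)),
        c("hip_r", "hip_r_flex"),
        c("knee_r", "knee_r"),
        c("ankle_r", "knee_r", ((_L["shank_r"], _DOWN),)),
        c("hip_l", "hip_l_flex"),
        c("knee_l", "knee_l"),
        c("ankle_l", "knee_l", ((_L["shank_l"], _DOWN),)),
    ]


JOINT_NAMES = tuple(d["name"] for d in _default_joint_table())

# Default adult anthropometry (m), scaled for a 1.77 m stature using
# standard segment-length proportions.
DEFAULT_ANTHROPOMETRY = np.array(
    [0.12, 0.42, 0.42, 0.43, 0.43, 0.22, 0.21, 0.19, 0.31, 0.31, 0.25, 0.25]
)


def _assemble(joint_defs: list[dict], jcp_defs: list[dict],
              lengths: np.ndarray) -> SkeletonModel:
    """Convert world-frame definitions into parent-frame JointSpecs.

    ``zero_rot[i]`` tracks the world orientation of frame i at the reference
    posture so that offsets and axes written in world coordinates can be
    re-expressed in the parent frame.
    """
    joints: list[JointSpec] = []
    zero_rot: list[np.ndarray] = []
    name_to_idx: dict[str, int] = {}
    for i, d in enumerate(joint_defs):
        parent = d["parent"]
        if isinstance(parent, str):
            parent = name_to_idx[parent] if parent else -1
        if parent >= i:
            raise ValueError(
                f"joint {d['name']!r}: parent must precede child")
        z_par = np.eye(3) if parent < 0 else zero_rot[parent]
        m = _AXIS_ROT[d["axis"]]
        lim = d["limits"]
        lo, hi = _LIMITS_DEG[lim] if isinstance(lim, str) else lim
        if not lo < hi:
            raise ValueError(f"joint {d['name']!r}: limit_lo must be < limit_hi")
        terms = tuple((k, z_par.T @ np.asarray(v, dtype=float))
                      for k, v in d["terms"])
        joints.append(JointSpec(
            name=d["name"], parent=parent, axis=d["axis"],
            r_pre=z_par.T @ m,
            t_const=z_par.T @ np.asarray(d.get("const", np.zeros(3)), float),
            t_lengths=terms,
            limit_lo=np.deg2rad(lo), limit_hi=np.deg2rad(hi),
            group=d["group"], tuning_key=d["key"]))
        zero_rot.append(m)
        name_to_idx[d["name"]] = i

    jcps: list[JcpSpec] = []
    for d in jcp_defs:
        jidx = d["joint"]
        if isinstance(jidx, str):
            jidx = name_to_idx[jidx]
        z = zero_rot[jidx]
        jcps.append(JcpSpec(
            name=d["name"], joint=jidx,
            off_const=z.T @ np.asarray(d.get("const", np.zeros(3)), float),
            off_lengths=tuple((k, z.T @ np.asarray(v, float))
                              for k, v in d["terms"])))
    return SkeletonModel(joints=joints, jcp_map=jcps,
                         default_lengths=np.asarray(lengths, dtype=float))


def build_default_skeleton(
        anthropometry: np.ndarray | None = None) -> SkeletonModel:
    """Build the canonical 22-joint / 12-segment / 15-center model.

    Parameters
    ----------
    anthropometry
        The 12 segment lengths in meters, ordered as ``LENGTH_NAMES``.
        Defaults to a generic 1.77 m adult.
    """
    if anthropometry is None:
        anthropometry = DEFAULT_ANTHROPOMETRY
    anthropometry = np.asarray(anthropometry, dtype=float)
    if anthropometry.shape != (N_LEN,):
        raise ValueError(f"expected {N_LEN} segment lengths")
    bad = np.flatnonzero(anthropometry <= 0)
    if bad.size:
        names = ", ".join(LENGTH_NAMES[i] for i in bad)
        raise ValueError(f"non-positive segment length(s): {names}")
    return _assemble(_default_joint_table(), _default_jcp_table(),
                     anthropometry)


# --------------------------------------------------------------------------
# Forward kinematics and Jacobians
# --------------------------------------------------------------------------

def _frames(model: SkeletonModel, theta: np.ndarray, lengths: np.ndarray):
    """World rotation and origin of every joint frame (root at origin)."""
    n = model.n_joints
    rot = np.empty((n, 3, 3))
    pos = np.empty((n, 3))
    offs = model._t_const + model._t_len @ lengths
    c, s = np.cos(theta), np.sin(theta)
    parents = model._parents
    r_pre = model._r_pre
    for i in range(n):
        par = parents[i]
        # r_pre @ Rz(theta): mixes the first two columns of r_pre
        a = r_pre[i]
        rz = np.empty((3, 3))
        rz[:, 0] = c[i] * a[:, 0] + s[i] * a[:, 1]
        rz[:, 1] = -s[i] * a[:, 0] + c[i] * a[:, 1]
        rz[:, 2] = a[:, 2]
        if par < 0:
            pos[i] = offs[i]
            rot[i] = rz
        else:
            pos[i] = pos[par] + rot[par] @ offs[i]
            rot[i] = rot[par] @ rz
    return rot, pos


def _centers(model: SkeletonModel, rot, pos, lengths) -> np.ndarray:
    jj = model._jcp_joint
    off = model._jcp_const + model._jcp_len @ lengths
    return pos[jj] + np.einsum("mab,mb->ma", rot[jj], off)


def forward_kinematics(model: SkeletonModel, theta: np.ndarray,
                       lengths: np.ndarray,
                       root: np.ndarray | None = None) -> np.ndarray:
    """Positions of the 15 tracked joint centers, shape (15, 3), meters.

    Stacking ``.ravel()`` gives the 45-vector measurement model ``h``.
    """
    theta = np.asarray(theta, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    if not np.all(np.isfinite(theta)):
        raise ValueError("joint angles must be finite")
    rot, pos = _frames(model, theta, lengths)
    out = _centers(model, rot, pos, lengths)
    if root is not None:
        out = out + np.asarray(root, dtype=float)
    return out


def fk_with_jacobian(model: SkeletonModel, theta: np.ndarray,
                     lengths: np.ndarray, root: np.ndarray | None = None):
    """Joint centers plus analytic Jacobians.

    Returns ``(p, J_theta, J_len)`` with ``p`` of shape (15, 3), ``J_theta``
    of shape (45, 22) and ``J_len`` of shape (45, 12), rows ordered as the
    raveled center positions.  Angle columns use the geometric Jacobian of a
    revolute joint (axis cross lever arm); length columns are exact because
    positions are affine in the lengths at fixed posture.
    """
    theta = np.asarray(theta, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    rot, pos = _frames(model, theta, lengths)
    p = _centers(model, rot, pos, lengths)

    # angle columns: axis x lever, masked to ancestors of each center
    axes = rot[:, :, 2]  # (22, 3) world Z axis of each joint frame
    lever = p[:, None, :] - pos[None, :, :]  # (15, 22, 3)
    jt = np.cross(np.broadcast_to(axes, lever.shape), lever)
    jt *= model._jcp_anc[:, :, None]
    j_theta = jt.transpose(0, 2, 1).reshape(3 * N_JCP, N_THETA)

    # length columns: positions are affine in lengths; each joint's offset
    # contributes its parent-rotated direction to every descendant center
    par = model._parents
    rot_par = np.where((par >= 0)[:, None, None], rot[par], np.eye(3))
    dworld = np.einsum("jab,jbk->jak", rot_par, model._t_len)  # (22,3,12)
    j_len = np.einsum("mj,jak->mak", model._jcp_anc, dworld)
    j_len += np.einsum("mab,mbk->mak", rot[model._jcp_joint],
                       model._jcp_len)
    j_len = j_len.reshape(3 * N_JCP, N_LEN)

    if root is not None:
        p = p + np.asarray(root, dtype=float)
    return p, j_theta, j_len


def measurement_jacobian(model: SkeletonModel, theta: np.ndarray,
                         lengths: np.ndarray) -> np.ndarray:
    """Jacobian H of the raveled measurement model w.r.t. the filter state.

    Velocity and acceleration columns are identically zero; root-position
    columns are stacked 3x3 identities.
    """
    _, j_theta, j_len = fk_with_jacobian(model, theta, lengths)
    h = np.zeros((3 * N_JCP, N_STATE))
    h[:, S_THETA] = j_theta
    h[:, S_LEN] = j_len
    h[:, S_ROOT] = np.tile(np.eye(3), (N_JCP, 1))
    return h


# --------------------------------------------------------------------------
# Segment table for length estimation and rigidity checks
# --------------------------------------------------------------------------

# length name -> list of (jcp A, jcp B) whose distance equals that length at
# every posture (averaged when a length is shared between sides).
SEGMENT_PAIRS: dict[str, list[tuple[str, str]]] = {
    "pelvis": [("spine_base", "hip_r"), ("spine_base", "hip_l")],
    "thigh_r": [("hip_r", "knee_r")],
    "thigh_l": [("hip_l", "knee_l")],
    "shank_r": [("knee_r", "ankle_r")],
    "shank_l": [("knee_l", "ankle_l")],
    "trunk_lower": [("spine_base", "spine_mid")],
    "trunk_upper": [("spine_mid", "spine_shoulder")],
    "clavicle": [("spine_shoulder", "shoulder_r"),
                 ("spine_shoulder", "shoulder_l")],
    "upper_arm_r": [("shoulder_r", "elbow_r")],
    "upper_arm_l": [("shoulder_l", "elbow_l")],
    "forearm_r": [("elbow_r", "wrist_r")],
    "forearm_l": [("elbow_l", "wrist_l")],
}

JCP_INDEX = {name: i for i, name in enumerate(JCP_NAMES)}


# --------------------------------------------------------------------------
# Serialization (key-value skeleton definition file)
# --------------------------------------------------------------------------

def _terms_to_yaml(terms) -> list[dict]:
    return [{"length": LENGTH_NAMES[k], "dir": [float(x) for x in d]}
            for k, d in terms]


def _terms_from_yaml(entries) -> tuple:
    return tuple((LENGTH_NAMES.index(e["length"]),
                  np.asarray(e["dir"], dtype=float)) for e in entries or ())


def save_skeleton(model: SkeletonModel, path) -> None:
    """Write the skeleton definition as YAML (limits in degrees).

    Offsets are stored in world coordinates of the reference posture, which
    is the convention of the in-code default table.
    """
    # Recover world-frame quantities from the stored parent-frame ones.
    zero_rot = []
    joints = []
    for js in model.joints:
        z_par = np.eye(3) if js.parent < 0 else zero_rot[js.parent]
        zero_rot.append(_AXIS_ROT[js.axis])
        joints.append({
            "name": js.name,
            "parent": model.joints[js.parent].name if js.parent >= 0 else "",
            "axis": js.axis,
            "offset": _terms_to_yaml(
                (k, z_par @ d) for k, d in js.t_lengths),
            "limits_deg": [float(np.rad2deg(js.limit_lo)),
                           float(np.rad2deg(js.limit_hi))],
            "group": js.group,
            "tuning_key": js.tuning_key,
        })
    jcps = []
    for spec in model.jcp_map:
        z = zero_rot[spec.joint]
        jcps.append({
            "name": spec.name,
            "joint": model.joints[spec.joint].name,
            "offset": _terms_to_yaml((k, z @ d) for k, d in spec.off_lengths),
        })
    doc = {
        "lengths": {n: float(v) for n, v in
                    zip(model.length_names, model.default_lengths)},
        "joints": joints,
        "jcp_map": jcps,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_skeleton(path) -> SkeletonModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lengths = np.array([doc["lengths"][n] for n in LENGTH_NAMES])
    joint_defs = []
    for e in doc["joints"]:
        joint_defs.append(dict(
            name=e["name"], parent=e["parent"] or -1, axis=e["axis"],
            limits=tuple(e["limits_deg"]), group=e["group"],
            key=e["tuning_key"], terms=_terms_from_yaml(e.get("offset"))))
    jcp_defs = [dict(name=e["name"], joint=e["joint"],
                     terms=_terms_from_yaml(e.get("offset")))
                for e in doc["jcp_map"]]
    return _assemble(joint_defs, jcp_defs, lengths)
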