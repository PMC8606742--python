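"""Rigid-body and joint-coordinate-system (JCS) kinematics.

Bones tracked with implanted markers are represented as rigid transforms
(rotation + translation, mm).  Anatomical frames attached to the bones define
the joint coordinate system; the pose of a joint at one instant is the distal
frame expressed in the proximal frame, decomposed into three Euler rotations
(degrees) and three translations (mm).

Conventions
-----------
* Units: millimetres and degrees, right-handed world frame.
* Euler order default: intrinsic rotations applied X then Y then Z
  (``"XYZ"``), i.e. abduction-adduction, then long-axis rotation, then
  flexion-extension.  The order is configurable and is recorded in every
  :class:`JointPose` so a mismatch cannot pass silently.
* Translations are the distal-frame origin expressed in proximal-frame
  coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

logger = logging.getLogger("geomma")

#: tolerance for rotation-matrix orthonormality checks
ORTHO_TOL = 1e-9
#: middle Euler angle closer than this (deg) to +/-90 is treated as gimbal lock
GIMBAL_TOL_DEG = 1e-6

DEFAULT_EULER_ORDER = "XYZ"

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


def _check_rotation(r: np.ndarray, tol: float = ORTHO_TOL) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {r.shape}")
    err = np.abs(r.T @ r - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"rotation matrix not orthonormal (max deviation {err:.3g})")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation matrix has determinant -1 (reflection)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x_world = rotation @ x_local + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local points (..., 3) into the world frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composite transform applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed anatomical axis frame attached to a bone.

    ``x_axis``/``y_axis``/``z_axis`` are the joint axes (abduction-adduction,
    long-axis rotation, flexion-extension) expressed in world coordinates;
    ``origin`` is the joint centre (mm).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    bone_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        axes = []
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
            axes.append(v)
        _check_rotation(np.column_stack(axes), tol=1e-8)
        if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
            raise ValueError("axes are left-handed: require x cross y = z")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are the frame axes (local -> world)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @staticmethod
    def from_transform(t: RigidTransform, bone_id: str = "") -> "AnatomicalFrame":
        r = t.rotation
        return AnatomicalFrame(t.translation, r[:, 0], r[:, 1], r[:, 2], bone_id)

    def to_transform(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.origin)

    def transformed(self, t: RigidTransform) -> "AnatomicalFrame":
        """This frame after a rigid motion ``t`` of the bone it is glued to."""
        r = t.rotation @ self.rotation
        return AnatomicalFrame(t.apply(self.origin), r[:, 0], r[:, 1], r[:, 2],
                               self.bone_id)


def _wrap_deg(a: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class JointPose:
    """Distal frame relative to proximal frame: rotations (deg), translations (mm)."""

    rx: float
    ry: float
    rz: float
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    euler_order: str = DEFAULT_EULER_ORDER
    gimbal_lock: bool = False

    def __post_init__(self) -> None:
        for name in ("rx", "ry", "rz"):
            object.__setattr__(self, name, _wrap_deg(float(getattr(self, name))))
        for name in ("tx", "ty", "tz"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if sorted(self.euler_order) != ["X", "Y", "Z"]:
            raise ValueError(f"unsupported euler order {self.euler_order!r}")

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    def to_transform(self) -> RigidTransform:
        """Relative transform (distal expressed in proximal) for this pose."""
        angles = [getattr(self, "r" + ax.lower()) for ax in self.euler_order]
        rot = Rotation.from_euler(self.euler_order, angles, degrees=True)
        return RigidTransform(rot.as_matrix(), self.translations)


def euler_from_matrix(r: np.ndarray, euler_order: str = DEFAULT_EULER_ORDER
                      ) -> tuple[np.ndarray, bool]:
    """Decompose a rotation matrix into intrinsic Euler angles (degrees).

    Returns angles ordered (rx, ry, rz) regardless of application order, plus
    a gimbal-lock flag.  In gimbal lock (middle angle within ``GIMBAL_TOL_DEG``
    of +/-90 deg) only the sum/difference of the outer angles is observable;
    the tie is broken deterministically by setting the third applied angle to
    zero and solving the first from the matrix.
    """
    r = _check_rotation(r, tol=1e-8)
    i0, i1, i2 = (_AXIS_INDEX[c] for c in euler_order)
    # sine of the middle angle sits at a fixed matrix slot for intrinsic orders
    sign = 1.0 if (i1 - i0) % 3 == 1 else -1.0
    s_mid = np.clip(sign * r[i0, i2], -1.0, 1.0)
    mid_deg = np.degrees(np.arcsin(s_mid))
    locked = abs(abs(mid_deg) - 90.0) < GIMBAL_TOL_DEG
    if not locked:
        angles_applied = Rotation.from_matrix(r).as_euler(euler_order, degrees=True)
    else:
        # third applied angle := 0; the first is then exactly the residual
        # rotation left after removing the +/-90 deg middle rotation.
        mid = 90.0 * np.sign(s_mid)
        r_mid = Rotation.from_euler(euler_order[1], mid, degrees=True).as_matrix()
        rv = Rotation.from_matrix(r @ r_mid.T).as_rotvec(degrees=True)
        angles_applied = np.array([rv[i0], mid, 0.0])
    out = np.empty(3)
    for k, axis_index in enumerate((i0, i1, i2)):
        out[axis_index] = angles_applied[k]
    return out, locked


def relative_pose(proximal: AnatomicalFrame, distal: AnatomicalFrame,
                  euler_order: str = DEFAULT_EULER_ORDER) -> JointPose:
    """Pose of ``distal`` expressed in ``proximal`` (rotations deg, translations mm)."""
    rp = proximal.rotation
    r_rel = rp.T @ distal.rotation
    t_rel = rp.T @ (distal.origin - proximal.origin)
    angles, locked = euler_from_matrix(r_rel, euler_order)
    if locked:
        logger.warning("gimbal lock in relative_pose (%s/%s): third angle set to 0",
                       proximal.bone_id, distal.bone_id)
    return JointPose(angles[0], angles[1], angles[2],
                     t_rel[0], t_rel[1], t_rel[2],
                     euler_order=euler_order, gimbal_lock=locked)


@dataclass
class TrialKinematics:
    """One experimental (or simulated) trial.

    ``bone_transforms`` maps bone id to a list of per-frame transforms;
    ``markers`` maps marker id to an (n_frames, 3) trajectory in mm.
    """

    frame_rate: float = 60.0
    bone_transforms: dict[str, list[RigidTransform]] = field(default_factory=dict)
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        lengths = {len(v) for v in self.bone_transforms.values()}
        lengths |= {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        for v in self.bone_transforms.values():
            return len(v)
        for v in self.markers.values():
            return v.shape[0]
        return 0


def lowpass_filter(series: np.ndarray, cutoff: float, frame_rate: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The study filtered marker kinematics at 3-8 Hz depending on trial speed;
    `cutoff` is that corner frequency in Hz.  Unit DC gain, no phase shift,
    reflective padding at the ends; series length is preserved.
    """
    x = np.asarray(series, dtype=float)
    nyquist = frame_rate / 2.0
    if not 0.0 < cutoff < nyquist:
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz, got {cutoff}")
    b, a = butter(order, cutoff / nyquist)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError(f"series too short to filter: need > {padlen} samples")
    return filtfilt(b, a, x, axis=0, padtype="even")


def filter_pose_series(poses: pd.DataFrame, cutoff: float,
                       frame_rate: float) -> pd.DataFrame:
    """Low-pass every numeric channel of a pose table (columns per DOF)."""
    out = poses.copy()
    cols = out.select_dtypes("number").columns
    out[cols] = lowpass_filter(out[cols].to_numpy(), cutoff, frame_rate)
    return out


# ---------------------------------------------------------------------------
# Transform CSV dialects
# ---------------------------------------------------------------------------
# "matrix" dialect: 16 row-major homogeneous-matrix columns per bone, suffixes
#   _00.._33; "euler" dialect: 6 columns per bone, suffixes _tx.._rz
#   (translations mm, intrinsic XYZ rotations in degrees).

_MATRIX_SUFFIXES = [f"{i}{j}" for i in range(4) for j in range(4)]
_EULER_SUFFIXES = ["tx", "ty", "tz", "rx", "ry", "rz"]


def write_transform_csv(path, bone_transforms: dict[str, list[RigidTransform]],
                        dialect: str = "matrix") -> None:
    if dialect not in ("matrix", "euler"):
        raise ValueError(f"unknown dialect {dialect!r}")
    data: dict[str, np.ndarray] = {}
    for bone, series in bone_transforms.items():
        if dialect == "matrix":
            mats = np.array([t.as_matrix().ravel() for t in series])
            for k, suf in enumerate(_MATRIX_SUFFIXES):
                data[f"{bone}_{suf}"] = mats[:, k]
        else:
            rows = []
            for t in series:
                ang, _ = euler_from_matrix(t.rotation)
                rows.append(np.concatenate([t.translation, ang]))
            arr = np.array(rows)
            for k, suf in enumerate(_EULER_SUFFIXES):
                data[f"{bone}_{suf}"] = arr[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def read_transform_csv(path) -> dict[str, list[RigidTransform]]:
    """Read per-bone, per-frame transforms; dialect auto-detected from headers."""
    df = pd.read_csv(path)
    bones: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if "_" not in col:
            continue
        bone, suf = col.rsplit("_", 1)
        bones.setdefault(bone, {})[suf] = col
    out: dict[str, list[RigidTransform]] = {}
    for bone, cols in bones.items():
        if set(_MATRIX_SUFFIXES) <= set(cols):
            dialect = "matrix"
            arr = df[[cols[s] for s in _MATRIX_SUFFIXES]].to_numpy()
            series = [RigidTransform.from_matrix(row.reshape(4, 4)) for row in arr]
        elif set(_EULER_SUFFIXES) <= set(cols):
            dialect = "euler"
            arr = df[[cols[s] for s in _EULER_SUFFIXES]].to_numpy()
            series = [
                RigidTransform(
                    Rotation.from_euler("XYZ", row[3:], degrees=True).as_matrix(),
                    row[:3])
                for row in arr
            ]
        else:
            continue
        logger.info("read_transform_csv: bone %r, dialect %r, %d frames",
                    bone, dialect, len(series))
        out[bone] = series
    if not out:
        raise ValueError(f"no recognisable transform columns in {path}")
    return out
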