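"""Geometric muscle moment arms (MMAs) about anatomical joint axes.

A muscle is idealised as a straight line of action between a proximal and a
distal marker.  For each joint axis the vector moment arm is the common
perpendicular between two skew lines: the axis line through the joint centre
and the muscle line.  The scalar (torque-per-unit-force) moment arm about an
axis is then the length of that perpendicular scaled by the fraction of the
muscle direction lying in the plane perpendicular to the axis, signed by the
right-hand rule:

    r_theta = sign((r x F_hat) . a_hat) * ||r|| * ||F_hat - (F_hat . a_hat) a_hat||

which equals the torque about the axis produced by a unit force along the
muscle.  A positive moment arm about the X axis of a joint produces a
positive (e.g. abduction) moment.

Sign contract: the muscle force direction runs from the proximal to the
distal marker; swapping the markers flips the sign of every moment arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rigid_kinematics import AnatomicalFrame, RigidTransform, TrialKinematics

logger = logging.getLogger("geomma")

#: minimum muscle length (mm) accepted as a valid line of action
MIN_MUSCLE_LENGTH = 1e-6
#: |sin(angle)| below this marks an axis/muscle pair as parallel (degenerate)
PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class AxisLine:
    """Infinite line: a point on the axis (mm) and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point",
                           np.asarray(self.point, dtype=float).reshape(3))
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis direction must be unit length, |d| = {n}")
        object.__setattr__(self, "direction", d)

    @staticmethod
    def through(point, direction) -> "AxisLine":
        """Build an axis through ``point``, normalising ``direction``."""
        d = np.asarray(direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        return AxisLine(point, d / n)


@dataclass(frozen=True)
class MuscleLine:
    """Straight muscle line of action between two belly markers (mm)."""

    p_prox: np.ndarray
    p_dist: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_prox",
                           np.asarray(self.p_prox, dtype=float).reshape(3))
        object.__setattr__(self, "p_dist",
                           np.asarray(self.p_dist, dtype=float).reshape(3))
        if self.length < MIN_MUSCLE_LENGTH:
            raise ValueError(
                f"muscle markers are coincident (length {self.length:.3g} mm)")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_dist - self.p_prox))

    @property
    def direction(self) -> np.ndarray:
        """Unit force direction F_hat, proximal marker -> distal marker."""
        v = self.p_dist - self.p_prox
        return v / np.linalg.norm(v)

    def as_line(self) -> AxisLine:
        return AxisLine(self.p_prox, self.direction)

    def flipped(self) -> "MuscleLine":
        """Same line with the force direction reversed.

        ``scalar_moment_arm`` reports torque per unit force directed from
        ``p_prox`` to ``p_dist``; the leverage of the muscle's pull on the
        bone carrying ``p_dist`` (what tendon travel measures) is the moment
        arm of the flipped line.
        """
        return MuscleLine(self.p_dist, self.p_prox)


@dataclass(frozen=True)
class VectorMomentArm:
    """Common-perpendicular segment between a joint axis and a muscle line."""

    r_vec: np.ndarray
    foot_axis: np.ndarray
    foot_muscle: np.ndarray
    degenerate: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.r_vec))


@dataclass(frozen=True)
class ScalarMomentArms:
    """Signed scalar moment arms (mm) about the three joint axes."""

    r_x: float
    r_y: float
    r_z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_x, self.r_y, self.r_z])


def common_perpendicular(a: AxisLine, b: AxisLine) -> VectorMomentArm:
    """Shortest segment joining two lines, directed from ``a`` to ``b``.

    For skew lines this is the unique common perpendicular; intersecting
    lines yield the zero segment at the intersection; parallel lines are
    flagged degenerate and one representative perpendicular is returned.
    """
    u, v = a.direction, b.direction
    w = b.point - a.point
    n = np.cross(u, v)
    n2 = float(n @ n)  # = sin^2(angle between lines)
    if n2 < PARALLEL_TOL:
        # parallel: drop the perpendicular from a.point onto b
        foot_a = a.point
        foot_b = b.point - (w @ v) * v
        return VectorMomentArm(foot_b - foot_a, foot_a, foot_b, degenerate=True)
    # closest points: a.point + s*u and b.point + t*v
    s = float(np.cross(w, v) @ n) / n2
    t = float(np.cross(w, u) @ n) / n2
    foot_a = a.point + s * u
    foot_b = b.point + t * v
    return VectorMomentArm(foot_b - foot_a, foot_a, foot_b)


def scalar_moment_arm(axis: AxisLine, muscle: MuscleLine) -> float:
    """Signed scalar moment arm (mm) of ``muscle`` about ``axis``.

    Equals the torque about the axis per unit force along the muscle; it is
    independent of which segment of the muscle line is marked and of the
    marker spacing.  A muscle line parallel to the axis (no capacity to
    generate a moment about it) returns exactly 0.
    """
    f_hat = muscle.direction
    a_hat = axis.direction
    perp = common_perpendicular(axis, muscle.as_line())
    if perp.degenerate:
        return 0.0  # parallel lines: in-plane fraction of F is zero
    in_plane = f_hat - (f_hat @ a_hat) * a_hat
    scale = float(np.linalg.norm(in_plane))
    sign = np.sign(float(np.cross(perp.r_vec, f_hat) @ a_hat))
    return sign * perp.length * scale


def mma_triple(frame: AnatomicalFrame, muscle: MuscleLine) -> ScalarMomentArms:
    """Scalar moment arms about the three axis lines through the joint centre."""
    values = [
        scalar_moment_arm(AxisLine(frame.origin, axis), muscle)
        for axis in (frame.x_axis, frame.y_axis, frame.z_axis)
    ]
    return ScalarMomentArms(*values)


@dataclass(frozen=True)
class JointDefinition:
    """A joint coordinate system glued to the bones of a trial.

    ``centre_local`` and ``axes_local`` (columns x,y,z) are expressed in the
    coordinates of the bone named by ``axes_from`` ("proximal" by default:
    the anatomical axes are fixed on the proximal bone and animated with it).
    """

    name: str
    proximal_bone: str
    distal_bone: str
    centre_local: np.ndarray = None
    axes_local: np.ndarray = None
    axes_from: str = "proximal"

    def __post_init__(self) -> None:
        centre = (np.zeros(3) if self.centre_local is None
                  else np.asarray(self.centre_local, dtype=float).reshape(3))
        axes = (np.eye(3) if self.axes_local is None
                else np.asarray(self.axes_local, dtype=float).reshape(3, 3))
        object.__setattr__(self, "centre_local", centre)
        object.__setattr__(self, "axes_local", axes)
        if self.axes_from not in ("proximal", "distal"):
            raise ValueError("axes_from must be 'proximal' or 'distal'")

    def frame_at(self, bone_transform: RigidTransform) -> AnatomicalFrame:
        """World-space joint frame given the carrying bone's transform."""
        r = bone_transform.rotation @ self.axes_local
        origin = bone_transform.apply(self.centre_local)
        return AnatomicalFrame(origin, r[:, 0], r[:, 1], r[:, 2], self.name)


def mma_time_series(trial: TrialKinematics, joint: JointDefinition,
                    muscle_markers: tuple[str, str]) -> pd.DataFrame:
    """Per-frame scalar moment arms of one muscle about one joint.

    ``muscle_markers`` is the (proximal, distal) pair of marker ids in the
    trial.  Frames with missing (NaN) marker data are reported by index.
    """
    prox_id, dist_id = muscle_markers
    for mid in (prox_id, dist_id):
        if mid not in trial.markers:
            raise KeyError(f"marker {mid!r} not present in trial")
    carrier = (joint.proximal_bone if joint.axes_from == "proximal"
               else joint.distal_bone)
    if carrier not in trial.bone_transforms:
        raise KeyError(f"bone {carrier!r} not present in trial")
    prox = trial.markers[prox_id]
    dist = trial.markers[dist_id]
    bad = np.where(~(np.isfinite(prox).all(axis=1) & np.isfinite(dist).all(axis=1)))[0]
    if bad.size:
        raise ValueError(f"missing muscle-marker data at frames {bad.tolist()}")
    rows = np.empty((trial.n_frames, 3))
    for i, bone_t in enumerate(trial.bone_transforms[carrier]):
        frame = joint.frame_at(bone_t)
        rows[i] = mma_triple(frame, MuscleLine(prox[i], dist[i])).as_array()
    return pd.DataFrame(rows, columns=["r_x", "r_y", "r_z"],
                        index=pd.RangeIndex(trial.n_frames, name="frame"))


def rmse(a, b) -> float:
    """Root mean square error between two equal-length series (mm)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def normalise_mma(series, model_series) -> tuple[np.ndarray, np.ndarray]:
    """Scale two paired MMA series by their joint maximum absolute value.

    Both series map into [-1, 1], preserving sign; the larger of the two
    peaks maps to +/-1.  Used for side-by-side sign/magnitude plots of
    experimental vs model estimates.
    """
    a = np.asarray(series, dtype=float)
    b = np.asarray(model_series, dtype=float)
    peak = max(np.abs(a).max(), np.abs(b).max())
    if peak == 0:
        raise ValueError("cannot normalise all-zero series")
    return a / peak, b / peak
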