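"""Tendon-travel moment arm estimation (the cross-validation arm).

Musculoskeletal modelling packages compute moment arms by a partial-velocity
method equivalent to tendon travel: the moment arm of a muscle about a joint
coordinate is the negative derivative of musculotendon length with respect to
that coordinate,

    r_theta = -dL/dtheta   (theta in radians).

For a straight-line muscle and a pure rotation about a fixed axis this agrees
with the geometric common-perpendicular construction to O(h^2) in the finite
difference step, which is the basis of the method-equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid_kinematics import RigidTransform

#: default central-difference step (degrees); truncation error O(h^2) is far
#: below the 0.1 mm reporting precision of the moment-arm tables
DEFAULT_STEP_DEG = 0.01
MIN_STEP_DEG = 1e-6


@dataclass(frozen=True)
class PointMusclePath:
    """Point-to-point muscle: origin fixed in the proximal bone, insertion in
    the distal bone (both in local bone coordinates, mm)."""

    origin: np.ndarray
    insertion: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "insertion",
                           np.asarray(self.insertion, dtype=float).reshape(3))
        if np.array_equal(self.origin, self.insertion):
            raise ValueError("origin and insertion must be distinct points")


def muscle_length(proximal: RigidTransform, distal: RigidTransform,
                  path: PointMusclePath) -> float:
    """World-space musculotendon length (mm) for one rig state."""
    o = proximal.apply(path.origin)
    i = distal.apply(path.insertion)
    return float(np.linalg.norm(i - o))


def length_at(rig, path: PointMusclePath, pose: dict[str, float]) -> float:
    """Musculotendon length at a rig pose (dict of DOF values)."""
    prox, dist = rig.transforms_at(pose)
    return muscle_length(prox, dist, path)


def tendon_travel_mma(rig, path: PointMusclePath, dof: str, angle_deg: float,
                      step_deg: float = DEFAULT_STEP_DEG,
                      at: dict[str, float] | None = None) -> float:
    """Moment arm (mm) about one rotational DOF via tendon travel.

    Central difference of musculotendon length across ``angle_deg`` +/-
    ``step_deg``, with the remaining DOFs held at ``at`` (default: zero).
    """
    if dof not in ("rx", "ry", "rz"):
        raise ValueError(f"dof must be a rotational coordinate, got {dof!r}")
    if step_deg < MIN_STEP_DEG:
        raise ValueError(
            f"step {step_deg} deg too small for float precision "
            f"(minimum {MIN_STEP_DEG})")
    base = dict(at or {})
    hi = base | {dof: angle_deg + step_deg}
    lo = base | {dof: angle_deg - step_deg}
    h_rad = np.radians(step_deg)
    return -(length_at(rig, path, hi) - length_at(rig, path, lo)) / (2.0 * h_rad)
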