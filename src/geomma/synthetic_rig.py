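"""Synthetic two-bone joint rigs with known ground truth.

Emulates the marker-based cadaver trials the pipeline is designed to
process: a static proximal bone and a mobile distal bone articulated by a
revolute, ball-and-socket, or free (6-DOF) joint, straight-line muscles
between the bones, at least three non-collinear tracking markers per bone,
proximal and distal muscle-belly markers, 60 frames/s sampling, and optional
isotropic Gaussian marker noise (tracking error; the study's marker
diameters of 0.8-1 mm bound plausible noise magnitudes well below 1 mm).

Every simulated trial carries its exact bone transforms, programmed joint
pose per frame, and analytic per-frame moment arms, so that the full
pipeline (markers -> rigid fit -> joint pose -> MMA) can be validated
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .rigid_kinematics import (DEFAULT_EULER_ORDER, AnatomicalFrame,
                               RigidTransform, TrialKinematics, _check_rotation)
from .tendon_travel import PointMusclePath
from .rom_analysis import PoseCloud

DOF_NAMES = ("rx", "ry", "rz", "tx", "ty", "tz")
_JOINT_DOFS = {
    "revolute": {"rz"},
    "ball": {"rx", "ry", "rz"},
    "free": set(DOF_NAMES),
}

#: second singular value of centred marker offsets below this means the
#: markers are collinear and the rigid fit is ill-posed
COLLINEAR_TOL = 1e-8


@dataclass
class SyntheticRig:
    """Two-bone rig: proximal bone fixed at the world origin, distal bone
    articulated at ``joint_centre`` about joint axes given by the columns of
    ``axes`` (in proximal/world coordinates).

    Distal-bone local coordinates have their origin at the joint centre and
    axes aligned with the joint axes at the zero pose.  Marker offsets are
    in local bone coordinates; muscle paths run origin (proximal local) to
    insertion (distal local).
    """

    joint_type: str = "ball"
    joint_centre: np.ndarray = None
    axes: np.ndarray = None
    proximal_markers: np.ndarray = None
    distal_markers: np.ndarray = None
    muscles: dict[str, PointMusclePath] = field(default_factory=dict)
    euler_order: str = DEFAULT_EULER_ORDER

    def __post_init__(self) -> None:
        if self.joint_type not in _JOINT_DOFS:
            raise ValueError(f"unknown joint type {self.joint_type!r}")
        self.joint_centre = (np.zeros(3) if self.joint_centre is None
                             else np.asarray(self.joint_centre, float).reshape(3))
        self.axes = (np.eye(3) if self.axes is None
                     else _check_rotation(np.asarray(self.axes, float), tol=1e-8))
        if self.proximal_markers is None:
            self.proximal_markers = np.array(
                [[-30.0, 0, 0], [-60, 10, 0], [-45, 0, 15]])
        if self.distal_markers is None:
            self.distal_markers = np.array(
                [[30.0, 0, 0], [60, 10, 0], [45, 0, 15]])
        for name in ("proximal_markers", "distal_markers"):
            offsets = np.asarray(getattr(self, name), float)
            setattr(self, name, offsets)
            check_marker_geometry(offsets, label=name)

    @property
    def allowed_dofs(self) -> set[str]:
        return _JOINT_DOFS[self.joint_type]

    def transforms_at(self, pose: dict[str, float]
                      ) -> tuple[RigidTransform, RigidTransform]:
        """World transforms of (proximal, distal) bone at a joint pose.

        ``pose`` maps DOF names (rx/ry/rz in degrees, tx/ty/tz in mm) to
        values; omitted DOFs are zero.  DOFs outside the joint type are
        rejected.
        """
        bad = set(pose) - self.allowed_dofs
        if any(pose[d] != 0.0 for d in bad):
            raise ValueError(
                f"DOFs {sorted(d for d in bad if pose[d] != 0.0)} not available "
                f"on a {self.joint_type} joint")
        angles = [pose.get("r" + c.lower(), 0.0) for c in self.euler_order]
        r_local = Rotation.from_euler(self.euler_order, angles,
                                      degrees=True).as_matrix()
        t_local = np.array([pose.get(k, 0.0) for k in ("tx", "ty", "tz")])
        a = self.axes
        rotation = a @ r_local
        translation = self.joint_centre + a @ t_local
        return RigidTransform.identity(), RigidTransform(rotation, translation)

    def joint_frames_at(self, pose: dict[str, float]
                        ) -> tuple[AnatomicalFrame, AnatomicalFrame]:
        """World-space proximal and distal joint frames at a pose."""
        prox_t, dist_t = self.transforms_at(pose)
        a = self.axes
        prox = AnatomicalFrame(self.joint_centre, a[:, 0], a[:, 1], a[:, 2],
                               "proximal")
        rd = dist_t.rotation @ np.eye(3)
        dist = AnatomicalFrame(dist_t.translation, rd[:, 0], rd[:, 1], rd[:, 2],
                               "distal")
        return prox, dist

    def marker_world(self, pose: dict[str, float]) -> dict[str, np.ndarray]:
        """World positions of every bone and muscle marker at a pose."""
        prox_t, dist_t = self.transforms_at(pose)
        out: dict[str, np.ndarray] = {}
        for i, off in enumerate(self.proximal_markers):
            out[f"proximal_m{i}"] = prox_t.apply(off)
        for i, off in enumerate(self.distal_markers):
            out[f"distal_m{i}"] = dist_t.apply(off)
        for name, path in self.muscles.items():
            out[f"{name}_prox"] = prox_t.apply(path.origin)
            out[f"{name}_dist"] = dist_t.apply(path.insertion)
        return out

    def true_mma(self, pose: dict[str, float], muscle: str) -> np.ndarray:
        """Analytic scalar moment arms (r_x, r_y, r_z) from exact geometry.

        Uses the torque-per-unit-force triple product on the exact attachment
        positions, independent of the marker-processing pipeline.
        """
        prox_t, dist_t = self.transforms_at(pose)
        path = self.muscles[muscle]
        p = prox_t.apply(path.origin)
        q = dist_t.apply(path.insertion)
        f_hat = (q - p) / np.linalg.norm(q - p)
        lever = np.cross(p - self.joint_centre, f_hat)
        return lever @ self.axes  # components about each joint axis column


def check_marker_geometry(offsets: np.ndarray, label: str = "markers") -> None:
    """Reject marker sets that cannot constrain a rigid fit.

    Fewer than three markers, or (near-)collinear markers, leave rotation
    about the marker line unconstrained - the failure mode that forced the
    study to animate the radius with the ulna's transforms.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim != 2 or offsets.shape[1] != 3 or offsets.shape[0] < 3:
        raise ValueError(f"{label}: need at least 3 markers with 3 coordinates")
    centred = offsets - offsets.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < COLLINEAR_TOL * max(sv[0], 1.0):
        raise ValueError(
            f"{label}: markers are collinear; rotation about the marker line "
            "is unconstrained and the rigid-body fit is ill-posed")


@dataclass
class MotionProgram:
    """Scripted per-frame DOF trajectories (degrees / mm) at a frame rate."""

    trajectories: dict[str, np.ndarray]
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        self.trajectories = {k: np.asarray(v, dtype=float)
                             for k, v in self.trajectories.items()}
        lengths = {v.shape[0] for v in self.trajectories.values()}
        if len(lengths) != 1:
            raise ValueError(f"trajectory lengths differ: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.trajectories.values())).shape[0]

    def pose_at(self, i: int) -> dict[str, float]:
        return {k: float(v[i]) for k, v in self.trajectories.items()}

    @staticmethod
    def sweep(dof: str, start: float, stop: float, n_frames: int,
              frame_rate: float = 60.0) -> "MotionProgram":
        """Linear sweep of a single DOF."""
        return MotionProgram({dof: np.linspace(start, stop, n_frames)},
                             frame_rate=frame_rate)

    @staticmethod
    def manipulation_cycles(primary: str = "rz", amplitude: float = 40.0,
                            offsets_dof: str = "rx",
                            offsets: tuple[float, ...] = (-20.0, 0.0, 20.0),
                            frames_per_cycle: int = 120,
                            frame_rate: float = 60.0) -> "MotionProgram":
        """Cycles of one motion at several fixed positions of another DOF,
        mimicking e.g. flexion-extension cycles at variously abducted and
        rotated poses."""
        prim, off = [], []
        t = np.linspace(0.0, 2 * np.pi, frames_per_cycle, endpoint=False)
        for o in offsets:
            prim.append(amplitude * np.sin(t))
            off.append(np.full(frames_per_cycle, o))
        return MotionProgram({primary: np.concatenate(prim),
                              offsets_dof: np.concatenate(off)},
                             frame_rate=frame_rate)


@dataclass
class SimulatedTrial:
    """Output of :func:`simulate_trial`: observed data plus ground truth."""

    trial: TrialKinematics                 # noisy marker + true transform series
    true_poses: pd.DataFrame               # programmed DOF values per frame
    true_mma: dict[str, pd.DataFrame]      # analytic per-frame moment arms
    noise_sd: float = 0.0
    seed: int | None = None


def simulate_trial(rig: SyntheticRig, program: MotionProgram,
                   noise_sd: float = 0.0, seed: int | None = None
                   ) -> SimulatedTrial:
    """Run a motion program on a rig and record markers (+ noise) and truth.

    Marker noise is iid isotropic Gaussian per coordinate with standard
    deviation ``noise_sd`` mm, reproducible under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = program.n_frames
    marker_ids = list(rig.marker_world(program.pose_at(0)))
    markers = {mid: np.empty((n, 3)) for mid in marker_ids}
    prox_series, dist_series = [], []
    mma_rows = {name: np.empty((n, 3)) for name in rig.muscles}
    for i in range(n):
        pose = program.pose_at(i)
        prox_t, dist_t = rig.transforms_at(pose)
        prox_series.append(prox_t)
        dist_series.append(dist_t)
        for mid, xyz in rig.marker_world(pose).items():
            markers[mid][i] = xyz
        for name in rig.muscles:
            mma_rows[name][i] = rig.true_mma(pose, name)
    if noise_sd > 0:
        for mid in marker_ids:
            markers[mid] += rng.normal(0.0, noise_sd, size=(n, 3))
    trial = TrialKinematics(
        frame_rate=program.frame_rate,
        bone_transforms={"proximal": prox_series, "distal": dist_series},
        markers=markers)
    poses = pd.DataFrame({k: v for k, v in program.trajectories.items()},
                         index=pd.RangeIndex(n, name="frame"))
    true_mma = {name: pd.DataFrame(rows, columns=["r_x", "r_y", "r_z"],
                                   index=pd.RangeIndex(n, name="frame"))
                for name, rows in mma_rows.items()}
    return SimulatedTrial(trial=trial, true_poses=poses, true_mma=true_mma,
                          noise_sd=noise_sd, seed=seed)


def fit_rigid_body(offsets: np.ndarray, observed: np.ndarray
                   ) -> RigidTransform | list[RigidTransform]:
    """Least-squares rigid fit of marker offsets to observed positions.

    Orthogonal Procrustes (Kabsch) per frame with det +1 enforced, so a
    reflection is never returned.  ``observed`` may be one frame (M, 3) or a
    series (n_frames, M, 3).
    """
    offsets = np.asarray(offsets, dtype=float)
    check_marker_geometry(offsets)
    observed = np.asarray(observed, dtype=float)
    single = observed.ndim == 2
    obs = observed[None] if single else observed
    if obs.shape[1:] != offsets.shape:
        raise ValueError("observed marker shape does not match offsets")
    centred_off = offsets - offsets.mean(axis=0)
    out = []
    for frame in obs:
        centroid = frame.mean(axis=0)
        h = centred_off.T @ (frame - centroid)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        out.append(RigidTransform(r, centroid - r @ offsets.mean(axis=0)))
    return out[0] if single else out


def fit_trial(markers: dict[str, np.ndarray],
              marker_offsets: dict[str, tuple[list[str], np.ndarray]],
              frame_rate: float = 60.0) -> TrialKinematics:
    """Reconstruct bone transforms from observed markers (the rigid-fit step
    of the pipeline).

    ``marker_offsets`` maps bone id to (marker ids, (M, 3) local offsets).
    Muscle markers are carried through unchanged.
    """
    bone_transforms = {}
    for bone, (ids, offsets) in marker_offsets.items():
        observed = np.stack([np.asarray(markers[mid], float) for mid in ids],
                            axis=1)
        bone_transforms[bone] = fit_rigid_body(offsets, observed)
    return TrialKinematics(frame_rate=frame_rate,
                           bone_transforms=bone_transforms,
                           markers={k: np.asarray(v, float)
                                    for k, v in markers.items()})


def rig_marker_offsets(rig: SyntheticRig) -> dict[str, tuple[list[str], np.ndarray]]:
    """Bone-marker bookkeeping for :func:`fit_trial` on a simulated rig."""
    return {
        "proximal": ([f"proximal_m{i}" for i in range(len(rig.proximal_markers))],
                     rig.proximal_markers),
        "distal": ([f"distal_m{i}" for i in range(len(rig.distal_markers))],
                   rig.distal_markers),
    }


def make_known_envelope_cloud(shape: str, n: int, seed: int | None = None,
                              size: float = 50.0,
                              semiaxes: tuple[float, float, float] = (30.0, 20.0, 10.0)
                              ) -> tuple[PoseCloud, float]:
    """Uniform point cloud inside a solid of known volume (hull fixtures).

    Shapes: ``cube`` (side ``size``, volume size^3, corners included),
    ``l_solid`` (cube minus the quadrant x > size/2 and y > size/2, volume
    3/4 size^3, prism vertices included), ``ellipsoid`` (semi-axes
    ``semiaxes``, volume 4*pi*abc/3).
    """
    if n < 100:
        raise ValueError("need n >= 100 samples")
    rng = np.random.default_rng(seed)
    s = float(size)
    if shape == "cube":
        pts = rng.uniform(0.0, s, size=(n, 3))
        corners = np.array([[x, y, z] for x in (0, s) for y in (0, s)
                            for z in (0, s)], dtype=float)
        pts = np.vstack([corners, pts])
        true_volume = s ** 3
    elif shape == "l_solid":
        pts_list = []
        while sum(len(p) for p in pts_list) < n:
            cand = rng.uniform(0.0, s, size=(n, 3))
            keep = ~((cand[:, 0] > s / 2) & (cand[:, 1] > s / 2))
            pts_list.append(cand[keep])
        pts = np.vstack(pts_list)[:n]
        h = s / 2
        l_outline = [(0, 0), (s, 0), (s, h), (h, h), (h, s), (0, s)]
        verts = np.array([[x, y, z] for (x, y) in l_outline for z in (0, s)],
                         dtype=float)
        pts = np.vstack([verts, pts])
        true_volume = 0.75 * s ** 3
    elif shape == "ellipsoid":
        a, b, c = (float(v) for v in semiaxes)
        pts_list = []
        while sum(len(p) for p in pts_list) < n:
            cand = rng.uniform(-1.0, 1.0, size=(n, 3))
            keep = (cand ** 2).sum(axis=1) <= 1.0
            pts_list.append(cand[keep] * [a, b, c])
        pts = np.vstack(pts_list)[:n]
        true_volume = 4.0 / 3.0 * np.pi * a * b * c
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return PoseCloud(pts), float(true_volume)
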