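"""Shared fixtures: deterministic RNGs and synthetic joint rigs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from geomma.synthetic_rig import SyntheticRig
from geomma.tendon_travel import PointMusclePath


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def hinge_rig() -> SyntheticRig:
    """Revolute (flexion-extension) rig with one flexor-like muscle."""
    return SyntheticRig(
        joint_type="revolute",
        muscles={"flexor": PointMusclePath(origin=[-40.0, 12.0, 0.0],
                                           insertion=[35.0, 8.0, 0.0])})


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def random_transform(rng: np.random.Generator):
    from geomma.rigid_kinematics import RigidTransform
    return RigidTransform(random_rotation(rng), rng.normal(scale=30.0, size=3))


def random_revolute_rig(rng: np.random.Generator,
                        min_length: float = 5.0) -> SyntheticRig:
    """Random single-DOF rig whose muscle stays well clear of zero length
    over a full revolution (keeps finite-difference curvature bounded)."""
    while True:
        centre = rng.normal(scale=20.0, size=3)
        axes = random_rotation(rng)
        origin = rng.uniform(-60.0, 60.0, size=3)
        insertion = rng.uniform(-60.0, 60.0, size=3)
        rig = SyntheticRig(joint_type="revolute", joint_centre=centre,
                           axes=axes,
                           muscles={"m": PointMusclePath(origin, insertion)})
        lengths = []
        from geomma.tendon_travel import length_at
        for ang in np.linspace(-180.0, 180.0, 37):
            lengths.append(length_at(rig, rig.muscles["m"], {"rz": ang}))
        if min(lengths) > min_length:
            return rig
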