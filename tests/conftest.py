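import numpy as np
import pytest

from momentarms import (AttachmentPoint, BodySegment, FixtureSpec, HingeJoint,
                        KinematicChain, MusclePath, generate_fixture)


@pytest.fixture
def two_body_chain():
    """Base + link, hinge at the origin about +z."""
    return KinematicChain(
        bodies=[BodySegment("base"), BodySegment("link")],
        joints=[HingeJoint("hinge", "base", "link",
                           center_local=(0.0, 0.0, 0.0),
                           axis_local=(0.0, 0.0, 1.0),
                           angle_limits=(-170.0, 170.0))])


@pytest.fixture
def three_joint_chain():
    """Serial pelvis-femur-tibia-foot chain along -y, all axes +z."""
    return KinematicChain(
        bodies=[BodySegment("pelvis"),
                BodySegment("femur", reference_length=35.75),
                BodySegment("tibia"), BodySegment("foot")],
        joints=[
            HingeJoint("hip", "pelvis", "femur", (0, 0, 0), (0, 0, 1),
                       angle_limits=(-60.0, 60.0)),
            HingeJoint("knee", "femur", "tibia", (0, -35.75, 0), (0, 0, 1),
                       angle_limits=(-90.0, 40.0)),
            HingeJoint("ankle", "tibia", "foot", (0, -75.75, 0), (0, 0, 1),
                       angle_limits=(-60.0, 60.0)),
        ])


@pytest.fixture(scope="session")
def rat_fixture():
    return generate_fixture(FixtureSpec("rat_like", seed=1))


@pytest.fixture(scope="session")
def pulley_fixture():
    return generate_fixture(FixtureSpec("pulley"))


@pytest.fixture(scope="session")
def planar_fixture():
    return generate_fixture(FixtureSpec("planar_two_body"))


def make_muscle(name, *attachments):
    return MusclePath(name, [AttachmentPoint(body, xyz, label=f"p{i}")
                             for i, (body, xyz) in enumerate(attachments)])


@pytest.fixture
def hip_muscle():
    """Monoarticular pelvis->femur muscle for the three-joint chain."""
    return make_muscle("hip_mono", ("pelvis", (-10.0, 5.0, 0.0)),
                       ("femur", (10.0, 5.0, 0.0)))


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    transform = np.eye(4)
    transform[:3, :3] = Rotation.from_rotvec(rng.uniform(-2, 2, 3)).as_matrix()
    transform[:3, 3] = rng.uniform(-50, 50, 3)
    return transform
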