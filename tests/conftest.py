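"""Shared fixtures: the generic model, a baseline squat trial, distributions."""

import numpy as np
import pytest

import squatmc as sq


@pytest.fixture(scope="session")
def generic_model():
    return sq.default_model()


@pytest.fixture(scope="session")
def baseline_trial(generic_model):
    return sq.generate_squat_trial(generic_model)


@pytest.fixture(scope="session")
def cv_spec():
    return sq.build_distributions(sq.default_cv_table())


@pytest.fixture(scope="session")
def baseline_result(generic_model, baseline_trial):
    return sq.simulate_trial(baseline_trial, generic_model)


def make_hinge_model(origin_xy, insertion_xy, joint_in_parent=(0.0, 0.0), sigma=1.0):
    """Minimal two-segment, one-hinge model with a single straight muscle."""
    segments = [
        sq.BodySegment("pelvis", mass=10.0, com_local=[0.0, 0.1], inertia_zz=0.1,
                       length=0.3, distal_joint="hip_flexion"),
        sq.BodySegment("thigh", mass=5.0, com_local=[0.0, -0.1], inertia_zz=0.05,
                       length=0.3, proximal_joint="hip_flexion"),
    ]
    dofs = [sq.JointDof("hip_flexion", parent="pelvis", child="thigh",
                        location_in_parent=list(joint_in_parent), sigma=sigma)]
    muscle = sq.MuscleTendonUnit(
        name="m1", mif=1000.0, tsl=0.05, pen_opt=0.0, l_opt=0.1,
        pathway=[
            sq.PathPoint("pelvis", list(origin_xy), "origin"),
            sq.PathPoint("thigh", list(insertion_xy), "insertion"),
        ],
    )
    model = sq.LowerLimbModel(
        segments=segments, dofs=dofs, muscles=[muscle],
        groups=[sq.MuscleGroup("lower_limb", ("m1",))],
        subject_mass=15.0, subject_height=1.0,
    )
    model.validate()
    return model


@pytest.fixture
def hinge_model_factory():
    return make_hinge_model
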