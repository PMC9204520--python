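"""Model geometry, Hill mechanics and scaling."""

import math

import numpy as np
import pytest

import squatmc as sq
from squatmc import model_core
from squatmc.errors import ConfigurationError, ModelLookupError, ValidationError


# ---------------------------------------------------------------------------
# MTU length
# ---------------------------------------------------------------------------

class TestMtuLength:
    def test_straight_two_point_muscle_at_zero_pose(self, hinge_model_factory):
        m = hinge_model_factory((0.0, 0.15), (0.0, -0.15))
        # chain: origin 0.15 above the joint, insertion 0.15 below -> 0.30 m
        assert sq.mtu_length(m, "m1", {"hip_flexion": 0.0}) == pytest.approx(0.30)

    def test_collinear_via_point_adds_no_length(self, generic_model):
        m = generic_model.copy()
        mus = m.muscle("bflh")  # two-point muscle; add a collinear midpoint
        cm = m.compile()
        pose = {d: 0.0 for d in m.dof_names}
        L2 = sq.mtu_length(m, "bflh", pose)
        pos = cm.point_positions(np.zeros((1, cm.n_dof)))[0]
        i = cm.muscle_ptr[m.muscle_names.index("bflh")]
        mid_global = 0.5 * (pos[i] + pos[i + 1])
        # express the midpoint in the pelvis frame (pelvis at origin, tilt 0)
        mus.pathway.insert(1, sq.PathPoint("pelvis", mid_global, "via"))
        L3 = sq.mtu_length(m, "bflh", pose)
        assert L3 == pytest.approx(L2, abs=1e-12)

    def test_hinge_at_90_degrees_matches_hand_geometry(self, hinge_model_factory):
        # origin (0, +0.10) on the parent, insertion (0, -0.10) on the child,
        # joint at both frame origins: after 90 deg of flexion the two points
        # sit on perpendicular radii of a 0.10 m circle -> chord 0.10*sqrt(2)
        m = hinge_model_factory((0.0, 0.10), (0.0, -0.10))
        L = sq.mtu_length(m, "m1", {"hip_flexion": math.pi / 2})
        assert L == pytest.approx(0.10 * math.sqrt(2), rel=1e-9)

    def test_unknown_muscle_raises_lookup_error(self, generic_model):
        with pytest.raises(ModelLookupError):
            sq.mtu_length(generic_model, "nosuch", {d: 0.0 for d in generic_model.dof_names})

    def test_length_is_lipschitz_in_pose(self, generic_model):
        cm = generic_model.compile()
        bound = sum(s.length for s in generic_model.segments) + 1.0
        rng = np.random.default_rng(3)
        q = rng.uniform([-0.3, 0.0, -0.4], [1.2, 1.4, 0.5], size=(30, 3))
        delta = 1e-4
        for j in range(cm.n_dof):
            dq = np.zeros(3)
            dq[j] = delta
            dL = np.abs(cm.lengths(q + dq) - cm.lengths(q))
            assert np.all(dL <= bound * delta)


# ---------------------------------------------------------------------------
# Moment arms
# ---------------------------------------------------------------------------

def perpendicular_distance(p1, p2, joint):
    """Analytic point-to-line distance oracle."""
    d = p2 - p1
    r = p1 - joint
    return abs(r[0] * d[1] - r[1] * d[0]) / np.linalg.norm(d)


class TestMomentArm:
    def test_pathway_through_joint_centre_has_zero_arm(self, hinge_model_factory):
        m = hinge_model_factory((0.0, 0.15), (0.0, -0.15))
        r = sq.moment_arm(m, "m1", {"hip_flexion": 0.0}, "hip_flexion")
        assert abs(r) < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_perpendicular_distance_on_random_hinges(
        self, hinge_model_factory, seed
    ):
        rng = np.random.default_rng(seed)
        origin = rng.uniform([-0.2, 0.05], [0.2, 0.3])
        insertion = rng.uniform([-0.2, -0.3], [0.2, -0.05])
        m = hinge_model_factory(origin, insertion)
        q = rng.uniform(-1.0, 1.0)
        r = sq.moment_arm(m, "m1", {"hip_flexion": q}, "hip_flexion")
        cm = m.compile()
        pos = cm.point_positions(np.array([[q]]))[0]
        d = perpendicular_distance(pos[0], pos[1], np.zeros(2))
        assert abs(abs(r) - d) <= 1e-4 * max(d, 1e-6)

    def test_flexor_side_muscle_has_positive_arm(self, generic_model):
        # hamstrings flex the knee: positive arm in the flexion-positive convention
        pose = sq.squat_closure_pose(generic_model, math.radians(30))
        assert sq.moment_arm(generic_model, "bflh", pose, "knee_flexion") > 0
        assert sq.moment_arm(generic_model, "vaslat", pose, "knee_flexion") < 0

    def test_one_sided_difference_at_range_boundary_warns(self, hinge_model_factory):
        m = hinge_model_factory((0.1, 0.15), (0.1, -0.15))
        m.dofs[0].angle_range = (0.0, 1.0)
        with pytest.warns(UserWarning, match="one-sided"):
            sq.moment_arm(m, "m1", {"hip_flexion": 0.0}, "hip_flexion")

    def test_via_point_perturbation_moves_knee_arm_by_centimetre_order(
        self, generic_model
    ):
        # 5 mm per-axis draws on the patellar via point change the extensor
        # knee moment arm on the order of 1e-2 m across draws
        pose = sq.squat_closure_pose(generic_model, math.radians(90))
        rng = np.random.default_rng(12)
        arms = []
        for _ in range(200):
            m = generic_model.copy()
            via = m.muscle("vaslat").pathway[1]
            via.position_local = via.position_local + rng.normal(0, 0.005, 2)
            arms.append(sq.moment_arm(m, "vaslat", pose, "knee_flexion"))
        spread = np.ptp(arms)
        assert 1e-3 < spread < 5e-2


# ---------------------------------------------------------------------------
# Hill mechanics
# ---------------------------------------------------------------------------

class TestFiberStateAndForce:
    def test_optimal_length_zero_pennation(self, generic_model):
        mus = sq.MuscleTendonUnit("t", mif=100.0, tsl=0.2, pen_opt=0.0, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.2 + 0.1, mtu_velocity=0.0)
        assert (st.lnorm, st.vnorm, st.pennation) == pytest.approx((1.0, 0.0, 0.0))
        assert not st.clamped

    def test_constant_thickness_pennation_relation(self, generic_model):
        pen = 0.2
        mus = sq.MuscleTendonUnit("t", mif=100.0, tsl=0.2, pen_opt=pen, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.2 + 0.1 * math.cos(pen))
        assert st.lnorm == pytest.approx(1.0, rel=1e-12)
        assert st.pennation == pytest.approx(pen, rel=1e-9)

    def test_slack_mtu_is_clamped_and_flagged(self, generic_model):
        mus = sq.MuscleTendonUnit("t", mif=100.0, tsl=0.2, pen_opt=0.0, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.2)
        assert st.clamped and st.lnorm == pytest.approx(0.01)

    def test_full_activation_at_optimum_gives_exactly_mif(self, generic_model):
        mus = sq.MuscleTendonUnit("t", mif=1234.5, tsl=0.2, pen_opt=0.0, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.3)
        f = sq.muscle_force_scalar(mus, 1.0, st, include_flv=True)
        assert f == mus.mif  # fL(1)=fV(0)=1, fPE(1)=0 by curve normalisation

    def test_zero_activation_at_optimum_gives_zero_force(self, generic_model):
        mus = sq.MuscleTendonUnit("t", mif=500.0, tsl=0.2, pen_opt=0.0, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.3)
        assert sq.muscle_force_scalar(mus, 0.0, st, include_flv=True) == 0.0

    def test_ideal_generator_is_linear_in_activation(self, generic_model):
        mus = sq.MuscleTendonUnit("t", mif=800.0, tsl=0.2, pen_opt=0.0, l_opt=0.1,
                                  pathway=generic_model.muscle("bflh").pathway)
        st = sq.fiber_state(mus, mtu_length=0.27)
        assert sq.muscle_force_scalar(mus, 0.5, st, include_flv=False) == pytest.approx(400.0)

    def test_activation_out_of_bounds_rejected(self, generic_model):
        mus = generic_model.muscle("bflh")
        st = sq.fiber_state(mus, mtu_length=mus.tsl + mus.l_opt)
        with pytest.raises(ValidationError):
            sq.muscle_force_scalar(mus, 1.2, st)


class TestHillCurves:
    def test_active_curve_normalisation_and_decay(self):
        l = np.linspace(0.2, 2.0, 200)
        fl = model_core.fl_active(l)
        assert np.all(fl >= 0)
        assert model_core.fl_active(1.0) == pytest.approx(1.0)
        # Gaussian with the standard width parameter decays monotonically
        # away from the optimum and is small at the curve bounds
        short, long_ = l < 1.0, l > 1.0
        assert np.all(np.diff(fl[short]) > 0) and np.all(np.diff(fl[long_]) < 0)
        assert model_core.fl_active(0.2) < 0.25 and model_core.fl_active(1.9) < 0.2

    def test_passive_curve_zero_at_optimum_and_nondecreasing(self):
        l = np.linspace(0.5, 1.8, 300)
        fpe = model_core.fl_passive(l)
        assert model_core.fl_passive(1.0) == 0.0
        assert np.all(np.diff(fpe) >= -1e-15)

    def test_force_velocity_normalisation(self):
        assert model_core.fv(0.0) == pytest.approx(1.0)
        assert model_core.fv(-1.0) == 0.0
        assert 1.0 < model_core.fv(0.5) <= model_core.FV_FLEN


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

class TestScaling:
    def test_identity_scaling_preserves_every_field(self, generic_model):
        landmarks = {
            "pelvis_width": generic_model.segment("pelvis").length,
            "femur_length": generic_model.segment("thigh").length,
            "tibia_length": generic_model.segment("shank").length,
        }
        scaled = sq.scale_model(generic_model, landmarks, generic_model.subject_mass)
        for s0, s1 in zip(generic_model.segments, scaled.segments):
            assert s1.mass == pytest.approx(s0.mass)
            assert s1.length == pytest.approx(s0.length)
            np.testing.assert_allclose(s1.com_local, s0.com_local)
        for m0, m1 in zip(generic_model.muscles, scaled.muscles):
            assert m1.mif == m0.mif
            assert m1.tsl == pytest.approx(m0.tsl, rel=1e-12)
            assert m1.l_opt == pytest.approx(m0.l_opt, rel=1e-12)
            for p0, p1 in zip(m0.pathway, m1.pathway):
                np.testing.assert_allclose(p1.position_local, p0.position_local)

    def test_uniform_10pct_scaling_stretches_geometry_not_strength(self, generic_model):
        landmarks = {
            "pelvis_width": 1.1 * generic_model.segment("pelvis").length,
            "femur_length": 1.1 * generic_model.segment("thigh").length,
            "tibia_length": 1.1 * generic_model.segment("shank").length,
        }
        scaled = sq.scale_model(generic_model, landmarks, generic_model.subject_mass)
        for s0, s1 in zip(generic_model.segments, scaled.segments):
            assert s1.length == pytest.approx(1.1 * s0.length)
        # brute-force MTU length ratio in the reference pose is 1.1 for every
        # muscle, so l_opt and tsl scale by 1.1 and their ratio is preserved
        for m0, m1 in zip(generic_model.muscles, scaled.muscles):
            assert m1.mif == m0.mif
            assert m1.l_opt == pytest.approx(1.1 * m0.l_opt, rel=1e-9)
            assert m1.tsl == pytest.approx(1.1 * m0.tsl, rel=1e-9)
            assert m1.tsl / m1.l_opt == pytest.approx(m0.tsl / m0.l_opt, rel=1e-9)

    def test_mass_only_scaling_leaves_geometry_untouched(self, generic_model):
        landmarks = {
            "pelvis_width": generic_model.segment("pelvis").length,
            "femur_length": generic_model.segment("thigh").length,
            "tibia_length": generic_model.segment("shank").length,
        }
        scaled = sq.scale_model(generic_model, landmarks, 2 * generic_model.subject_mass)
        for s0, s1 in zip(generic_model.segments, scaled.segments):
            assert s1.mass == pytest.approx(2 * s0.mass)
            assert s1.length == pytest.approx(s0.length)
        assert sum(s.mass for s in scaled.segments) == pytest.approx(scaled.subject_mass)

    def test_missing_landmark_is_configuration_error(self, generic_model):
        with pytest.raises(ConfigurationError):
            sq.scale_model(generic_model, {"femur_length": 0.4}, 80.0)

    def test_nonpositive_distance_is_validation_error(self, generic_model):
        landmarks = {"pelvis_width": 0.3, "femur_length": -0.4, "tibia_length": 0.4}
        with pytest.raises(ValidationError):
            sq.scale_model(generic_model, landmarks, 80.0)


# ---------------------------------------------------------------------------
# Model definition files and invariants
# ---------------------------------------------------------------------------

class TestModelDefinition:
    def test_yaml_round_trip(self, generic_model, tmp_path):
        path = tmp_path / "model.yaml"
        sq.save_model(generic_model, path)
        loaded = sq.load_model(path)
        assert loaded.muscle_names == generic_model.muscle_names
        for m0, m1 in zip(generic_model.muscles, loaded.muscles):
            assert m1.tsl == pytest.approx(m0.tsl, rel=1e-9)

    def test_group_semantics_validated(self, generic_model):
        groups = {g.name: set(g.members) for g in generic_model.groups}
        assert groups["knee_hip_biarticular"] <= (
            groups["knee_extensors"] | groups["knee_flexors"]
        )
        for name, members in groups.items():
            if name != "lower_limb":
                assert members <= groups["lower_limb"]

    def test_bad_group_membership_rejected(self, generic_model):
        bad = generic_model.copy()
        bad.groups[1] = sq.MuscleGroup("knee_extensors", ("vaslat", "ghost"))
        with pytest.raises(ValidationError):
            bad.validate()

    def test_invalid_muscle_parameters_rejected(self, generic_model):
        path = generic_model.muscle("bflh").pathway
        with pytest.raises(ValidationError):
            sq.MuscleTendonUnit("bad", mif=-5.0, tsl=0.1, pen_opt=0.0, l_opt=0.1,
                                pathway=path)
        with pytest.raises(ValidationError):
            sq.MuscleTendonUnit("bad", mif=5.0, tsl=0.1, pen_opt=1.6, l_opt=0.1,
                                pathway=path)
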