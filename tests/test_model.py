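"""Musculoskeletal model tests: scaling, moment arms, morphing, diagnostics."""

import numpy as np
import pytest

from paleogait.core import AUSTRALOPITH_LIKE, HUMAN_LIKE
from paleogait.model import (
    MuscleElement, Posture, build_subject_model, check_muscle_paths,
    forward_kinematics, moment_arm, moment_arm_matrix, morph_attachments,
    muscle_length, _CI,
)
from paleogait.morphology import fit_tps
from paleogait.synthetic import generate_cohort, generate_hip_geometry


def standing_posture(subject, flexion=0.0):
    q = np.zeros(18)
    q[_CI["pelvis_z"]] = 0.95
    q[_CI["hip_flexion_left"]] = flexion
    q[_CI["hip_flexion_right"]] = flexion
    return Posture(q)


class TestConstruction:
    def test_total_mass_equals_body_mass(self, human_model, subject):
        assert abs(human_model.total_mass - subject.body_mass) < 1e-9

    def test_mass_scales_proportionally(self, subject):
        import dataclasses

        heavy = dataclasses.replace(subject, body_mass=2 * subject.body_mass)
        m1 = build_subject_model(HUMAN_LIKE, subject)
        m2 = build_subject_model(HUMAN_LIKE, heavy)
        for name in m1.segments:
            assert abs(m2.segments[name].mass - 2 * m1.segments[name].mass) < 1e-9

    def test_variants_share_joint_center_distances(self, human_model, austral_model):
        for m in (human_model, austral_model):
            hiphip = np.linalg.norm(
                m.segments["thigh_left"].origin_in_parent
                - m.segments["thigh_right"].origin_in_parent)
            hipknee = abs(m.segments["shank_left"].origin_in_parent[2])
            assert abs(hiphip - m.subject.hip_breadth) < 1e-9
            assert abs(hipknee - m.subject.femur_length) < 1e-9

    def test_gluteal_element_counts(self, human_model):
        for group in ("gluteus_medius", "gluteus_minimus", "gluteus_maximus"):
            assert len(human_model.elements_of(group, "left")) == 12
            assert len(human_model.elements_of(group, "right")) == 12

    def test_marker_template_variant_independent(self, human_model, austral_model):
        """Markers live on the subject's skin, not on the model variant."""
        for name, (seg, loc) in human_model.marker_local.items():
            seg_a, loc_a = austral_model.marker_local[name]
            assert seg == seg_a
            assert np.array_equal(loc, loc_a)
        assert len(human_model.marker_local) == 52


class TestMomentArms:
    def test_straight_muscle_perpendicular_distance(self, subject):
        """A sagittal muscle passing at distance d from the knee has arm d."""
        model = build_subject_model(HUMAN_LIKE, subject)
        d = 0.04
        lf = subject.femur_length
        el = MuscleElement(
            "toy", "toy", "left",
            origin=("thigh_left", np.array([d, 0.0, -0.5 * lf])),
            insertion=("shank_left", np.array([d, 0.0, -0.10])),
        )
        p = standing_posture(subject)
        arm = moment_arm(model, p, el, "knee_flexion_left")
        assert abs(abs(arm) - d) < 1e-6

    def test_two_point_muscle_matches_law_of_cosines(self, subject):
        """Closed-form -dL/dtheta for a hinge-spanning two-point muscle."""
        model = build_subject_model(HUMAN_LIKE, subject)
        lf = subject.femur_length
        a, b = 0.30 * lf, 0.12
        el = MuscleElement(
            "toy", "toy", "left",
            origin=("thigh_left", np.array([0.0, 0.0, -(lf - a)])),
            insertion=("shank_left", np.array([0.0, 0.0, -b])),
        )
        theta = 0.7
        q = standing_posture(subject).replace_coord("knee_flexion_left", theta)
        # L(theta) = sqrt(a^2 + b^2 - 2ab cos(pi - theta)); flexion shortens
        # the chord, so the arm -dL/dtheta is positive
        analytic = (a * b * np.sin(np.pi - theta)
                    / np.sqrt(a**2 + b**2 - 2 * a * b * np.cos(np.pi - theta)))
        arm = moment_arm(model, q, el, "knee_flexion_left")
        assert abs(arm - analytic) < 1e-6

    def test_path_through_joint_center_has_zero_arm(self, subject):
        model = build_subject_model(HUMAN_LIKE, subject)
        lf = subject.femur_length
        el = MuscleElement(
            "toy", "toy", "left",
            origin=("thigh_left", np.array([0.0, 0.0, -0.5 * lf])),
            insertion=("shank_left", np.array([0.0, 0.0, -0.10])),
        )
        arm = moment_arm(model, standing_posture(subject), el, "knee_flexion_left")
        assert abs(arm) < 1e-9

    def test_invariant_to_rigid_whole_body_transform(self, human_model):
        p = standing_posture(human_model.subject, flexion=0.3)
        arms = moment_arm_matrix(human_model, p)
        q = p.q.copy()
        q[_CI["pelvis_x"]] += 1.7
        q[_CI["pelvis_y"]] -= 0.4
        q[_CI["pelvis_rz"]] = 0.8
        arms2 = moment_arm_matrix(human_model, Posture(q))
        assert np.abs(arms - arms2).max() < 1e-8

    def test_zero_length_segment_raises(self, human_model):
        el = MuscleElement(
            "toy", "toy", "left",
            origin=("thigh_left", np.array([0.01, 0.0, -0.1])),
            insertion=("thigh_left", np.array([0.01, 0.0, -0.1])),
        )
        with pytest.raises(ValueError, match="zero-length"):
            muscle_length(human_model, standing_posture(human_model.subject), el)


class TestMorphAttachments:
    def _warp(self, subject):
        pel_h, _ = generate_hip_geometry(HUMAN_LIKE, subject)
        pel_a, _ = generate_hip_geometry(AUSTRALOPITH_LIKE, subject)
        names = sorted(pel_h.landmarks)
        return fit_tps(pel_h.landmark_array(names), pel_a.landmark_array(names))

    def test_identity_warp_changes_nothing(self, human_model, subject):
        pel_h, _ = generate_hip_geometry(HUMAN_LIKE, subject)
        names = sorted(pel_h.landmarks)
        ident = fit_tps(pel_h.landmark_array(names), pel_h.landmark_array(names))
        out = morph_attachments(human_model, ident, ["pelvis"])
        for a, b in zip(human_model.muscles, out.muscles):
            assert np.abs(a.origin[1] - b.origin[1]).max() < 1e-9

    def test_joint_centers_and_inertia_untouched(self, human_model, subject):
        out = morph_attachments(human_model, self._warp(subject), ["pelvis"])
        for name in human_model.segments:
            assert np.array_equal(out.segments[name].origin_in_parent,
                                  human_model.segments[name].origin_in_parent)
            assert np.array_equal(out.segments[name].inertia,
                                  human_model.segments[name].inertia)

    def test_anterior_medius_origins_move_posteriorly(self, human_model, subject):
        """The weaker anterior wrap pulls anterior abductor origins back."""
        out = morph_attachments(human_model, self._warp(subject), ["pelvis"])
        for side in ("left", "right"):
            before = human_model.elements_of("gluteus_medius", side)[-1].origin[1]
            after = out.elements_of("gluteus_medius", side)[-1].origin[1]
            assert after[0] < before[0]


class TestPathChecks:
    def test_clean_model_has_no_flags(self, human_model, kinematics, stride_window):
        window, _ = stride_window
        postures = [kinematics.posture(f) for f in range(window.start, window.stop, 12)]
        assert check_muscle_paths(human_model, postures) == {}

    def test_malrouted_via_point_is_flagged(self, subject, kinematics, stride_window):
        window, _ = stride_window
        postures = [kinematics.posture(f) for f in range(window.start, window.stop, 12)]
        bad = build_subject_model(HUMAN_LIKE, subject)
        for m in bad.muscles:
            if m.name == "vasti_left_0":
                m.via_points = [("thigh_left",
                                 np.array([0.003, 0.0, -subject.femur_length + 0.003]))]
        flags = check_muscle_paths(bad, postures)
        assert "near_joint_center" in flags.get("vasti_left_0", [])

    def test_report_deterministic(self, human_model, kinematics, stride_window):
        window, _ = stride_window
        postures = [kinematics.posture(f) for f in range(window.start, window.stop, 20)]
        assert check_muscle_paths(human_model, postures) == check_muscle_paths(human_model, postures)


def test_posture_limit_warning(human_model):
    q = np.zeros(18)
    q[_CI["knee_flexion_left"]] = 3.0  # beyond the documented limit
    with pytest.warns(UserWarning, match="joint limits"):
        Posture(q).warn_outside_limits()
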