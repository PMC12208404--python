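"""Shape-operation tests: TPS, ICP, CPD, symmetry, scaling, orientation."""

import numpy as np
import pytest

from paleogait.core import AUSTRALOPITH_LIKE, HUMAN_LIKE
from paleogait.morphology import (
    CPDConfig, LandmarkedMesh, RigidTransform, SingularLandmarkError,
    apply_tps, asymmetry_score, build_hybrid_femur, cpd_correspond,
    farthest_point_sample, fit_tps, icp_align, orient_pelvis, reduce_asymmetry,
    scale_to_joint_centers, warp_mesh, _rotation_about_axis,
)
from paleogait.synthetic import generate_cohort, generate_hip_geometry


@pytest.fixture(scope="module")
def geometry():
    subj = generate_cohort(1, 7)[0]
    pel_h, fem_h = generate_hip_geometry(HUMAN_LIKE, subj)
    pel_a, fem_a = generate_hip_geometry(AUSTRALOPITH_LIKE, subj)
    return subj, pel_h, fem_h, pel_a, fem_a


PAIRS = [(f"{b}_left", f"{b}_right") for b in (
    "asis", "psis", "pubic_tubercle", "ischial_tuberosity", "iliac_crest",
    "hip_center", "gluteus_medius_origin_anterior", "gluteus_maximus_origin_middle",
    "gluteus_minimus_origin_posterior")]
MIDLINE = ["sacral_endplate_anterior", "sacral_endplate_posterior"]


# ---------------------------------------------------------------------------
# Thin-plate splines


class TestTPS:
    def test_identity_and_translation(self):
        rng = np.random.default_rng(0)
        src = rng.normal(size=(12, 3))
        probe = rng.normal(size=(7, 3))
        w_id = fit_tps(src, src)
        assert np.abs(apply_tps(w_id, probe) - probe).max() < 1e-10
        t = np.array([0.3, -0.1, 0.7])
        w_t = fit_tps(src, src + t)
        assert np.abs(w_t.kernel_weights).max() < 1e-10
        assert np.abs(apply_tps(w_t, probe) - (probe + t)).max() < 1e-10

    def test_exact_interpolation_and_side_conditions(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(20, 3))
        dst = src + 0.1 * rng.normal(size=(20, 3))
        w = fit_tps(src, dst, regularization=0.0)
        bbox = np.linalg.norm(src.max(axis=0) - src.min(axis=0))
        assert np.abs(apply_tps(w, src) - dst).max() < 1e-8 * bbox
        # kernel weights orthogonal to constants and coordinates
        assert np.abs(w.kernel_weights.sum(axis=0)).max() < 1e-9
        assert np.abs(src.T @ w.kernel_weights).max() < 1e-9

    @pytest.mark.parametrize("bad", ["coplanar", "duplicate", "too_few"])
    def test_singular_configurations_raise(self, bad):
        rng = np.random.default_rng(1)
        if bad == "coplanar":
            src = rng.normal(size=(8, 3))
            src[:, 2] = 0.0
        elif bad == "duplicate":
            src = rng.normal(size=(8, 3))
            src[3] = src[5]
        else:
            src = rng.normal(size=(3, 3))
        with pytest.raises(SingularLandmarkError):
            fit_tps(src, src + 0.1)

    def test_warp_mesh_preserves_topology(self, geometry):
        _, pel_h, _, pel_a, _ = geometry
        names = sorted(pel_h.landmarks)
        w = fit_tps(pel_h.landmark_array(names), pel_a.landmark_array(names))
        out = warp_mesh(w, pel_h)
        assert out.vertices.shape == pel_h.vertices.shape
        assert np.array_equal(out.faces, pel_h.faces)

    def test_pelvis_morph_round_trip(self, geometry):
        """Human -> australopith -> human leaves probe points near home."""
        _, pel_h, _, pel_a, _ = geometry
        names = sorted(pel_h.landmarks)
        fwd = fit_tps(pel_h.landmark_array(names), pel_a.landmark_array(names))
        back = fit_tps(pel_a.landmark_array(names), pel_h.landmark_array(names))
        probe = pel_h.vertices
        round_trip = apply_tps(back, apply_tps(fwd, probe))
        assert np.linalg.norm(round_trip - probe, axis=1).max() < 0.01 * pel_h.bbox_diagonal()


# ---------------------------------------------------------------------------
# Rigid registration


class TestICP:
    def test_identity(self):
        rng = np.random.default_rng(2)
        cloud = rng.normal(size=(100, 3))
        tf, rms, _ = icp_align(cloud, cloud)
        assert rms < 1e-12
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-12

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(5)
        cloud = rng.normal(size=(300, 3))
        R = _rotation_about_axis(np.array([0.2, 1.0, -0.4]), 0.25)
        t = np.array([0.05, -0.02, 0.08])
        moving = cloud @ R.T + t
        tf, rms, _ = icp_align(moving, cloud)
        # composing with the applied transform must give the identity
        comp = tf.compose(RigidTransform(R, t))
        assert np.abs(comp.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(comp.translation).max() < 1e-6
        assert rms < 1e-6

    def test_rms_non_increasing(self):
        rng = np.random.default_rng(8)
        fixed = rng.normal(size=(150, 3))
        moving = fixed @ _rotation_about_axis(np.array([0, 0, 1.0]), 0.4).T + 0.1
        # track RMS by re-running with increasing iteration caps
        rms_seq = [icp_align(moving, fixed, max_iter=k)[1] for k in (1, 3, 6, 12, 40)]
        assert all(b <= a + 1e-12 for a, b in zip(rms_seq, rms_seq[1:]))


# ---------------------------------------------------------------------------
# Coherent point drift


def _blob_surface(n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    x, y, z = v.T
    r = 1 + 0.15 * x * y + 0.12 * np.sin(2 * z) + 0.1 * x * z * z + 0.08 * np.cos(2 * x + y)
    return v * r[:, None] * np.array([0.06, 0.08, 0.10])


def _banana_bend(p, k=0.4):
    th = k * (p[:, 2] - p[:, 2].min()) / np.ptp(p[:, 2])
    return np.column_stack([
        p[:, 0],
        p[:, 1] * np.cos(th) - p[:, 2] * np.sin(th),
        p[:, 1] * np.sin(th) + p[:, 2] * np.cos(th),
    ])


class TestCPD:
    def test_default_schedule(self):
        cfg = CPDConfig()
        assert cfg.lambda_reg == 1.0
        assert cfg.beta_schedule == (50.0, 30.0, 10.0, 8.0)

    def test_identity(self):
        rng = np.random.default_rng(4)
        cloud = _blob_surface(400, rng)
        d = cpd_correspond(cloud, cloud)
        bbox = np.linalg.norm(cloud.max(axis=0) - cloud.min(axis=0))
        assert np.linalg.norm(d - cloud, axis=1).mean() < 1e-6 * bbox

    def test_known_homology_bend(self):
        rng = np.random.default_rng(1)
        template = _blob_surface(600, rng)
        target = _banana_bend(template)
        d = cpd_correspond(template, target)
        diam = np.linalg.norm(target.max(axis=0) - target.min(axis=0))
        err = np.linalg.norm(d - target, axis=1).mean()
        assert err < 0.05 * diam


# ---------------------------------------------------------------------------
# Asymmetry reduction


class TestAsymmetry:
    def test_symmetric_mesh_is_fixed_point(self, geometry):
        _, pel_h, _, _, _ = geometry
        assert asymmetry_score(pel_h, PAIRS, MIDLINE) < 1e-9
        out = reduce_asymmetry(pel_h, PAIRS, MIDLINE)
        assert np.abs(out.vertices - pel_h.vertices).max() < 1e-9

    def test_single_offset_splits_in_half(self, geometry):
        _, pel_h, _, _, _ = geometry
        pert = pel_h.copy()
        delta = np.array([1e-3, 0.0, 0.0])
        pert.landmarks["asis_left"] = pert.landmarks["asis_left"] + delta
        out = reduce_asymmetry(pert, PAIRS, MIDLINE)
        moved_l = out.landmarks["asis_left"] - pel_h.landmarks["asis_left"]
        moved_r = out.landmarks["asis_right"] - pel_h.landmarks["asis_right"]
        # half the offset on each side (Procrustes coupling stays small)
        assert abs(moved_l[0] - 5e-4) < 1.5e-4
        assert abs(moved_r[0] - 5e-4) < 1.5e-4

    def test_random_perturbation_score_decreases(self, geometry):
        _, pel_h, _, _, _ = geometry
        rng = np.random.default_rng(3)
        pert = pel_h.copy()
        for name in ("asis_left", "iliac_crest_right", "psis_left"):
            pert.landmarks[name] = pert.landmarks[name] + 0.004 * rng.standard_normal(3)
        before = asymmetry_score(pert, PAIRS, MIDLINE)
        after = asymmetry_score(reduce_asymmetry(pert, PAIRS, MIDLINE), PAIRS, MIDLINE)
        assert after < before

    def test_missing_landmark_raises(self, geometry):
        _, pel_h, _, _, _ = geometry
        with pytest.raises(KeyError):
            reduce_asymmetry(pel_h, [("nope_left", "nope_right")], MIDLINE)


# ---------------------------------------------------------------------------
# Hybrid femur


class TestHybridFemur:
    def test_documented_defaults(self):
        import inspect

        sig = inspect.signature(build_hybrid_femur)
        assert sig.parameters["proximal_fraction"].default == 0.2
        assert sig.parameters["n_proximal"].default == 237
        assert sig.parameters["n_distal"].default == 2500

    def test_identity_pipeline(self, geometry):
        _, _, fem_h, _, _ = geometry
        hybrid = build_hybrid_femur(fem_h, fem_h, n_proximal=120, n_distal=400)
        assert np.abs(hybrid.vertices - fem_h.vertices).max() < 1e-6

    def test_proximal_moves_toward_fossil_distal_stays(self, geometry):
        _, _, fem_h, _, fem_a = geometry
        hybrid = build_hybrid_femur(fem_h, fem_a, n_proximal=150, n_distal=500)
        # greater-trochanter region (lateral y extent) moves toward the
        # longer-necked fossil shape
        assert fem_h.vertices[:, 1].max() < hybrid.vertices[:, 1].max() <= fem_a.vertices[:, 1].max() + 1e-6
        # distal third is (near-)untouched: control vertices are exact TPS
        # interpolation points, vertices between them move only micrometres
        distal = fem_h.vertices[:, 2] < fem_h.vertices[:, 2].min() + 0.3 * np.ptp(fem_h.vertices[:, 2])
        assert np.abs(hybrid.vertices[distal] - fem_h.vertices[distal]).max() < 5e-5
        assert np.array_equal(hybrid.faces, fem_h.faces)


# ---------------------------------------------------------------------------
# Scaling and orientation


class TestScaleAndOrient:
    def test_scale_arithmetic(self):
        mesh = LandmarkedMesh(
            vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int),
            landmarks={"a": np.array([0.0, 0.07, 0.0]), "b": np.array([0.0, -0.07, 0.0])})
        out = scale_to_joint_centers(mesh, {"d": ("a", "b")}, {"d": 0.170})
        d = np.linalg.norm(out.landmarks["a"] - out.landmarks["b"])
        assert abs(d - 0.170) < 1e-12

    def test_identity_and_idempotence(self, geometry):
        _, pel_h, _, _, _ = geometry
        jp = {"hip_to_hip": ("hip_center_left", "hip_center_right")}
        current = np.linalg.norm(pel_h.landmarks["hip_center_left"]
                                 - pel_h.landmarks["hip_center_right"])
        out = scale_to_joint_centers(pel_h, jp, {"hip_to_hip": current})
        assert np.abs(out.vertices - pel_h.vertices).max() < 1e-12
        once = scale_to_joint_centers(pel_h, jp, {"hip_to_hip": 0.18})
        twice = scale_to_joint_centers(once, jp, {"hip_to_hip": 0.18})
        assert np.abs(twice.vertices - once.vertices).max() < 1e-9

    def test_femur_scaled_from_fossil_length(self, geometry):
        """A 0.277 m femur scales exactly onto the subject's femur length."""
        subj, _, fem_h, _, _ = geometry
        fossil = fem_h.copy()
        s = 0.277 / np.linalg.norm(fossil.landmarks["knee_center"] - fossil.landmarks["hip_center"])
        fossil.vertices = fossil.vertices * s
        fossil.landmarks = {k: v * s for k, v in fossil.landmarks.items()}
        out = scale_to_joint_centers(
            fossil, {"hip_to_knee": ("hip_center", "knee_center")},
            {"hip_to_knee": subj.femur_length})
        d = np.linalg.norm(out.landmarks["knee_center"] - out.landmarks["hip_center"])
        assert abs(d - subj.femur_length) < 1e-12

    def test_conflicting_targets_report_scales(self, geometry):
        _, pel_h, _, _, _ = geometry
        jp = {"hips": ("hip_center_left", "hip_center_right"),
              "crests": ("iliac_crest_left", "iliac_crest_right")}
        with pytest.raises(ValueError, match="implied scales"):
            scale_to_joint_centers(pel_h, jp, {"hips": 0.20, "crests": 0.20})

    def test_orient_neutral_and_pretilted(self, geometry):
        _, pel_h, _, pel_a, _ = geometry
        out, achieved = orient_pelvis(pel_h)
        assert abs(achieved["anterior_pelvic_plane_deg"]) < 1e-9
        tilted = pel_a.copy()
        R = _rotation_about_axis(np.array([0.0, 1.0, 0.0]), np.radians(12.0))
        tilted.vertices = tilted.vertices @ R.T
        tilted.landmarks = {k: R @ v for k, v in tilted.landmarks.items()}
        out, achieved = orient_pelvis(tilted)
        assert abs(achieved["anterior_pelvic_plane_deg"]) < 1e-9
        # the generator builds the sacral endplate at its ~30 deg target
        assert abs(achieved["sacral_slope_deg"] - 30.0) < 1.0


def test_farthest_point_sampling_deterministic_and_spread():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(500, 3))
    a = farthest_point_sample(pts, 40, seed=3)
    b = farthest_point_sample(pts, 40, seed=3)
    assert np.array_equal(a, b)
    assert len(set(a.tolist())) == 40
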