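"""Landmark-driven shape operations on bone surface meshes.

This module holds every geometric primitive of the morphing chain that turns a
modern-human-shaped pelvis/femur into an australopithecine-shaped one while
keeping the mesh triangulation (and hence downstream vertex bookkeeping)
intact:

* thin-plate-spline (TPS) warps fitted to named landmark pairs and applied to
  whole vertex sets (:func:`fit_tps`, :func:`apply_tps`);
* rigid iterative-closest-point alignment (:func:`icp_align`);
* non-rigid coherent-point-drift correspondence (:func:`cpd_correspond`);
* reflect-relabel-average asymmetry reduction (:func:`reduce_asymmetry`);
* the hybrid femur construction — fossil-shaped proximal end, human distal
  end, TPS-smoothed shaft (:func:`build_hybrid_femur`);
* joint-center-preserving uniform scaling (:func:`scale_to_joint_centers`)
  and anterior-pelvic-plane orientation (:func:`orient_pelvis`).

The 3D TPS kernel is U(r) = r.  With zero regularization the warp interpolates
its landmarks exactly; the kernel weights satisfy the side conditions (they
are orthogonal to constants and to the source coordinates), which makes the
far-field behaviour affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LandmarkedMesh",
    "TPSWarp",
    "CPDConfig",
    "RigidTransform",
    "SingularLandmarkError",
    "fit_tps",
    "apply_tps",
    "icp_align",
    "cpd_correspond",
    "reduce_asymmetry",
    "asymmetry_score",
    "build_hybrid_femur",
    "scale_to_joint_centers",
    "orient_pelvis",
    "farthest_point_sample",
]


class SingularLandmarkError(ValueError):
    """Raised when a landmark configuration cannot support a TPS fit."""


@dataclass
class LandmarkedMesh:
    """A triangulated surface with named landmarks.

    Landmarks are stored as explicit 3D coordinates (metres).  Faces index
    into ``vertices``; morphing operations never change the face array.
    """

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int
    landmarks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        clean: Dict[str, np.ndarray] = {}
        for name, p in self.landmarks.items():
            if name in clean:
                raise ValueError(f"duplicate landmark name {name!r}")
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")
            clean[name] = p
        self.landmarks = clean

    def copy(self) -> "LandmarkedMesh":
        return LandmarkedMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
        )

    def landmark_array(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")
        return np.array([self.landmarks[n] for n in names])

    def bbox_diagonal(self) -> float:
        pts = self.vertices if len(self.vertices) else self.landmark_array(sorted(self.landmarks))
        return float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))


@dataclass
class TPSWarp:
    """A fitted 3D thin-plate-spline map f(x) = A[x;1] + sum_i w_i |x - c_i|."""

    source_landmarks: np.ndarray  # (n, 3)
    target_landmarks: np.ndarray  # (n, 3)
    affine_part: np.ndarray  # (3, 4): rows map [x, y, z, 1]
    kernel_weights: np.ndarray  # (n, 3)
    regularization: float = 0.0


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class CPDConfig:
    """Settings for staged non-rigid coherent point drift.

    ``beta_schedule`` lists the Gaussian kernel widths of successive stages,
    expressed as a percentage of the cloud RMS scale (the clouds are centered
    and scaled to unit RMS internally, and a configured width of 50 means an
    internal width of 0.5).  ``lambda_reg`` weighs deformation smoothness
    against data fit.
    """

    lambda_reg: float = 1.0
    beta_schedule: Tuple[float, ...] = (50.0, 30.0, 10.0, 8.0)
    max_iter: int = 60
    tolerance: float = 1e-6
    outlier_weight: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_reg <= 0:
            raise ValueError("lambda_reg must be positive")
        if not self.beta_schedule or any(b <= 0 for b in self.beta_schedule):
            raise ValueError("beta_schedule must be non-empty and positive")


# ---------------------------------------------------------------------------
# Thin-plate splines


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between every point of ``a`` and every point of ``b``."""
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def fit_tps(source: np.ndarray, target: np.ndarray, regularization: float = 0.0) -> TPSWarp:
    """Fit a 3D thin-plate-spline warp mapping ``source`` landmarks to ``target``.

    With ``regularization`` 0 the warp interpolates every landmark pair
    exactly.  Raises :class:`SingularLandmarkError` when landmarks are
    duplicated or coplanar (the affine part is then unidentifiable), naming
    the offending points.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(source)
    if n < 4:
        raise SingularLandmarkError("need at least 4 landmarks for a 3D TPS")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")

    scale = float(np.linalg.norm(source.max(axis=0) - source.min(axis=0)))
    d = _tps_kernel(source, source)
    np.fill_diagonal(d, np.inf)
    dup = np.argwhere(d < 1e-12 * max(scale, 1.0))
    if len(dup):
        i, j = dup[0]
        raise SingularLandmarkError(f"duplicate source landmarks at indices {i} and {j}")

    centered = source - source.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-9 * max(svals[0], 1e-30):
        raise SingularLandmarkError(
            "source landmarks are coplanar/collinear; the affine part is "
            f"unidentifiable (singular values {svals})"
        )

    K = _tps_kernel(source, source)
    if regularization > 0:
        K = K + regularization * np.eye(n)
    P = np.hstack([source, np.ones((n, 1))])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target
    sol = np.linalg.solve(L, rhs)
    return TPSWarp(
        source_landmarks=source.copy(),
        target_landmarks=target.copy(),
        affine_part=sol[n:].T,  # (3, 4), columns [x, y, z, 1]
        kernel_weights=sol[:n],
        regularization=float(regularization),
    )


def apply_tps(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS warp at ``points`` ((m, 3) -> (m, 3), order kept)."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    U = _tps_kernel(pts, warp.source_landmarks)
    out = (
        np.hstack([pts, np.ones((len(pts), 1))]) @ warp.affine_part.T
        + U @ warp.kernel_weights
    )
    return out[0] if squeeze else out


def warp_mesh(warp: TPSWarp, mesh: LandmarkedMesh) -> LandmarkedMesh:
    """Apply a TPS warp to a mesh's vertices and landmarks; topology unchanged."""
    out = mesh.copy()
    if len(out.vertices):
        out.vertices = apply_tps(warp, out.vertices)
    out.landmarks = {k: apply_tps(warp, v) for k, v in out.landmarks.items()}
    return out


# ---------------------------------------------------------------------------
# Rigid registration


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform taking ``moving`` onto ``fixed``."""
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, fc - R @ mc)


def icp_align(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> Tuple[RigidTransform, float, bool]:
    """Rigidly align ``moving`` onto ``fixed`` by iterative closest point.

    Point-to-point variant with nearest-neighbour matching.  Returns
    ``(transform, final_rms, converged)``; non-convergence within ``max_iter``
    is flagged, not raised.  The nearest-neighbour RMS is non-increasing
    across iterations.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if len(moving) < 3 or len(fixed) < 3:
        raise ValueError("both point sets need at least 3 points")
    tree = cKDTree(fixed)
    transform = RigidTransform(np.eye(3), np.zeros(3))
    current = moving.copy()
    prev_rms = np.inf
    converged = False
    rms = float(np.sqrt(np.mean(tree.query(current)[0] ** 2)))
    for _ in range(max_iter):
        dist, idx = tree.query(current)
        rms = float(np.sqrt(np.mean(dist**2)))
        if prev_rms - rms < tol:
            converged = True
            break
        prev_rms = rms
        step = _kabsch(current, fixed[idx])
        current = step.apply(current)
        transform = step.compose(transform)
    return transform, rms, converged


# ---------------------------------------------------------------------------
# Coherent point drift (non-rigid)


class CPDStageError(RuntimeError):
    """Raised when a CPD stage diverges."""

    def __init__(self, stage: int, message: str):
        super().__init__(f"CPD stage {stage}: {message}")
        self.stage = stage


def _gaussian_kernel(y: np.ndarray, beta: float) -> np.ndarray:
    d2 = np.sum((y[:, None, :] - y[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * beta**2))


def _cpd_stage(
    X: np.ndarray, Y: np.ndarray, beta: float, lam: float, w: float,
    max_iter: int, tol: float, sigma2: Optional[float] = None,
) -> Tuple[np.ndarray, float]:
    """One stage of non-rigid CPD: deform template Y onto target X.

    Standard Gaussian-mixture formulation: the template points are mixture
    centroids displaced by a kernel-smoothed field T = Y + G W; each EM
    iteration solves (diag(P1) G + lam * sigma^2 I) W = P X - diag(P1) Y.
    ``sigma2`` continues the annealed mixture variance from a previous stage;
    re-initializing it from the all-pairs distance at every stage would
    re-run the early coarse-correspondence phase and accumulate drift.
    """
    N, M = len(X), len(Y)
    G = _gaussian_kernel(Y, beta)
    T = Y.copy()
    if sigma2 is None:
        sigma2 = np.sum((X[None, :, :] - Y[:, None, :]) ** 2) / (3.0 * M * N)
    prev_q = np.inf
    for it in range(max_iter):
        d2 = np.sum((X[None, :, :] - T[:, None, :]) ** 2, axis=-1)  # (M, N)
        c = (2 * np.pi * sigma2) ** 1.5 * (w / (1 - w)) * (M / N)
        P = np.exp(-d2 / (2 * sigma2))
        den = P.sum(axis=0, keepdims=True) + c
        P = P / den
        p1 = P.sum(axis=1)  # (M,)
        Np = p1.sum()
        A = G * p1[:, None] + lam * sigma2 * np.eye(M)
        B = P @ X - p1[:, None] * Y
        W = np.linalg.solve(A, B)
        T = Y + G @ W
        xPx = np.sum(P.sum(axis=0) * np.sum(X**2, axis=1))
        trPXT = np.sum((P @ X) * T)
        tTt = np.sum(p1 * np.sum(T**2, axis=1))
        sigma2_new = (xPx - 2 * trPXT + tTt) / (3.0 * Np)
        if not np.isfinite(sigma2_new):
            raise CPDStageError(it, "variance update diverged")
        sigma2 = max(sigma2_new, 1e-12)
        # absolute change of the (normalized-units) variance: running EM to
        # machine convergence degenerates into density fitting, because the
        # coherence penalty scales with sigma^2
        if abs(prev_q - sigma2) < tol:
            break
        prev_q = sigma2
    if not np.all(np.isfinite(T)):
        raise CPDStageError(it, "non-finite deformed template")
    return T, sigma2


def cpd_correspond(
    template: np.ndarray, target_cloud: np.ndarray, config: Optional[CPDConfig] = None
) -> np.ndarray:
    """Deform ``template`` onto ``target_cloud``, returning homologous points.

    Runs the staged schedule in ``config`` (broad-to-fine kernel widths), each
    stage initialized from the previous stage's deformed template.  Clouds are
    centered and scaled to unit RMS internally; configured kernel widths are
    percentages of that scale.  Output has one point per template point, in
    template order, de-normalized back to input units.
    """
    config = config or CPDConfig()
    X = np.asarray(target_cloud, dtype=float)
    Y = np.asarray(template, dtype=float)
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("both clouds must be non-empty")

    mu = X.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((X - mu) ** 2, axis=1))))
    if scale <= 0:
        raise ValueError("degenerate target cloud")
    Xn = (X - mu) / scale
    Tn = (Y - mu) / scale
    # the clouds are pre-aligned (precondition), so anneal from the scale of
    # the actual mismatch: the classic all-pairs initialization would start a
    # coarse-correspondence collapse that drags pre-aligned points off their
    # homologues
    nn = cKDTree(Xn).query(Tn)[0]
    sigma2: Optional[float] = float(2.0 * np.mean(nn**2) + 1e-12)
    for stage, beta in enumerate(config.beta_schedule):
        try:
            Tn, sigma2 = _cpd_stage(
                Xn,
                Tn,
                beta / 100.0,
                config.lambda_reg,
                config.outlier_weight,
                config.max_iter,
                config.tolerance,
                sigma2,
            )
        except CPDStageError as err:
            raise CPDStageError(stage, str(err)) from err
    return Tn * scale + mu


# ---------------------------------------------------------------------------
# Asymmetry reduction


def _pair_schema(
    mesh: LandmarkedMesh,
    paired: Sequence[Tuple[str, str]],
    midline: Sequence[str],
) -> None:
    names = set(mesh.landmarks)
    wanted = {n for pair in paired for n in pair} | set(midline)
    missing = sorted(wanted - names)
    if missing:
        raise KeyError(f"missing landmarks for asymmetry reduction: {missing}")


def _reflect_relabel(
    landmarks: Dict[str, np.ndarray],
    paired: Sequence[Tuple[str, str]],
    midline: Sequence[str],
) -> Tuple[Dict[str, np.ndarray], np.ndarray, float]:
    """Reflect landmarks across the best-fit midsagittal plane and swap sides."""
    lefts = np.array([landmarks[l] for l, _ in paired])
    rights = np.array([landmarks[r] for _, r in paired])
    diffs = lefts - rights
    # plane normal: dominant direction of left-right separation
    normal = diffs.mean(axis=0)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-12:
        u, s, vt = np.linalg.svd(diffs)
        normal = vt[0]
        nrm = 1.0
    normal = normal / np.linalg.norm(normal)
    anchors = np.vstack([[landmarks[m] for m in midline], (lefts + rights) / 2.0])
    c = float(anchors.mean(axis=0) @ normal)

    def reflect(p: np.ndarray) -> np.ndarray:
        return p - 2.0 * (p @ normal - c) * normal

    out = {name: reflect(p) for name, p in landmarks.items()}
    for l, r in paired:
        out[l], out[r] = out[r], out[l]
    return out, normal, c


def asymmetry_score(
    mesh: LandmarkedMesh,
    paired_landmarks: Sequence[Tuple[str, str]],
    midline_landmarks: Sequence[str],
) -> float:
    """RMS mismatch between the landmark set and its reflected-relabelled copy."""
    _pair_schema(mesh, paired_landmarks, midline_landmarks)
    names = sorted({n for pair in paired_landmarks for n in pair} | set(midline_landmarks))
    config = {n: mesh.landmarks[n] for n in names}
    reflected, _, _ = _reflect_relabel(config, paired_landmarks, midline_landmarks)
    orig = np.array([config[n] for n in names])
    refl = np.array([reflected[n] for n in names])
    aligned = _kabsch(refl, orig).apply(refl)
    return float(np.sqrt(np.mean(np.sum((aligned - orig) ** 2, axis=1))))


def reduce_asymmetry(
    mesh: LandmarkedMesh,
    paired_landmarks: Sequence[Tuple[str, str]],
    midline_landmarks: Sequence[str],
) -> LandmarkedMesh:
    """Symmetrize a landmark configuration by reflect-relabel-averaging.

    The landmark set is reflected across the best-fit midsagittal plane,
    left/right labels are swapped, the copy is rigidly aligned back onto the
    original, and the two configurations are averaged.  The mesh surface is
    carried along by the TPS warp from the original landmarks to the
    symmetrized ones, so triangulation is preserved.  An already-symmetric
    configuration is a fixed point.
    """
    _pair_schema(mesh, paired_landmarks, midline_landmarks)
    names = sorted({n for pair in paired_landmarks for n in pair} | set(midline_landmarks))
    config = {n: mesh.landmarks[n] for n in names}
    reflected, _, _ = _reflect_relabel(config, paired_landmarks, midline_landmarks)
    orig = np.array([config[n] for n in names])
    refl = np.array([reflected[n] for n in names])
    aligned = _kabsch(refl, orig).apply(refl)
    symm = 0.5 * (orig + aligned)

    out = mesh.copy()
    if np.max(np.linalg.norm(symm - orig, axis=1)) < 1e-12 * max(mesh.bbox_diagonal(), 1.0):
        return out  # already symmetric: avoid fitting a degenerate warp
    # carry the surface and any unpaired landmarks along with the TPS warp
    # from the original configuration to the symmetrized one
    warp = fit_tps(orig, symm, regularization=0.0)
    if len(out.vertices):
        out.vertices = apply_tps(warp, out.vertices)
    out.landmarks = {
        k: (apply_tps(warp, v) if k not in names else v)
        for k, v in mesh.landmarks.items()
    }
    for n, p in zip(names, symm):
        out.landmarks[n] = p
    return out


# ---------------------------------------------------------------------------
# Control-vertex sampling and the hybrid femur


def farthest_point_sample(points: np.ndarray, n_samples: int, seed: int = 0) -> np.ndarray:
    """Indices of ``n_samples`` approximately evenly spread points.

    Greedy farthest-point sampling; the (seeded) random start point makes the
    result deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n_samples > n:
        raise ValueError(f"cannot sample {n_samples} of {n} points")
    rng = np.random.default_rng(seed)
    chosen = np.empty(n_samples, dtype=int)
    chosen[0] = rng.integers(n)
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    for i in range(1, n_samples):
        chosen[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(points - points[chosen[i]], axis=1))
    return chosen


def _proximal_mask(mesh: LandmarkedMesh, fraction: float) -> np.ndarray:
    """Vertices within ``fraction`` of the shaft length from the hip center.

    The shaft axis runs from the hip-center landmark to the knee-center
    landmark (midpoint of the knee axis points when no single knee center is
    present).
    """
    hip = mesh.landmarks.get("hip_center")
    if hip is None:
        raise KeyError("femur mesh needs a 'hip_center' landmark")
    if "knee_center" in mesh.landmarks:
        knee = mesh.landmarks["knee_center"]
    else:
        knee = 0.5 * (
            mesh.landmarks["knee_axis_medial"] + mesh.landmarks["knee_axis_lateral"]
        )
    axis = knee - hip
    length = np.linalg.norm(axis)
    t = (mesh.vertices - hip) @ (axis / length) / length
    return t <= fraction


def build_hybrid_femur(
    human_femur: LandmarkedMesh,
    austral_femur: LandmarkedMesh,
    proximal_fraction: float = 0.2,
    n_proximal: int = 237,
    n_distal: int = 2500,
    cpd: Optional[CPDConfig] = None,
    seed: int = 0,
) -> LandmarkedMesh:
    """Build a femur with a fossil-shaped proximal end and a human distal end.

    Pipeline: scale the australopith femur to the human femur length; rigidly
    align its proximal region onto the human proximal region (ICP); spread
    ``n_proximal`` control vertices evenly over the human proximal region and
    find their homologues on the australopith surface by staged CPD; pick
    ``n_distal`` control vertices on the human distal end (held fixed); fit
    the TPS from (human proximal + distal) controls to (australopith proximal
    + human distal) controls and apply it to every human femur vertex.  The
    shaft becomes the smooth TPS interpolation between the two ends.
    """
    if not 0.0 < proximal_fraction < 1.0:
        raise ValueError("proximal_fraction must lie in (0, 1)")
    cpd = cpd or CPDConfig()

    def femur_length(mesh: LandmarkedMesh) -> float:
        mask = _proximal_mask(mesh, 1.0)  # validates landmarks
        hip = mesh.landmarks["hip_center"]
        if "knee_center" in mesh.landmarks:
            knee = mesh.landmarks["knee_center"]
        else:
            knee = 0.5 * (
                mesh.landmarks["knee_axis_medial"] + mesh.landmarks["knee_axis_lateral"]
            )
        return float(np.linalg.norm(knee - hip))

    try:
        s = femur_length(human_femur) / femur_length(austral_femur)
        austral = austral_femur.copy()
        hip_a = austral.landmarks["hip_center"].copy()
        austral.vertices = hip_a + s * (austral.vertices - hip_a)
        austral.landmarks = {k: hip_a + s * (v - hip_a) for k, v in austral.landmarks.items()}

        prox_h_mask = _proximal_mask(human_femur, proximal_fraction)
        transform, _, _ = icp_align(
            austral.vertices[_proximal_mask(austral, proximal_fraction)],
            human_femur.vertices[prox_h_mask],
        )
        austral.vertices = transform.apply(austral.vertices)
        austral.landmarks = {k: transform.apply(v) for k, v in austral.landmarks.items()}
    except Exception as err:
        raise RuntimeError(f"hybrid femur: scale/align stage failed: {err}") from err

    try:
        prox_idx = np.flatnonzero(prox_h_mask)
        prox_controls = prox_idx[
            farthest_point_sample(human_femur.vertices[prox_h_mask],
                                  min(n_proximal, prox_h_mask.sum()), seed=seed)
        ]
        prox_src = human_femur.vertices[prox_controls]
        prox_dst = cpd_correspond(prox_src, austral.vertices[_proximal_mask(austral, proximal_fraction + 0.05)], cpd)
    except Exception as err:
        raise RuntimeError(f"hybrid femur: proximal correspondence stage failed: {err}") from err

    try:
        distal_mask = ~_proximal_mask(human_femur, proximal_fraction + 0.1)
        distal_idx = np.flatnonzero(distal_mask)
        distal_controls = distal_idx[
            farthest_point_sample(human_femur.vertices[distal_mask],
                                  min(n_distal, distal_mask.sum()), seed=seed + 1)
        ]
        distal_pts = human_femur.vertices[distal_controls]
        src = np.vstack([prox_src, distal_pts])
        dst = np.vstack([prox_dst, distal_pts])
        warp = fit_tps(src, dst, regularization=0.0)
        hybrid = warp_mesh(warp, human_femur)
    except Exception as err:
        raise RuntimeError(f"hybrid femur: TPS stage failed: {err}") from err
    return hybrid


# ---------------------------------------------------------------------------
# Joint-center scaling and pelvic orientation


def scale_to_joint_centers(
    mesh: LandmarkedMesh,
    joint_landmark_pairs: Mapping[str, Tuple[str, str]],
    target_distances: Mapping[str, float],
) -> LandmarkedMesh:
    """Uniformly scale a mesh so named joint-center distances hit their targets.

    Each entry of ``joint_landmark_pairs`` maps a distance name (e.g.
    ``"hip_to_hip"``) to the two landmark names it spans.  A single isometric
    scale must satisfy every target; conflicting targets raise an error
    listing the implied scales.  Scaling is about the midpoint of the first
    named pair, so shape (all distance ratios) is preserved.
    """
    if not joint_landmark_pairs:
        raise ValueError("need at least one joint landmark pair")
    implied: Dict[str, float] = {}
    for name, (a, b) in joint_landmark_pairs.items():
        if name not in target_distances:
            raise KeyError(f"no target distance for {name!r}")
        target = float(target_distances[name])
        if target <= 0:
            raise ValueError(f"target distance {name!r} must be positive")
        current = float(np.linalg.norm(mesh.landmarks[a] - mesh.landmarks[b]))
        if current <= 0:
            raise ValueError(f"degenerate current distance for {name!r}")
        implied[name] = target / current
    scales = np.array(list(implied.values()))
    if np.max(scales) - np.min(scales) > 1e-9 * np.max(scales):
        raise ValueError(
            "no single uniform scale satisfies all targets; implied scales: "
            + ", ".join(f"{k}={v:.9g}" for k, v in implied.items())
        )
    s = float(np.mean(scales))
    first = next(iter(joint_landmark_pairs.values()))
    center = 0.5 * (mesh.landmarks[first[0]] + mesh.landmarks[first[1]])
    out = mesh.copy()
    if len(out.vertices):
        out.vertices = center + s * (out.vertices - center)
    out.landmarks = {k: center + s * (v - center) for k, v in out.landmarks.items()}
    return out


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def orient_pelvis(
    pelvis: LandmarkedMesh, convention: str = "anterior_pelvic_plane_vertical"
) -> Tuple[LandmarkedMesh, Dict[str, float]]:
    """Rotate a pelvis about its inter-hip-center axis into neutral tilt.

    Neutral means the anterior pelvic plane — through both anterior superior
    iliac spines and the pubic tubercles — is parallel to the coronal (YZ)
    plane, i.e. the ASIS midpoint sits vertically above the pubic-tubercle
    midpoint.  Left-right symmetry fixes the remaining rotations.  Returns the
    rotated mesh and the achieved anterior-pelvic-plane angle and sacral slope
    in degrees.
    """
    if convention != "anterior_pelvic_plane_vertical":
        raise ValueError(f"unknown convention {convention!r}")
    needed = [
        "asis_left", "asis_right", "pubic_tubercle_left", "pubic_tubercle_right",
        "hip_center_left", "hip_center_right",
        "sacral_endplate_anterior", "sacral_endplate_posterior",
    ]
    missing = [n for n in needed if n not in pelvis.landmarks]
    if missing:
        raise KeyError(f"orient_pelvis: missing landmarks {missing}")

    def app_angle(lm: Mapping[str, np.ndarray]) -> float:
        asis_mid = 0.5 * (lm["asis_left"] + lm["asis_right"])
        pt_mid = 0.5 * (lm["pubic_tubercle_left"] + lm["pubic_tubercle_right"])
        v = asis_mid - pt_mid
        return float(np.arctan2(v[0], v[2]))  # tilt of APP off vertical, in sagittal plane

    angle = app_angle(pelvis.landmarks)
    hip_axis = pelvis.landmarks["hip_center_left"] - pelvis.landmarks["hip_center_right"]
    pivot = 0.5 * (pelvis.landmarks["hip_center_left"] + pelvis.landmarks["hip_center_right"])
    # rotate about the inter-hip axis (nominally Y) to zero the APP angle
    sign = 1.0 if hip_axis[1] >= 0 else -1.0
    R = _rotation_about_axis(sign * hip_axis, -angle)
    out = pelvis.copy()
    if len(out.vertices):
        out.vertices = (out.vertices - pivot) @ R.T + pivot
    out.landmarks = {k: R @ (v - pivot) + pivot for k, v in out.landmarks.items()}

    sac = out.landmarks["sacral_endplate_anterior"] - out.landmarks["sacral_endplate_posterior"]
    sacral_slope = float(np.degrees(np.arctan2(sac[2], sac[0])))
    achieved = {
        "anterior_pelvic_plane_deg": float(np.degrees(app_angle(out.landmarks))),
        "sacral_slope_deg": sacral_slope,
    }
    return out, achieved
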