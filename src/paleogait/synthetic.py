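"""Seeded synthetic cohorts, walking trials, and parametric hip geometry.

Everything downstream — morphing, inverse dynamics, recruitment, curve
statistics — is exercised on data from this module, so it is first-class,
tested code.  The generator emulates the study conditions: a cohort of ten
adults (five female, five male) spanning small-to-large body sizes, three
self-selected-speed walking passes each (52-marker trajectories, two force
plates, gait events), and pelvis/femur geometry in two shape variants.

Walking trials are built from planted foot contacts: ankle targets sit on
the floor through stance (with heel-strike and toe-off rockers), swing
follows a smooth quintic, the pelvis rides the stance leg like a partially
flattened inverted pendulum, and closed-form leg inverse kinematics turn
those targets into joint angles.  The ground reaction forces are then
*derived* from the posed model's own whole-body dynamics — the total
external force is the total mass times (COM acceleration minus gravity),
split between the two plates by smooth stance-weight functions, with centers
of pressure and vertical free moments adjusted per frame to close the
moment balance.  Because the kinetics are computed from the same
filtered-marker reconstruction that inverse dynamics uses, noiseless trials
close the force balance to machine precision (documented bound: residual
force below 1% of body weight).
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np

from .core import GRAVITY, GaitTrial, HipShapeParams, PlateRecord, SubjectAnthropometry
from .dynamics import (KinematicsTrajectory, fit_kinematics_from_markers, lowpass,
                       segment_kinematics)
from .model import (COORD_NAMES, SkeletonModel, _CI, build_subject_model,
                    forward_kinematics, marker_positions)
from . import model as _model_mod
from .morphology import LandmarkedMesh, farthest_point_sample

__all__ = [
    "COHORT_RANGES",
    "GAIT_DEFAULTS",
    "GeometryError",
    "generate_cohort",
    "generate_gait_trial",
    "generate_hip_geometry",
]


class GeometryError(ValueError):
    """Raised when shape parameters produce degenerate geometry."""


#: Anthropometry sampling bounds per sex (the generator's documented ranges,
#: spanning small-to-large adults).  hip_breadth and femur_length are drawn
#: as fractions of stature.
COHORT_RANGES = {
    "F": {"stature": (1.50, 1.76), "bmi": (19.0, 27.0)},
    "M": {"stature": (1.62, 1.92), "bmi": (20.0, 28.0)},
    "hip_breadth_frac": (0.095, 0.107),
    "femur_length_frac": (0.235, 0.255),
}

#: Parametric gait profile.  Pelvis oscillation amplitudes are metres per
#: 1.70 m stature; step width and swing foot lift are metres.  Joint angles
#: are not prescribed directly: foot contacts are planted on the floor and
#: the leg angles follow from closed-form inverse kinematics, so the stance
#: foot is stationary under the advancing body (which keeps the required
#: center of pressure inside the foot).  The vertical GRF that results is
#: the classic two-peak stance profile (peaks near 1.1 BW, midstance valley
#: near 0.9 BW) because the plate force is derived from the COM motion.
GAIT_DEFAULTS = {
    "stance_fraction": 0.6,
    "double_support": 0.1,
    "stride_length_factor": 1.60,  # stride length = factor * (femur+shank length)
    "pelvis_osc": {"x": 0.010, "y": 0.015, "z": 0.005},
    "pelvic_rotation": 7.0,  # deg, axial rotation amplitude (advances the swing hip)
    "step_width": 0.10,  # m per 1.70 m stature, ankle-to-ankle
    "swing_lift": 0.035,  # m per 1.70 m stature, mid-swing foot lift
    "heel_rise": 1.1,  # rad, terminal-stance heel-rise (toe rocker) pitch
    "heel_rocker": 0.45,  # rad, initial-contact heel-rocker pitch
    "ankle_lever": 0.13,  # m per 1.70 m stature, rocker pivot-to-ankle lever
    "ride_flatten": 0.65,  # fraction of the compass-gait vertical excursion kept
    "speed_range": (0.7, 1.8),  # m/s, calibrated range
    "trial_variability": 0.03,  # fractional jitter of profile amplitudes per trial
}


def generate_cohort(n_subjects: int, seed: int) -> list[SubjectAnthropometry]:
    """Generate a deterministic cohort with alternating sexes.

    Sexes alternate F, M, F, ... so an even count splits evenly; masses and
    statures are drawn uniformly from :data:`COHORT_RANGES`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        sex = "F" if i % 2 == 0 else "M"
        r = COHORT_RANGES[sex]
        stature = rng.uniform(*r["stature"])
        bmi = rng.uniform(*r["bmi"])
        out.append(SubjectAnthropometry(
            subject_id=f"S{i + 1:02d}",
            sex=sex,
            body_mass=round(bmi * stature**2, 3),
            stature=round(stature, 4),
            hip_breadth=round(stature * rng.uniform(*COHORT_RANGES["hip_breadth_frac"]), 4),
            femur_length=round(stature * rng.uniform(*COHORT_RANGES["femur_length_frac"]), 4),
        ))
    return out


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _stance_weight(phi: np.ndarray, stance: float, ds: float) -> np.ndarray:
    """Smooth load share of a foot whose stance spans phase [0, stance)."""
    phi = np.mod(phi, 1.0)
    w = np.zeros_like(phi)
    w += _smoothstep(phi / ds) * (phi < stance)
    w = np.where(phi >= stance - ds, 1.0 - _smoothstep((phi - (stance - ds)) / ds), w)
    w = np.where((phi >= ds) & (phi < stance - ds), 1.0, w)
    w = np.where(phi >= stance, 0.0, w)
    return w


def generate_gait_trial(
    subject: SubjectAnthropometry,
    walking_speed: float,
    trial_seed: int,
    noise_std: float = 0.0,
    sample_rate: float = 100.0,
    side: str = "right",
    model: Optional[SkeletonModel] = None,
    filter_cutoff: float = 6.0,
) -> GaitTrial:
    """Generate one kinetically consistent walking pass.

    The skeleton (modern-human variant) is posed by planting foot contacts
    and solving closed-form leg inverse kinematics under a prescribed pelvis
    ride (seeded per-trial jitter of the profile amplitudes emulates
    stride-to-stride variability); markers come from the model's template,
    with optional i.i.d. Gaussian noise of ``noise_std`` metres.  Plate
    forces, centers of pressure and free moments are derived from the posed
    model's whole-body dynamics as seen through the ``filter_cutoff``
    marker-processing pipeline, so with ``noise_std=0`` the trial is
    dynamically consistent with its own inverse-dynamics reconstruction.
    Deterministic for fixed ``(subject, walking_speed, trial_seed)``.
    """
    if walking_speed <= 0:
        raise ValueError("walking_speed must be positive")
    lo, hi = GAIT_DEFAULTS["speed_range"]
    if not lo <= walking_speed <= hi:
        warnings.warn(
            f"walking speed {walking_speed} m/s outside calibrated range "
            f"[{lo}, {hi}]; clamping", stacklevel=2,
        )
        walking_speed = float(np.clip(walking_speed, lo, hi))
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    rng = np.random.default_rng(trial_seed)
    var = GAIT_DEFAULTS["trial_variability"]

    def jitter() -> float:
        return 1.0 + var * float(rng.standard_normal())

    if model is None:
        model = build_subject_model(HipShapeParams(variant="human_like"), subject)
    st = subject.stature
    lf = subject.femur_length
    ls = 0.246 * st
    ha = 0.039 * st
    stride_len = GAIT_DEFAULTS["stride_length_factor"] * (lf + 0.246 * st) * jitter()
    T = stride_len / walking_speed
    t0 = 0.4 * T
    n = int(round(1.8 * T * sample_rate)) + 1
    t = np.arange(n) / sample_rate

    other = "left" if side == "right" else "right"
    off = {side: 0.0, other: 0.5}
    phi = {s: (t - t0) / T + off[s] for s in (side, other)}
    phi_r = phi["right"]

    stance = GAIT_DEFAULTS["stance_fraction"]
    osc = GAIT_DEFAULTS["pelvis_osc"]
    sc = st / 1.70
    amp_x = osc["x"] * sc * jitter()
    amp_y = osc["y"] * sc * jitter()
    amp_z = osc["z"] * sc * jitter()
    step_width = GAIT_DEFAULTS["step_width"] * sc * jitter()
    lift = GAIT_DEFAULTS["swing_lift"] * sc * jitter()

    pel_x = walking_speed * t + amp_x * np.sin(4 * np.pi * phi_r)
    pel_y = amp_y * np.sin(2 * np.pi * phi_r + 2.827)
    osc_z = amp_z * np.cos(4 * np.pi * phi_r + 2.513)
    # axial pelvic rotation: positive yaw advances the right hip, so the
    # pelvis leads with the landing side at each initial contact
    yaw = np.radians(GAIT_DEFAULTS["pelvic_rotation"]) * jitter() * np.cos(2 * np.pi * phi_r)
    cy, sy = np.cos(yaw), np.sin(yaw)

    # ankle (shank distal endpoint) targets: fixed on the floor through most
    # of stance, rising with the heel in terminal stance, smooth quintic
    # swing between consecutive contacts
    z_ankle = 0.8 * ha + 0.012
    gamma_max = GAIT_DEFAULTS["heel_rise"] * jitter()
    gamma_ic = GAIT_DEFAULTS["heel_rocker"] * jitter()
    lever = GAIT_DEFAULTS["ankle_lever"] * sc
    ankle = {}
    heel_pitch = {}
    for s in (side, other):
        sgn = 1.0 if s == "left" else -1.0
        ph = phi[s]
        k = np.floor(ph)
        contact_x = lambda kk: walking_speed * (t0 + (kk + 0.5 * stance - off[s]) * T)
        u = np.mod(ph, 1.0)
        sw = np.clip((u - stance) / (1.0 - stance), 0.0, 1.0)
        sig = sw**3 * (10.0 - 15.0 * sw + 6.0 * sw**2)
        # foot pitch: heel-first contact rolling flat (toes up, negative),
        # flat midstance, heel rise into toe-off (toes down, positive),
        # swing morphing back to the landing pitch
        g_st = (gamma_max * _smoothstep((u - 0.42) / 0.18)
                - gamma_ic * (1.0 - _smoothstep(u / 0.12)))
        g_sw = gamma_max + (-gamma_ic - gamma_max) * _smoothstep(sw / 0.75)
        gamma = np.where(u < stance, g_st, g_sw)
        x = np.where(u < stance, contact_x(k), contact_x(k) * (1 - sig) + contact_x(k + 1) * sig)
        # the ankle rides up over the heel/toe rocker pivots
        z = z_ankle + lever * np.sin(np.abs(gamma)) \
            + np.where(u < stance, 0.0, lift * np.sin(np.pi * sw) ** 2)
        y = np.full(n, sgn * 0.5 * step_width)
        ankle[s] = np.column_stack([x, y, z])
        heel_pitch[s] = gamma

    # pelvis height rides the (slightly bent) stance leg like an inverted
    # pendulum, blended across double support by the stance load shares;
    # this is what produces the two-peak vertical GRF
    r_straight = 0.975 * (lf + ls)
    half = subject.hip_breadth / 2
    reaches = []
    for s in (side, other):
        sgn = 1.0 if s == "left" else -1.0
        hip_x = pel_x - sy * sgn * half
        hip_y = pel_y + cy * sgn * half
        horiz2 = (ankle[s][:, 0] - hip_x) ** 2 + (ankle[s][:, 1] - hip_y) ** 2
        reaches.append(ankle[s][:, 2] + np.sqrt(np.maximum(r_straight**2 - horiz2, 1e-6)))
    # smooth minimum of the two legs' reach curves: both legs stay within
    # reach and the double-support valleys emerge naturally
    beta = 150.0
    R2 = np.stack(reaches)
    z_ref = -np.log(np.exp(-beta * R2).sum(axis=0)) / beta
    # keep only part of the compass-gait excursion (humans flatten the COM
    # path with knee flexion and pelvic motion) and smooth the ride so
    # vertical accelerations stay well below 1 g
    # flatten no further than a small foot-hover allowance permits (the
    # flattened ride can lift the pelvis above the exact-contact surface)
    dip = float(np.max(z_ref.mean() - z_ref))
    flatten = max(GAIT_DEFAULTS["ride_flatten"], 1.0 - 0.035 / max(dip, 1e-9))
    z_ref = z_ref.mean() + flatten * (z_ref - z_ref.mean())
    z_ref = lowpass(z_ref, sample_rate, cutoff=4.0)
    pel_z = z_ref + osc_z
    # smoothing and flattening can lift the pelvis above the exact-contact
    # surface; lower the whole ride so feet hover at most ~3 cm
    excess = float(np.max(pel_z - R2.min(axis=0)))
    pel_z = pel_z - max(excess - 0.03, 0.0)

    q = np.zeros((n, len(COORD_NAMES)))
    q[:, _CI["pelvis_x"]] = pel_x
    q[:, _CI["pelvis_y"]] = pel_y
    q[:, _CI["pelvis_z"]] = pel_z
    q[:, _CI["pelvis_rz"]] = yaw

    # closed-form leg inverse kinematics (pelvis orientation is identity):
    # knee from the law of cosines, then hip ab/adduction and flexion from
    # the hip-to-ankle vector, then ankle dorsiflexion keeping the foot level
    for s in ("left", "right"):
        sgn = 1.0 if s == "left" else -1.0
        hip_w = np.column_stack([pel_x - sy * sgn * half, pel_y + cy * sgn * half, pel_z])
        u_world = ankle[s] - hip_w
        # express the hip-to-ankle vector in the (yawed) pelvis frame
        u_vec = np.column_stack([
            cy * u_world[:, 0] + sy * u_world[:, 1],
            -sy * u_world[:, 0] + cy * u_world[:, 1],
            u_world[:, 2],
        ])
        r = np.linalg.norm(u_vec, axis=1)
        r = np.minimum(r, 0.9995 * (lf + ls))
        kappa = np.arccos(np.clip((r**2 - lf**2 - ls**2) / (2 * lf * ls), -1.0, 1.0))
        v = np.column_stack([-ls * np.sin(kappa), np.zeros(n), -(lf + ls * np.cos(kappa))])
        # adduction from the mediolateral component: u_y = -v_z sin(theta)
        theta = np.arcsin(np.clip(-u_vec[:, 1] / v[:, 2], -1.0, 1.0))
        add = -sgn * theta
        w_x = v[:, 0]
        w_z = v[:, 2] * np.cos(theta)
        flex = np.arctan2(w_x * u_vec[:, 2] - w_z * u_vec[:, 0],
                          w_x * u_vec[:, 0] + w_z * u_vec[:, 2])
        q[:, _CI[f"hip_flexion_{s}"]] = flex
        q[:, _CI[f"hip_adduction_{s}"]] = add
        q[:, _CI[f"knee_flexion_{s}"]] = kappa
        # ankle angle: foot level through stance, pitching toes-down with
        # the terminal-stance heel rise
        q[:, _CI[f"ankle_flexion_{s}"]] = kappa - flex - heel_pitch[s]

    # verify the IK closes before smoothing: ankle targets reproduced by
    # forward kinematics up to the documented foot-hover allowance
    kin_raw = KinematicsTrajectory(q=q.copy(), sample_rate=sample_rate)
    for f in (n // 3, 2 * n // 3):
        poses = forward_kinematics(model, kin_raw.posture(f))
        for s in ("left", "right"):
            dev = np.linalg.norm(poses[f"talus_{s}"][1] - ankle[s][f])
            if dev > 4e-2:
                raise RuntimeError(f"gait IK failed to close ({dev:.4f} m at frame {f})")

    # band-limit the trajectory (a few harmonics of the stride rate, kept
    # below the downstream marker-filter cutoff) so the generated motion is
    # smooth through the processing pipeline
    cutoff = float(np.clip(4.0 / T, 3.0, 5.5))
    motion = lowpass(q - np.outer(t, np.eye(len(COORD_NAMES))[_CI["pelvis_x"]]) * walking_speed,
                     sample_rate, cutoff=cutoff)
    q = motion + np.outer(t, np.eye(len(COORD_NAMES))[_CI["pelvis_x"]]) * walking_speed
    kin = KinematicsTrajectory(q=q, sample_rate=sample_rate)

    # noiseless marker geometry (kinetics always use this), then add noise
    clean: Dict[str, np.ndarray] = {name: np.empty((n, 3)) for name in model.marker_local}
    for f in range(n):
        for name, pos in marker_positions(model, kin.posture(f)).items():
            clean[name][f] = pos
    markers = {name: arr.copy() for name, arr in clean.items()}
    if noise_std > 0:
        for name in markers:
            markers[name] += noise_std * rng.standard_normal((n, 3))

    # ground reaction forces from whole-body dynamics, derived from the
    # motion as reconstructed through the documented processing pipeline
    # (filtered markers -> cluster pose fit), so that the published kinetics
    # are exactly consistent with what inverse dynamics will recompute
    kin_recon = fit_kinematics_from_markers(clean, sample_rate, model, filter_cutoff)
    sk = segment_kinematics(model, kin_recon)
    M_tot = model.total_mass
    com = sum(model.segments[s].mass * sk[s]["com"] for s in model.segments) / M_tot
    dt = 1.0 / sample_rate
    a_com = np.gradient(np.gradient(com, dt, axis=0), dt, axis=0)
    F_tot = M_tot * (a_com - GRAVITY)

    stance = GAIT_DEFAULTS["stance_fraction"]
    ds = GAIT_DEFAULTS["double_support"]
    sides_ordered = (side, "left" if side == "right" else "right")
    w = {s: _stance_weight(phi[s], stance, ds) for s in sides_ordered}
    forces = {s: w[s][:, None] * F_tot for s in sides_ordered}

    # base centers of pressure: heel-to-toe progression under the stance foot
    cops = {}
    for s in sides_ordered:
        pre = "L" if s == "left" else "R"
        heel, toe = clean[f"{pre}HEE"], clean[f"{pre}TOE"]
        u = np.clip(np.mod(phi[s], 1.0) / stance, 0.0, 1.0)
        cop = (1 - u[:, None]) * heel + u[:, None] * toe
        cop[:, 2] = 0.0
        cops[s] = cop

    # close the whole-body moment balance with per-frame COP/free-moment
    # corrections (min-norm least squares)
    L = np.zeros((n, 3))
    M_grav = np.zeros((n, 3))
    for s, seg in model.segments.items():
        k = sk[s]
        I_w = np.einsum("fij,jk,flk->fil", k["R"], seg.inertia, k["R"])
        L += seg.mass * np.cross(k["com"], k["v"]) + np.einsum("fij,fj->fi", I_w, k["omega"])
        M_grav += np.cross(k["com"], seg.mass * GRAVITY)
    M_req = np.gradient(L, dt, axis=0) - M_grav
    free = {s: np.zeros(n) for s in sides_ordered}
    ez = np.array([0.0, 0.0, 1.0])
    for f in range(n):
        M0 = sum(np.cross(cops[s][f], forces[s][f]) for s in sides_ordered)
        delta = M_req[f] - M0
        cols = []
        keys = []
        for s in sides_ordered:
            Fv = forces[s][f]
            cols += [np.cross([1.0, 0, 0], Fv), np.cross([0, 1.0, 0], Fv), ez * max(w[s][f], 0.0)]
            keys += [(s, "dx"), (s, "dy"), (s, "tz")]
        A = np.array(cols).T  # (3, 6)
        sol, *_ = np.linalg.lstsq(A, delta, rcond=None)
        for (s, kind), val in zip(keys, sol):
            if kind == "dx":
                cops[s][f, 0] += val
            elif kind == "dy":
                cops[s][f, 1] += val
            else:
                free[s][f] += val * max(w[s][f], 0.0)
    # keep centers of pressure inside the feet; the vertical free moment
    # absorbs the remaining yaw error exactly, the small horizontal moment
    # error stays in the documented residual bound
    for s in sides_ordered:
        pre = "L" if s == "left" else "R"
        heel, toe = clean[f"{pre}HEE"], clean[f"{pre}TOE"]
        lo_x = np.minimum(heel[:, 0], toe[:, 0]) - 0.02
        hi_x = np.maximum(heel[:, 0], toe[:, 0]) + 0.03
        mid_y = 0.5 * (heel[:, 1] + toe[:, 1])
        clamped = cops[s].copy()
        clamped[:, 0] = np.clip(cops[s][:, 0], lo_x, hi_x)
        clamped[:, 1] = np.clip(cops[s][:, 1], mid_y - 0.05, mid_y + 0.05)
        dmz = np.cross(cops[s], forces[s])[:, 2] - np.cross(clamped, forces[s])[:, 2]
        free[s] += dmz
        cops[s] = clamped

    plates = tuple(
        PlateRecord(force=forces[s], cop=cops[s], free_moment=free[s])
        for s in sides_ordered
    )
    events = {"ic": int(round(t0 * sample_rate)),
              "ic_ipsilateral": int(round((t0 + T) * sample_rate))}
    return GaitTrial(
        subject=subject, side=side, marker_trajectories=markers,
        grf_records=plates, events=events, sample_rate=sample_rate,
        meta={
            "plate_feet": sides_ordered, "walking_speed": walking_speed,
            "stride_period": T, "trial_seed": trial_seed, "noise_std": noise_std,
        },
    )


# ---------------------------------------------------------------------------
# Parametric hip geometry


def _tube_mesh(path: np.ndarray, radii: np.ndarray, n_circ: int = 16) -> Tuple[np.ndarray, np.ndarray]:
    """Triangulated tube around a polyline (capped); fixed topology."""
    path = np.asarray(path, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(path)
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([1.0, 0.0, 0.0])
    verts = []
    for i in range(n):
        tz = tangents[i]
        u = ref - (ref @ tz) * tz
        if np.linalg.norm(u) < 1e-6:
            u = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ tz) * tz
        u /= np.linalg.norm(u)
        v = np.cross(tz, u)
        ang = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
        ring = path[i] + radii[i] * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(n - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces += [[a, b, c], [b, d, c]]
    top = len(verts)
    verts = np.vstack([verts, path[0], path[-1]])
    for j in range(n_circ):
        faces.append([top, (j + 1) % n_circ, j])
        base = (n - 1) * n_circ
        faces.append([top + 1, base + j, base + (j + 1) % n_circ])
    return verts, np.array(faces)


def _icosphere(subdivisions: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=int)


def generate_hip_geometry(
    params: HipShapeParams, subject: SubjectAnthropometry
) -> Tuple[LandmarkedMesh, LandmarkedMesh]:
    """Parametric pelvis and (left) femur meshes for a shape variant.

    Both variants share vertex count, connectivity and a 63-name pelvis
    landmark schema, so any variant pair is directly usable as a TPS
    source/target.  At equal subject ``hip_breadth`` the inter-hip-center
    distance is identical across variants; the australopith-like preset
    compresses the pelvis anteroposteriorly, weakens the anterior wrap of
    the abductor origins, and lengthens the femoral neck.
    """
    hb, lf = subject.hip_breadth, subject.femur_length
    ps = hb / params.biacetabular_breadth_ratio
    ap = params.ap_depth_ratio
    flare = np.radians(params.iliac_flare_angle)
    ax, ay, az = 0.40 * ps * ap, 0.62 * hb, 0.45 * ps
    if min(ax, ay, az) < 0.01 * hb:
        raise GeometryError(f"degenerate pelvis semi-axes ({ax:.4f}, {ay:.4f}, {az:.4f})")

    base_v, faces = _icosphere(3)
    verts = base_v * np.array([ax, ay, az])
    # iliac blades shear anteriorly with flare; quadratic in height and
    # smooth over the whole surface so landmark warps stay well-behaved
    wrap = 0.20 * ps * ap * np.sin(flare) * ((base_v[:, 2] + 1.0) / 2.0) ** 2
    verts[:, 0] += wrap

    lm: Dict[str, np.ndarray] = {}
    lm["hip_center_left"] = np.array([0.0, hb / 2, 0.0])
    lm["hip_center_right"] = np.array([0.0, -hb / 2, 0.0])
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        asis = _model_mod._asis_position(subject, params, sgn)
        lm[f"asis_{side}"] = asis
        lm[f"psis_{side}"] = np.array([-0.22 * ps * ap, sgn * 0.15 * ps, 0.30 * ps])
        # neutral construction pose: pubic tubercles vertically below the ASISs
        lm[f"pubic_tubercle_{side}"] = np.array([asis[0], sgn * 0.06 * ps, -0.14 * ps])
        lm[f"ischial_tuberosity_{side}"] = np.array([-0.24 * ps * ap, sgn * 0.18 * hb, -0.14 * ps])
        lm[f"iliac_crest_{side}"] = np.array([0.02 * ps * ap, sgn * 0.55 * hb, 0.50 * ps])
        hip = lm[f"hip_center_{side}"]
        for label, psi in (("anterior", flare), ("middle", 0.5 * (flare + np.radians(-65))),
                           ("posterior", np.radians(-65.0))):
            lm[f"gluteus_medius_origin_{label}_{side}"] = hip + np.array([
                0.42 * ps * np.sin(psi) * ap,
                sgn * (0.08 + 0.10 * np.cos(psi)) * hb,
                (0.40 + 0.08 * np.cos(psi)) * ps,
            ])
        for label, psi in (("anterior", 0.9 * flare), ("middle", 0.45 * flare + np.radians(-27.5)),
                           ("posterior", np.radians(-55.0))):
            lm[f"gluteus_minimus_origin_{label}_{side}"] = hip + np.array([
                0.30 * ps * np.sin(psi) * ap,
                sgn * (0.06 + 0.09 * np.cos(psi)) * hb,
                (0.26 + 0.06 * np.cos(psi)) * ps,
            ])
        for label, psi, frac in (("superior", np.radians(-72.0), 0.0),
                                 ("middle", np.radians(-98.0), 0.5),
                                 ("inferior", np.radians(-125.0), 1.0)):
            lm[f"gluteus_maximus_origin_{label}_{side}"] = hip + np.array([
                0.50 * ps * np.sin(psi) * ap,
                sgn * (0.14 + 0.10 * np.cos(psi)) * hb,
                (0.34 - 0.30 * frac) * ps,
            ])
    # sacral endplate built at the generator's target slope (~30 deg) in the
    # neutral (APP vertical) construction pose
    slope = np.radians(30.0)
    ant = np.array([-0.10 * ps * ap, 0.0, 0.30 * ps])
    lm["sacral_endplate_anterior"] = ant
    lm["sacral_endplate_posterior"] = ant - 0.05 * np.array([np.cos(slope), 0.0, np.sin(slope)])
    # fill the schema to 63 with evenly spread homologous surface points
    # (sampled on the undeformed sphere so indices match across variants)
    n_fill = 63 - len(lm)
    fill_idx = farthest_point_sample(base_v, n_fill, seed=12345)
    for k, vi in enumerate(fill_idx):
        lm[f"surface_{k:02d}"] = verts[vi].copy()
    assert len(lm) == 63
    pelvis = LandmarkedMesh(vertices=verts, faces=faces, landmarks=lm)

    # left femur as a capped tube: head -> neck -> trochanter -> shaft -> condyles
    d_neck = 0.13 * lf * params.neck_length_ratio
    r_head = 0.055 * lf
    if d_neck <= 1.1 * r_head:
        raise GeometryError(
            f"femoral neck length {d_neck:.4f} m not clear of head radius {r_head:.4f} m"
        )
    path = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 0.5 * d_neck, 0.008],
        [-0.003, d_neck, 0.012],
        [0.0, 0.9 * d_neck, -0.08 * lf],
        [0.0, 0.35 * d_neck, -0.35 * lf],
        [0.0, 0.012, -0.70 * lf],
        [0.0, 0.0, -0.95 * lf],
        [0.0, 0.0, -lf],
    ])
    radii = np.array([r_head, 0.55 * r_head, 0.45 * r_head, 0.35 * r_head,
                      0.28 * r_head, 0.28 * r_head, 0.5 * r_head, 0.65 * r_head])
    # densify along the bone so the default control-vertex counts (237
    # proximal, 2500 distal) fit comfortably on the surface
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
    s /= s[-1]
    sd = np.linspace(0.0, 1.0, 75)
    dense_path = np.column_stack([np.interp(sd, s, path[:, j]) for j in range(3)])
    dense_radii = np.interp(sd, s, radii)
    fv, ff = _tube_mesh(dense_path, dense_radii, n_circ=48)
    femur = LandmarkedMesh(vertices=fv, faces=ff, landmarks={
        "hip_center": np.array([0.0, 0.0, 0.0]),
        "greater_trochanter": np.array([-0.003, d_neck, 0.012]),
        "lesser_trochanter": np.array([-0.01, 0.4 * d_neck, -0.05 * lf]),
        "knee_center": np.array([0.0, 0.0, -lf]),
        "knee_axis_medial": np.array([0.0, -0.045 * lf / 0.42, -lf]),
        "knee_axis_lateral": np.array([0.0, 0.045 * lf / 0.42, -lf]),
    })
    return pelvis, femur
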