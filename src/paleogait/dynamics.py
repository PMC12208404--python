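"""Inverse dynamics: marker-driven kinematics, net joint loads, residuals.

The chain is the classic one: low-pass filter the measured signals, fit the
rigid-segment model pose frame by frame, double-differentiate, and run a
recursive Newton–Euler pass from the feet up to the pelvis.  Whole-body
force/moment imbalance is reported as a residual wrench at the pelvis and is
never silently corrected.

Pose fitting is hierarchical: each segment's orientation comes from a
least-squares (Kabsch) fit of its own marker cluster, and joint angles are
extracted from the relative rotations in the model's joint conventions.  With
noiseless markers this recovers the generating angles exactly; with noise it
is a documented approximation to a full joint-constrained trajectory
optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .core import GRAVITY, GaitTrial
from .model import (
    COORD_NAMES, RECRUITED_DOFS, Posture, SkeletonModel, _CI, _Rx, _Ry, _Rz,
    forward_kinematics,
)

__all__ = [
    "KinematicsTrajectory",
    "JointLoads",
    "fit_kinematics",
    "net_joint_loads",
    "residual_loads",
    "extract_stride",
    "generalized_net_torques",
    "segment_kinematics",
    "lowpass",
]


def lowpass(x: np.ndarray, sample_rate: float, cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-lag Butterworth low-pass along axis 0 (4th order, 6 Hz default)."""
    if cutoff <= 0 or cutoff >= sample_rate / 2:
        return np.asarray(x, dtype=float)
    b, a = butter(order // 2, cutoff / (sample_rate / 2))  # filtfilt doubles the order
    return filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


@dataclass
class KinematicsTrajectory:
    """Generalized-coordinate time series with derived derivatives."""

    q: np.ndarray  # (n_frames, n_coords), ordering COORD_NAMES
    sample_rate: float
    qd: np.ndarray = field(init=False)
    qdd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.all(np.isfinite(self.q)):
            raise ValueError("kinematics must be finite")
        dt = 1.0 / self.sample_rate
        self.qd = np.gradient(self.q, dt, axis=0)
        self.qdd = np.gradient(self.qd, dt, axis=0)

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    def posture(self, frame: int) -> Posture:
        return Posture(self.q[frame])


@dataclass
class JointLoads:
    """Per-joint net moment and intersegmental force time series (lab axes).

    ``force[joint]`` is the intersegmental force the distal segment applies
    to the proximal one (so the stance-limb vertical hip force is positive);
    ``moment[joint]`` is the net joint moment acting on the distal segment —
    the moment the muscles crossing that joint must generate.
    """

    moment: Dict[str, np.ndarray]
    force: Dict[str, np.ndarray]
    sample_rate: float

    def __post_init__(self) -> None:
        for d in (self.moment, self.force):
            for k, v in d.items():
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"non-finite loads for joint {k}")


# ---------------------------------------------------------------------------
# Pose fitting


def _kabsch_rt(local: np.ndarray, world: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    lc, wc = local.mean(axis=0), world.mean(axis=0)
    H = (local - lc).T @ (world - wc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, wc - R @ lc


def _euler_yxz(M: np.ndarray) -> Tuple[float, float, float]:
    """Angles (a, b, c) with M = Ry(a) @ Rx(b) @ Rz(c)."""
    b = np.arcsin(np.clip(-M[1, 2], -1.0, 1.0))
    a = np.arctan2(M[0, 2], M[2, 2])
    c = np.arctan2(M[1, 0], M[1, 1])
    return a, b, c


def _euler_zyx(M: np.ndarray) -> Tuple[float, float, float]:
    """Angles (rz, ry, rx) with M = Rz(rz) @ Ry(ry) @ Rx(rx)."""
    ry = np.arcsin(np.clip(-M[2, 0], -1.0, 1.0))
    rz = np.arctan2(M[1, 0], M[0, 0])
    rx = np.arctan2(M[2, 1], M[2, 2])
    return rz, ry, rx


def _fill_gaps(traj: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs up to ``max_gap`` frames; else raise."""
    out = traj.copy()
    bad = ~np.all(np.isfinite(traj), axis=1)
    if not bad.any():
        return out
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if len(run) > max_gap or run[0] == 0 or run[-1] == len(traj) - 1:
            raise ValueError(
                f"marker dropout beyond gap-fill limit in frames {run[0]}..{run[-1]}"
            )
        lo, hi = run[0] - 1, run[-1] + 1
        w = (run - lo) / (hi - lo)
        out[run] = (1 - w[:, None]) * traj[lo] + w[:, None] * traj[hi]
    return out


def fit_kinematics(
    trial: GaitTrial,
    model: SkeletonModel,
    filter_cutoff: float = 6.0,
    max_gap: int = 10,
) -> KinematicsTrajectory:
    """Fit the model's generalized coordinates to the trial's markers.

    Markers are gap-filled, low-pass filtered (zero-lag Butterworth,
    ``filter_cutoff`` Hz), and each segment's pose is fitted per frame by
    least squares over its marker cluster; joint angles follow from the
    relative rotations.  Velocities and accelerations come from central
    differences at the trial sample rate.
    """
    traj = {}
    for mname in model.marker_local:
        if mname not in trial.marker_trajectories:
            raise KeyError(f"trial is missing marker {mname!r}")
        traj[mname] = trial.marker_trajectories[mname]
    return fit_kinematics_from_markers(
        traj, trial.sample_rate, model, filter_cutoff, max_gap)


def fit_kinematics_from_markers(
    trajectories: Mapping[str, np.ndarray],
    sample_rate: float,
    model: SkeletonModel,
    filter_cutoff: float = 6.0,
    max_gap: int = 10,
) -> KinematicsTrajectory:
    """Marker-cluster pose fit on raw trajectories (see fit_kinematics)."""
    by_segment: Dict[str, List[str]] = {}
    for mname, (seg, _) in model.marker_local.items():
        by_segment.setdefault(seg, []).append(mname)
    for seg in ("pelvis", "thigh_left", "shank_left", "foot_left",
                "thigh_right", "shank_right", "foot_right"):
        locs = np.array([model.marker_local[m][1] for m in by_segment[seg]])
        if len(locs) < 3 or np.linalg.matrix_rank(locs - locs.mean(axis=0)) < 2:
            raise ValueError(f"segment {seg}: need >= 3 non-collinear markers")

    filtered: Dict[str, np.ndarray] = {}
    for mname in model.marker_local:
        filled = _fill_gaps(np.asarray(trajectories[mname], dtype=float), max_gap)
        filtered[mname] = lowpass(filled, sample_rate, filter_cutoff)

    n = next(iter(filtered.values())).shape[0]
    q = np.zeros((n, len(COORD_NAMES)))

    def seg_rotation(seg: str, f: int) -> Tuple[np.ndarray, np.ndarray]:
        names = by_segment[seg]
        local = np.array([model.marker_local[m][1] for m in names])
        world = np.array([filtered[m][f] for m in names])
        return _kabsch_rt(local, world)

    for f in range(n):
        R_pel, p_pel = seg_rotation("pelvis", f)
        rz, ry, rx = _euler_zyx(R_pel)
        q[f, _CI["pelvis_x"]:_CI["pelvis_z"] + 1] = p_pel
        q[f, _CI["pelvis_rx"]] = rx
        q[f, _CI["pelvis_ry"]] = ry
        q[f, _CI["pelvis_rz"]] = rz
        for side, sgn in (("left", 1.0), ("right", -1.0)):
            R_th, _ = seg_rotation(f"thigh_{side}", f)
            a, b, c = _euler_yxz(R_pel.T @ R_th)
            q[f, _CI[f"hip_flexion_{side}"]] = -a
            q[f, _CI[f"hip_adduction_{side}"]] = -sgn * b
            q[f, _CI[f"hip_rotation_{side}"]] = sgn * c
            R_sh, _ = seg_rotation(f"shank_{side}", f)
            a, b, c = _euler_yxz(R_th.T @ R_sh)
            q[f, _CI[f"knee_flexion_{side}"]] = a
            R_ft, _ = seg_rotation(f"foot_{side}", f)
            M = R_sh.T @ R_ft  # Ry(-ankle) @ Rx(sgn * subtalar)
            ankle = -np.arctan2(M[0, 2], M[2, 2])
            q[f, _CI[f"ankle_flexion_{side}"]] = ankle
            q[f, _CI[f"subtalar_{side}"]] = sgn * np.arcsin(np.clip(-M[1, 2], -1, 1))
    # the nonlinear pose extraction regenerates content above the marker
    # filter band; filter the coordinates once more before differentiation
    q = lowpass(q, sample_rate, filter_cutoff)
    return KinematicsTrajectory(q=q, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# Segment world kinematics


def segment_kinematics(
    model: SkeletonModel, kin: KinematicsTrajectory
) -> Dict[str, Dict[str, np.ndarray]]:
    """World pose, COM motion and angular velocity/acceleration per segment."""
    n = kin.n_frames
    dt = 1.0 / kin.sample_rate
    names = list(model.segments)
    R = {s: np.empty((n, 3, 3)) for s in names}
    org = {s: np.empty((n, 3)) for s in names}
    for f in range(n):
        poses = forward_kinematics(model, kin.posture(f))
        for s in names:
            R[s][f], org[s][f] = poses[s]
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for s in names:
        seg = model.segments[s]
        com = org[s] + np.einsum("fij,j->fi", R[s], seg.com_local)
        v = np.gradient(com, dt, axis=0)
        a = np.gradient(v, dt, axis=0)
        Rdot = np.gradient(R[s], dt, axis=0)
        W = np.einsum("fij,fkj->fik", Rdot, R[s])  # Rdot @ R^T, skew(omega)
        omega = np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)
        alpha = np.gradient(omega, dt, axis=0)
        out[s] = {
            "R": R[s], "origin": org[s], "com": com,
            "v": v, "a": a, "omega": omega, "alpha": alpha,
        }
    return out


def _external_wrenches(
    model: SkeletonModel, trial: GaitTrial, grf_cutoff: float
) -> Dict[str, Dict[str, np.ndarray]]:
    """Plate wrenches keyed by the foot segment they act on.

    ``grf_cutoff`` of 0 (the default used by the load computations) takes
    the plate signals as published; a positive value low-pass filters them,
    which is only needed for noisy measured plates.
    """
    plate_feet = trial.meta.get(
        "plate_feet",
        (trial.side, "left" if trial.side == "right" else "right"),
    )
    out = {}
    for plate, foot_side in zip(trial.grf_records, plate_feet):
        out[f"foot_{foot_side}"] = {
            "force": lowpass(plate.force, trial.sample_rate, grf_cutoff),
            "cop": lowpass(plate.cop, trial.sample_rate, grf_cutoff),
            "free_moment": lowpass(plate.free_moment, trial.sample_rate, grf_cutoff),
        }
    return out


# ---------------------------------------------------------------------------
# Newton-Euler recursion


def newton_euler(
    model: SkeletonModel,
    sk: Dict[str, Dict[str, np.ndarray]],
    ext: Dict[str, Dict[str, np.ndarray]],
) -> JointLoads:
    """Recursive Newton–Euler pass over precomputed segment kinematics.

    ``sk`` holds per-segment world kinematics (as from
    :func:`segment_kinematics`, or supplied analytically for verification);
    ``ext`` maps segment names to external wrenches (force, cop,
    free_moment).  Moments are taken about the joint centers and, like
    forces, expressed in lab axes (X travel, Y mediolateral, Z vertical).
    """
    n = len(next(iter(sk.values()))["com"])

    joint_of = {  # distal segment -> joint name
        "thigh_left": "hip_left", "thigh_right": "hip_right",
        "shank_left": "knee_left", "shank_right": "knee_right",
        "talus_left": "ankle_left", "talus_right": "ankle_right",
        "foot_left": "subtalar_left", "foot_right": "subtalar_right",
        "hat": "lumbar",
    }
    children: Dict[str, List[str]] = {s: model.children(s) for s in model.segments}

    # F[s]: force on segment s from its parent; M[s]: moment about s's
    # proximal joint on s from its parent
    F: Dict[str, np.ndarray] = {}
    M: Dict[str, np.ndarray] = {}

    def recurse(s: str) -> None:
        for c in children[s]:
            recurse(c)
        seg = model.segments[s]
        k = sk[s]
        I_world = np.einsum("fij,jk,flk->fil", k["R"], seg.inertia, k["R"])
        f_ext = np.zeros((n, 3))
        m_ext_about_com = np.zeros((n, 3))
        if s in ext:
            w = ext[s]
            f_ext = w["force"]
            m_ext_about_com = (
                np.cross(w["cop"] - k["com"], w["force"])
                + np.stack([np.zeros(n), np.zeros(n), w["free_moment"]], axis=1)
            )
        Fs = seg.mass * (k["a"] - GRAVITY) - f_ext
        # moment balance about the COM, then shift the joint-force lever in
        Mcom = (
            np.einsum("fij,fj->fi", I_world, k["alpha"])
            + np.cross(k["omega"], np.einsum("fij,fj->fi", I_world, k["omega"]))
            - m_ext_about_com
        )
        for c in children[s]:
            Fs = Fs + F[c]
            Mcom = Mcom + M[c] + np.cross(sk[c]["origin"] - k["com"], F[c])
        Ms = Mcom - np.cross(k["origin"] - k["com"], Fs)
        F[s], M[s] = Fs, Ms

    for s in children["pelvis"]:
        recurse(s)

    moment = {}
    force = {}
    for s, jname in joint_of.items():
        if s in F:
            moment[jname] = M[s]
            force[jname] = -F[s]  # force the distal segment applies to the proximal one
    return JointLoads(moment=moment, force=force, sample_rate=0.0)


def net_joint_loads(
    model: SkeletonModel,
    kin: KinematicsTrajectory,
    trial: GaitTrial,
    grf_cutoff: float = 0.0,
) -> JointLoads:
    """Net joint loads for a trial: filter, differentiate, recurse.

    Convenience wrapper combining :func:`segment_kinematics` (central
    differences at the trial sample rate) with :func:`newton_euler` and the
    trial's filtered plate wrenches.
    """
    if kin.n_frames != trial.n_frames:
        raise ValueError("kinematics and trial are not time-synchronized")
    sk = segment_kinematics(model, kin)
    ext = _external_wrenches(model, trial, grf_cutoff)
    loads = newton_euler(model, sk, ext)
    loads.sample_rate = kin.sample_rate
    return loads


def residual_loads(
    model: SkeletonModel,
    kin: KinematicsTrajectory,
    trial: GaitTrial,
    grf_cutoff: float = 0.0,
) -> Dict[str, np.ndarray]:
    """Whole-body Newton–Euler imbalance assigned at the pelvis origin.

    Returns ``{"force": (n, 3), "moment": (n, 3)}``; a perfectly measured and
    fitted trial would give zeros.  Reported, never corrected.
    """
    sk = segment_kinematics(model, kin)
    ext = _external_wrenches(model, trial, grf_cutoff)
    n = kin.n_frames
    dt = 1.0 / kin.sample_rate

    F_net = np.zeros((n, 3))
    L = np.zeros((n, 3))  # angular momentum about the lab origin
    M_ext = np.zeros((n, 3))
    for s, seg in model.segments.items():
        k = sk[s]
        F_net += seg.mass * k["a"]
        I_world = np.einsum("fij,jk,flk->fil", k["R"], seg.inertia, k["R"])
        L += seg.mass * np.cross(k["com"], k["v"]) + np.einsum("fij,fj->fi", I_world, k["omega"])
        M_ext += np.cross(k["com"], seg.mass * GRAVITY)
        F_net -= seg.mass * GRAVITY
    for w in ext.values():
        F_net -= w["force"]
        M_ext += np.cross(w["cop"], w["force"])
        M_ext[:, 2] += w["free_moment"]
    Ldot = np.gradient(L, dt, axis=0)
    M_res_origin = Ldot - M_ext
    pelvis = sk["pelvis"]["origin"]
    # total residual force already in F_net; move the moment to the pelvis
    M_res = M_res_origin - np.cross(pelvis, F_net)
    return {"force": F_net, "moment": M_res}


def extract_stride(trial: GaitTrial) -> Tuple[slice, str]:
    """Half-open frame window [IC, ipsilateral IC) and the stance side."""
    ic = trial.events["ic"]
    ic2 = trial.events["ic_ipsilateral"]
    if ic2 <= ic:
        raise ValueError("missing or out-of-order ipsilateral initial contact")
    return slice(ic, ic2), trial.side


# ---------------------------------------------------------------------------
# Generalized torques for the recruitment solver


def generalized_net_torques(
    model: SkeletonModel,
    kin: KinematicsTrajectory,
    loads: JointLoads,
    dofs: Sequence[str] = RECRUITED_DOFS,
) -> np.ndarray:
    """Project net joint moments onto the joint coordinate axes.

    The result (n_frames, n_dofs) is the generalized torque conjugate to each
    recruited coordinate — exactly what the muscle generalized forces
    (tendon-excursion moment arms times muscle forces) must balance.
    """
    n = kin.n_frames
    out = np.zeros((n, len(dofs)))
    for f in range(n):
        p = kin.posture(f)
        poses = forward_kinematics(model, p)
        R_pel = poses["pelvis"][0]
        for i, dof in enumerate(dofs):
            side = "left" if dof.endswith("left") else "right"
            sgn = 1.0 if side == "left" else -1.0
            if dof.startswith("hip"):
                Mv = loads.moment[f"hip_{side}"][f]
                flex = p[f"hip_flexion_{side}"]
                add = p[f"hip_adduction_{side}"]
                if dof.startswith("hip_flexion"):
                    axis = R_pel @ np.array([0.0, -1.0, 0.0])
                elif dof.startswith("hip_adduction"):
                    axis = R_pel @ _Ry(-flex) @ np.array([-sgn, 0.0, 0.0])
                else:
                    axis = R_pel @ _Ry(-flex) @ _Rx(-sgn * add) @ np.array([0.0, 0.0, sgn])
            elif dof.startswith("knee"):
                Mv = loads.moment[f"knee_{side}"][f]
                axis = poses[f"thigh_{side}"][0] @ np.array([0.0, 1.0, 0.0])
            else:  # ankle dorsiflexion
                Mv = loads.moment[f"ankle_{side}"][f]
                axis = poses[f"shank_{side}"][0] @ np.array([0.0, -1.0, 0.0])
            out[f, i] = Mv @ axis
    return out
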