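"""Rigid-segment musculoskeletal model with parametric hip muscle geometry.

The skeleton is the conventional lower-body rigid-segment model: a pelvis
root carrying a lumped head-arms-trunk (HAT) segment and, per side, thigh,
shank, talus and foot.  Joints are a 3-DOF ball at the hip and hinges at the
knee, ankle (dorsi/plantarflexion) and subtalar joint.  Muscles are
straight-line elements with optional via points; the gluteal groups are
subdivided into fans of 12 elements per side whose origin placement on the
iliac blade is governed by :class:`~paleogait.core.HipShapeParams` — this is
where the two hip shape variants differ mechanically.  Joint-center
distances (hip-to-hip, hip-to-knee) are identical across variants by
construction, so variants can consume identical kinematics and kinetics.

Muscle moment arms use the tendon-excursion relation r = -dL/dtheta,
evaluated by central finite differences on the generalized coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GRAVITY, HipShapeParams, SubjectAnthropometry
from .morphology import TPSWarp, apply_tps

__all__ = [
    "BodySegment",
    "MuscleElement",
    "SkeletonModel",
    "Posture",
    "COORD_NAMES",
    "RECRUITED_DOFS",
    "build_subject_model",
    "forward_kinematics",
    "marker_positions",
    "muscle_length",
    "all_muscle_lengths",
    "moment_arm",
    "moment_arm_matrix",
    "morph_attachments",
    "check_muscle_paths",
]

SIDES = ("left", "right")

#: Generalized coordinate ordering used by every Posture vector.
COORD_NAMES: Tuple[str, ...] = (
    "pelvis_x", "pelvis_y", "pelvis_z", "pelvis_rx", "pelvis_ry", "pelvis_rz",
    "hip_flexion_left", "hip_adduction_left", "hip_rotation_left",
    "knee_flexion_left", "ankle_flexion_left", "subtalar_left",
    "hip_flexion_right", "hip_adduction_right", "hip_rotation_right",
    "knee_flexion_right", "ankle_flexion_right", "subtalar_right",
)
_CI = {name: i for i, name in enumerate(COORD_NAMES)}

#: Degrees of freedom entering the muscle-recruitment constraint set:
#: bilateral hip ball joint plus knee and ankle flexion.
RECRUITED_DOFS: Tuple[str, ...] = tuple(
    f"{dof}_{side}"
    for side in SIDES
    for dof in ("hip_flexion", "hip_adduction", "hip_rotation", "knee_flexion", "ankle_flexion")
)

#: Soft joint limits in radians (warn outside; plumbing sanity check).
JOINT_LIMITS = {
    "hip_flexion": (-0.6, 2.4),
    "hip_adduction": (-1.0, 0.7),
    "hip_rotation": (-1.0, 1.0),
    "knee_flexion": (-0.2, 2.6),
    "ankle_flexion": (-1.0, 0.8),
    "subtalar": (-0.6, 0.6),
}

# Segment mass fractions of body mass (per segment; HAT takes the remainder
# so the total is exactly the body mass).
MASS_FRACTIONS = {"pelvis": 0.1117, "thigh": 0.1416, "shank": 0.0433, "talus": 0.0020, "foot": 0.0117}


def _Rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _Ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _Rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class BodySegment:
    """One rigid segment: inertial properties in its local frame."""

    name: str
    mass: float
    com_local: np.ndarray  # (3,) in segment frame, origin at proximal joint
    inertia: np.ndarray  # (3, 3) about COM, segment frame
    length: float
    parent: Optional[str]  # parent segment name (None for pelvis)
    origin_in_parent: np.ndarray  # proximal joint position in parent frame

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be non-negative")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ValueError(f"segment {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) < -1e-12):
            raise ValueError(f"segment {self.name}: inertia must be PSD")


@dataclass
class MuscleElement:
    """A straight-line muscle element with optional via points."""

    name: str
    anatomical_group: str
    side: str
    origin: Tuple[str, np.ndarray]  # (segment, local point)
    insertion: Tuple[str, np.ndarray]
    via_points: List[Tuple[str, np.ndarray]] = field(default_factory=list)
    max_strength: float = 1.0  # N

    def __post_init__(self) -> None:
        if self.max_strength <= 0:
            raise ValueError(f"element {self.name}: max_strength must be positive")

    def path(self) -> List[Tuple[str, np.ndarray]]:
        return [self.origin, *self.via_points, self.insertion]


@dataclass
class Posture:
    """Generalized coordinate vector (ordering :data:`COORD_NAMES`)."""

    q: np.ndarray
    qd: Optional[np.ndarray] = None
    qdd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(COORD_NAMES),):
            raise ValueError(f"posture must have {len(COORD_NAMES)} coordinates")

    def __getitem__(self, name: str) -> float:
        return float(self.q[_CI[name]])

    def replace_coord(self, name: str, value: float) -> "Posture":
        q = self.q.copy()
        q[_CI[name]] = value
        return Posture(q)

    def warn_outside_limits(self) -> List[str]:
        bad = []
        for side in SIDES:
            for dof, (lo, hi) in JOINT_LIMITS.items():
                v = self[f"{dof}_{side}"]
                if not lo <= v <= hi:
                    bad.append(f"{dof}_{side}={v:.3f}")
        if bad:
            warnings.warn(f"posture outside joint limits: {bad}", stacklevel=2)
        return bad


@dataclass
class SkeletonModel:
    """Segments, joints and muscle elements for one subject and hip variant."""

    subject: SubjectAnthropometry
    variant: str
    shape_params: HipShapeParams
    segments: Dict[str, BodySegment]
    muscles: List[MuscleElement]
    marker_local: Dict[str, Tuple[str, np.ndarray]]  # marker -> (segment, local)

    # flattened muscle-path arrays (built lazily) for vectorized lengths
    _path_seg: Optional[np.ndarray] = None
    _path_loc: Optional[np.ndarray] = None
    _path_ptr: Optional[np.ndarray] = None
    _seg_order: Optional[List[str]] = None

    def __post_init__(self) -> None:
        total = sum(s.mass for s in self.segments.values())
        if abs(total - self.subject.body_mass) > 1e-9:
            raise ValueError("segment masses must sum to the subject body mass")

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def children(self, name: str) -> List[str]:
        return [s.name for s in self.segments.values() if s.parent == name]

    def elements_of(self, group: str, side: Optional[str] = None) -> List[MuscleElement]:
        return [
            m for m in self.muscles
            if m.anatomical_group == group and (side is None or m.side == side)
        ]

    def _ensure_path_arrays(self) -> None:
        if self._path_seg is not None:
            return
        self._seg_order = list(self.segments)
        seg_index = {s: i for i, s in enumerate(self._seg_order)}
        seg_ids, locs, ptr = [], [], [0]
        for m in self.muscles:
            for seg, loc in m.path():
                seg_ids.append(seg_index[seg])
                locs.append(loc)
            ptr.append(len(seg_ids))
        self._path_seg = np.array(seg_ids)
        self._path_loc = np.array(locs)
        self._path_ptr = np.array(ptr)


# ---------------------------------------------------------------------------
# Model construction


def _pelvis_scale(subject: SubjectAnthropometry, params: HipShapeParams) -> float:
    """Characteristic pelvis (blade) scale after matching the hip spacing.

    A relatively broad biacetabular spacing, rescaled so the inter-hip
    distance matches the subject, leaves the rest of the pelvis — iliac
    blades included — proportionally smaller.
    """
    return subject.hip_breadth / params.biacetabular_breadth_ratio


def _asis_position(subject: SubjectAnthropometry, params: HipShapeParams, sgn: float) -> np.ndarray:
    """ASIS location in the pelvis frame; flare wraps it anteriorly."""
    ps = _pelvis_scale(subject, params)
    hb = subject.hip_breadth
    flare = np.radians(params.iliac_flare_angle)
    return np.array([
        0.45 * ps * np.sin(flare + np.radians(8.0)) * params.ap_depth_ratio,
        sgn * (hb / 2 + 0.10 * ps * np.cos(flare)),
        0.38 * ps,
    ])


def _build_hip_muscles(
    subject: SubjectAnthropometry, params: HipShapeParams, side: str,
    n_gluteals: int = 12,
) -> List[MuscleElement]:
    """Parametric hip and leg muscle elements for one side."""
    sgn = 1.0 if side == "left" else -1.0
    hb, lf = subject.hip_breadth, subject.femur_length
    ls = 0.246 * subject.stature
    fl = 0.152 * subject.stature
    ha = 0.039 * subject.stature
    ps = _pelvis_scale(subject, params)
    ap = params.ap_depth_ratio
    flare = np.radians(params.iliac_flare_angle)
    hip = np.array([0.0, sgn * hb / 2, 0.0])
    d_neck = 0.13 * lf * params.neck_length_ratio

    elements: List[MuscleElement] = []

    def add(group: str, k: int, origin: np.ndarray, insertion: Tuple[str, np.ndarray],
            via: Optional[List[Tuple[str, np.ndarray]]] = None) -> None:
        elements.append(MuscleElement(
            name=f"{group}_{side}_{k}", anatomical_group=group, side=side,
            origin=("pelvis", origin), insertion=insertion, via_points=via or [],
        ))

    # gluteus medius: fan on the outer iliac blade from posterior to the
    # anterior wrap limit set by the flare angle
    psis = np.linspace(np.radians(-65.0), flare, n_gluteals)
    for k, psi in enumerate(psis):
        # lateral reach of the blade tracks the hip spacing (flaring crests);
        # blade height tracks the blade size
        origin = hip + np.array([
            0.42 * ps * np.sin(psi) * ap,
            sgn * (0.08 + 0.10 * np.cos(psi)) * hb,
            (0.40 + 0.08 * np.cos(psi)) * ps,
        ])
        ins = np.array([-0.01 + 0.002 * (k - n_gluteals / 2) / n_gluteals,
                        sgn * d_neck, 0.005])
        add("gluteus_medius", k, origin, (f"thigh_{side}", ins))

    # gluteus minimus: deeper, shorter fan under medius
    psis = np.linspace(np.radians(-55.0), 0.9 * flare, n_gluteals)
    for k, psi in enumerate(psis):
        origin = hip + np.array([
            0.30 * ps * np.sin(psi) * ap,
            sgn * (0.06 + 0.09 * np.cos(psi)) * hb,
            (0.26 + 0.06 * np.cos(psi)) * ps,
        ])
        ins = np.array([0.008, sgn * 0.9 * d_neck, 0.0])
        add("gluteus_minimus", k, origin, (f"thigh_{side}", ins))

    # gluteus maximus: broad posterior fan from upper ilium to sacrum/coccyx,
    # inserting along the gluteal tuberosity
    psis = np.linspace(np.radians(-125.0), np.radians(-72.0), n_gluteals)
    for k, psi in enumerate(psis):
        frac = k / (n_gluteals - 1)
        origin = hip + np.array([
            0.50 * ps * np.sin(psi) * ap,
            sgn * (0.14 + 0.10 * np.cos(psi)) * hb,
            (0.34 - 0.30 * frac) * ps,
        ])
        ins = np.array([-0.025, sgn * 0.02, -0.05 - 0.05 * frac])
        add("gluteus_maximus", k, origin, (f"thigh_{side}", ins))

    # iliopsoas: iliac fossa / lumbar origins, deflected at the anterior hip
    for k in range(6):
        origin = hip + np.array([
            (0.10 + 0.02 * k) * ps * ap * 0.8,
            sgn * (-0.10 + 0.025 * k) * ps,
            (0.18 + 0.04 * k) * ps,
        ])
        via = [(f"thigh_{side}", np.array([0.035, sgn * 0.005, -0.005]))]
        add("iliopsoas", k, origin,
            (f"thigh_{side}", np.array([-0.005, -sgn * 0.015, -0.05])), via)

    # rectus femoris: AIIS -> patella -> tibial tuberosity
    for k in range(2):
        origin = hip + np.array([0.07 * ps * ap, sgn * (0.04 + 0.02 * k) * ps, 0.03 * ps])
        via = [(f"thigh_{side}", np.array([0.05, 0.0, -lf + 0.02]))]
        add("rectus_femoris", k, origin,
            (f"shank_{side}", np.array([0.04, 0.0, -0.08 * ls])), via)

    # hamstrings: ischial tuberosity -> medial/lateral proximal shank
    for k in range(6):
        # the ischium is a relatively long, extension-favoring lever in the
        # australopith form: its tuberosity keeps its position relative to
        # the hip spacing rather than shrinking with the blade
        origin = hip + np.array([
            (-0.24 + 0.01 * k) * hb,
            sgn * (0.04 + 0.01 * (k % 3)) * hb,
            -0.12 * hb,
        ])
        lat = 1.0 if k >= 3 else -1.0  # biceps femoris laterally, semis medially
        add("hamstrings", k, origin,
            (f"shank_{side}", np.array([-0.018, sgn * lat * 0.028, -0.05])))

    # adductors: pubic/ischiopubic ramus -> medial femoral shaft
    for k in range(8):
        origin = hip + np.array([
            (0.10 - 0.035 * k) * ps * ap,
            -sgn * (0.42 - 0.02 * k) * hb / 2 * 0.9 + sgn * 0.0,
            (-0.05 - 0.02 * k) * ps,
        ])
        add("adductors", k, origin,
            (f"thigh_{side}", np.array([-0.005, -sgn * 0.012, -(0.15 + 0.05 * k) * lf * 0.9])))

    # tensor fasciae latae and sartorius from the ASIS
    asis = _asis_position(subject, params, sgn)
    add("tfl_sartorius", 0, asis,
        (f"shank_{side}", np.array([0.012, sgn * 0.035, -0.03])),
        [(f"thigh_{side}", np.array([0.005, sgn * (d_neck + 0.012), -0.03]))])
    add("tfl_sartorius", 1, asis,
        (f"shank_{side}", np.array([0.012, -sgn * 0.030, -0.08 * ls])))

    # deep external rotators: posterior pelvis -> trochanteric fossa
    for k in range(4):
        origin = hip + np.array([
            (-0.10 - 0.015 * k) * ps * ap,
            sgn * (0.01 + 0.015 * k) * ps,
            (0.02 - 0.02 * k) * ps,
        ])
        add("deep_rotators", k, origin,
            (f"thigh_{side}", np.array([-0.012, sgn * 0.8 * d_neck, 0.008])))

    # knee/ankle machinery (origins on thigh/shank, not shape-variant)
    thigh = f"thigh_{side}"
    shank = f"shank_{side}"
    foot = f"foot_{side}"
    for k in range(6):
        o = np.array([0.022, sgn * (-0.02 + 0.008 * k), -(0.30 + 0.04 * k) * lf])
        elements.append(MuscleElement(
            f"vasti_{side}_{k}", "vasti", side, (thigh, o),
            (shank, np.array([0.04, 0.0, -0.08 * ls])),
            [(thigh, np.array([0.05, 0.0, -lf + 0.02]))],
        ))
    for k in range(4):
        o = np.array([-0.03, sgn * (-0.018 + 0.012 * (k % 2)), -lf + 0.03])
        elements.append(MuscleElement(
            f"gastrocnemius_{side}_{k}", "gastrocnemius", side, (thigh, o),
            (foot, np.array([-0.28 * fl, 0.0, -0.5 * ha])),
        ))
    for k in range(2):
        elements.append(MuscleElement(
            f"soleus_{side}_{k}", "soleus", side,
            (shank, np.array([-0.025, sgn * (-0.01 + 0.02 * k), -0.30 * ls])),
            (foot, np.array([-0.28 * fl, 0.0, -0.5 * ha])),
        ))
    for k in range(2):
        elements.append(MuscleElement(
            f"tibialis_anterior_{side}_{k}", "tibialis_anterior", side,
            (shank, np.array([0.022, sgn * 0.005, -0.25 * ls])),
            (foot, np.array([0.15 * fl, -sgn * 0.02, -0.8 * ha])),
            [(shank, np.array([0.038, 0.0, -0.97 * ls]))],
        ))
    for k in range(2):
        elements.append(MuscleElement(
            f"peroneals_{side}_{k}", "peroneals", side,
            (shank, np.array([-0.005, sgn * 0.028, -(0.3 + 0.1 * k) * ls])),
            (foot, np.array([0.05 * fl, sgn * 0.04, -0.9 * ha])),
            [(shank, np.array([-0.012, sgn * 0.035, -0.98 * ls]))],
        ))
    return elements


#: Group strengths in newtons per kilogram body mass, per side, divided
#: equally among the group's elements.  Order-of-magnitude values from the
#: strength ranges reported for adult lower-limb muscle groups; the pipeline's
#: claims are comparative across variants, which share these numbers exactly.
GROUP_STRENGTH_PER_KG = {
    "gluteus_medius": 28.0,
    "gluteus_minimus": 12.0,
    "gluteus_maximus": 32.0,
    "iliopsoas": 24.0,
    "rectus_femoris": 14.0,
    "hamstrings": 34.0,
    "adductors": 28.0,
    "tfl_sartorius": 8.0,
    "deep_rotators": 8.0,
    "vasti": 60.0,
    "gastrocnemius": 30.0,
    "soleus": 50.0,
    "tibialis_anterior": 14.0,
    "peroneals": 8.0,
}


def _marker_template(subject: SubjectAnthropometry) -> Dict[str, Tuple[str, np.ndarray]]:
    """The 52-marker set, placed on the modern-human-shaped body.

    Markers live on the subject's skin, so the template never depends on the
    model's hip shape variant — both variants are driven by identical marker
    data, which is the comparative design's central control.
    """
    hb, lf, st = subject.hip_breadth, subject.femur_length, subject.stature
    ls, fl, ha = 0.246 * st, 0.152 * st, 0.039 * st
    human = HipShapeParams(variant="human_like")
    markers: Dict[str, Tuple[str, np.ndarray]] = {}
    for side, pre, sgn in (("left", "L", 1.0), ("right", "R", -1.0)):
        asis = _asis_position(subject, human, sgn)
        markers[f"{pre}ASI"] = ("pelvis", asis)
        markers[f"{pre}PSI"] = ("pelvis", np.array([-0.17 * hb, sgn * 0.12 * hb, 0.35 * hb]))
        markers[f"{pre}CRE"] = ("pelvis", np.array([0.05 * hb, sgn * 0.55 * hb, 0.52 * hb]))
        d_neck = 0.13 * lf
        thigh = f"thigh_{side}"
        markers[f"{pre}GTR"] = (thigh, np.array([0.0, sgn * (d_neck + 0.02), 0.0]))
        markers[f"{pre}THI1"] = (thigh, np.array([0.02, sgn * 0.05, -0.35 * lf]))
        markers[f"{pre}THI2"] = (thigh, np.array([-0.02, sgn * 0.05, -0.50 * lf]))
        markers[f"{pre}THI3"] = (thigh, np.array([0.03, sgn * 0.04, -0.62 * lf]))
        markers[f"{pre}KNEL"] = (thigh, np.array([0.0, sgn * 0.05, -lf]))
        markers[f"{pre}KNEA"] = (thigh, np.array([0.06, 0.0, -0.93 * lf]))
        shank = f"shank_{side}"
        markers[f"{pre}KNEM"] = (shank, np.array([0.0, -sgn * 0.05, 0.0]))
        markers[f"{pre}TIB1"] = (shank, np.array([0.03, sgn * 0.02, -0.3 * ls]))
        markers[f"{pre}TIB2"] = (shank, np.array([0.01, sgn * 0.045, -0.5 * ls]))
        markers[f"{pre}TIB3"] = (shank, np.array([0.03, sgn * 0.01, -0.7 * ls]))
        markers[f"{pre}ANKL"] = (shank, np.array([0.0, sgn * 0.04, -ls]))
        markers[f"{pre}ANKM"] = (shank, np.array([0.0, -sgn * 0.04, -ls]))
        foot = f"foot_{side}"
        markers[f"{pre}HEE"] = (foot, np.array([-0.30 * fl, 0.0, -0.6 * ha]))
        markers[f"{pre}TOE"] = (foot, np.array([0.70 * fl, 0.0, -0.8 * ha]))
        markers[f"{pre}MT1"] = (foot, np.array([0.45 * fl, -sgn * 0.035, -0.8 * ha]))
        markers[f"{pre}MT5"] = (foot, np.array([0.40 * fl, sgn * 0.040, -0.8 * ha]))
        markers[f"{pre}FOO1"] = (foot, np.array([0.15 * fl, sgn * 0.02, -0.2 * ha]))
        markers[f"{pre}FOO2"] = (foot, np.array([0.10 * fl, -sgn * 0.02, -0.2 * ha]))
    hat_len = 0.48 * st
    for name, loc in {
        "C7": [-0.05, 0.0, 0.55 * hat_len],
        "T10": [-0.07, 0.0, 0.30 * hat_len],
        "CLAV": [0.05, 0.0, 0.52 * hat_len],
        "STRN": [0.08, 0.0, 0.35 * hat_len],
        "LSHO": [-0.02, 0.20, 0.55 * hat_len],
        "RSHO": [-0.02, -0.20, 0.55 * hat_len],
        "LFHD": [0.07, 0.06, 0.80 * hat_len],
        "RFHD": [0.07, -0.06, 0.80 * hat_len],
        "LBHD": [-0.07, 0.06, 0.80 * hat_len],
        "RBHD": [-0.07, -0.06, 0.80 * hat_len],
    }.items():
        markers[name] = ("hat", np.array(loc))
    assert len(markers) == 52
    return markers


def build_subject_model(
    params: HipShapeParams,
    subject: SubjectAnthropometry,
    n_gluteal_elements: int = 12,
) -> SkeletonModel:
    """Build a subject-scaled skeleton with the given hip shape variant.

    Segment lengths come from the subject's stature and joint-center
    distances; masses and inertias from fixed anthropometric fractions of
    body mass (HAT takes the remainder, so total mass equals body mass
    exactly).  Muscle attachment geometry is placed parametrically from the
    shape variant; joint-center distances are variant-independent.
    """
    st, bm = subject.stature, subject.body_mass
    lf, hb = subject.femur_length, subject.hip_breadth
    ls, fl, ha = 0.246 * st, 0.152 * st, 0.039 * st

    def rod_inertia(m: float, L: float, rx: float, ry: float, rz: float) -> np.ndarray:
        return np.diag([m * (rx * L) ** 2, m * (ry * L) ** 2, m * (rz * L) ** 2])

    segments: Dict[str, BodySegment] = {}
    m_pelvis = MASS_FRACTIONS["pelvis"] * bm
    segments["pelvis"] = BodySegment(
        "pelvis", m_pelvis, np.array([0.0, 0.0, 0.03]),
        rod_inertia(m_pelvis, hb, 0.31, 0.31, 0.30), hb, None, np.zeros(3))
    used = m_pelvis
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        m_t = MASS_FRACTIONS["thigh"] * bm
        segments[f"thigh_{side}"] = BodySegment(
            f"thigh_{side}", m_t, np.array([0.0, 0.0, -0.433 * lf]),
            rod_inertia(m_t, lf, 0.329, 0.329, 0.149), lf,
            "pelvis", np.array([0.0, sgn * hb / 2, 0.0]))
        m_s = MASS_FRACTIONS["shank"] * bm
        segments[f"shank_{side}"] = BodySegment(
            f"shank_{side}", m_s, np.array([0.0, 0.0, -0.433 * ls]),
            rod_inertia(m_s, ls, 0.255, 0.249, 0.103), ls,
            f"thigh_{side}", np.array([0.0, 0.0, -lf]))
        m_ta = MASS_FRACTIONS["talus"] * bm
        segments[f"talus_{side}"] = BodySegment(
            f"talus_{side}", m_ta, np.array([0.0, 0.0, -0.005]),
            rod_inertia(m_ta, 0.02, 0.3, 0.3, 0.3), 0.01,
            f"shank_{side}", np.array([0.0, 0.0, -ls]))
        m_f = MASS_FRACTIONS["foot"] * bm
        segments[f"foot_{side}"] = BodySegment(
            f"foot_{side}", m_f, np.array([0.12 * fl, 0.0, -0.7 * ha]),
            rod_inertia(m_f, fl, 0.25, 0.12, 0.25), fl,
            f"talus_{side}", np.array([0.0, 0.0, -0.01]))
        used += m_t + m_s + m_ta + m_f
    m_hat = bm - used
    hat_len = 0.48 * st
    segments["hat"] = BodySegment(
        "hat", m_hat, np.array([0.0, 0.0, 0.32 * hat_len]),
        rod_inertia(m_hat, hat_len, 0.42, 0.36, 0.22), hat_len,
        "pelvis", np.array([0.0, 0.0, 0.10]))

    muscles: List[MuscleElement] = []
    for side in SIDES:
        side_elems = _build_hip_muscles(subject, params, side, n_gluteal_elements)
        counts: Dict[str, int] = {}
        for m in side_elems:
            counts[m.anatomical_group] = counts.get(m.anatomical_group, 0) + 1
        for m in side_elems:
            m.max_strength = GROUP_STRENGTH_PER_KG[m.anatomical_group] * bm / counts[m.anatomical_group]
        muscles.extend(side_elems)

    return SkeletonModel(
        subject=subject, variant=params.variant, shape_params=params,
        segments=segments, muscles=muscles, marker_local=_marker_template(subject),
    )


# ---------------------------------------------------------------------------
# Forward kinematics


def forward_kinematics(model: SkeletonModel, posture: Posture) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """World pose (R, origin) of every segment for one posture."""
    q = posture
    p_pel = np.array([q["pelvis_x"], q["pelvis_y"], q["pelvis_z"]])
    R_pel = _Rz(q["pelvis_rz"]) @ _Ry(q["pelvis_ry"]) @ _Rx(q["pelvis_rx"])
    poses: Dict[str, Tuple[np.ndarray, np.ndarray]] = {"pelvis": (R_pel, p_pel)}
    hat = model.segments["hat"]
    poses["hat"] = (R_pel, p_pel + R_pel @ hat.origin_in_parent)
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        thigh = model.segments[f"thigh_{side}"]
        hip_w = p_pel + R_pel @ thigh.origin_in_parent
        R_th = R_pel @ _Ry(-q[f"hip_flexion_{side}"]) @ _Rx(-sgn * q[f"hip_adduction_{side}"]) \
            @ _Rz(sgn * q[f"hip_rotation_{side}"])
        poses[f"thigh_{side}"] = (R_th, hip_w)
        shank = model.segments[f"shank_{side}"]
        knee_w = hip_w + R_th @ shank.origin_in_parent
        R_sh = R_th @ _Ry(q[f"knee_flexion_{side}"])
        poses[f"shank_{side}"] = (R_sh, knee_w)
        talus = model.segments[f"talus_{side}"]
        ankle_w = knee_w + R_sh @ talus.origin_in_parent
        R_ta = R_sh @ _Ry(-q[f"ankle_flexion_{side}"])
        poses[f"talus_{side}"] = (R_ta, ankle_w)
        foot = model.segments[f"foot_{side}"]
        subt_w = ankle_w + R_ta @ foot.origin_in_parent
        R_ft = R_ta @ _Rx(sgn * q[f"subtalar_{side}"])
        poses[f"foot_{side}"] = (R_ft, subt_w)
    return poses


def marker_positions(model: SkeletonModel, posture: Posture) -> Dict[str, np.ndarray]:
    """World position of every marker of the template."""
    poses = forward_kinematics(model, posture)
    out = {}
    for name, (seg, loc) in model.marker_local.items():
        R, p = poses[seg]
        out[name] = p + R @ loc
    return out


# ---------------------------------------------------------------------------
# Muscle lengths and moment arms


def _world_path_points(model: SkeletonModel, poses: Mapping[str, Tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    model._ensure_path_arrays()
    Rs = np.array([poses[s][0] for s in model._seg_order])  # (S, 3, 3)
    ps = np.array([poses[s][1] for s in model._seg_order])  # (S, 3)
    return np.einsum("pij,pj->pi", Rs[model._path_seg], model._path_loc) + ps[model._path_seg]


def all_muscle_lengths(model: SkeletonModel, posture: Posture) -> np.ndarray:
    """Polyline length of every muscle element (vectorized)."""
    poses = forward_kinematics(model, posture)
    pts = _world_path_points(model, poses)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    # zero out the virtual connections between consecutive muscles, then read
    # per-muscle sums off the cumulative sum
    ptr = model._path_ptr
    mask = np.ones(len(pts) - 1)
    mask[ptr[1:-1] - 1] = 0.0
    c = np.concatenate([[0.0], np.cumsum(seg_len * mask)])
    return c[ptr[1:] - 1] - c[ptr[:-1]]


def muscle_length(model: SkeletonModel, posture: Posture, element: MuscleElement) -> float:
    """Polyline length origin -> via points -> insertion in the world frame."""
    poses = forward_kinematics(model, posture)
    pts = []
    for seg, loc in element.path():
        R, p = poses[seg]
        pts.append(p + R @ loc)
    pts = np.array(pts)
    lens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(lens < 1e-12):
        raise ValueError(f"element {element.name}: zero-length path segment")
    return float(lens.sum())


def moment_arm(
    model: SkeletonModel, posture: Posture, element: MuscleElement, dof: str,
    step: float = 1e-5,
) -> float:
    """Tendon-excursion moment arm r = -dL/dtheta by central finite difference."""
    lp = muscle_length(model, posture.replace_coord(dof, posture[dof] + step), element)
    lm = muscle_length(model, posture.replace_coord(dof, posture[dof] - step), element)
    return -(lp - lm) / (2.0 * step)


def moment_arm_matrix(
    model: SkeletonModel, posture: Posture, dofs: Sequence[str] = RECRUITED_DOFS,
    step: float = 1e-5,
) -> np.ndarray:
    """(n_dofs, n_elements) matrix of tendon-excursion moment arms."""
    R = np.empty((len(dofs), len(model.muscles)))
    for i, dof in enumerate(dofs):
        lp = all_muscle_lengths(model, posture.replace_coord(dof, posture[dof] + step))
        lm = all_muscle_lengths(model, posture.replace_coord(dof, posture[dof] - step))
        R[i] = -(lp - lm) / (2.0 * step)
    return R


# ---------------------------------------------------------------------------
# Morphing and path checking


def morph_attachments(
    model: SkeletonModel, warp: TPSWarp, affected_segments: Sequence[str]
) -> SkeletonModel:
    """Map muscle attachment points on the affected segments through a warp.

    Only origin/insertion/via points are warped (in their segment-local
    frames); joint centers, masses, inertias and markers are untouched, so
    joint-center distances are preserved exactly.
    """
    affected = set(affected_segments)
    new_muscles = []
    for m in model.muscles:
        def maybe(pt: Tuple[str, np.ndarray]) -> Tuple[str, np.ndarray]:
            seg, loc = pt
            return (seg, apply_tps(warp, loc)) if seg in affected else (seg, loc.copy())

        new_muscles.append(MuscleElement(
            name=m.name, anatomical_group=m.anatomical_group, side=m.side,
            origin=maybe(m.origin), insertion=maybe(m.insertion),
            via_points=[maybe(v) for v in m.via_points],
            max_strength=m.max_strength,
        ))
    return SkeletonModel(
        subject=model.subject, variant=model.variant, shape_params=model.shape_params,
        segments=model.segments, muscles=new_muscles, marker_local=model.marker_local,
    )


def check_muscle_paths(
    model: SkeletonModel,
    postures: Sequence[Posture],
    joint_clearance: float = 0.006,
    max_length_change: float = 0.5,
    dofs: Sequence[str] = RECRUITED_DOFS,
) -> Dict[str, List[str]]:
    """Diagnostic report on muscle path plausibility over a set of postures.

    Flags, per element: moment-arm sign flips across the postures on any
    spanned DOF, the path passing within ``joint_clearance`` of a joint
    center, and length changes beyond ``max_length_change`` of the mean.
    Report-only and deterministic.
    """
    n = len(model.muscles)
    arms = np.array([moment_arm_matrix(model, p, dofs) for p in postures])  # (T, D, n)
    lengths = np.array([all_muscle_lengths(model, p) for p in postures])  # (T, n)
    flags: Dict[str, List[str]] = {m.name: [] for m in model.muscles}

    # a malrouted element reverses a *substantial* moment arm; small
    # secondary-action arms crossing zero with posture (e.g. abductor fibers
    # switching rotation direction with hip flexion) are physiological
    flip_arm = 0.025  # m
    for j, m in enumerate(model.muscles):
        for i, dof in enumerate(dofs):
            if arms[:, i, j].max() > flip_arm and arms[:, i, j].min() < -flip_arm:
                flags[m.name].append(f"moment_arm_sign_flip:{dof}")
        rel = lengths[:, j].max() - lengths[:, j].min()
        if rel > max_length_change * lengths[:, j].mean():
            flags[m.name].append("excursion_exceeds_physiologic_fraction")

    joint_names = [("pelvis", s) for s in ("thigh_left", "thigh_right")]
    for p in postures:
        poses = forward_kinematics(model, p)
        centers = []
        for side in SIDES:
            centers.append(poses[f"thigh_{side}"][1])  # hip
            centers.append(poses[f"shank_{side}"][1])  # knee
            centers.append(poses[f"talus_{side}"][1])  # ankle
        centers = np.array(centers)
        for m in model.muscles:
            pts = []
            for seg, loc in m.path():
                R, org = poses[seg]
                pts.append(org + R @ loc)
            pts = np.array(pts)
            for a, b in zip(pts[:-1], pts[1:]):
                ab = b - a
                t = np.clip(((centers - a) @ ab) / (ab @ ab), 0.0, 1.0)
                d = np.linalg.norm(a + t[:, None] * ab - centers, axis=1)
                if d.min() < joint_clearance and "near_joint_center" not in flags[m.name]:
                    flags[m.name].append("near_joint_center")
    return {k: v for k, v in flags.items() if v}
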