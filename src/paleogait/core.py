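"""Shared domain types for the comparative hip-morphology gait pipeline.

The pipeline asks a single comparative question: holding a walker's size,
kinematics and external kinetics fixed, what changes in muscle recruitment and
hip joint loading follow from swapping a modern-human-shaped hip for an
australopithecine-shaped one?  The types here are the vocabulary every stage
shares: who is walking (:class:`SubjectAnthropometry`), one recorded walking
pass (:class:`GaitTrial`), and the parametric description of the two hip shape
variants (:class:`HipShapeParams`).

Coordinate convention (used everywhere in the package): X is the direction of
travel, Y is mediolateral (positive to the subject's left) at midstance, and Z
is vertical (up).  All lengths are metres, masses kilograms, forces newtons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Tuple

import numpy as np

__all__ = [
    "GRAVITY",
    "SubjectAnthropometry",
    "PlateRecord",
    "GaitTrial",
    "HipShapeParams",
    "HUMAN_LIKE",
    "AUSTRALOPITH_LIKE",
    "hip_shape_preset",
]

#: Gravitational acceleration vector (m/s^2); Z is up.
GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass(frozen=True)
class SubjectAnthropometry:
    """Body dimensions of one walking subject.

    ``hip_breadth`` is the inter-hip-joint-center distance and ``femur_length``
    the hip-to-knee-center distance; both are the joint-center distances that
    subject scaling must preserve across hip shape variants.
    """

    subject_id: str
    sex: Literal["F", "M"]
    body_mass: float  # kg
    stature: float  # m
    hip_breadth: float  # m, inter-hip-center distance
    femur_length: float  # m, hip-to-knee-center distance

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.stature <= 0:
            raise ValueError("stature must be positive")
        if not 0 < self.hip_breadth < self.stature:
            raise ValueError("hip_breadth must lie in (0, stature)")
        if not 0 < self.femur_length < self.stature:
            raise ValueError("femur_length must lie in (0, stature)")

    @property
    def body_weight(self) -> float:
        """Body weight in newtons."""
        return self.body_mass * 9.81


@dataclass
class PlateRecord:
    """Per-frame record of one force plate.

    ``force`` is the ground reaction force the plate exerts on the foot (N),
    ``cop`` the center of pressure on the plate surface (m, lab frame, z=0),
    and ``free_moment`` the vertical free moment about the COP (N·m).
    """

    force: np.ndarray  # (n_frames, 3)
    cop: np.ndarray  # (n_frames, 3)
    free_moment: np.ndarray  # (n_frames,)

    def n_frames(self) -> int:
        return self.force.shape[0]


@dataclass
class GaitTrial:
    """One walking pass: marker motion, two plate records, events.

    ``events`` holds the frame index of initial contact with the first force
    plate (``ic``) and the ipsilateral initial contact ending the stride
    (``ic_ipsilateral``); ``side`` is the foot making that first contact.
    ``marker_trajectories`` maps each of the 52 marker names to an
    ``(n_frames, 3)`` position series in metres.
    """

    subject: SubjectAnthropometry
    side: Literal["left", "right"]
    marker_trajectories: Dict[str, np.ndarray]
    grf_records: Tuple[PlateRecord, PlateRecord]
    events: Dict[str, int]
    sample_rate: float  # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {v.shape[0] for v in self.marker_trajectories.values()}
        counts |= {p.n_frames() for p in self.grf_records}
        if len(counts) != 1:
            raise ValueError("all trajectories and plate records must share a frame count")
        (self._n_frames,) = counts
        for name in ("ic", "ic_ipsilateral"):
            if name not in self.events:
                raise ValueError(f"missing gait event {name!r}")
            if not 0 <= self.events[name] < self._n_frames:
                raise ValueError(f"event {name!r} outside the recording")
        for p in self.grf_records:
            if np.any(p.force[:, 2] < -1e-9):
                raise ValueError("vertical GRF must be non-negative")

    @property
    def n_frames(self) -> int:
        return self._n_frames

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


@dataclass(frozen=True)
class HipShapeParams:
    """Parametric description of a hip shape variant.

    All ratios are relative to the modern-human-like reference at equal
    inter-hip-center distance:

    ``biacetabular_breadth_ratio``
        how broad the acetabular spacing is relative to overall pelvis size;
        a relatively broad pelvis, rescaled to a fixed hip spacing, ends up
        with a smaller iliac blade.
    ``neck_length_ratio``
        femoral neck length (hip center to greater trochanter) relative to
        the human reference.
    ``iliac_flare_angle``
        how far anterior of the coronal plane the iliac blade (and with it
        the anterior abductor origin fan) wraps, in degrees.
    ``ap_depth_ratio``
        anteroposterior compression of the pelvis; < 1 flattens the pelvis
        front-to-back, pulling ischial and pubic points toward the hip axis.
    """

    variant: Literal["human_like", "australopith_like"]
    biacetabular_breadth_ratio: float = 1.0
    neck_length_ratio: float = 1.0
    iliac_flare_angle: float = 42.0  # degrees
    ap_depth_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("biacetabular_breadth_ratio", "neck_length_ratio", "ap_depth_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.iliac_flare_angle < 90.0:
            raise ValueError("iliac_flare_angle must lie in (0, 90) degrees")


#: Modern-human-like hip: anteriorly wrapped iliac blades place the anterior
#: abductor origins well in front of the coronal plane through the hip centers.
HUMAN_LIKE = HipShapeParams(
    variant="human_like",
    biacetabular_breadth_ratio=1.0,
    neck_length_ratio=1.0,
    iliac_flare_angle=42.0,
    ap_depth_ratio=1.0,
)

#: Australopithecine-like hip: relatively broad biacetabular spacing, a
#: femoral neck modestly longer relative to femur length (the marked
#: elongation of the australopith neck is relative to head size, not bone
#: length), weakly wrapped (more coronal) iliac blades, and an
#: anteroposteriorly compressed pelvis.
AUSTRALOPITH_LIKE = HipShapeParams(
    variant="australopith_like",
    biacetabular_breadth_ratio=1.22,
    neck_length_ratio=1.08,
    iliac_flare_angle=16.0,
    ap_depth_ratio=0.75,
)

_PRESETS = {"human_like": HUMAN_LIKE, "australopith_like": AUSTRALOPITH_LIKE}


def hip_shape_preset(variant: str, **overrides) -> HipShapeParams:
    """Return the named preset, optionally with parameter overrides."""
    try:
        base = _PRESETS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
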