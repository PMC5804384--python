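"""Per-joint measurements, cohort containers and position-change kinematics.

Bite positions are numbered as in the study protocol: 1 = maximal
intercuspation (habitual closure), 2 = anterior repositioning splint
posture (protruded, opened), 3 = stabilization splint posture (opened at
the same vertical dimension, not protruded).

Movements between positions are reported as the componentwise difference
of fossa-frame coordinates, split into named anatomical directions:
negative Δx is anterior movement (frame x is posterior-positive), negative
Δy is inferior movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional

import numpy as np

from .errors import EmptyGroupError, ValidationError
from .geometry import (
    FrameCoords,
    LandmarkSet,
    build_fossa_frame,
    disc_condyle_angle,
    to_frame_coords,
)

__all__ = [
    "POSITIONS",
    "DIAGNOSES",
    "JointMeasurement",
    "JointRecord",
    "PatientMeta",
    "Cohort",
    "DisplacementVector",
    "measure_joint",
    "measure_cohort",
    "displacement",
    "group_mean_displacement",
    "mandibular_posture_summary",
]

POSITIONS = (1, 2, 3)
DIAGNOSES = ("normal", "DDwR", "DDwoR")


@dataclass(frozen=True)
class JointMeasurement:
    """Derived quantities for one joint in one bite position."""

    angle: float  # disc-condyle angle, degrees, anterior positive
    condyle: FrameCoords  # C point in the fossa frame, mm
    disc: FrameCoords  # D point in the fossa frame, mm


@dataclass
class JointRecord:
    """One joint followed across bite positions 1-3."""

    joint_id: str
    patient_id: str
    side: str
    diagnosis: str
    landmarks: Dict[int, LandmarkSet] = field(default_factory=dict)
    measurements: Dict[int, JointMeasurement] = field(default_factory=dict)
    #: generator-drawn ground truth, present only for simulated joints
    truth: Dict[int, JointMeasurement] = field(default_factory=dict)

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"unknown diagnosis {self.diagnosis!r} for joint {self.joint_id}; "
                f"expected one of {DIAGNOSES}"
            )
        for pos in list(self.landmarks) + list(self.measurements):
            if pos not in POSITIONS:
                raise ValidationError(
                    f"joint {self.joint_id}: position {pos} outside {POSITIONS}"
                )


@dataclass(frozen=True)
class PatientMeta:
    """Incisor distances and overjet recorded per patient.

    D1/D2/D3 are the inter-gingival distances of the central incisors in
    positions 1-3 (D2 is shared by positions 2 and 3 by protocol; D3 is
    registered at the D2 opening).  Overjet is recorded in positions 1
    and 3.
    """

    D1: float
    D2: float
    D3: float
    overjet_p1: float
    overjet_p3: float

    def __post_init__(self):
        for name in ("D1", "D2", "D3", "overjet_p1", "overjet_p3"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError(f"PatientMeta.{name} must be non-negative, got {v}")


@dataclass
class Cohort:
    """A set of joints plus optional per-patient metadata."""

    records: List[JointRecord] = field(default_factory=list)
    meta: Dict[str, PatientMeta] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def group(self, diagnosis: str) -> List[JointRecord]:
        return [r for r in self.records if r.diagnosis == diagnosis]


@dataclass(frozen=True)
class DisplacementVector:
    """Signed frame-coordinate change with anatomical direction labels.

    Exactly one of each direction pair is nonzero: ``anterior_mm = -dx``
    when dx < 0 else 0 (then ``posterior_mm = dx``), and likewise for the
    vertical pair.
    """

    dx: float
    dy: float

    @property
    def anterior_mm(self) -> float:
        return -self.dx if self.dx < 0 else 0.0

    @property
    def posterior_mm(self) -> float:
        return self.dx if self.dx > 0 else 0.0

    @property
    def inferior_mm(self) -> float:
        return -self.dy if self.dy < 0 else 0.0

    @property
    def superior_mm(self) -> float:
        return self.dy if self.dy > 0 else 0.0

    def __neg__(self) -> "DisplacementVector":
        return DisplacementVector(dx=-self.dx, dy=-self.dy)

    def describe(self) -> str:
        """Human-readable direction summary, 0.01 mm precision."""
        horiz = (
            f"{self.anterior_mm:.2f} mm anterior"
            if self.dx < 0
            else f"{self.posterior_mm:.2f} mm posterior"
        )
        vert = (
            f"{self.inferior_mm:.2f} mm inferior"
            if self.dy < 0
            else f"{self.superior_mm:.2f} mm superior"
        )
        return f"{horiz}, {vert}"


def measure_joint(landmarks: LandmarkSet, fh_offset_deg: float = 0.0) -> JointMeasurement:
    """Run the full geometric measurement of one landmark set."""
    frame = build_fossa_frame(landmarks)
    return JointMeasurement(
        angle=disc_condyle_angle(landmarks, fh_offset_deg),
        condyle=to_frame_coords(landmarks.C, frame),
        disc=to_frame_coords(landmarks.D, frame),
    )


def measure_cohort(cohort: Cohort, fh_offset_deg: float = 0.0) -> Cohort:
    """Fill every record's measurements from its landmarks (in place);
    records that already carry measurements but no landmarks are kept."""
    for rec in cohort.records:
        for pos, lm in rec.landmarks.items():
            rec.measurements[pos] = measure_joint(lm, fh_offset_deg)
    return cohort


def displacement(from_: FrameCoords, to: FrameCoords) -> DisplacementVector:
    """Position change between two bite positions (to − from)."""
    return DisplacementVector(dx=to.x - from_.x, dy=to.y - from_.y)


def group_mean_displacement(
    cohort: Iterable[JointRecord] | Cohort,
    structure: Literal["condyle", "disc"],
    from_pos: int,
    to_pos: int,
    group: Optional[str] = None,
) -> DisplacementVector:
    """Mean displacement vector of the condyle or disc over a diagnosis
    group.

    Joints missing either position are excluded pairwise.  By linearity of
    the mean this equals the displacement between the group-mean
    coordinates, so feeding published group means through
    :func:`displacement` reproduces group movement figures exactly.
    """
    if structure not in ("condyle", "disc"):
        raise ValueError(f"structure must be 'condyle' or 'disc', got {structure!r}")
    records = cohort.records if isinstance(cohort, Cohort) else list(cohort)
    if group is not None:
        records = [r for r in records if r.diagnosis == group]
    deltas = []
    for rec in records:
        m_from = rec.measurements.get(from_pos)
        m_to = rec.measurements.get(to_pos)
        if m_from is None or m_to is None:
            continue
        d = displacement(getattr(m_from, structure), getattr(m_to, structure))
        deltas.append((d.dx, d.dy))
    if not deltas:
        raise EmptyGroupError(
            f"no joints in group {group!r} with both positions {from_pos} and {to_pos}"
        )
    arr = np.asarray(deltas)
    return DisplacementVector(dx=float(arr[:, 0].mean()), dy=float(arr[:, 1].mean()))


def mandibular_posture_summary(meta: PatientMeta) -> Dict[str, float]:
    """Vertical-opening and protrusion changes implied by the bite
    registrations: positions 2/3 open the bite by D2 − D1; position 3's
    protrusion change is the overjet reduction overjet_p1 − overjet_p3
    (≈ 0 when the mandible moved only downward)."""
    return {
        "vertical_opening_change": meta.D2 - meta.D1,
        "protrusion_change": meta.overjet_p1 - meta.overjet_p3,
    }
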