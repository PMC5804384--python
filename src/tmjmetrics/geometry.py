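"""Landmark geometry for sagittal TMJ MRI morphometry.

All measurements derive from five anatomical landmarks annotated on the
mid-condylar oblique-sagittal slice, in millimetres:

* ``T`` — lowest point of the articular tubercle (anterior);
* ``P`` — highest edge of the porus acusticus externus (posterior);
* ``G`` — highest point of the glenoid fossa, the coordinate origin;
* ``C`` — estimated center of the condylar head;
* ``D`` — midpoint of the posterior margin of the posterior band of the disc.

Two coordinate-free constructions are implemented:

1. The **fossa frame**: the x-axis runs through G parallel to the T→P
   tangent (posterior positive), the y-axis is its superior-pointing
   perpendicular, and G is the origin.  Condyle and disc positions are the
   (x, y) coordinates of C and D in this frame.
2. The **disc-condyle angle** (Drace's method): the signed angle at C
   between the superior-pointing perpendicular of the Frankfort-horizontal
   trace and the ray C→D, positive when D lies anterior of that vertical.

Sign conventions (the source tables only fix them jointly with the verbal
reading of results): frame x positive = posterior, y positive = superior,
angle positive = anterior displacement of the disc.  Both constructions are
invariant under rigid motion of the whole scene and under mirroring of a
left-side image, because anterior is taken from the T→P landmarks rather
than from the image axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateLandmarksError, OrientationError

__all__ = [
    "LandmarkSet",
    "FossaFrame",
    "FrameCoords",
    "build_fossa_frame",
    "to_frame_coords",
    "disc_condyle_angle",
]

_MIN_SEPARATION_MM = 1e-6

Point = np.ndarray  # shape (2,), millimetres in image space


def _as_point(value, name: str) -> Point:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a 2D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


def _cross(a: Point, b: Point) -> float:
    """z-component of the 2D cross product."""
    return float(a[0] * b[1] - a[1] * b[0])


def _normalize(v: Point, name: str) -> Point:
    n = float(np.hypot(v[0], v[1]))
    if n < _MIN_SEPARATION_MM:
        raise OrientationError(f"{name} is (near-)zero: {v}")
    return v / n


def _perp_toward(v: Point, ref: Point, context: str) -> Point:
    """The unit perpendicular of unit vector ``v`` with positive dot
    product against ``ref``; raises if ``ref`` is parallel to ``v``."""
    perp = np.array([-v[1], v[0]])
    d = float(perp @ ref)
    if abs(d) < 1e-12 * float(np.hypot(ref[0], ref[1])) or d == 0.0:
        raise OrientationError(
            f"{context}: reference direction {ref} is parallel to {v}; "
            "cannot orient the perpendicular"
        )
    return perp if d > 0 else -perp


@dataclass(frozen=True)
class LandmarkSet:
    """The five landmarks of one joint in one bite position.

    ``fh_dir`` is the in-image trace of the Frankfort horizontal plane; it
    cannot be derived from the five landmarks, so it is an explicit input.
    When absent it defaults to the T→P tangent direction, optionally tilted
    by ``fh_offset_deg`` at measurement time.  ``superior_dir`` orients the
    frame (image y is assumed to increase superiorly by default).
    """

    T: Point
    P: Point
    G: Point
    C: Point
    D: Point
    fh_dir: Optional[Point] = None
    superior_dir: Point = field(default_factory=lambda: np.array([0.0, 1.0]))
    side: str = "right"

    def __post_init__(self):
        for name in ("T", "P", "G", "C", "D"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        if self.fh_dir is not None:
            object.__setattr__(self, "fh_dir", _as_point(self.fh_dir, "fh_dir"))
            _normalize(self.fh_dir, "fh_dir")
        sup = _as_point(self.superior_dir, "superior_dir")
        object.__setattr__(self, "superior_dir", sup)
        _normalize(sup, "superior_dir")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def resolved_fh_dir(self, fh_offset_deg: float = 0.0) -> Point:
        """The Frankfort-horizontal direction used for angle measurement.

        Falls back to the T→P tangent when no ``fh_dir`` was supplied,
        rotated by ``fh_offset_deg`` (positive offset raises the posterior
        end toward superior, so the convention is mirror-consistent).
        """
        if self.fh_dir is not None:
            base = _normalize(self.fh_dir, "fh_dir")
        else:
            base = _normalize(self.P - self.T, "T->P direction")
        if fh_offset_deg == 0.0:
            return base
        s = 1.0 if _cross(base, self.superior_dir) > 0 else -1.0
        a = np.deg2rad(fh_offset_deg) * s
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return rot @ base


@dataclass(frozen=True)
class FossaFrame:
    """Orthonormal measurement frame anchored at the glenoid fossa.

    ``origin`` is G; ``x_hat`` points posterior along the T→P tangent;
    ``y_hat`` is the superior-pointing perpendicular.
    """

    origin: Point
    x_hat: Point
    y_hat: Point


@dataclass(frozen=True)
class FrameCoords:
    """Position in the fossa frame: x positive = posterior (mm), y positive
    = superior (mm).  ``(1.21, -1.70)`` reads "1.21 mm behind and 1.70 mm
    below" the fossa point G."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite frame coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


def build_fossa_frame(landmarks: LandmarkSet) -> FossaFrame:
    """Construct the fossa coordinate frame from T, P and G.

    The x-axis is the line through G parallel to the T→P tangent, oriented
    T→P (posterior positive); the y-axis is the perpendicular through G
    chosen to point superior.  Raises :class:`DegenerateLandmarksError`
    when T and P coincide and :class:`OrientationError` when
    ``superior_dir`` cannot disambiguate the perpendicular.
    """
    tp = landmarks.P - landmarks.T
    if float(np.hypot(tp[0], tp[1])) <= _MIN_SEPARATION_MM:
        raise DegenerateLandmarksError(
            f"T and P coincide (separation <= {_MIN_SEPARATION_MM} mm); "
            "the tangent line is undefined"
        )
    x_hat = tp / float(np.hypot(tp[0], tp[1]))
    y_hat = _perp_toward(x_hat, landmarks.superior_dir, "build_fossa_frame")
    return FossaFrame(origin=landmarks.G.copy(), x_hat=x_hat, y_hat=y_hat)


def to_frame_coords(pt, frame: FossaFrame) -> FrameCoords:
    """Project an image-space point into the fossa frame (mm)."""
    p = _as_point(pt, "pt")
    rel = p - frame.origin
    return FrameCoords(x=float(rel @ frame.x_hat), y=float(rel @ frame.y_hat))


def disc_condyle_angle(landmarks: LandmarkSet, fh_offset_deg: float = 0.0) -> float:
    """Signed disc-condyle angle in degrees, in (−180, 180].

    The reference ray is the superior perpendicular of the Frankfort
    horizontal trace through C; the measured ray is C→D.  The sign is
    positive when D lies on the anterior side of the reference (anterior
    taken from T→P: T anterior, P posterior), so anteriorly displaced discs
    get positive angles.  Raises :class:`DegenerateLandmarksError` when C
    and D coincide.
    """
    v = landmarks.D - landmarks.C
    if float(np.hypot(v[0], v[1])) <= _MIN_SEPARATION_MM:
        raise DegenerateLandmarksError(
            f"C and D coincide (separation <= {_MIN_SEPARATION_MM} mm); "
            "the disc-condyle angle is undefined"
        )
    fh = landmarks.resolved_fh_dir(fh_offset_deg)
    u = _perp_toward(fh, landmarks.superior_dir, "disc_condyle_angle")
    anterior = _normalize(landmarks.T - landmarks.P, "P->T direction")
    orient = _cross(u, anterior)
    if abs(orient) < 1e-12:
        raise OrientationError(
            "anterior direction is parallel to the angle reference; "
            "cannot assign a sign to the disc-condyle angle"
        )
    s = 1.0 if orient > 0 else -1.0
    angle = s * np.degrees(np.arctan2(_cross(u, v), float(u @ v)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)
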