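"""Disc-position classification and recapture decisions.

The clinical rule is purely angular: a disc-condyle angle within the closed
band [−15°, +15°] is normal; greater than +15° is anterior disc
displacement; below −15° posterior displacement.  "Recapture" asks whether
a disc that was anteriorly displaced at the baseline bite position returns
to the normal band in a treated position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import EmptyGroupError, NotApplicableError

__all__ = [
    "NORMAL_BAND_DEG",
    "DiscPosition",
    "DiscStatus",
    "classify_disc_position",
    "is_recaptured",
    "recapture_rate",
    "RecaptureResult",
]

#: Half-width of the normal disc-condyle angle band, degrees (inclusive).
NORMAL_BAND_DEG = 15.0


class DiscPosition(str, Enum):
    NORMAL = "NORMAL"
    ANTERIOR_DISPLACED = "ANTERIOR_DISPLACED"
    POSTERIOR_DISPLACED = "POSTERIOR_DISPLACED"


@dataclass(frozen=True)
class DiscStatus:
    status: DiscPosition
    angle: float


def classify_disc_position(angle: float, band: float = NORMAL_BAND_DEG) -> DiscStatus:
    """Classify a disc-condyle angle.

    The band is closed: exactly ±15° is NORMAL, because displacement is
    defined as strictly *greater than* 15°.
    """
    if not math.isfinite(angle):
        raise ValueError(f"disc-condyle angle must be finite, got {angle}")
    if angle > band:
        status = DiscPosition.ANTERIOR_DISPLACED
    elif angle < -band:
        status = DiscPosition.POSTERIOR_DISPLACED
    else:
        status = DiscPosition.NORMAL
    return DiscStatus(status=status, angle=float(angle))


def is_recaptured(
    baseline_angle: float, treated_angle: float, band: float = NORMAL_BAND_DEG
) -> bool:
    """True when an anteriorly displaced disc returns to the normal band.

    Raises :class:`NotApplicableError` when the baseline is not anteriorly
    displaced — recapture is only defined for displaced discs.
    """
    if classify_disc_position(baseline_angle, band).status is not DiscPosition.ANTERIOR_DISPLACED:
        raise NotApplicableError(
            f"baseline angle {baseline_angle:.1f}° is not anteriorly displaced; "
            "recapture is undefined"
        )
    return classify_disc_position(treated_angle, band).status is DiscPosition.NORMAL


@dataclass(frozen=True)
class RecaptureResult:
    count: int
    total: int
    pct: float  # 100 * count / total, rounded to one decimal


def recapture_rate(
    treated_angles: Sequence[float],
    baseline_angles: Sequence[float],
    band: float = NORMAL_BAND_DEG,
) -> RecaptureResult:
    """Fraction of displaced discs recaptured in a treated bite position."""
    if len(treated_angles) == 0:
        raise EmptyGroupError("recapture_rate requires at least one joint")
    if len(treated_angles) != len(baseline_angles):
        raise ValueError(
            f"length mismatch: {len(treated_angles)} treated vs "
            f"{len(baseline_angles)} baseline angles"
        )
    count = sum(
        is_recaptured(b, t, band) for b, t in zip(baseline_angles, treated_angles)
    )
    total = len(treated_angles)
    return RecaptureResult(count=count, total=total, pct=round(100.0 * count / total, 1))
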