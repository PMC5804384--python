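"""Exception hierarchy.

``TmjMetricsError`` is the common base so callers can catch everything the
package raises; ``ValidationError`` covers malformed user input (files,
configs) and maps to CLI exit code 2.
"""


class TmjMetricsError(Exception):
    """Base class for all errors raised by tmjmetrics."""


class DegenerateLandmarksError(TmjMetricsError, ValueError):
    """Two landmarks that must be distinct coincide (e.g. T == P, C == D)."""


class OrientationError(TmjMetricsError, ValueError):
    """A direction vector needed to orient the frame or angle is degenerate
    (zero, or parallel to the axis it must disambiguate)."""


class NotApplicableError(TmjMetricsError, ValueError):
    """An operation was asked about a joint outside its domain, e.g. disc
    recapture for a baseline that is not anteriorly displaced."""


class EmptyGroupError(TmjMetricsError, ValueError):
    """A group/cohort aggregate was requested on an empty selection."""


class ValidationError(TmjMetricsError, ValueError):
    """Malformed input data or configuration."""
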