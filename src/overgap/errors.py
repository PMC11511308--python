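"""Exception hierarchy.

All package-specific failures derive from :class:`OvergapError` so callers can
catch everything with one clause; each concrete class also derives from the
closest built-in (``ValueError``/``RuntimeError``) so untyped call sites keep
working.
"""


class OvergapError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedFovError(OvergapError, ValueError):
    """An unknown field-of-view kind was requested."""


class InvalidInputError(OvergapError, ValueError):
    """An argument violates a documented precondition (empty, nonpositive, ...)."""


class DimensionMismatchError(OvergapError, ValueError):
    """Array shapes that must agree (column heights, channel counts) do not."""


class InvalidBinningError(OvergapError, ValueError):
    """Histogram bin edges are unusable (fewer than two, or not increasing)."""


class IncompatibleBinningError(OvergapError, ValueError):
    """Two binned distributions do not share the same support."""


class InvalidScaleError(OvergapError, ValueError):
    """A vertical rescale offset would leave fewer than two pixels."""


class MisuseError(OvergapError, ValueError):
    """A correction routine was invoked on a report of the wrong anomaly kind."""


class UnrecoverableAnomalyError(OvergapError, RuntimeError):
    """The detected anomaly cannot be corrected (e.g. wider than the frame)."""


class MonotonicityError(OvergapError, ValueError):
    """The along-track position stream regressed."""


class ScenarioError(OvergapError, ValueError):
    """A synthetic scenario specification is inconsistent or does not fit."""
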