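"""Exception hierarchy for the screening pipeline.

Every anticipated failure mode raises a subclass of :class:`ScreenError`,
so callers can catch one base class at the campaign level while tests pin
the specific condition.
"""


class ScreenError(Exception):
    """Base class for all phytoscreen errors."""


class FormatError(ScreenError):
    """Malformed input file (unknown role, non-numeric value, bad header)."""


class DuplicateWellError(FormatError):
    """The same plate/row/col address appears more than once in a plate map."""


class OrphanWellError(FormatError):
    """A measurement refers to an address absent from the plate map."""


class ScheduleError(FormatError):
    """A kinetic well does not match the configured read schedule."""


class DegenerateDesignError(ScreenError):
    """Standard curve requested on fewer than two distinct concentrations."""


class CalibrationError(ScreenError):
    """Calibration failed (e.g. fitted slope not positive)."""


class InsufficientDataError(ScreenError):
    """Too few readings to evaluate (single kinetic read, < 2 time points)."""


class InvalidBaselineError(ScreenError):
    """Background-corrected fluorescence at t=0 is not positive."""


class DegenerateAnchorError(ScreenError):
    """Stress and untreated/blank anchors coincide; induction failed."""


class DegenerateControlError(ScreenError):
    """Viability control mean is not positive."""


class DegenerateVarianceError(ScreenError):
    """Pooled within-group variance is zero; t statistics undefined."""


class UndefinedCorrelationError(ScreenError):
    """Correlation requested on a constant vector."""


class ConfigError(ScreenError):
    """Simulation or run configuration is invalid or infeasible."""
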