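"""Exception hierarchy for the IVGP pipeline."""


class IvgpError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IvgpError):
    """An input file does not have the expected structure (e.g. missing column)."""


class ValidationError(IvgpError):
    """Data violates an invariant (decreasing cumulative pressure, bad mass, ...)."""


class ConfigurationError(IvgpError):
    """A configuration value is missing or out of its admissible range."""


class QCError(IvgpError):
    """A quality-control rule failed in a way that blocks further analysis."""


class CalibrationError(IvgpError):
    """A GC standard-curve fit is unusable (singular or below the R^2 bound)."""
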