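"""Exception hierarchy shared across the package."""


class PhytoplexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhytoplexError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(PhytoplexError):
    """A table is missing required columns or maps to no known analyte."""


class ParseError(PhytoplexError):
    """Malformed input file (missing header, non-numeric cell, decimal comma)."""


class DegenerateDesignError(PhytoplexError):
    """A regression design with no usable variation (e.g. one calibration level)."""


class CalibrationError(PhytoplexError):
    """Calibration curve unusable for inversion (non-positive slope)."""


class DomainError(PhytoplexError):
    """A value outside its physical domain (negative TEAC, non-positive denominator)."""


class NormalizationError(PhytoplexError):
    """A sample shares no positive feature with the normalization reference."""


class AlignmentError(PhytoplexError):
    """No overlap between sample identifiers of two tables."""


class ParameterError(PhytoplexError):
    """A statistical routine called with impossible parameters."""


class StateError(PhytoplexError):
    """Operation requested on an unfitted or otherwise unready model."""


class InsufficientReplicationError(PhytoplexError):
    """Fewer replicates than the uncertainty computation requires."""


class DesignError(PhytoplexError):
    """A phytocomplex depletion design is incomplete or inconsistent."""
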