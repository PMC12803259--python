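"""Exception types shared across the pipeline."""


class ChemotaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChemotaxError, ValueError):
    """A configuration value violates an invariant (names the offending field)."""


class ParameterError(ChemotaxError, ValueError):
    """A runtime parameter is out of its valid range."""


class CalibrationError(ChemotaxError, ValueError):
    """Image and geometry calibration disagree."""


class DomainError(ChemotaxError, ValueError):
    """A coordinate lies outside the imaged field."""


class StabilityError(ChemotaxError, ValueError):
    """A numerical scheme would be unstable with the requested discretization."""
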