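"""Exception hierarchy shared across the pipeline stages."""


class ScofuelError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpeciesError(ScofuelError, ValueError):
    """Fatty-acid species with impossible chain length / unsaturation."""


class DegenerateInputError(ScofuelError, ValueError):
    """Input with no information content (empty or all-zero profile, zero DCW...)."""


class DomainError(ScofuelError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class ConsistencyError(ScofuelError, ValueError):
    """Physically inconsistent measurements (e.g. lipid titre above DCW)."""


class ConsistencyWarning(UserWarning):
    """Suspicious but tolerated input (e.g. net sugar production)."""


class CalibrationError(ScofuelError, ValueError):
    """Single-point calibration impossible (zero standard peak area)."""


class UndefinedCorrelationError(ScofuelError, ValueError):
    """Pearson correlation undefined (zero variance in a variable)."""


class ConfigurationError(ScofuelError, ValueError):
    """Unknown registry key, malformed config, or unknown output format."""


class ParseError(ScofuelError, ValueError):
    """Malformed input table; message names the offending row/column."""
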