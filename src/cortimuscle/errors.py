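"""Exception hierarchy for the pipeline."""


class CortimuscleError(Exception):
    """Base class for all package errors."""


class FormatError(CortimuscleError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(CortimuscleError):
    """Data violate a declared invariant (shape, sign, vocabulary, ...)."""


class ConfigurationError(CortimuscleError):
    """Constants or parameters are inconsistent (e.g. singular extinction matrix)."""


class ParameterError(CortimuscleError):
    """An operation parameter is out of its admissible range."""
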