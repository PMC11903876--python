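"""Exception hierarchy for the urispec pipeline."""


class UrispecError(Exception):
    """Base class for all errors raised by urispec."""


class ConfigurationError(UrispecError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(UrispecError):
    """A dataset file violates the expected layout (e.g. ragged channel counts)."""


class JoinError(UrispecError):
    """Spectra reference sample ids absent from the laboratory table."""


class DegenerateSpectrumError(UrispecError):
    """A constant spectrum cannot be SNV-scaled (zero standard deviation)."""


class DegenerateMarkerError(UrispecError):
    """A laboratory vector with fewer than two distinct values."""


class DegenerateOutcomeError(UrispecError):
    """A binary outcome with only one class present."""


class SeparationError(UrispecError):
    """Perfect separation made the logistic likelihood unbounded."""


class SelectionFailureError(UrispecError):
    """No candidate subset produced a converged model."""


class EvaluationError(UrispecError):
    """Cross-validation could not be completed (e.g. unsplittable outcome)."""


class SchemaError(UrispecError):
    """Design-matrix columns do not match the fitted model's features."""
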