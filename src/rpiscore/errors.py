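"""Exception hierarchy used across the package."""


class RpiScoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RpiScoreError):
    """A file could not be parsed (malformed record, truncated input)."""


class ValidationError(RpiScoreError, ValueError):
    """Input violated a domain invariant (alphabet, label set, duplicate id)."""


class SchemaError(RpiScoreError):
    """A tabular input is missing required columns."""


class BackendContractError(RpiScoreError):
    """A pluggable backend (folder, secondary-structure predictor) returned
    output violating its contract."""


class EncodingError(RpiScoreError):
    """A residue could not be mapped to a numeric value."""


class DomainError(RpiScoreError, ValueError):
    """An operation was called outside its mathematical domain."""


class TrainingError(RpiScoreError):
    """Model training failed."""


class DegenerateTrainingError(TrainingError):
    """The two classes are indistinguishable (identical means)."""


class CalibrationError(RpiScoreError):
    """Score calibration is undefined (c1 == c2)."""


class ModelIOError(RpiScoreError):
    """A model archive is missing, corrupted, or of an unsupported version."""
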