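"""Exception taxonomy shared across the pipeline stages."""


class MotionLocError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MotionLocError):
    """A sensor log could not be parsed; the message names the offending line."""


class ValidationError(MotionLocError):
    """A domain object violates one of its invariants."""


class SchemaError(MotionLocError):
    """Columns/channels/feature names do not match what a stage expects."""


class ParameterError(MotionLocError):
    """An operation was called with an out-of-range parameter."""


class DegenerateSignalError(MotionLocError):
    """A signal has no usable variation (zero energy / zero variance)."""


class EmptySelectionError(MotionLocError):
    """Variance-threshold selection removed every feature."""


class AugmentationError(MotionLocError):
    """A class cannot be augmented (e.g. its only window is too short)."""


class TrainingError(MotionLocError):
    """The classifier cannot be fitted on the given data."""


class StratificationError(MotionLocError):
    """A class is too small for the requested number of stratified folds."""


class UndefinedMetricError(MotionLocError):
    """A metric is undefined for the given truth/prediction combination."""


class ConfigError(MotionLocError):
    """A configuration file is missing or malformed."""
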