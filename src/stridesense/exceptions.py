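"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`StridesenseError`, so callers (and the CLI exit-code mapping) can
distinguish package errors from programming errors.
"""


class StridesenseError(Exception):
    """Base class for all package errors."""


class ConfigError(StridesenseError):
    """Invalid configuration value or malformed config file."""


class FormatError(StridesenseError):
    """Input file does not match the expected layout (e.g. missing column)."""


class ParseError(StridesenseError):
    """Input file is structurally unreadable (ragged rows, non-numeric cells)."""


class LabelError(StridesenseError):
    """Unknown condition/label token in a stride dataset."""


class ParameterError(StridesenseError):
    """Operation called with out-of-range parameters."""


class SegmentationError(StridesenseError):
    """Stride segmentation could not find enough gait cycles."""


class CalibrationError(StridesenseError):
    """Baseline template could not be calibrated (too few NF strides)."""


class TrainingError(StridesenseError):
    """Model training preconditions violated (e.g. single-class labels)."""


class CapabilityError(StridesenseError):
    """An optional backend (e.g. a deep-learning framework) is unavailable."""
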