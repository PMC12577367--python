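"""Exception hierarchy.

``AbscissionError`` is the common base; ``ConfigError`` and ``DataError``
are distinguished so the pipeline can map them to different exit codes.
"""


class AbscissionError(Exception):
    """Base class for all package errors."""


class ConfigError(AbscissionError):
    """Invalid configuration (unknown keys, missing calibration, bad types)."""


class DataError(AbscissionError):
    """Input data violates a precondition (bad ordering, empty input, ...)."""


class ValidationError(DataError):
    """Scene or record parameters violate a stated invariant."""


class AmbiguousThresholdError(DataError):
    """Automatic thresholding cannot separate a constant image."""


class CalibrationError(ConfigError):
    """Physical calibration (pixel size / frame interval) missing."""


class NoMidbodySignalError(DataError):
    """Midbody segmentation found no signal inside the seed ROI."""
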