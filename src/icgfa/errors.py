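"""Exception hierarchy for the icgfa package."""


class ICGFAError(Exception):
    """Base class for all package errors."""


class VideoFormatError(ICGFAError):
    """Raised when a video file cannot be read or violates stack invariants."""


class CurveFormatError(ICGFAError):
    """Raised when a curve CSV is malformed (e.g. missing a required column)."""


class UnquantifiableCurveError(ICGFAError):
    """Raised when a curve carries no usable signal (constant or zero-area)."""


class ConfigError(ICGFAError):
    """Raised for invalid configuration values (empty grids, bad windows...)."""
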