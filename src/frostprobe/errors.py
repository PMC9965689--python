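"""Exception hierarchy shared across the package."""


class FrostProbeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FrostProbeError, ValueError):
    """An argument is outside the physically/mathematically valid domain."""


class SingularityError(DomainError):
    """The reflection expression is evaluated at its pole (ZP == -ZL)."""


class NoPassiveSolutionError(DomainError):
    """No passive (|reflection| < 1) load can produce the requested voltage."""


class InsufficientDataError(FrostProbeError, ValueError):
    """Too few samples/pairs to carry out the requested computation."""


class MissingBaselineError(FrostProbeError):
    """A series is frozen from its first sample: the pre-freeze water-content
    baseline cannot be established.  Supply ``theta0`` explicitly."""


class CalibrationFileError(FrostProbeError, ValueError):
    """A persisted calibration file is malformed; the message names the field."""


class ReadingsFormatError(FrostProbeError, ValueError):
    """A readings CSV is malformed; the message names the offending row."""


class ConfigError(FrostProbeError, ValueError):
    """A configuration file is malformed or contains unknown keys."""
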