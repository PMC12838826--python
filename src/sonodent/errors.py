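"""Exception hierarchy for sonodent.

``SonodentError`` is the common base.  ``ValidationError`` subclasses signal
bad configuration or bad inputs (CLI exit code 2); everything else that goes
wrong at run time surfaces as an ordinary ``SonodentError`` (exit code 1).
"""


class SonodentError(Exception):
    """Base class for all sonodent errors."""


class ValidationError(SonodentError, ValueError):
    """Invalid configuration, protocol, or input data."""


class InvalidConfigurationError(ValidationError):
    """Pulse/sampling/phantom configuration violates a precondition."""


class InvalidLoadError(ValidationError):
    """A load step is negative, unresolvable, or inconsistent."""


class InvalidProtocolError(ValidationError):
    """A load protocol is empty or its baseline is not the lowest load."""


class InvalidInputError(ValidationError):
    """Generic invalid argument (missing inclusion, negative tau, ...)."""


class InvalidSignalError(ValidationError):
    """A signal contains non-finite samples, no energy, or no usable peak."""


class InvalidWindowError(ValidationError):
    """A search window is empty or lies outside the signal."""


class IncompatibleSignalsError(ValidationError):
    """Two signals cannot be compared (e.g. different sampling rates)."""


class AlignmentError(SonodentError):
    """Surface-echo alignment failed for a named signal."""


class DegenerateSweepError(SonodentError):
    """A load sweep carries no stiffness information (non-positive slope)."""


class NoSensitivityError(SonodentError):
    """A sensitivity curve has no positive rate of change anywhere."""


class ProtocolMismatchError(ValidationError):
    """Reference and test measurement protocols do not match."""


class InvalidReferenceError(ValidationError):
    """A reference measurement set is unusable (non-positive mean tau)."""
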