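"""Exception hierarchy for the SDPPG pipeline.

Every stage raises a subclass of :class:`SdppgError`, so callers (and the
command-line wrapper) can distinguish user/configuration problems from
signal-content problems without string matching.
"""


class SdppgError(Exception):
    """Base class for all package errors."""


class ConfigError(SdppgError):
    """Missing or inconsistent run configuration (e.g. no sampling rate)."""


class SignalParseError(SdppgError):
    """A signal file could not be parsed; the message names the row."""


class FilterDesignError(SdppgError):
    """An FIR design request is infeasible (cutoff vs. Nyquist, ripples...)."""


class SegmentationError(SdppgError):
    """Beat segmentation failed or found fewer beats than requested."""


class DetectionError(SdppgError):
    """The a-e wave pattern could not be resolved on a waveform."""


class GenerationError(SdppgError):
    """The synthetic generator was asked for an unattainable waveform."""
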