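"""Exception hierarchy.

Every error raised by dgephys derives from :class:`DGEphysError` so callers
can catch pipeline failures without masking programming errors.
"""


class DGEphysError(Exception):
    """Base class for all dgephys errors."""


class ParameterError(DGEphysError, ValueError):
    """Invalid parameter value (nonpositive rate, empty group, ...)."""


class ConfigError(DGEphysError, ValueError):
    """Invalid or contradictory run configuration."""


class ParseError(DGEphysError, ValueError):
    """Malformed input file; message names the offending row/column."""


class DegenerateWaveformError(DGEphysError):
    """Waveform lacks the trough/peak structure a feature requires."""


class NoBimodalityError(DGEphysError):
    """AHP distribution is not bimodal; caller should fall back to 70."""


class SmallSampleError(DGEphysError):
    """Group too small for the requested normality test (n < 8)."""


class DegenerateDataError(DGEphysError):
    """Zero-variance / all-identical data where a test statistic is undefined."""


class NoAPError(DGEphysError):
    """No action potential detected in a sweep that requires one."""


class UndefinedRatioError(DGEphysError):
    """SI ratio undefined (phase-1 interaction time is zero)."""


class UndefinedPreferenceError(DGEphysError):
    """Sucrose preference undefined (no fluid consumed)."""


class UndefinedCorrelationError(DGEphysError):
    """Pearson correlation undefined (zero variance in one series)."""
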