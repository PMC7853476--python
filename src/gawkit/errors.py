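"""Exception hierarchy shared across the pipeline."""


class GawkitError(Exception):
    """Base class for all gawkit errors."""


class ConfigurationError(GawkitError):
    """Invalid configuration values (fractions out of range, bad rates...)."""


class DegenerateSignalError(GawkitError):
    """Signal unusable for the requested operation (constant, all-zero...)."""


class UnvoicedSignalError(DegenerateSignalError):
    """No periodicity found in the admissible 80-400 Hz band."""


class TooFewCyclesError(GawkitError):
    """Fewer complete oscillation cycles than the operation requires."""


class AlignmentError(GawkitError):
    """Signals or cycle sets that should share a time base do not."""


class FormatError(GawkitError):
    """Malformed input file (missing columns, NaN, stereo WAV...)."""
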