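"""Exception hierarchy.

Every stage raises a subclass of :class:`SstWinError` so the CLI can attach
stage names and exit nonzero with a single diagnostic line.
"""


class SstWinError(Exception):
    """Base class for all errors raised by this package."""


class InvalidSignalError(SstWinError):
    """Signal violates its invariants (non-finite values, too short, bad rate)."""


class InvalidGridError(SstWinError):
    """Scale/frequency grid is inconsistent or extends past Nyquist."""


class InvalidThresholdError(SstWinError):
    """Negative magnitude threshold for the phase transform."""


class InconsistentInputError(SstWinError):
    """Shapes or axes of paired inputs do not agree."""


class DegenerateInputError(SstWinError):
    """Input carries no usable information (e.g. all-zero matrix)."""


class InvalidBandError(SstWinError):
    """Amplitude band half-width exceeds the frequency grid."""


class InsufficientDataError(SstWinError):
    """Fewer samples remain than the operation requires."""


class InvalidIFError(SstWinError):
    """Instantaneous-frequency values are zero or negative where a ratio is needed."""


class DegenerateCohortError(SstWinError):
    """Cohort lacks one of the two outcome classes."""


class ModelViolationError(SstWinError):
    """Generated amplitude/phase failed the slow-variation conditions repeatedly."""


class InvalidNoiseError(SstWinError):
    """Noise specification is unusable (e.g. non-positive envelope)."""


class InvalidSpecError(SstWinError):
    """Artifact or design specification is infeasible."""


class InvalidDesignError(SstWinError):
    """Cohort design with an empty group."""


class FormatError(SstWinError):
    """Waveform file cannot be parsed or has a non-uniform time axis."""


class MissingRateError(FormatError):
    """One-column waveform file without a sampling rate."""
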