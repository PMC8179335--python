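"""Exception hierarchy.

Every error raised on a bad input or an inconsistent dataset derives from
:class:`FieldUnfoldError`, so callers can catch the package's failures with a
single except clause while letting programming errors propagate.
"""


class FieldUnfoldError(Exception):
    """Base class for all errors raised by fieldunfold."""


class TopologyError(FieldUnfoldError):
    """Invalid strand topology (overlapping ranges, missing couplings, ...)."""


class ConfigurationError(FieldUnfoldError):
    """Invalid schedule, detector or mixture configuration."""


class FormatError(FieldUnfoldError):
    """A trajectory file does not parse under the requested dialect."""


class ElementError(FieldUnfoldError):
    """An element symbol has no form-factor table entry."""


class EnsembleError(FieldUnfoldError):
    """Runs of an ensemble are mutually inconsistent, or the ensemble is empty."""


class EncodingError(FieldUnfoldError):
    """A coupling distance required for state encoding is missing."""


class SamplingError(FieldUnfoldError):
    """A requested probe/sample time does not lie on the trajectory grid."""


class AnalysisError(FieldUnfoldError):
    """An analysis operation received degenerate input (empty curve, N < 2, ...)."""
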