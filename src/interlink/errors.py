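"""Exception hierarchy for interlink."""


class InterlinkError(Exception):
    """Base class for all interlink errors."""


class ConfigurationError(InterlinkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(InterlinkError, ValueError):
    """A malformed input row; the message carries the line number."""


class AlignmentError(InterlinkError, ValueError):
    """Patient ID lists of two datasets do not match."""


class EmptyTargetMapError(InterlinkError, ValueError):
    """A target map with no usable pairs (the inter-relation sum would be zero)."""


class DegenerateScoresError(InterlinkError, ValueError):
    """Constant inter-relation scores: z-normalization is undefined."""


class InvalidLaplacianError(InterlinkError, ValueError):
    """A matrix presented as a graph Laplacian fails its invariants."""


class ConvergenceError(InterlinkError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""


class UndefinedAUCError(InterlinkError, ValueError):
    """AUC requested with only one class present in the truth labels."""
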