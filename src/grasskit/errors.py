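"""Exception types shared across the toolkit."""


class GrasskitError(Exception):
    """Base class for all toolkit errors."""


class InvalidSpecError(GrasskitError, ValueError):
    """A simulation or analysis specification is internally inconsistent."""


class ContigTooShortError(GrasskitError, ValueError):
    """A contig is too short for the requested end trim."""


class UnresolvedGapError(GrasskitError):
    """Gap closure could not merge all contigs into one circle.

    Carries the partial result so callers can inspect what was assembled.
    """

    def __init__(self, message, contigs, open_ends):
        super().__init__(message)
        self.contigs = contigs
        self.open_ends = open_ends


class NoQuadripartiteStructureError(GrasskitError):
    """No inverted-repeat pair of the required size was found."""


class EstimationFailedError(GrasskitError):
    """The k-mer histogram has no coverage peak separable from the error slope."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientRangeError(GrasskitError, ValueError):
    """Observed Ci values do not span enough range to classify a curve."""
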