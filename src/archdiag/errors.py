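"""Exception hierarchy for archdiag.

Every error raised deliberately by the package derives from
:class:`ArchDiagError` so callers can catch package failures with a
single except clause while letting genuine bugs propagate.
"""


class ArchDiagError(Exception):
    """Base class for all archdiag errors."""


class ParameterError(ArchDiagError, ValueError):
    """An argument value is outside its documented domain."""


class DimensionError(ArchDiagError, ValueError):
    """Shapes, lengths or index ranges are inconsistent."""


class DegenerateDataError(ArchDiagError, ValueError):
    """Input carries no usable signal (constant matrix, all-zero gene, ...)."""


class GenerationError(ArchDiagError, RuntimeError):
    """A synthetic-data generator failed its own postcondition."""


class FitFailureError(ArchDiagError, RuntimeError):
    """A curve or frequency fit could not produce a usable result.

    Carries optional diagnostics (last iterate, loss trace) in
    :attr:`diagnostics`.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(ArchDiagError, ValueError):
    """Too few observations for the requested analysis."""


class FormatError(ArchDiagError, ValueError):
    """A file does not parse in the declared dialect."""
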