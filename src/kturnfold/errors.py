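"""Exception hierarchy shared across kturnfold modules."""


class KTurnFoldError(Exception):
    """Base class for all kturnfold errors."""


class InputError(KTurnFoldError):
    """Malformed or out-of-range user input (sequences, indices, grids)."""


class AnnotationError(KTurnFoldError):
    """A required position label is missing or cannot be assigned."""


class ClassificationError(KTurnFoldError):
    """A base pair cannot be classified (ambiguous or gapped bases)."""


class FormatError(KTurnFoldError):
    """A file does not parse in its declared format."""


class ConfigError(KTurnFoldError):
    """Invalid configuration (column maps, rankings, thresholds)."""


class FittingError(KTurnFoldError):
    """Nonlinear fit failed to converge.

    Carries the best parameter estimate seen so far in ``best_fit``
    (may be None) and a free-text ``diagnostics`` flag.
    """

    def __init__(self, message, best_fit=None, diagnostics=""):
        super().__init__(message)
        self.best_fit = best_fit
        self.diagnostics = diagnostics


class GeometryError(KTurnFoldError):
    """Coordination-geometry computation is undefined for this site."""
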