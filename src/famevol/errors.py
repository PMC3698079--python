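"""Exception hierarchy.

Every error raised on invalid user input derives from :class:`FamevolError`
so callers (and the CLI) can catch one base class.
"""


class FamevolError(Exception):
    """Base class for all package errors."""


class AlignmentError(FamevolError):
    """Rows of an alignment disagree in length or are otherwise inconsistent."""


class FrameError(FamevolError):
    """A coding sequence length is not a multiple of three or gaps break frame."""


class ValidationError(FamevolError):
    """A sequence violates a coding-sequence invariant (e.g. internal stop)."""


class AnnotationError(FamevolError):
    """A domain annotation is malformed or out of range."""


class LookupError_(FamevolError):
    """A named domain / leaf / clade does not exist."""


class InputError(FamevolError):
    """A parameter value violates an operation's preconditions."""


class ConfigurationError(FamevolError):
    """A pipeline configuration is incomplete or inconsistent."""


class UndefinedDistanceError(FamevolError):
    """A sequence pair shares no comparable columns."""


class SaturationError(FamevolError):
    """A corrected distance is undefined (p = 1 under the Poisson model)."""


class UndefinedCorrelationError(FamevolError):
    """A distance-matrix triangle has zero variance."""


class OptimizationError(FamevolError):
    """A likelihood optimization failed to converge."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
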