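"""Exception hierarchy for the ador package."""


class AdorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AdorError, ValueError):
    """Input violates a documented precondition or invariant."""


class UnderdeterminedFitError(AdorError):
    """Fewer observations than coefficients requested for a fit."""


class NoCoreSetError(AdorError):
    """The iterative co-expression degree filter removed every gene."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MissingControlCohortError(AdorError):
    """An operation requiring matched control samples found none."""


class NoAdmissibleSourceError(AdorError):
    """Every producing organ was excluded (brain, non-hypothalamus)."""


class NoSignificantModelError(AdorError):
    """All-subsets regression found no subset with all coefficients significant.

    The best inadmissible fit is attached as ``diagnostics`` so callers can
    inspect how close the data came to supporting a model.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class InsufficientCohortError(AdorError):
    """Too few usable samples/bins to estimate an infection curve."""


class DegenerateClusterError(AdorError):
    """A gene cluster has no expression variance to summarise."""
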