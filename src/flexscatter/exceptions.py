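"""Exception hierarchy.

All flexscatter errors derive from :class:`FlexscatterError` so callers can
catch the package's failures with a single ``except`` clause.  Subclasses are
``ValueError`` as well, since they almost always signal bad input.
"""


class FlexscatterError(ValueError):
    """Base class for all flexscatter errors."""


class ArgumentError(FlexscatterError):
    """An operation was called with inconsistent or out-of-range arguments."""


class FormatError(FlexscatterError):
    """A file could not be parsed in the expected format."""


class InsufficientDataError(FlexscatterError):
    """Too few data points to carry out the requested analysis."""


class ValidationError(FlexscatterError):
    """Data violates a structural invariant (grids, monotonicity, ...)."""


class NoGuinierRegionError(FlexscatterError):
    """No low-q window satisfying the Guinier criteria could be found."""


class DegenerateDistributionError(FlexscatterError):
    """A P(r) function integrates to a non-positive total."""


class SamplingFailureError(FlexscatterError):
    """Monte-Carlo chain sampling reached its retry limit.

    Carries the ``seed`` attribute of the failed attempt for reproduction.
    """

    def __init__(self, message, seed=None):
        super().__init__(message)
        self.seed = seed


class ClashError(FlexscatterError):
    """A built model has an unacceptable fraction of steric clashes."""


class AmbiguityError(FlexscatterError):
    """A contact graph has no unique linear path (branch point present)."""


class DegenerateGeometryError(FlexscatterError):
    """Geometry is degenerate (e.g. collinear points given to a helix fit)."""


class UnknownElementError(FlexscatterError):
    """An atom's element has no entry in the van der Waals radius table."""


class UnsupportedSpaceGroupError(FlexscatterError):
    """The space-group symbol was not recognised."""
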