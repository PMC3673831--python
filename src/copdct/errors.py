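"""Exception hierarchy for the copdct pipeline.

Every error raised by the package derives from :class:`CopdCtError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class CopdCtError(Exception):
    """Base class for all copdct errors."""


class ConfigurationError(CopdCtError):
    """A configuration value is invalid; the message names the offending field."""


class GeometryError(CopdCtError):
    """A geometric precondition is violated (object outside the grid, bad point)."""


class SeedPointError(CopdCtError):
    """The region-growing seed point does not lie in air-filled lumen."""


class DegenerateInputError(CopdCtError):
    """Input is structurally valid but degenerate (empty mask, single class...)."""


class DegenerateMaskError(DegenerateInputError):
    """A mask has no interior suitable for skeletonization."""


class DegenerateRegressionError(DegenerateInputError):
    """Fewer than two distinct abscissa values; a regression line is undefined."""


class SeparationError(CopdCtError):
    """Complete separation: the logistic likelihood has no finite maximizer."""


class ConvergenceError(CopdCtError):
    """Iterative fit failed to converge within the iteration budget."""


class MissingDataError(CopdCtError):
    """Records contain missing covariates; imputation is out of scope."""
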