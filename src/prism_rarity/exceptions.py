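"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors -> 2, routing
errors -> 3, numeric errors -> 4.
"""


class PrismError(Exception):
    """Base class for all package errors."""


class ValidationError(PrismError):
    """Malformed input data, configuration, or violated preconditions."""


class FitError(PrismError):
    """Curve fitting could not be performed or did not converge.

    ``last_iterate`` carries the optimizer's final parameter vector when
    the failure happened mid-optimization, for diagnostics.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class RoutingError(PrismError):
    """No rarity-estimation method is applicable to the evidence profile."""


class NumericError(PrismError):
    """A numerical procedure (root finding, quadrature) failed to converge."""


class NotFoundError(PrismError):
    """A scan over a discrete range found no value meeting the criterion."""
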