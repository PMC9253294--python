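"""Exception hierarchy shared across the package."""


class GatecycleError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GatecycleError, ValueError):
    """A parameter value is outside its mathematical domain.

    The message always names the offending parameter.
    """


class InputError(GatecycleError, ValueError):
    """Malformed or inconsistent user input (schemas, ladders, corner sets)."""


class FitError(GatecycleError, RuntimeError):
    """A curve fit failed or the data are degenerate.

    Parameters
    ----------
    message : str
    diagnostics : dict, optional
        Solver/diagnostic details for the caller (starts tried, RSS values,
        reason for degeneracy).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EstimationError(GatecycleError, RuntimeError):
    """A statistical estimate is undefined or inconsistent.

    Raised e.g. when the current variance exceeds the binomial bound
    (i*I <= sigma^2) so the channel count has no finite positive value, or
    when an open probability falls outside (0, 1].
    """
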