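"""Exception hierarchy shared across the toolkit.

Exit-code mapping for the command line lives in :mod:`cttkit.cli`
(input errors -> 2, convergence errors -> 3).
"""


class CttkitError(Exception):
    """Base class for all toolkit errors."""


class InputError(CttkitError, ValueError):
    """Invalid user input: bad dimensions, asymmetric matrix, bad codes."""


class DimensionError(InputError):
    """Shapes of weights/items/covariances do not conform."""


class DegenerateScaleError(InputError):
    """An item has zero sample variance where a scale is required."""


class NotApplicableError(InputError):
    """A closed form does not apply to this input (e.g. sign-indeterminate)."""


class NumericError(CttkitError, ArithmeticError):
    """Singular or otherwise numerically unusable matrix."""


class ConvergenceError(CttkitError, RuntimeError):
    """Iterative estimation failed to converge.

    Carries the best state found so the caller can inspect it.
    """

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state
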