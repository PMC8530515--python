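"""Exception hierarchy for model-level failures."""


class TlfoptError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TlfoptError, ValueError):
    """A global or per-factor parameter violates its constraints."""


class InputError(TlfoptError, ValueError):
    """A user-supplied table or value is malformed or out of range."""


class AllocationInfeasibleError(TlfoptError):
    """Factor fractions exhaust the translation sector (phi_act <= 0)."""


class BudgetInfeasibleError(TlfoptError):
    """The tRNA budget cannot cover the minimal steady-state occupancies."""


class ConvergenceError(TlfoptError):
    """An iterative solver failed to reach its tolerance.

    Carries the iterate trace for diagnosis.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
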