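"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class InfeasibleSimulationError(RuntimeError):
    """Raised when a constrained range simulation cannot be completed.

    Carries enough context (stuck species, uncovered cells) for the caller
    to diagnose whether the targets were infeasible or the retry budget was
    simply too small.
    """

    def __init__(self, message: str, *, species=None, cells=None):
        super().__init__(message)
        self.species = species
        self.cells = cells
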