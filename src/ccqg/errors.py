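"""Exception taxonomy shared across the package."""


class CcqgError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CcqgError, ValueError):
    """An argument violates a documented precondition."""


class InconsistentInputError(CcqgError, ValueError):
    """Two inputs that must agree (e.g. share a genetic map) do not."""


class DegenerateDesignError(CcqgError, ValueError):
    """A regression design matrix is singular; the message names the factor."""


class StageError(CcqgError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
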