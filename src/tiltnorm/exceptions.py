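"""Exception hierarchy shared across the package."""


class TiltnormError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TiltnormError, ValueError):
    """A model, observer, or fitting parameter violates its domain."""


class InvalidInputError(TiltnormError, ValueError):
    """Input data (stimulus, trial table, binned data) violates a precondition."""


class DivergenceError(TiltnormError, ArithmeticError):
    """A requested quantity is unbounded (e.g. saturating rate with kappa = 0)."""


class UndecodableError(TiltnormError, RuntimeError):
    """The population response carries no signal in the decoding window."""


class NonIdentifiableError(TiltnormError, RuntimeError):
    """The likelihood has no interior optimum (e.g. responses constant at all levels)."""


class UndefinedStatisticError(TiltnormError, ArithmeticError):
    """A statistic is undefined for the given inputs (zero variance, unconverged fit)."""


class ValidationError(TiltnormError, ValueError):
    """A serialized table or config failed schema validation."""


class PipelineStageError(TiltnormError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
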