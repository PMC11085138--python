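"""Exception hierarchy shared across the package.

All errors raised on invalid scientific input derive from
:class:`PhycobatchError`, so callers (and the CLI) can distinguish bad data
from programming errors.
"""


class PhycobatchError(Exception):
    """Base class for all domain errors raised by phycobatch."""


class DomainError(PhycobatchError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class InsufficientDataError(PhycobatchError, ValueError):
    """Too few usable observations for the requested estimate."""


class NoExponentialPhaseError(PhycobatchError):
    """No window of the growth curve satisfies the log-linearity criterion."""

    def __init__(self, message: str, best_r_squared: float | None = None):
        super().__init__(message)
        self.best_r_squared = best_r_squared


class NegativeGrowthError(PhycobatchError, ValueError):
    """Final biomass below initial biomass in a yield calculation."""


class NoConsumptionError(PhycobatchError, ValueError):
    """Substrate series shows no net consumption."""


class ParseError(PhycobatchError, ValueError):
    """A data file does not match its documented format.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class PipelineError(PhycobatchError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
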