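"""Exception hierarchy shared across kinseq modules."""


class KinseqError(Exception):
    """Base class for all kinseq errors."""


class ConfigurationError(KinseqError):
    """A spec/config object is internally inconsistent or names an unknown option."""


class PreconditionError(KinseqError):
    """An operation was called with inputs that violate its contract."""


class IntegrationDivergedError(KinseqError):
    """Brownian-dynamics integration produced non-finite coordinates."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class TrainingDivergedError(KinseqError):
    """A neural-network training run produced a non-finite loss."""


class DegenerateInputError(KinseqError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class ParseError(KinseqError):
    """A trajectory or state-sequence file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class UnsupportedOperationError(KinseqError):
    """The operation is not available for this model variant."""
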