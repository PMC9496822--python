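"""Exception hierarchy shared across the package."""


class MfmicdError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MfmicdError, ValueError):
    """A parameter violates its documented constraints."""


class InvalidInputError(MfmicdError, ValueError):
    """An input object violates its documented invariants."""


class DegenerateSignalError(MfmicdError, ValueError):
    """A signal is degenerate (e.g. identically zero) for the requested analysis."""


class UndefinedMetricError(MfmicdError, ValueError):
    """The requested metric is undefined for the given input (e.g. Q on an edgeless graph)."""


class StageError(MfmicdError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
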