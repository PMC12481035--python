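"""Exception hierarchy for minfluxpair."""


class MinfluxPairError(Exception):
    """Base class for all package errors."""


class FormatError(MinfluxPairError):
    """A file does not conform to the documented schema (e.g. missing column)."""


class ParseError(MinfluxPairError):
    """A cell in an input file could not be parsed; carries the row number."""


class ConfigurationError(MinfluxPairError):
    """A configuration value violates its invariants."""


class InsufficientDataError(MinfluxPairError):
    """An operation needs more points/samples than were provided."""


class DomainError(MinfluxPairError):
    """An argument is outside the mathematical domain of an operation."""


class ConsistencyError(MinfluxPairError):
    """Two artifacts that must describe the same field do not."""


class StageError(MinfluxPairError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
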