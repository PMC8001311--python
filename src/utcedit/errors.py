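"""Exception hierarchy shared across the pipeline stages."""


class UtcEditError(Exception):
    """Base class for all errors raised by this package."""


class InvalidConfigError(UtcEditError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class NoSignalError(UtcEditError, ValueError):
    """A chromatogram window carries no intensity in the channels of interest."""


class TableFormatError(UtcEditError, ValueError):
    """A candidate/validation ledger could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class PipelineError(UtcEditError, RuntimeError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
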