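"""Exception hierarchy shared across the package."""


class SpliceDegreeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpliceDegreeError):
    """An input table is malformed (missing column, duplicate ID, conflict)."""


class PipelineError(SpliceDegreeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
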