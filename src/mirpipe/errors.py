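"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`MirpipeError` so callers can
catch one base class; validation failures additionally derive from
``ValueError`` so they behave sensibly in generic code.
"""


class MirpipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MirpipeError, ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(MirpipeError, ValueError):
    """Invalid argument values or an invalid configuration object."""


class ConfigurationError(MirpipeError, ValueError):
    """A policy or config refers to something the data does not provide."""


class DataIntegrityError(MirpipeError, ValueError):
    """Inconsistent data across arrays (e.g. a probe missing from one array)."""


class PipelineStageError(MirpipeError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
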