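"""Exception hierarchy shared across the package."""


class PirnasigError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PirnasigError, ValueError):
    """A file did not parse under the named standard format."""


class ConfigError(PirnasigError, ValueError):
    """An invalid parameter or preset was supplied."""


class BoundsError(PirnasigError, ValueError):
    """A coordinate fell outside its valid range."""


class NormalizationError(PirnasigError, ValueError):
    """A normalization denominator could not be computed or is zero."""


class EmptySetError(PirnasigError, ValueError):
    """An operation received an empty read set where reads are required."""


class DegenerateBackgroundError(PirnasigError, ValueError):
    """Background dispersion is zero; a Z score would be infinite."""


class StratumExhaustedError(PirnasigError, ValueError):
    """A required sampling stratum is empty."""

    def __init__(self, nucleotide: str, message: str | None = None):
        self.nucleotide = nucleotide
        super().__init__(message or f"sampling stratum for nucleotide {nucleotide!r} is empty")


class PipelineStageError(PirnasigError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
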