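"""Exception hierarchy for ihcnorm."""


class IHCNormError(Exception):
    """Base class for all ihcnorm errors."""


class StainEstimationError(IHCNormError):
    """Stain-vector estimation failed (too few pixels, degenerate OD cloud, ...)."""


class DegenerateStainError(IHCNormError):
    """A stain density row is degenerate (zero pseudo-maximum with nonzero mass)."""


class ConfigError(IHCNormError):
    """Invalid configuration file or parameter value."""


class PipelineStageError(IHCNormError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
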