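"""Exception hierarchy for pahrisk."""


class PahRiskError(Exception):
    """Base class for all pahrisk errors."""


class ConfigurationError(PahRiskError, ValueError):
    """A run or generator configuration is invalid (e.g. a PMF that does not sum to 1)."""


class ValidationError(PahRiskError, ValueError):
    """An input value violates a documented precondition (negative count, missing LOD, ...)."""


class MetadataError(PahRiskError, ValueError):
    """Analyte metadata is inconsistent (unknown parent, missing analyte, ...)."""


class FitError(PahRiskError, RuntimeError):
    """Maximum-likelihood fitting failed (degenerate sample, non-convergence)."""


class PipelineError(PahRiskError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
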