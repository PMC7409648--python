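"""Exception hierarchy.

Validation failures (bad input data, malformed files) and statistical-stage
failures (degenerate samples, rank deficiency) are kept distinct so the CLI
can map them to different exit codes.
"""


class SurvcutError(Exception):
    """Base class for all package errors."""


class ValidationError(SurvcutError):
    """Invalid input data or configuration.

    ``field`` names the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class StatisticalError(SurvcutError):
    """A statistical stage cannot be carried out on the given sample."""


class NoAdmissibleCutpointError(StatisticalError):
    """No candidate threshold satisfies the minimum group-size constraint."""


class SubsetScanError(StatisticalError):
    """A cross-validation fold's cut-point scan failed.

    Carries the seed of the random split so callers can resample or report.
    """

    def __init__(self, message: str, seed: int, subset: str):
        self.seed = seed
        self.subset = subset
        super().__init__(f"subset {subset} (split seed {seed}): {message}")


class RankDeficiencyError(StatisticalError):
    """Design matrix is rank deficient (constant or collinear columns)."""


class PipelineError(SurvcutError):
    """A pipeline stage aborted; carries the stage name and partial results."""

    def __init__(self, stage: str, cause: Exception, partial: dict | None = None):
        self.stage = stage
        self.cause = cause
        self.partial = partial or {}
        super().__init__(f"stage '{stage}' failed: {cause}")
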