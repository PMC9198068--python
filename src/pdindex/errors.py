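"""Exception types shared across the pipeline stages."""


class PdindexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PdindexError, ValueError):
    """Invalid generator or pipeline configuration."""


class SchemaError(PdindexError, ValueError):
    """An input table violates its expected schema."""


class ZeroVarianceError(PdindexError, ValueError):
    """A PCA input column has no variance."""


class ColumnMismatchError(PdindexError, ValueError):
    """Scoring matrix columns do not match the fitted model."""


class RasterExtentError(PdindexError, ValueError):
    """A queried point falls outside the raster extent."""


class DegenerateRangeError(PdindexError, ValueError):
    """Min-max normalization requested on a zero-width range."""


class SingularSystemError(PdindexError, ValueError):
    """The penalized spline system is numerically singular."""


class DomainError(PdindexError, ValueError):
    """A prediction location falls outside the spline domain."""


class StageError(PdindexError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
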