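"""Exception hierarchy shared across the pipeline stages."""


class AnBrainageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AnBrainageError, ValueError):
    """Invalid cohort/pipeline configuration (bad counts, ranges, unknown keys)."""


class ShapeError(AnBrainageError, ValueError):
    """Voxel grids, templates or design matrices with inconsistent shapes."""


class EmptyMaskError(AnBrainageError, ValueError):
    """A brain mask with no voxels selected."""


class DegenerateModelError(AnBrainageError, RuntimeError):
    """All basis functions pruned, or a model otherwise collapsed."""


class NumericalError(AnBrainageError, RuntimeError):
    """Non-finite evidence or failed linear algebra during fitting."""


class InsufficientDataError(AnBrainageError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateFitError(AnBrainageError, ValueError):
    """A regression with zero predictor variance."""


class CollinearityError(AnBrainageError, ValueError):
    """Rank-deficient design matrix; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; offending columns: {self.columns}")


class ValidationError(AnBrainageError, ValueError):
    """Malformed input table or file; message cites row/column where possible."""
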