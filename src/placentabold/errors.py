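"""Exception hierarchy shared across the pipeline."""


class PlacentaBoldError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PlacentaBoldError, ValueError):
    """An input violates a documented precondition or type invariant."""


class DimensionError(ValidationError):
    """An array does not have the expected dimensionality or shape."""


class SchemaError(ValidationError):
    """Tabular records have inconsistent keys."""


class GeometryError(ValidationError):
    """A phantom geometry does not fit the requested voxel grid."""


class InsufficientBaselineError(ValidationError):
    """Fewer than the minimum number of usable baseline frames remain."""


class RangeError(ValidationError):
    """A requested time point lies outside the supported interval."""


class CollinearityError(ValidationError):
    """A regression design matrix is rank deficient."""

    def __init__(self, fields):
        self.fields = list(fields)
        super().__init__(f"collinear fixed-effect columns: {self.fields}")
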