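"""Exception and warning types shared across the pipeline stages."""


class FmritexError(Exception):
    """Base class for all package errors."""


class FormatError(FmritexError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(FmritexError):
    """Input volume is not the expected 3-D mean EPI volume."""


class EmptyROIError(FmritexError):
    """ROI mask selects no voxels."""


class GeometryError(FmritexError):
    """A requested ROI geometry does not fit inside the volume."""


class FeatureUndefinedError(FmritexError):
    """Texture features cannot be computed (e.g. no co-occurring pixel pair)."""


class ContractError(FmritexError):
    """An operation received input violating its stated precondition."""


class ClusterTooSmallError(FmritexError):
    """Cluster falls below the minimum voxel count and is filtered out."""


class UnlabelableError(FmritexError):
    """Cluster cannot be assigned an E/NE label (unknown regions or Z tie)."""


class SingularDesignError(FmritexError):
    """Design matrix is rank deficient (e.g. a constant feature column)."""


class SchemaError(FmritexError):
    """Tabular input is missing required columns."""


class UndefinedAUCError(FmritexError):
    """ROC/AUC undefined because only one class is present."""


class SeparationWarning(UserWarning):
    """Logistic fit encountered (quasi-)perfect separation."""


class DegenerateStatisticWarning(UserWarning):
    """A statistic hit a degenerate case (zero variance, empty direction)."""
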