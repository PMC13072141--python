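"""Exception hierarchy shared across the package."""


class MorphoMILError(Exception):
    """Base class for all package errors."""


class ValidationError(MorphoMILError):
    """An object violates one of its declared invariants."""


class FormatError(MorphoMILError):
    """A file does not conform to the expected on-disk layout."""


class SchemaError(MorphoMILError):
    """A table is missing required columns or has the wrong types."""


class ShapeError(MorphoMILError):
    """Array dimensions are inconsistent with the operation's contract."""


class MissingDataError(MorphoMILError):
    """Required per-patient values are absent."""


class StratificationError(MorphoMILError):
    """A class/stratum is too small to split as requested."""


class DegenerateLabelError(MorphoMILError):
    """A training set contains only one outcome label."""


class DivergenceError(MorphoMILError):
    """Optimization produced a non-finite loss."""


class InfeasibleKError(MorphoMILError):
    """Requested number of clusters exceeds the number of distinct rows."""


class GroupSizeError(MorphoMILError):
    """A comparison group is empty or too small."""


class UndefinedMetricError(MorphoMILError):
    """A metric's denominator is empty (e.g. single-class labels)."""


class EmptyGridError(MorphoMILError):
    """Image too small to contain a single patch."""


class GenerationError(MorphoMILError):
    """Synthetic-cohort generation produced an infeasible dataset."""
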