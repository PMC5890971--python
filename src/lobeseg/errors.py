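"""Exception hierarchy shared across the package."""


class LobeSegError(Exception):
    """Base class for all lobeseg errors."""


class FormatError(LobeSegError):
    """A file could not be read or written in a supported image format."""


class DimensionalityError(FormatError):
    """An image is not a 3-D volume."""


class ValidationError(LobeSegError):
    """An object violates one of its declared invariants."""


class GridMismatchError(ValidationError):
    """Two gridded objects do not share shape/spacing."""


class EmptyInputError(LobeSegError):
    """An operation received an empty mask or image where content is required."""


class SeedNotFoundError(LobeSegError):
    """No tracheal air seed could be located in the cranial slices."""


class SegmentationFailureError(LobeSegError):
    """A segmentation stage could not produce a usable result."""


class LabelingError(LobeSegError):
    """Anatomical labeling of the airway graph failed."""


class UndefinedMetricError(LobeSegError):
    """A metric is undefined for the given inputs (e.g. both masks empty)."""


class InsufficientDataError(LobeSegError):
    """Too few samples for the requested statistic."""
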