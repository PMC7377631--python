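"""Exception hierarchy for the suturemap pipeline."""


class SutureMapError(Exception):
    """Base class for all suturemap errors."""


class UnsupportedFormatError(SutureMapError):
    """A volume or image file could not be read as any supported format."""


class AmbiguousSeriesError(SutureMapError):
    """A DICOM directory holds more than one series."""


class ValidationError(SutureMapError):
    """An input violates a domain-type invariant (e.g. non-binary image)."""


class EmptySkullError(SutureMapError):
    """An operation that needs bone voxels received an empty mask."""


class ResolutionError(SutureMapError):
    """A phantom cannot be rendered at the requested voxel spacing."""


class InsufficientDataError(SutureMapError):
    """Too few cases per class to build the requested dataset split."""


class DegenerateDataError(SutureMapError):
    """A training set with fewer than two classes cannot fit a classifier."""
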