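"""Exception hierarchy for the speckler toolkit."""


class SpecklerError(Exception):
    """Base class for all speckler errors."""


class FormatError(SpecklerError):
    """The image file could not be read or has an unsupported layout."""


class CalibrationMissingError(SpecklerError):
    """No voxel-size metadata in the file and no user override supplied."""


class IncompatibleStacksError(SpecklerError):
    """Stacks differ in shape or voxel size and cannot be merged."""


class DegenerateHistogramError(SpecklerError):
    """Automatic thresholding is undefined (constant image)."""


class EmptyMatchingError(SpecklerError):
    """No bead could be matched across channels."""


class InsufficientBeadsError(SpecklerError):
    """Too few matched beads to constrain the requested aberration model."""


class CalibrationMismatchError(SpecklerError):
    """An aberration calibration does not cover the target's channels."""


class ParseError(SpecklerError):
    """A results or calibration file does not follow the expected schema."""


class EmptySummaryError(SpecklerError):
    """A summary was requested over zero measurable records."""


class UsageError(SpecklerError):
    """Invalid pipeline configuration."""


class PlacementError(SpecklerError):
    """Could not place the requested beads at the required separation."""
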