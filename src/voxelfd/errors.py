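"""Exception hierarchy for voxelfd.

Every error raised by the public API derives from :class:`VoxelFDError`,
so callers can catch a single base class at pipeline boundaries.
"""


class VoxelFDError(Exception):
    """Base class for all voxelfd errors."""


# --- volume / cohort I/O -------------------------------------------------

class FileUnreadableError(VoxelFDError):
    """The input file does not exist or cannot be parsed."""


class NotThreeDimensionalError(VoxelFDError):
    """The loaded image is not a 3-D volume."""


class AnisotropicVoxelsError(VoxelFDError):
    """Voxel spacing is anisotropic beyond the allowed tolerance."""


class PathNotWritableError(VoxelFDError):
    """The output path cannot be written."""


class MissingColumnError(VoxelFDError):
    """A required column is absent from the cohort table."""


class NonNumericValueError(VoxelFDError):
    """A column expected to be numeric contains non-numeric values."""


class DuplicateSubjectIdError(VoxelFDError):
    """Subject identifiers in the cohort table are not unique."""


# --- phantom generation --------------------------------------------------

class InvalidSizeError(VoxelFDError):
    """Phantom size parameter out of range."""


class LevelOutOfRangeError(VoxelFDError):
    """Menger-sponge recursion level outside the supported range."""


class InvalidRadiusError(VoxelFDError):
    """Shell radius too small."""


class InvalidParamsError(VoxelFDError):
    """Invalid synthetic-cohort parameters."""


# --- box counting --------------------------------------------------------

class EmptyVolumeError(VoxelFDError):
    """The volume contains no foreground voxels."""


class OffsetOutOfRangeError(VoxelFDError):
    """A grid offset component lies outside [0, s)."""


# --- scale selection -----------------------------------------------------

class IntervalOutOfRangeError(VoxelFDError):
    """Interval indices do not address the sampled scales."""


class DegenerateIntervalError(VoxelFDError):
    """Fewer than two distinct scales in the interval."""


class TooFewScalesError(VoxelFDError):
    """Not enough sampled scales for the requested selection."""


class BoundsNotSampledError(VoxelFDError):
    """Requested interval bounds are not members of the sampled scale set."""


class InvalidBoundsError(VoxelFDError):
    """mfs/Mfs bounds are non-positive or inverted."""


# --- statistics ----------------------------------------------------------

class ConstantInputError(VoxelFDError):
    """Correlation requested on a constant vector."""


class LengthMismatchError(VoxelFDError):
    """Paired vectors differ in length."""


class TooFewSubjectsError(VoxelFDError):
    """Cohort too small for the requested cross-validation."""


class MissingValuesError(VoxelFDError):
    """Missing values in columns used by a model."""
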