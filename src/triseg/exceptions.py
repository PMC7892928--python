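"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`TrisegError`
so callers (and the CLI) can distinguish usage problems from bugs.
"""


class TrisegError(Exception):
    """Base class for all triseg errors."""


class VolumeIOError(TrisegError, OSError):
    """A file could not be read or written as a NIfTI volume."""


class DimensionalityError(TrisegError):
    """Input volume is not 3D and cannot be squeezed to 3D."""


class GeometryError(TrisegError):
    """Affine/shape/orientation mismatch between grids."""


class DegenerateInputError(TrisegError):
    """Input has no usable signal (e.g. constant intensity volume)."""


class DegenerateMaskError(TrisegError):
    """Mask is empty or full where a boundary is required."""


class ShapeError(TrisegError):
    """Array shapes are incompatible with the requested operation."""


class SamplingError(TrisegError):
    """A patch cannot be sampled under the requested constraints."""


class ConfigError(TrisegError):
    """Invalid configuration value."""


class ScheduleError(TrisegError):
    """Epoch outside the configured schedule horizon."""


class SplitError(TrisegError):
    """A train/validation/test split cannot be constructed."""


class EnsembleError(TrisegError):
    """The three-orientation model ensemble is incomplete."""


class PairingError(TrisegError):
    """Prediction/ground-truth subject lists do not match."""


class PhantomSpecError(TrisegError):
    """Synthetic phantom specification is invalid."""
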