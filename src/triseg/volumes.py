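"""Volumetric data types, NIfTI I/O, intensity normalization and orientation.

The three segmentation networks are specialized on the sagittal, coronal and
axial planes, so "which array axis is which plane" must be unambiguous.  Every
input volume is reoriented (axis permutations and flips only, never resampled)
to the RAS+ convention:

* axis 0 runs left -> right   (slicing it yields sagittal planes),
* axis 1 runs posterior -> anterior (coronal planes),
* axis 2 runs inferior -> superior  (axial planes).

The reorientation is recorded in an :class:`OrientationFrame` so that output
masks can be mapped back, bit-exactly, to the native grid of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio

from .exceptions import (
    DegenerateInputError,
    DimensionalityError,
    GeometryError,
    VolumeIOError,
)

CANONICAL_AXCODES = ("R", "A", "S")
#: role of each canonical array axis
AXIS_ROLES = ("sagittal", "coronal", "axial")
ORIENTATIONS = AXIS_ROLES
ORIENTATION_AXIS = {name: i for i, name in enumerate(AXIS_ROLES)}


@dataclass
class ImageVolume:
    """A 3D scalar grid with its grid-to-world affine.

    ``normalized`` records whether :func:`minmax_normalize` has been applied;
    normalized volumes are guaranteed to lie in [0, 1].
    """

    data: np.ndarray
    affine: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(f"expected 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DegenerateInputError("volume contains NaN or Inf voxels")
        if self.normalized and (self.data.min() < 0 or self.data.max() > 1):
            raise DegenerateInputError("normalized volume must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each array axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class LabelVolume:
    """A binary mask living on the same grid as its paired :class:`ImageVolume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(f"expected 3D mask, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise DegenerateInputError(f"mask values must be exactly {{0,1}}, got {vals}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class OrientationFrame:
    """Invertible record of the permutation/flips applied by :func:`to_canonical`.

    ``transform`` is a nibabel orientation array mapping native array axes to
    canonical RAS+ axes; ``native_shape``/``native_affine`` describe the grid
    the volume came from.
    """

    transform: np.ndarray
    native_shape: tuple[int, int, int]
    native_affine: np.ndarray

    @property
    def axis_roles(self) -> dict[int, str]:
        """Role played by each *native* array axis."""
        return {int(src): AXIS_ROLES[dst] for src, (dst, _flip) in enumerate(self.transform)}

    @property
    def flips(self) -> tuple[bool, bool, bool]:
        """Whether each native axis was flipped on the way to canonical."""
        return tuple(self.transform[i, 1] < 0 for i in range(3))

    @property
    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.transform[:, 0], [0, 1, 2]) and np.all(self.transform[:, 1] == 1)
        )

    def inverse_transform(self) -> np.ndarray:
        """Orientation array mapping canonical axes back to native axes."""
        inv = np.zeros_like(self.transform)
        for src in range(3):
            dst = int(self.transform[src, 0])
            inv[dst] = (src, self.transform[src, 1])
        return inv

    def to_native(self, canonical_data: np.ndarray) -> np.ndarray:
        """Undo the canonicalizing permutation/flips on an array (bit-exact)."""
        canonical_shape = tuple(np.asarray(self.native_shape)[self.transform[:, 0].argsort()])
        if canonical_data.shape != canonical_shape:
            raise GeometryError(
                f"array shape {canonical_data.shape} does not match this frame "
                f"(expected {canonical_shape})"
            )
        return nio.apply_orientation(canonical_data, self.inverse_transform())


def read_volume(path: str | Path) -> ImageVolume:
    """Load a NIfTI-1/2 file as an :class:`ImageVolume` (data untouched).

    Trailing singleton dimensions (e.g. a (X, Y, Z, 1) file) are squeezed;
    genuinely 4D inputs are rejected.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim > 3:
        squeezable = all(s == 1 for s in data.shape[3:])
        if not squeezable:
            raise DimensionalityError(
                f"{path} has shape {data.shape}; only 3D (or singleton-padded) supported"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim != 3:
        raise DimensionalityError(f"{path} has shape {data.shape}; expected 3D")
    return ImageVolume(data=np.asarray(data, dtype=np.float32), affine=np.asarray(img.affine))


def write_volume(v: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine), str(path))


def read_mask(path: str | Path) -> LabelVolume:
    vol = read_volume(path)
    return LabelVolume(data=(vol.data > 0.5).astype(np.uint8), affine=vol.affine)


def minmax_normalize(v: ImageVolume) -> ImageVolume:
    """Rescale intensities linearly to [0, 1] over the whole volume.

    Constant volumes are rejected: mapping them silently to zero would feed
    meaningless patches to training.
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi <= lo:
        raise DegenerateInputError("constant-intensity volume cannot be minmax-normalized")
    data = (v.data.astype(np.float32) - lo) / (hi - lo)
    return ImageVolume(data=data, affine=v.affine.copy(), normalized=True)


def to_canonical(v: ImageVolume) -> tuple[ImageVolume, OrientationFrame]:
    """Permute/flip axes into RAS+ order; never resamples.

    Returns the canonical volume and the frame needed to map results back.
    """
    if abs(np.linalg.det(v.affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular; orientation is undefined")
    native_ornt = nio.io_orientation(v.affine)
    target_ornt = nio.axcodes2ornt(CANONICAL_AXCODES)
    transform = nio.ornt_transform(native_ornt, target_ornt).astype(int)
    data = nio.apply_orientation(v.data, transform)
    affine = v.affine @ nio.inv_ornt_aff(transform, v.data.shape)
    frame = OrientationFrame(
        transform=transform,
        native_shape=tuple(int(s) for s in v.data.shape),
        native_affine=v.affine.copy(),
    )
    vol = ImageVolume(data=data, affine=affine, normalized=v.normalized)
    return vol, frame


def canonical_mask(m: LabelVolume, frame: OrientationFrame) -> LabelVolume:
    """Transport a native-space mask into the canonical frame of its image."""
    if m.shape != frame.native_shape:
        raise GeometryError(f"mask shape {m.shape} != frame native shape {frame.native_shape}")
    data = nio.apply_orientation(m.data, frame.transform)
    affine = frame.native_affine @ nio.inv_ornt_aff(frame.transform, frame.native_shape)
    return LabelVolume(data=data, affine=affine)


def write_mask(m: LabelVolume, frame: OrientationFrame, path: str | Path) -> None:
    """Write a canonical-grid mask back in the ORIGINAL file's space.

    The inverse permutation/flips are applied and the native affine restored,
    so the saved mask overlays the input volume voxel-for-voxel.  Masks are
    stored as uint8 with values {0, 1}.
    """
    native = frame.to_native(m.data).astype(np.uint8)
    nib.save(nib.Nifti1Image(native, frame.native_affine), str(path))
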