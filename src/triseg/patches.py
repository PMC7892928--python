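"""Extended-2D patch extraction and runtime augmentation.

Training patches are 3-channel 2D windows: the slice containing the target
window plus its two neighbours along the slicing axis, giving the planar
network a sliver of through-plane context.  Positive patches are centered on
a voxel of the structure's inner border; negative patches are centered
anywhere in the head, teaching the network what the structure is *not*.
Patches are drawn fresh every epoch (never pre-materialized) and augmented on
the fly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, SamplingError, ShapeError
from .volumes import ORIENTATION_AXIS, ORIENTATIONS, ImageVolume, LabelVolume


@dataclass
class AugmentConfig:
    """Ranges of the runtime augmentations.

    Defaults: additive intensity shift in [-0.05, 0.05], rotation in
    [-10, 10] degrees, isotropic scaling in [-10, 10] percent, and additive
    Gaussian noise with mean 0 and variance 2e-4.
    """

    intensity_shift_range: tuple[float, float] = (-0.05, 0.05)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    scale_range_pct: tuple[float, float] = (-10.0, 10.0)
    noise_mean: float = 0.0
    noise_variance: float = 2e-4
    enabled: bool = True


@dataclass
class SamplerConfig:
    """Patch geometry and the positive/negative mix.

    ``patch_size`` sides must be divisible by 2**depth of the network that
    will consume the patches.  ``positive_fraction`` is the probability that
    a drawn patch is border-centered rather than a random head location.
    """

    patch_size: tuple[int, int] = (32, 32)
    positive_fraction: float = 0.8
    head_intensity_floor: float = 0.05
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def validate(self, depth: int | None = None) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ConfigError("positive_fraction must lie in [0, 1]")
        if depth is not None:
            div = 2**depth
            if any(s % div for s in self.patch_size):
                raise ConfigError(
                    f"patch_size {self.patch_size} not divisible by 2**{depth}"
                )


@dataclass
class ExtendedPatch:
    """A (3, h, w) image window plus the binary target of its CENTER channel."""

    channels: np.ndarray  # (3, h, w) float32
    target: np.ndarray  # (h, w) uint8
    orientation: str
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ShapeError(f"channels must be (3,h,w), got {self.channels.shape}")
        if self.target.shape != self.channels.shape[1:]:
            raise ShapeError("target window must match channel size")


def border_voxels(m: LabelVolume) -> np.ndarray:
    """Inner-border voxels: mask voxels with at least one background 6-neighbour.

    Computed as the mask minus its 6-connectivity erosion.  Returns an (n, 3)
    integer coordinate array (empty for an empty mask).
    """
    mask = m.data.astype(bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.intp)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def _window_bounds(center: int, size: int, extent: int) -> tuple[int, int]:
    """Start/stop of a size-long window around center, clamped inside [0, extent)."""
    start = center - size // 2
    start = max(0, min(start, extent - size))
    return start, start + size


def _extended_window(
    volume: np.ndarray, orientation: str, center: tuple[int, int, int], size: tuple[int, int]
) -> np.ndarray:
    """(3, h, w) window: slices k-1, k, k+1 along the orientation axis.

    Edge slices replicate their existing neighbour; in-plane windows are
    shifted (clamped) to stay inside the volume so they keep full size.
    """
    axis = ORIENTATION_AXIS[orientation]
    moved = np.moveaxis(volume, axis, 0)  # (n_slices, H, W)
    k = center[axis]
    n = moved.shape[0]
    inplane_center = tuple(c for i, c in enumerate(center) if i != axis)
    (r0, r1) = _window_bounds(inplane_center[0], size[0], moved.shape[1])
    (c0, c1) = _window_bounds(inplane_center[1], size[1], moved.shape[2])
    idx = [max(0, k - 1), k, min(n - 1, k + 1)]
    return np.stack([moved[i, r0:r1, c0:c1] for i in idx]).astype(np.float32)


def sample_patch(
    v: ImageVolume,
    m: LabelVolume,
    positive: bool,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    orientation: str | None = None,
) -> ExtendedPatch:
    """Draw one extended-2D patch.

    Positive patches are centered on a uniformly drawn inner-border voxel of
    the mask; negative patches on a uniformly drawn head voxel (normalized
    intensity above ``head_intensity_floor``).  If ``orientation`` is None a
    plane is drawn uniformly; orientation-specialized training passes its own.
    """
    if v.data.shape != m.data.shape:
        raise ShapeError(f"image {v.data.shape} and mask {m.data.shape} differ")
    if orientation is None:
        orientation = ORIENTATIONS[rng.integers(0, 3)]
    if positive:
        borders = border_voxels(m)
        if len(borders) == 0:
            raise SamplingError("positive patch requested but the mask is empty")
        center = tuple(int(c) for c in borders[rng.integers(0, len(borders))])
    else:
        head = np.argwhere(v.data > cfg.head_intensity_floor)
        if len(head) == 0:
            raise SamplingError("no head voxels above the intensity floor")
        center = tuple(int(c) for c in head[rng.integers(0, len(head))])
    channels = _extended_window(v.data, orientation, center, cfg.patch_size)
    axis = ORIENTATION_AXIS[orientation]
    target3 = _extended_window(m.data, orientation, center, cfg.patch_size)
    target = (target3[1] > 0.5).astype(np.uint8)  # target belongs to the CENTER slice
    patch = ExtendedPatch(channels=channels, target=target, orientation=orientation, center=center)
    if cfg.augment.enabled:
        patch = augment(patch, cfg.augment, rng)
    return patch


def extract_extended_slice(
    v: ImageVolume,
    orientation: str,
    index: int,
    depth: int,
    crop: tuple[int, int] | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Full-slice prediction input: (3, h, w) window plus its crop offsets.

    Each in-plane side is center-cropped to the largest length <= the
    requested crop (or the slice side, if no crop is given) that is divisible
    by 2**depth, so the window fits the network's downsampling.  The returned
    (row, col) offsets let the activation be padded back exactly.
    """
    axis = ORIENTATION_AXIS[orientation]
    moved = np.moveaxis(v.data, axis, 0)
    n, H, W = moved.shape
    if not (0 <= index < n):
        raise ShapeError(f"slice index {index} out of range [0, {n})")
    div = 2**depth
    limits = (H, W) if crop is None else (min(H, crop[0]), min(W, crop[1]))
    sizes = tuple((lim // div) * div for lim in limits)
    if any(s == 0 for s in sizes):
        raise ShapeError(f"slice {H}x{W} too small for depth {depth}")
    off = ((H - sizes[0]) // 2, (W - sizes[1]) // 2)
    idx = [max(0, index - 1), index, min(n - 1, index + 1)]
    window = np.stack(
        [moved[i, off[0] : off[0] + sizes[0], off[1] : off[1] + sizes[1]] for i in idx]
    ).astype(np.float32)
    return window, off


def augment(p: ExtendedPatch, cfg: AugmentConfig, rng: np.random.Generator) -> ExtendedPatch:
    """One random draw of each transform, within the configured ranges.

    Rotation and scaling are applied identically to all three channels and to
    the target (re-binarized at 0.5 after interpolation); the intensity shift
    and Gaussian noise touch the image channels only.  Channels are clipped
    back to [0, 1].
    """
    shift = rng.uniform(*cfg.intensity_shift_range)
    angle = rng.uniform(*cfg.rotation_range_deg)
    scale = 1.0 + rng.uniform(*cfg.scale_range_pct) / 100.0
    noise_sd = float(np.sqrt(cfg.noise_variance))

    channels = p.channels.astype(np.float32)
    target = p.target.astype(np.float32)
    if angle != 0.0:
        channels = np.stack(
            [ndimage.rotate(c, angle, reshape=False, order=1, mode="nearest") for c in channels]
        )
        target = ndimage.rotate(target, angle, reshape=False, order=1, mode="nearest")
    if scale != 1.0:
        channels = np.stack([_zoom_keep_shape(c, scale) for c in channels])
        target = _zoom_keep_shape(target, scale)
    channels = channels + shift
    if noise_sd > 0.0:
        channels = channels + rng.normal(cfg.noise_mean, noise_sd, channels.shape)
    channels = np.clip(channels, 0.0, 1.0).astype(np.float32)
    return ExtendedPatch(
        channels=channels,
        target=(target > 0.5).astype(np.uint8),
        orientation=p.orientation,
        center=p.center,
    )


def _zoom_keep_shape(arr: np.ndarray, scale: float) -> np.ndarray:
    """Zoom about the center, cropping/padding back to the original shape."""
    out = ndimage.zoom(arr.astype(np.float32), scale, order=1, mode="nearest")
    res = np.zeros_like(arr, dtype=np.float32)
    for_shape, out_shape = arr.shape, out.shape
    src, dst = [], []
    for a, b in zip(out_shape, for_shape):
        if a >= b:
            start = (a - b) // 2
            src.append(slice(start, start + b))
            dst.append(slice(0, b))
        else:
            start = (b - a) // 2
            src.append(slice(0, a))
            dst.append(slice(start, start + a))
    res[tuple(dst)] = out[tuple(src)]
    return res
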