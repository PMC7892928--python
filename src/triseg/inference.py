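"""Slice-wise prediction, three-way consensus, and post-processing.

Each orientation network sweeps its plane over the canonical volume: every
slice (with its two neighbours as extra channels, center-cropped so sides
divide the network's downsampling factor) is pushed through the network and
the resulting foreground probabilities are written back at the recorded crop
offsets, building an activation volume per orientation.  The three volumes
are averaged voxelwise ("consensus"), thresholded, and cleaned by keeping at
most the two largest 26-connected components — the target structure is
bilateral, so two components are expected, or one if a side is absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, EnsembleError, ShapeError
from .patches import extract_extended_slice
from .volumes import (
    ORIENTATION_AXIS,
    ORIENTATIONS,
    ImageVolume,
    LabelVolume,
    OrientationFrame,
    minmax_normalize,
    to_canonical,
)


@dataclass
class ConsensusConfig:
    """Binarization threshold (strict >) and the component cap."""

    threshold: float = 0.5
    max_components: int = 2
    crop: tuple[int, int] | None = None  # optional in-plane crop at prediction time
    batch_slices: int = 32

    def validate(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError(f"threshold must lie in (0,1), got {self.threshold}")
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")


@dataclass
class ActivationVolume:
    """Per-orientation voxelwise foreground probabilities on the canonical grid."""

    data: np.ndarray
    orientation: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.min() < 0 or self.data.max() > 1:
            raise ShapeError("activations must lie in [0, 1]")


class IdentityStub:
    """Test double: returns the center channel unchanged (sigmoid layout)."""

    def __init__(self, depth: int = 4):
        from .nn import NetworkConfig

        self.cfg = NetworkConfig(depth=depth)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.clip(x[:, 1:2], 0.0, 1.0)


class ConstantStub:
    """Test double: constant probability everywhere."""

    def __init__(self, value: float, depth: int = 4):
        from .nn import NetworkConfig

        self.cfg = NetworkConfig(depth=depth)
        self.value = float(value)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.full((x.shape[0], 1) + x.shape[2:], self.value, dtype=np.float32)


def _foreground(prob: np.ndarray) -> np.ndarray:
    return prob[:, 0] if prob.shape[1] == 1 else prob[:, 1]


def predict_orientation(
    model, v: ImageVolume, orientation: str, cfg: ConsensusConfig | None = None
) -> ActivationVolume:
    """Build one orientation's activation volume slice by slice.

    Voxels outside the center-crop window stay exactly 0.
    """
    cfg = cfg or ConsensusConfig()
    cfg.validate()
    axis = ORIENTATION_AXIS[orientation]
    n = v.data.shape[axis]
    depth = model.cfg.depth
    windows, offsets = [], None
    for index in range(n):
        w, off = extract_extended_slice(v, orientation, index, depth, cfg.crop)
        windows.append(w)
        offsets = off  # identical for every index of a given volume
    act_plane = np.zeros(
        (n,) + tuple(s for i, s in enumerate(v.data.shape) if i != axis), dtype=np.float32
    )
    stack = np.stack(windows)
    h, w = stack.shape[2], stack.shape[3]
    for start in range(0, n, cfg.batch_slices):
        batch = stack[start : start + cfg.batch_slices]
        prob = _foreground(model.forward(batch, train=False))
        act_plane[
            start : start + cfg.batch_slices,
            offsets[0] : offsets[0] + h,
            offsets[1] : offsets[1] + w,
        ] = prob
    data = np.moveaxis(act_plane, 0, axis)
    return ActivationVolume(data=data, orientation=orientation, affine=v.affine.copy())


def consensus(*activations: ActivationVolume) -> ActivationVolume:
    """Voxelwise arithmetic mean of the per-orientation activations."""
    shapes = {a.data.shape for a in activations}
    if len(shapes) != 1:
        raise ShapeError(f"activation shapes differ: {shapes}")
    mean = np.mean([a.data for a in activations], axis=0).astype(np.float32)
    return ActivationVolume(data=mean, orientation="consensus", affine=activations[0].affine)


def binarize(c: ActivationVolume, cfg: ConsensusConfig | None = None) -> LabelVolume:
    """Voxel = 1 iff activation > threshold (strict, so ties go to background)."""
    cfg = cfg or ConsensusConfig()
    cfg.validate()
    return LabelVolume(data=(c.data > cfg.threshold).astype(np.uint8), affine=c.affine)


def keep_largest_components(m: LabelVolume, max_components: int = 2) -> LabelVolume:
    """Retain at most the ``max_components`` largest 26-connected components.

    Ties at the size cut are broken by the smallest component label (scan
    order), which makes the operation deterministic.  Empty masks pass
    through unchanged.
    """
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(m.data, structure=structure)
    if n <= max_components:
        return LabelVolume(data=(labeled > 0).astype(np.uint8), affine=m.affine)
    sizes = np.bincount(labeled.ravel())[1:]  # size per label, label order
    # stable sort on descending size preserves label order among equals
    keep = np.argsort(-sizes, kind="stable")[:max_components] + 1
    return LabelVolume(data=np.isin(labeled, keep).astype(np.uint8), affine=m.affine)


def segment(
    v: ImageVolume,
    models: dict[str, object],
    cfg: ConsensusConfig | None = None,
    return_consensus: bool = False,
):
    """Full pipeline: canonicalize, normalize, predict x3, fuse, clean, un-orient.

    Returns the mask in the input volume's native space (same affine and axis
    order as the input).
    """
    cfg = cfg or ConsensusConfig()
    cfg.validate()
    missing = [o for o in ORIENTATIONS if o not in models]
    if missing:
        raise EnsembleError(f"missing orientation model(s): {', '.join(missing)}")
    canon, frame = to_canonical(v)
    if not canon.normalized:
        canon = minmax_normalize(canon)
    acts = [predict_orientation(models[o], canon, o, cfg) for o in ORIENTATIONS]
    fused = consensus(*acts)
    mask = keep_largest_components(binarize(fused, cfg), cfg.max_components)
    native = LabelVolume(data=frame.to_native(mask.data), affine=frame.native_affine)
    if return_consensus:
        return native, fused, frame
    return native
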