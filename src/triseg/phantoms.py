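"""Seeded synthetic "head" phantoms with bilateral target structures.

Each phantom is a smooth ellipsoidal brain envelope containing two
mirror-placed, curved prolate ellipsoids standing in for the left and right
hippocampi.  Optionally one side is "resected": the structure is removed from
the label, its interior replaced by a dark cavity, and — deliberately — a
faint textured rim with near-target intensity is left behind.  Segmentation
models trained only on intact anatomy tend to hallucinate the structure in
exactly such remnant textures, which is the domain-shift failure mode this
fixture exists to expose.

All randomness flows from ``PhantomSpec.seed``; identical specs produce
bit-identical volumes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import PhantomSpecError
from .volumes import ImageVolume, LabelVolume, read_mask, read_volume, write_volume

LEFT, RIGHT = "left", "right"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Intensities are on the [0, 1] scale of a minmax-normalized T1 volume:
    brain parenchyma around 0.3 and the (brighter-than-surroundings, for
    contrast) target structure at 0.6 by default, with additive Gaussian
    noise of sd 0.03.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    brain_intensity: float = 0.3
    target_intensity: float = 0.6
    noise_sd: float = 0.03
    structure_semiaxes: tuple[float, float, float] = (4.5, 11.0, 6.0)
    structure_offset: float = 13.0  # lateral distance of each structure center from midline
    bend: float = 4.0  # lateral displacement at the structure's A-P extremes (curvature)
    cavity_intensity: float = 0.12
    rim_intensity_drop: float = 0.06  # rim sits this far below target intensity
    rim_noise_sd: float = 0.05
    resect_side: str | None = None  # None, "left" or "right"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.brain_intensity < self.target_intensity <= 1.0):
            raise PhantomSpecError(
                "need 0 < brain_intensity < target_intensity <= 1, got "
                f"{self.brain_intensity}, {self.target_intensity}"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if self.resect_side not in (None, LEFT, RIGHT):
            raise PhantomSpecError(f"resect_side must be None/'left'/'right', got {self.resect_side!r}")
        shape = np.asarray(self.shape, dtype=float)
        semi = np.asarray(self.structure_semiaxes, dtype=float)
        reach = np.array(
            [self.structure_offset + semi[0] + self.bend, semi[1], semi[2]]
        )
        if np.any(reach + 2 >= shape / 2):
            raise PhantomSpecError(
                f"structures (reach {reach}) do not fit inside grid {self.shape}"
            )


def _structure_field(spec: PhantomSpec, side: str) -> np.ndarray:
    """Normalized radial coordinate of one curved ellipsoid (<=1 inside)."""
    nx, ny, nz = spec.shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    sign = -1.0 if side == LEFT else 1.0
    x = np.arange(nx, dtype=np.float32)[:, None, None]
    y = np.arange(ny, dtype=np.float32)[None, :, None]
    z = np.arange(nz, dtype=np.float32)[None, None, :]
    ax, ay, az = spec.structure_semiaxes
    yc = (y - cy) / ay
    # the structure bows outward: its lateral center drifts with A-P position
    x_center = cx + sign * (spec.structure_offset - spec.bend * yc**2)
    r2 = ((x - x_center) / ax) ** 2 + yc**2 + ((z - cz) / az) ** 2
    return np.sqrt(r2, dtype=np.float32)


def _brain_envelope(spec: PhantomSpec) -> np.ndarray:
    """Smooth [0,1] envelope of the head: 1 inside, smoothstep to 0 at the edge."""
    nx, ny, nz = spec.shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x = np.arange(nx, dtype=np.float32)[:, None, None]
    y = np.arange(ny, dtype=np.float32)[None, :, None]
    z = np.arange(nz, dtype=np.float32)[None, None, :]
    sx, sy, sz = 0.44 * nx, 0.46 * ny, 0.42 * nz
    r = np.sqrt(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 + ((z - cz) / sz) ** 2)
    t = np.clip((1.0 - r) / 0.08, 0.0, 1.0).astype(np.float32)
    return t * t * (3.0 - 2.0 * t)  # smoothstep


def generate_subject(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Render one phantom volume and its ground-truth structure mask.

    The grid is already canonical (RAS+, identity-scaled affine): axis 0 is
    left->right, so the "left" structure occupies the low-index half.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    env = _brain_envelope(spec)
    image = spec.brain_intensity * env
    label = np.zeros(spec.shape, dtype=np.uint8)

    for side in (LEFT, RIGHT):
        r = _structure_field(spec, side)
        inside = r <= 1.0
        if side == spec.resect_side:
            cavity = r <= 0.8
            rim = inside & ~cavity
            image[cavity] = spec.cavity_intensity
            # remnant tissue rim: intensity close to the target's, extra texture
            rim_val = spec.target_intensity - spec.rim_intensity_drop
            image[rim] = rim_val + rng.normal(0.0, spec.rim_noise_sd, rim.sum())
        else:
            image[inside] = spec.target_intensity
            label[inside] = 1

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, spec.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    affine = np.eye(4)
    return ImageVolume(data=image, affine=affine), LabelVolume(data=label, affine=affine)


@dataclass
class Subject:
    """One cohort member: rendered volumes plus ground-truth metadata."""

    subject_id: str
    image: ImageVolume
    label: LabelVolume
    group: str  # "control" or "patient"
    resect_side: str | None
    spec: PhantomSpec


def generate_cohort(
    n_controls: int,
    n_patients: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    size_jitter: float = 0.10,
    position_jitter: float = 1.5,
) -> list[Subject]:
    """Render a reproducible cohort with per-subject anatomical jitter.

    Structure semi-axes are scaled by U(1-size_jitter, 1+size_jitter) and
    centers shifted by U(-position_jitter, +position_jitter) voxels per axis;
    patients get a resected side drawn uniformly from {left, right}.
    """
    if n_controls < 0 or n_patients < 0:
        raise PhantomSpecError("cohort counts must be >= 0")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    groups = ["control"] * n_controls + ["patient"] * n_patients
    for i, group in enumerate(groups):
        semi = np.asarray(base.structure_semiaxes) * rng.uniform(
            1 - size_jitter, 1 + size_jitter, 3
        )
        offset = base.structure_offset + rng.uniform(-position_jitter, position_jitter)
        side = rng.choice([LEFT, RIGHT]) if group == "patient" else None
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            structure_semiaxes=tuple(float(s) for s in semi),
            structure_offset=float(offset),
            resect_side=side,
            seed=sub_seed,
        )
        image, label = generate_subject(spec)
        subjects.append(
            Subject(
                subject_id=f"sub-{i:03d}",
                image=image,
                label=label,
                group=group,
                resect_side=side,
                spec=spec,
            )
        )
    return subjects


def write_cohort(subjects: list[Subject], outdir: str | Path) -> Path:
    """Write cohort volumes/labels as NIfTI plus a tabular manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "image", "label", "group", "resect_side"])
        for s in subjects:
            img_path = outdir / f"{s.subject_id}_T1.nii"
            lab_path = outdir / f"{s.subject_id}_mask.nii"
            write_volume(s.image, img_path)
            write_volume(
                ImageVolume(s.label.data.astype(np.float32), s.label.affine), lab_path
            )
            w.writerow([s.subject_id, img_path.name, lab_path.name, s.group, s.resect_side or ""])
    return manifest


def load_cohort(manifest: str | Path) -> list[Subject]:
    """Re-load a cohort written by :func:`write_cohort`."""
    manifest = Path(manifest)
    root = manifest.parent
    subjects = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = read_volume(root / row["image"])
            label = read_mask(root / row["label"])
            subjects.append(
                Subject(
                    subject_id=row["subject_id"],
                    image=image,
                    label=label,
                    group=row["group"],
                    resect_side=row["resect_side"] or None,
                    spec=PhantomSpec(),
                )
            )
    return subjects
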