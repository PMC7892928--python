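# Methods

This document describes the model, the synthetic data generator, the numerical
conventions, and the known limitations. Nothing here is an empirical claim
beyond what `scripts/acceptance.py` and the test suite recompute.

## Canonical orientation

All processing happens on a canonical RAS+ grid: axis 0 runs left→right
(sagittal slicing axis), axis 1 posterior→anterior (coronal), axis 2
inferior→superior (axial). Input volumes are reoriented with nibabel's
orientation transforms — **axis permutations and flips only, never
resampling** — and the transform is retained (`OrientationFrame`) so predicted
masks are transported back to the input's native axis order and affine exactly.
A singular affine is rejected (`GeometryError`). Volumes stored with a
singleton fourth dimension are squeezed; true 4D volumes are rejected.

Intensities are min–max normalized to [0, 1] per volume; constant volumes are
rejected rather than silently mapped to zeros.

## Network

Each orientation has an independent 2D encoder–decoder:

- input: 3 channels — slice k−1, k, k+1 of the canonical volume along that
  orientation's axis (edge slices replicate their existing neighbor);
- residual blocks: two 3×3 unbiased convolutions each followed by batch norm
  and ReLU, summed with a parallel 1×1 convolution of the block input;
- encoder: one block per level followed by 2×2 max pooling; decoder: 2×2
  stride-2 transposed convolutions, concatenation with the matching encoder
  skip, then a block;
- head: 1×1 convolution to either 1 channel + sigmoid (`sigmoid_1ch`, for the
  plain Dice loss) or 2 channels + channel softmax (`softmax_2ch`, for GDL and
  the boundary loss).

`NetworkConfig`: `base_width` (channels at the first level; doubles per level),
`depth` (number of pooling steps; input sides must be divisible by 2^depth),
`output_mode`, `encoder_init` (optional hook for initializing encoder weights;
default is seeded He initialization), `seed`. Everything is float32. The whole
stack is NumPy: convolutions are computed as kernel-position-shifted
`tensordot` contractions (BLAS), and every layer implements an explicit
backward pass. Optimization is Adam (lr 1e-3, β=0.9/0.999, ε=1e-8) with
bias-corrected moments.

## Patch sampling and augmentation

Training draws 2D extended patches (default 32×32):

- *positive* patches (default fraction 0.8) are centered on **inner-border
  voxels** of the label — mask voxels with at least one 6-connected background
  neighbor (mask minus its 6-connectivity erosion) — putting most supervision
  where the boundary is;
- *negative* patches are centered anywhere the normalized intensity exceeds
  0.05 (inside the head, not in air);
- windows are clamped inside the volume, so corner centers still yield
  full-size patches; the target comes from the center slice only.

Augmentation (applied to the 3 channels coherently, seeded): intensity shift
uniform in [−0.05, 0.05], rotation uniform in [−10°, 10°], isotropic scale
uniform in [−10 %, 10 %] (resampled back to the original patch size), additive
Gaussian noise with variance 2·10⁻⁴. Channels are clipped back to [0, 1] and
the warped target is re-binarized at 0.5.

**Default patch size is 32×32, not larger**: on a single CPU a 64×64 batch step
costs roughly an order of magnitude more, and 32×32 already saturates phantom
performance (test Dice 0.99). `SamplerConfig(patch_size=...)` accepts any size
divisible by 2^depth.

## Losses

With predicted probabilities `p` and binary target `g`:

- **soft Dice loss** `1 − (2Σpg + ε)/(Σp² + Σg² + ε)`, ε = 10⁻⁶ (squared-sum
  denominator; identical to 2|P∩G|/(|P|+|G|) on binary inputs);
- **generalized Dice loss** over the two channels [background, foreground] with
  weights `w_c = 1/(Σ g_c + ε)²`, countering class imbalance;
- **boundary loss** `α·GDL + (1−α)·mean(d·p₁)` where `d` is the signed
  Euclidean distance to the target boundary, computed as
  `edt(1−g)·(1−g) − (edt(g)−1)·g`: zero on the inner boundary voxels, negative
  strictly inside, positive outside. α follows the linear schedule
  `α(e) = (T−e)/(T−1)` from 1 at epoch 1 to 0 at epoch T, so training starts
  purely regional and ends purely boundary-driven.

Batch handling: Dice is computed batch-wise (sums before the ratio). The
surface term is averaged over the samples whose target is non-degenerate;
empty- or full-target patches contribute only the GDL term (a signed distance
map is undefined without a boundary). All gradients are analytic and verified
against central finite differences (relative tolerance 10⁻⁴).

## Training protocol

`make_holdout` performs a stratified (by `group`, by default) seeded split with
largest-remainder rounding per stratum; `make_kfold` builds k stratified folds
whose test sets partition the cohort. Per orientation, each epoch draws fresh
patches from a stream seeded by `[master_seed, orientation_index, epoch]` — no
two epochs repeat, and runs are bit-reproducible. Model selection keeps the
epoch with the best soft Dice on a **fixed seeded set of validation patches**
(full-volume validation segmentation per epoch would dominate the runtime);
without validation subjects the final epoch is kept. The three orientation
networks get distinct initialization seeds (`seed`, `seed+1`, `seed+2` fan-out
from the master seed via `RunConfig.reseeded()`).

## Inference

Each network sweeps its plane: every slice is center-cropped to the largest
size divisible by 2^depth (offsets recorded), batched through the network, and
written back at the recorded offsets — voxels outside the crop window stay
exactly 0. The three activation volumes are averaged, binarized with a
**strict** `> threshold` comparison (default 0.5; a voxel exactly at threshold
is background), and at most the `max_components` (default 2) largest
26-connected components are kept. Size ties at the cut are broken toward the
component appearing first in scan order (stable sort), making the operation
deterministic.

## Evaluation conventions

Per subject: Dice on the whole mask and on the left/right halves of the
canonical grid (split at the mid-sagittal plane; with an odd extent the
mid-plane column joins the left half), plus voxelwise precision and recall.
Conventions:

- both masks empty → Dice 1.0 (correctly predicted absence);
- empty ground truth vs non-empty prediction → Dice 0.0, so a hallucinated
  structure on a resected side scores zero on that side;
- precision/recall 0/0 → 1.0 only when both masks are empty, else 0.0.

Cohort summaries report mean ± **population** standard deviation (ddof = 0)
per group.

## Phantom generator

A phantom is: a smoothstep-edged ellipsoidal "brain" envelope at intensity
0.3; two mirror-image bent prolate ellipsoids ("targets") at intensity 0.6;
Gaussian noise (sd 0.03); clipped to [0, 1]. Patients have one target removed:
the cavity drops to intensity 0.12, but a rim at intensity ≈ 0.54 with extra
texture noise (sd 0.05) remains around it. Cohorts add per-subject size jitter
(±10 %), position jitter (±1.5 voxels), and a random resection side. The
generator validates that the structures fit inside the grid and that the
intensity ordering (cavity < brain < target) holds.

**What the phantoms emulate:** bright bilateral structures in a darker
background, boundary ambiguity from noise and soft envelope edges, and —
critically — post-operative tissue whose texture resembles the target, the
condition under which a control-trained model produces confident false
positives. **What they do not emulate:** real MRI contrast and bias fields,
anatomical shape variability, partial-volume effects, multi-site intensity
differences, or registration error. Dice ≈ 0.99 on phantoms says the pipeline
is correct, not that it would reach that on clinical data (reported
hippocampus results on real cohorts are in the 0.76–0.90 range).

## Numerical choices

- float32 parameters and activations; float64 only inside metric/loss oracles
  and distance transforms where SciPy returns it.
- Strict `>` at binarization; max-pool backward splits gradients equally among
  tied maxima; component-size ties keep scan order.
- `np.random.default_rng` with list seeds (`[seed, stream, epoch]`) for
  independent, collision-free streams.
- Sigmoid via `scipy.special.expit` (no overflow); softmax with max
  subtraction.

## Limitations

- Single CPU, NumPy-only: full-scale training (3 networks × 15 epochs × 512
  patches) takes ~6 minutes on phantoms; real-resolution MRI volumes would be
  orders of magnitude slower than a GPU framework.
- No built-in registration: volumes are assumed roughly aligned with the
  canonical axes. `triseg predict` can shell out to an external registration
  tool via `--register-cmd`/`--unregister-cmd`.
- The consensus is a plain mean of three networks; no learned fusion.
- Validation-patch model selection is a proxy for full-volume validation Dice.
- Left/right is defined geometrically by the mid-sagittal grid plane, which is
  correct for the phantoms and for well-centered heads, but not robust to
  strongly tilted acquisitions.
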