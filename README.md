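# triseg

Triplanar consensus segmentation of bilateral brain structures (hippocampus-style
targets) in 3D volumes, implemented in pure NumPy.

Three independent 2D encoder–decoder networks — one per anatomical plane
(sagittal, coronal, axial) — are trained on patches built from a slice plus its
two neighboring slices as input channels ("extended 2D"). At inference each
network sweeps its plane across the whole volume, producing a per-orientation
probability volume; the three volumes are averaged voxelwise (the *consensus*),
thresholded at 0.5, and cleaned by keeping at most the two largest 26-connected
components (the target is bilateral, so two components are expected — or one
when a side is surgically absent).

Training supports three losses: soft Dice, the generalized Dice loss (GDL, with
per-class weights inversely proportional to squared class volume), and a
boundary loss `α·GDL + (1−α)·surface` whose surface term integrates predicted
probability against the ground truth's signed distance map, with α annealed
linearly from 1 to 0 over training.

Because real labeled MRI cohorts cannot ship with a library, the package
includes a seeded synthetic phantom generator: soft-edged "brain" envelopes
containing two bright bilateral bent-ellipsoid targets, plus "patient" phantoms
where one target is resected but a textured rim of near-target intensity
remains — a deliberate false-positive trap that reproduces the qualitative
failure mode of models trained on controls only.

The entire neural-network stack (convolutions, batch norm, transposed
convolutions, Adam, backpropagation) is implemented in NumPy/SciPy; there is no
deep-learning framework dependency, and everything runs on one CPU.

## Command-line usage

```bash
# 1. a seeded synthetic cohort (NIfTI volumes + labels + manifest.csv)
triseg generate --controls 32 --patients 8 --seed 1 --out runs/cohort

# 2. train the three orientation networks with a stratified hold-out
triseg train --cohort runs/cohort --out runs/model --seed 1

# 3. segment a volume (output mask is in the input's native orientation)
triseg predict --model-dir runs/model \
    --input runs/cohort/sub-000_T1.nii --output runs/sub-000_pred.nii

# 4. evaluate predictions named <subject_id>_pred.nii against the cohort
triseg evaluate --pred-dir runs/preds --cohort runs/cohort --out runs/eval
```

`triseg predict` accepts `--register-cmd` / `--unregister-cmd` templates to
wrap an external rigid-registration tool around prediction, and
`--save-consensus` to keep the pre-threshold probability volume.
`triseg train` takes a YAML run configuration (`--config`); unknown keys are
rejected by name.

## Worked example

`examples/03_train_and_segment.py` trains a reduced ensemble (width-8, depth-3
networks, 5 epochs × 128 patches on five 64³ phantoms) in about a minute on one
CPU and segments two held-out phantoms. Its actual output:

```
split: 5 train / 1 val / 2 test

orientation  final train loss  best val soft-Dice
sagittal              -0.1080               0.828
coronal               -0.0100               0.567
axial                 +0.0085               0.728

held-out test subjects:
sub-003: Dice=0.797 (L 0.804 / R 0.790) precision=0.931 recall=0.697 components=2
sub-000: Dice=0.806 (L 0.805 / R 0.807) precision=0.915 recall=0.720 components=2
```

(The boundary loss goes negative late in training: its surface term is negative
when predicted mass lies inside the target.)

At full scale — 20 training / 4 validation / 8 test control phantoms, 15 epochs
× 512 patches per orientation (≈6 minutes on one CPU, seed 1) — the ensemble
reaches **mean test Dice 0.988** on held-out controls, every mask has at most 2
connected components, and control mean precision is **0.992**. Evaluated on 8
resected phantoms the same control-trained ensemble hallucinates the missing
structure on the textured resection rim: every resected side scores Dice 0.0,
and patient mean precision drops to **0.947** — the false-positive failure mode
the post-processing and per-side reporting are designed to expose.

Other examples: `01_generate_phantoms.py` (what the phantoms contain),
`02_losses_walkthrough.py` (losses on a hand-checkable map),
`04_evaluation_conventions.py` (empty-mask conventions and per-side Dice).

## Reproduction

All headline numbers are recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes a JSON dictionary of named quantities (metric-oracle agreement
counts, loss-identity and gradient errors, assembly exactness, the end-to-end
Dice/precision numbers above, augmentation statistics, split-protocol checks).
The test suite covers the same ground per module, plus one test per acceptance
property, in `tests/`:

```bash
python -m pytest -q tests/          # ~8 minutes; dominated by one end-to-end run
```

Everything is seeded: the same seed gives bit-identical phantoms, patch
streams, initial weights, and therefore identical trained models and metrics.

## Repository layout

- `src/triseg/volumes.py` — NIfTI I/O, min–max normalization, canonical RAS+
  orientation with exact inverse transport of masks to native space
- `src/triseg/phantoms.py` — seeded synthetic cohort generator
- `src/triseg/patches.py` — border-targeted positive/negative patch sampling,
  extended-slice extraction, intensity/rotation/scale/noise augmentation
- `src/triseg/nn/` — NumPy layers (conv, batch norm, pooling, transposed conv),
  residual U-Net-style architecture, Adam
- `src/triseg/losses.py` — soft Dice, GDL, signed-distance surface term,
  annealed boundary loss, with analytic gradients
- `src/triseg/training.py` — stratified hold-out / k-fold splits, seeded
  per-orientation training loop with validation-based model selection
- `src/triseg/inference.py` — slice-sweep prediction, consensus fusion,
  thresholding, connected-component cleanup, native-space output
- `src/triseg/metrics.py` — Dice (whole/left/right), precision, recall, cohort
  summaries (mean ± population sd)
- `src/triseg/config.py`, `src/triseg/cli.py` — YAML run configuration and the
  `triseg` command

See `docs/methods.md` for model details, parameter meanings, numerical
conventions, and limitations.
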