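"""Train a small three-orientation ensemble and segment a held-out phantom.

The pipeline: three 2D encoder-decoder networks, one per anatomical plane,
each fed a slice plus its two neighbors as channels; at inference every
network sweeps its plane over the volume, the three probability volumes are
averaged ("consensus"), thresholded at 0.5, and cleaned by keeping at most
the two largest 26-connected components.

This example uses a reduced schedule so it finishes in about a minute; see
the README's reproduction section for the full-scale run.

Run:  python examples/03_train_and_segment.py
"""

import numpy as np
from scipy import ndimage

from triseg.inference import segment
from triseg.losses import LossConfig
from triseg.metrics import evaluate_subject
from triseg.nn import NetworkConfig
from triseg.phantoms import generate_cohort
from triseg.training import TrainConfig, make_holdout, prepare_subjects, train_ensemble

cohort = generate_cohort(n_controls=8, n_patients=0, seed=3)
subjects = prepare_subjects(cohort)
plan = make_holdout(cohort, (0.625, 0.125, 0.25), seed=3)
print(f"split: {len(plan.train)} train / {len(plan.validation)} val / {len(plan.test)} test")

cfg = TrainConfig(
    epochs=5,
    patches_per_epoch=128,
    batch_size=16,
    loss=LossConfig(kind="boundary", total_epochs=5),
    network=NetworkConfig(base_width=8, depth=3, output_mode="softmax_2ch", seed=3),
    seed=3,
)
models, history = train_ensemble(subjects, plan, cfg)

print("\norientation  final train loss  best val soft-Dice")
for orientation in ("sagittal", "coronal", "axial"):
    recs = [h for h in history if h["orientation"] == orientation]
    best = max(r["val_dice"] for r in recs)
    print(f"{orientation:11s}  {recs[-1]['train_loss']:+16.4f}  {best:18.3f}")

print("\nheld-out test subjects:")
for sid in plan.test:
    s = subjects[sid]
    mask = segment(s.image, models)
    n_comp = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))[1]
    rec = evaluate_subject(mask, s.label, sid)
    print(
        f"{sid}: Dice={rec.dice_both:.3f} (L {rec.dice_left:.3f} / R {rec.dice_right:.3f}) "
        f"precision={rec.precision:.3f} recall={rec.recall:.3f} components={n_comp}"
    )
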