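"""Evaluation protocol and its empty-mask conventions, on constructed masks.

Reported per subject: Dice on the whole mask and on each half of the grid
(split at the mid-sagittal plane), plus voxelwise precision and recall.
The conventions are chosen for the resection use case:

- both masks empty            -> Dice 1.0 (a correctly predicted absence)
- empty truth, non-empty pred -> Dice 0.0 (hallucination is fully penalized)

Run:  python examples/04_evaluation_conventions.py
"""

import numpy as np

from triseg.metrics import evaluate_cohort, evaluate_subject
from triseg.volumes import LabelVolume


def lv(a):
    return LabelVolume(np.asarray(a, dtype=np.uint8), np.eye(4))


# ground truth: a right-side structure only (left side surgically absent)
g = np.zeros((16, 8, 8))
g[10:13, 3:6, 3:6] = 1

# prediction A: perfect
rec = evaluate_subject(lv(g), lv(g), "perfect")
print(f"perfect:        Dice={rec.dice_both:.2f}  L={rec.dice_left:.2f}  R={rec.dice_right:.2f}")

# prediction B: right side correct, but a blob hallucinated on the empty left
p = g.copy()
p[3:6, 3:6, 3:6] = 1
rec = evaluate_subject(lv(p), lv(g), "hallucinated")
print(
    f"hallucinated:   Dice={rec.dice_both:.2f}  L={rec.dice_left:.2f}  R={rec.dice_right:.2f}  "
    f"precision={rec.precision:.2f}  recall={rec.recall:.2f}"
)
print("  -> the fabricated left blob gives left-side Dice 0.0 and halves precision,")
print("     while recall stays 1.0: precision is the metric that exposes it.")

# cohort summary: mean +/- population standard deviation per group
table, summary = evaluate_cohort(
    {"a": lv(g), "b": lv(p)},
    {"a": lv(g), "b": lv(g)},
    groups={"a": "control", "b": "patient"},
)
print("\nper-subject table:")
print(table.to_string(index=False))
print("\ngroup summary (mean / population sd):")
print(summary.round(3).to_string())
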