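"""Walk through the three training losses on a tiny hand-checkable example.

- soft Dice: overlap-based, the evaluation metric in loss form
- generalized Dice loss (GDL): class-rebalanced two-channel variant
- boundary loss: alpha * GDL + (1 - alpha) * surface term, where the surface
  term integrates predicted probability against the ground truth's signed
  distance map and alpha anneals linearly from 1 to 0 over training

Run:  python examples/02_losses_walkthrough.py
"""

import numpy as np

from triseg.losses import (
    LossConfig,
    alpha_schedule,
    boundary_loss,
    generalized_dice_loss,
    one_hot,
    signed_distance,
    soft_dice,
    surface_loss,
)

# |P| = 4, |G| = 6, overlap 3  ->  Dice = 2*3 / (4+6) = 0.6
p = np.zeros(16)
g = np.zeros(16)
p[:4] = 1
g[1:7] = 1
print(f"worked Dice example: {soft_dice(p, g):.6f}  (expected 0.6)")

# a 2D map with a square target; the signed distance map is negative inside
gm = np.zeros((8, 8))
gm[2:6, 2:6] = 1
dist = signed_distance(gm)
print(f"\nsigned distance at center (inside):  {dist[3, 3]:+.3f}")
print(f"signed distance on the boundary:     {dist[2, 2]:+.3f}")
print(f"signed distance at the corner:       {dist[0, 0]:+.3f}")

# a blurry prediction: correct region, soft edges
rng = np.random.default_rng(0)
z = np.clip(gm * 0.8 + rng.random((8, 8)) * 0.2, 0, 1)
pred = np.stack([1 - z, z])  # [background, foreground] channels
print(f"\nGDL of the blurry prediction:      {generalized_dice_loss(pred, one_hot(gm)):.4f}")
print(f"surface loss of the same:          {surface_loss(z, dist):+.4f}  (negative = mass inside)")

# the boundary loss interpolates between the two as training progresses
cfg = LossConfig(kind="boundary", total_epochs=10)
print("\nepoch  alpha  boundary loss")
for epoch in (1, 5, 10):
    a = alpha_schedule(epoch, cfg.total_epochs)
    print(f"{epoch:5d}  {a:5.2f}  {boundary_loss(pred, gm, epoch, cfg):+.4f}")
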