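"""Segmentation evaluation: Dice, precision, recall, per-side breakdown.

Per subject, Dice is reported for the whole mask and separately for the left
and right halves of the canonical grid (split at the mid-sagittal plane).
The empty-mask conventions matter for the resection domain: an empty ground
truth side scored against a non-empty prediction yields Dice 0 — this is what
drags the per-side mean down when a model hallucinates a surgically removed
structure, and it is deliberate.  Summaries report mean +/- population sd per
cohort tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GeometryError, PairingError, ShapeError
from .volumes import LabelVolume

METRICS = ("dice_both", "dice_left", "dice_right", "precision", "recall")


def dice_binary(p: LabelVolume | np.ndarray, g: LabelVolume | np.ndarray) -> float:
    """Dice on binary masks (squared-sum denominator; identical to 2|I|/(|P|+|G|)).

    Both masks empty -> 1.0 by convention (a correctly predicted absence).
    """
    pa = (p.data if isinstance(p, LabelVolume) else np.asarray(p)).astype(bool)
    ga = (g.data if isinstance(g, LabelVolume) else np.asarray(g)).astype(bool)
    if pa.shape != ga.shape:
        raise ShapeError(f"shape mismatch: {pa.shape} vs {ga.shape}")
    psum, gsum = int(pa.sum()), int(ga.sum())
    if psum == 0 and gsum == 0:
        return 1.0
    return 2.0 * int((pa & ga).sum()) / (psum + gsum)


def precision_recall(p: LabelVolume | np.ndarray, g: LabelVolume | np.ndarray) -> tuple[float, float]:
    """Voxelwise precision TP/(TP+FP) and recall TP/(TP+FN).

    0/0 denominators yield 1.0 only when both masks are empty, else 0.0.
    """
    pa = (p.data if isinstance(p, LabelVolume) else np.asarray(p)).astype(bool)
    ga = (g.data if isinstance(g, LabelVolume) else np.asarray(g)).astype(bool)
    if pa.shape != ga.shape:
        raise ShapeError(f"shape mismatch: {pa.shape} vs {ga.shape}")
    tp = int((pa & ga).sum())
    fp = int((pa & ~ga).sum())
    fn = int((~pa & ga).sum())
    both_empty = not pa.any() and not ga.any()
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if both_empty else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if both_empty else 0.0)
    return precision, recall


def split_left_right(m: LabelVolume) -> tuple[LabelVolume, LabelVolume]:
    """Partition a canonical-grid mask at the mid-sagittal plane.

    Canonical axis 0 runs left -> right, so low indices are the left half;
    with an odd extent the mid-plane column is assigned to the left.  The
    returned masks live on the full grid (other half zeroed) so they can be
    compared voxelwise.
    """
    n = m.data.shape[0]
    cut = n // 2 + n % 2  # mid-plane joins the left half when n is odd
    left = np.zeros_like(m.data)
    right = np.zeros_like(m.data)
    left[:cut] = m.data[:cut]
    right[cut:] = m.data[cut:]
    return LabelVolume(left, m.affine), LabelVolume(right, m.affine)


@dataclass
class EvalRecord:
    subject_id: str
    dice_both: float
    dice_left: float
    dice_right: float
    precision: float
    recall: float
    group: str = ""


def evaluate_subject(p: LabelVolume, g: LabelVolume, subject_id: str = "", group: str = "") -> EvalRecord:
    pl, pr = split_left_right(p)
    gl, gr = split_left_right(g)
    prec, rec = precision_recall(p, g)
    return EvalRecord(
        subject_id=subject_id,
        dice_both=dice_binary(p, g),
        dice_left=dice_binary(pl, gl),
        dice_right=dice_binary(pr, gr),
        precision=prec,
        recall=rec,
        group=group,
    )


def evaluate_cohort(
    predictions: dict[str, LabelVolume],
    ground_truths: dict[str, LabelVolume],
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject records plus a mean +/- sd summary grouped by cohort tag.

    Subject id sets must match exactly.
    """
    if set(predictions) != set(ground_truths):
        missing = set(predictions) ^ set(ground_truths)
        raise PairingError(f"prediction/ground-truth ids differ: {sorted(missing)}")
    groups = groups or {}
    records = [
        evaluate_subject(predictions[sid], ground_truths[sid], sid, groups.get(sid, "all"))
        for sid in sorted(predictions)
    ]
    table = pd.DataFrame([r.__dict__ for r in records])
    summary = (
        table.groupby("group")[list(METRICS)]
        .agg(["mean", lambda x: float(np.std(x, ddof=0))])
        .rename(columns={"<lambda_0>": "sd"})
    )
    return table, summary
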