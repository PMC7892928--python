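"""Training objectives: soft Dice loss, Generalized Dice Loss, Boundary Loss.

Three objectives are available for the orientation networks:

* **Dice loss** ``1 - 2*sum(p*g) / (sum(p^2) + sum(g^2) + eps)`` on the
  single foreground channel (squared-denominator soft Dice).
* **Generalized Dice Loss (GDL)** over the two-channel background/foreground
  softmax output, with per-label weights ``w_l = 1/(sum_i g_li + eps)^2`` so
  scarce labels are not drowned out by the background.
* **Boundary loss** ``B = alpha*GDL + (1-alpha)*S`` where the surface term
  ``S = mean_i(d_i * p_i)`` integrates the predicted foreground probability
  against the ground truth's signed boundary-distance map (negative inside,
  positive outside, zero on the inner boundary), and ``alpha`` anneals
  linearly from 1 at the first epoch to 0 at the last.

All functions are plain numpy and come with analytic gradients with respect
to the predicted probabilities, consumed by the trainer's backward pass.
Batch losses sum voxel statistics over the whole batch before taking ratios
("batch Dice"), which stabilizes patches with little or no foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, DegenerateMaskError, ScheduleError, ShapeError

LOSS_KINDS = ("dice", "gdl", "boundary")


@dataclass
class LossConfig:
    """Loss selection plus the boundary-loss schedule horizon."""

    kind: str = "boundary"
    epsilon: float = 1e-6
    total_epochs: int = 15

    def validate(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ConfigError(f"loss kind must be one of {LOSS_KINDS}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.kind == "boundary" and self.total_epochs < 2:
            raise ConfigError("boundary loss needs total_epochs >= 2")

    @property
    def output_mode(self) -> str:
        """Network head this loss expects."""
        return "sigmoid_1ch" if self.kind == "dice" else "softmax_2ch"


def _check_same_shape(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {g.shape}")


# ---------------------------------------------------------------------------
# soft Dice
# ---------------------------------------------------------------------------

def soft_dice(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> float:
    """Squared-denominator soft Dice: 2*sum(p*g) / (sum(p^2)+sum(g^2)+eps)."""
    _check_same_shape(p, g)
    num = 2.0 * float((p * g).sum())
    den = float((p * p).sum() + (g * g).sum()) + eps
    return num / den


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> float:
    """1 - soft Dice."""
    return 1.0 - soft_dice(p, g, eps)


def dice_loss_grad(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """d(dice_loss)/dp, elementwise."""
    _check_same_shape(p, g)
    num = 2.0 * (p * g).sum()
    den = (p * p).sum() + (g * g).sum() + eps
    # d(num/den)/dp = (2g*den - num*2p)/den^2 ; loss is the negative of that
    return -(2.0 * g * den - num * 2.0 * p) / den**2


# ---------------------------------------------------------------------------
# Generalized Dice Loss (background/foreground channels)
# ---------------------------------------------------------------------------

def _gdl_terms(p: np.ndarray, g: np.ndarray, eps: float):
    if p.ndim < 3 or p.shape[-3] != 2:
        raise ShapeError(f"expected (..., 2, H, W) two-channel input, got {p.shape}")
    _check_same_shape(p, g)
    axes = tuple(i for i in range(p.ndim) if i != p.ndim - 3)  # all but channel
    gsum = g.sum(axis=axes)
    w = 1.0 / (gsum + eps) ** 2
    num = (w * (p * g).sum(axis=axes)).sum()
    den = (w * (p + g).sum(axis=axes)).sum()
    return w, num, den, axes


def generalized_dice_loss(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> float:
    """GDL = 1 - 2*(sum_l w_l sum_i p_li g_li)/(sum_l w_l sum_i (p_li+g_li)).

    ``p`` holds channel probabilities summing to 1 per pixel; ``g`` is the
    one-hot target; ``w_l = 1/(sum_i g_li + eps)^2``.  Batch dimensions, if
    present, are folded into the pixel index i.
    """
    _, num, den, _ = _gdl_terms(p, g, eps)
    return float(1.0 - 2.0 * num / den)


def generalized_dice_loss_grad(p: np.ndarray, g: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """d(GDL)/dp, elementwise."""
    w, num, den, _ = _gdl_terms(p, g, eps)
    shape = [1] * p.ndim
    shape[p.ndim - 3] = 2
    wb = w.reshape(shape)
    return -2.0 * (wb * g * den - num * wb) / den**2


def one_hot(g: np.ndarray) -> np.ndarray:
    """Stack (background, foreground) channels from a binary mask.

    Input (..., H, W) binary; output (..., 2, H, W).
    """
    g = np.asarray(g)
    return np.stack([1 - g, g], axis=-3).astype(np.float64 if g.dtype.kind == "f" else np.float32)


# ---------------------------------------------------------------------------
# signed distance / surface loss / boundary loss
# ---------------------------------------------------------------------------

def signed_distance(g: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the region boundary.

    Positive outside the region, negative strictly inside, zero exactly on
    the inner-boundary pixels.  Empty or full masks have no boundary and are
    rejected; the trainer treats such patches separately.
    """
    mask = np.asarray(g) > 0.5
    if not mask.any() or mask.all():
        raise DegenerateMaskError("signed distance undefined for empty or full masks")
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask) - 1.0
    return (outside * ~mask - inside * mask).astype(np.float64)


def surface_loss(p: np.ndarray, dmap: np.ndarray) -> float:
    """Mean of the elementwise product of probabilities and signed distances."""
    _check_same_shape(p, dmap)
    return float((p * dmap).mean())


def surface_loss_grad(p: np.ndarray, dmap: np.ndarray) -> np.ndarray:
    _check_same_shape(p, dmap)
    return dmap / dmap.size


def alpha_schedule(epoch: int, total_epochs: int) -> float:
    """Linear anneal: alpha(1) = 1, alpha(total_epochs) = 0."""
    if total_epochs < 2:
        raise ConfigError("alpha schedule needs total_epochs >= 2")
    if not 1 <= epoch <= total_epochs:
        raise ScheduleError(f"epoch {epoch} outside [1, {total_epochs}]")
    return (total_epochs - epoch) / (total_epochs - 1)


def boundary_loss(
    p: np.ndarray, g: np.ndarray, epoch: int, cfg: LossConfig
) -> float:
    """B = alpha*GDL(p, onehot(g)) + (1-alpha)*S(p_fg, signed_distance(g)).

    ``p`` is the two-channel softmax output (channel -3 indexes background/
    foreground); ``g`` the binary foreground target.
    """
    if cfg.kind != "boundary":
        raise ConfigError("boundary_loss called with a non-boundary LossConfig")
    cfg.validate()
    a = alpha_schedule(epoch, cfg.total_epochs)
    gdl = generalized_dice_loss(p, one_hot(g), cfg.epsilon)
    fg = np.take(p, 1, axis=p.ndim - 3)
    s = surface_loss(fg, signed_distance(g))
    return a * gdl + (1.0 - a) * s


def boundary_loss_grad(
    p: np.ndarray, g: np.ndarray, epoch: int, cfg: LossConfig
) -> np.ndarray:
    a = alpha_schedule(epoch, cfg.total_epochs)
    grad = a * generalized_dice_loss_grad(p, one_hot(g), cfg.epsilon)
    dmap = signed_distance(g)
    fg_idx = [slice(None)] * p.ndim
    fg_idx[p.ndim - 3] = 1
    grad[tuple(fg_idx)] += (1.0 - a) * surface_loss_grad(np.take(p, 1, axis=p.ndim - 3), dmap)
    return grad


# ---------------------------------------------------------------------------
# trainer-facing batch loss
# ---------------------------------------------------------------------------

class BatchLoss:
    """Value-and-gradient of the configured loss on an (N, C, H, W) batch.

    Dice: single-channel predictions vs binary targets, batch-summed.
    GDL: two-channel predictions, batch folded into the pixel index.
    Boundary: GDL plus the surface term; the surface term is averaged over
    the samples whose target has a boundary (neither empty nor full) — a
    legitimate negative patch contains no foreground, so it contributes only
    the alpha-weighted regional term.
    """

    def __init__(self, cfg: LossConfig):
        cfg.validate()
        self.cfg = cfg

    def __call__(
        self, pred: np.ndarray, target: np.ndarray, epoch: int = 1
    ) -> tuple[float, np.ndarray]:
        cfg = self.cfg
        t = target.astype(np.float32)
        if t.ndim == 3:
            t = t[:, None]
        if cfg.kind == "dice":
            return (
                dice_loss(pred, t, cfg.epsilon),
                dice_loss_grad(pred, t, cfg.epsilon).astype(np.float32),
            )
        g2 = one_hot(t[:, 0]).astype(np.float32)
        gdl = generalized_dice_loss(pred, g2, cfg.epsilon)
        grad = generalized_dice_loss_grad(pred, g2, cfg.epsilon)
        if cfg.kind == "gdl":
            return gdl, grad.astype(np.float32)
        a = alpha_schedule(epoch, cfg.total_epochs)
        grad *= a
        s_vals = []
        for i in range(pred.shape[0]):
            gi = t[i, 0]
            if not gi.any() or gi.all():
                continue
            dmap = signed_distance(gi)
            s_vals.append((i, dmap))
        s_total = 0.0
        if s_vals:
            for i, dmap in s_vals:
                s_total += surface_loss(pred[i, 1], dmap)
                grad[i, 1] += (1.0 - a) * dmap / (dmap.size * len(s_vals))
            s_total /= len(s_vals)
        return a * gdl + (1.0 - a) * s_total, grad.astype(np.float32)
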