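"""Cohort splitting and per-orientation network training.

Training is orientation-specialized: the same subjects and split plan are
used three times, once per anatomical plane, each run drawing fresh extended
2D patches at runtime (positive patches centered on structure-border voxels,
negatives anywhere in the head) and optimizing the configured loss with Adam.
Every random stream is derived from the master seed plus a named context
(split / orientation / epoch), so patch streams differ across epochs while
the whole run stays reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError, SplitError
from .losses import BatchLoss, LossConfig, alpha_schedule, soft_dice
from .nn import Adam, NetworkConfig, UNet, build_network
from .patches import SamplerConfig, sample_patch
from .phantoms import Subject
from .volumes import ORIENTATIONS, ImageVolume, minmax_normalize

ROLES = ("train", "validation", "test")


@dataclass
class SplitPlan:
    """Disjoint subject-id sets per role; ``fold`` is set for k-fold plans."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    fold: int | None = None

    def role_of(self, subject_id: str) -> str | None:
        for role in ROLES:
            if subject_id in getattr(self, role):
                return role
        return None

    def validate(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise SplitError("split roles overlap")


def _stratum_labels(cohort: list[Subject], stratify_by) -> list:
    if stratify_by is None:
        return [None] * len(cohort)
    if callable(stratify_by):
        return [stratify_by(s) for s in cohort]
    return [getattr(s, stratify_by) for s in cohort]


def _allocate(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items to the fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_holdout(
    cohort: list[Subject],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    stratify_by: str | None = "group",
    seed: int = 0,
) -> SplitPlan:
    """Stratified, seeded train/validation/test hold-out.

    Fractions are honored per stratum up to rounding (largest remainder).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    labels = _stratum_labels(cohort, stratify_by)
    roles: dict[str, list[str]] = {r: [] for r in ROLES}
    for stratum in sorted(set(labels), key=str):
        ids = [s.subject_id for s, lab in zip(cohort, labels) if lab == stratum]
        ids = list(rng.permutation(ids))
        counts = _allocate(len(ids), fractions)
        pos = 0
        for role, c in zip(ROLES, counts):
            roles[role] += ids[pos : pos + c]
            pos += c
    for role, frac in zip(ROLES, fractions):
        if frac > 0 and not roles[role]:
            raise SplitError(f"stratification leaves role '{role}' empty")
    plan = SplitPlan(
        train=tuple(roles["train"]),
        validation=tuple(roles["validation"]),
        test=tuple(roles["test"]),
    )
    plan.validate()
    return plan


def make_kfold(cohort: list[Subject], k: int, seed: int = 0, stratify_by: str | None = "group") -> list[SplitPlan]:
    """k stratified folds whose test sets partition the cohort (no overlap)."""
    if k < 2:
        raise SplitError("k-fold requires k >= 2")
    if k > len(cohort):
        raise SplitError(f"k={k} exceeds cohort size {len(cohort)}")
    rng = np.random.default_rng(seed)
    labels = _stratum_labels(cohort, stratify_by)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for stratum in sorted(set(labels), key=str):
        ids = [s.subject_id for s, lab in zip(cohort, labels) if lab == stratum]
        ids = list(rng.permutation(ids))
        for i, sid in enumerate(ids):
            folds[(i + offset) % k].append(sid)
        offset += len(ids)  # rotate so small strata don't pile onto fold 0
    all_ids = {s.subject_id for s in cohort}
    plans = []
    for f in range(k):
        test = tuple(folds[f])
        train = tuple(sorted(all_ids - set(test)))
        plans.append(SplitPlan(train=train, validation=(), test=test, fold=f))
    return plans


@dataclass
class TrainConfig:
    """Everything that determines one training run (all seeds included)."""

    epochs: int = 15
    patches_per_epoch: int = 512
    batch_size: int = 16
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: LossConfig = field(default_factory=LossConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    # the default loss (boundary) trains against the two-channel softmax head
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(output_mode="softmax_2ch")
    )
    val_patches: int = 64
    seed: int = 0

    def validate(self) -> None:
        for name in ("epochs", "patches_per_epoch", "batch_size", "val_patches"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is provided")
        self.loss.validate()
        self.sampler.validate(depth=self.network.depth)
        if self.loss.output_mode != self.network.output_mode:
            raise ConfigError(
                f"loss '{self.loss.kind}' needs output_mode {self.loss.output_mode!r}, "
                f"network has {self.network.output_mode!r}"
            )
        if self.loss.kind == "boundary" and self.loss.total_epochs < self.epochs:
            raise ConfigError("boundary loss schedule horizon shorter than epochs")


def prepare_subjects(cohort: list[Subject]) -> dict[str, Subject]:
    """Index the cohort by id, minmax-normalizing any unnormalized image."""
    out = {}
    for s in cohort:
        image = s.image if s.image.normalized else minmax_normalize(s.image)
        out[s.subject_id] = Subject(
            subject_id=s.subject_id,
            image=image,
            label=s.label,
            group=s.group,
            resect_side=s.resect_side,
            spec=s.spec,
        )
    return out


def _foreground(prob: np.ndarray) -> np.ndarray:
    """Foreground probability map from either head layout."""
    return prob[:, 0] if prob.shape[1] == 1 else prob[:, 1]


def _draw_batch(subjects, ids, orientation, cfg: TrainConfig, rng, n: int):
    xs, ts = [], []
    drawn = []
    for _ in range(n):
        sid = ids[rng.integers(0, len(ids))]
        s = subjects[sid]
        positive = bool(rng.random() < cfg.sampler.positive_fraction)
        if positive and not s.label.data.any():
            positive = False  # resected-everything edge case: fall back to negative
        patch = sample_patch(s.image, s.label, positive, cfg.sampler, rng, orientation)
        xs.append(patch.channels)
        ts.append(patch.target)
        drawn.append(sid)
    return np.stack(xs), np.stack(ts), drawn


def train_orientation(
    model: UNet,
    subjects: dict[str, Subject],
    plan: SplitPlan,
    orientation: str,
    cfg: TrainConfig,
) -> tuple[UNet, list[dict]]:
    """Train one orientation network; returns (best model, per-epoch history).

    Patches are drawn fresh every epoch (stream seeded by master seed +
    orientation + epoch, so no two epochs repeat).  Model selection keeps the
    checkpoint with the best validation soft Dice, computed on a fixed seeded
    set of validation patches; without validation subjects the final epoch is
    kept.
    """
    cfg.validate()
    if not plan.train:
        raise ConfigError("split plan has no training subjects")
    orient_idx = ORIENTATIONS.index(orientation)
    loss_fn = BatchLoss(cfg.loss)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    train_ids = list(plan.train)
    val_ids = [i for i in plan.validation]

    val_batch = None
    if val_ids:
        vrng = np.random.default_rng([cfg.seed, orient_idx, 10**6])
        vx, vt, _ = _draw_batch(subjects, val_ids, orientation, cfg, vrng, cfg.val_patches)
        val_batch = (vx, vt)

    history: list[dict] = []
    best_val = -np.inf
    best_state = None
    n_batches = max(1, cfg.patches_per_epoch // cfg.batch_size)
    for epoch in range(1, cfg.epochs + 1):
        rng = np.random.default_rng([cfg.seed, orient_idx, epoch])
        losses = []
        used: set[str] = set()
        for _ in range(n_batches):
            x, t, drawn = _draw_batch(subjects, train_ids, orientation, cfg, rng, cfg.batch_size)
            used.update(drawn)
            model.zero_grad()
            pred = model.forward(x, train=True)
            value, grad = loss_fn(pred, t, epoch=epoch)
            model.backward(grad)
            opt.step()
            losses.append(value)
        val_dice = np.nan
        if val_batch is not None:
            vp = _foreground(model.forward(val_batch[0], train=False))
            val_dice = soft_dice(vp, val_batch[1].astype(np.float32))
            if val_dice > best_val:
                best_val = val_dice
                best_state = copy.deepcopy(model.state_dict())
        record = {
            "epoch": epoch,
            "orientation": orientation,
            "train_loss": float(np.mean(losses)),
            "val_dice": float(val_dice),
            "subjects_used": tuple(sorted(used)),
        }
        if cfg.loss.kind == "boundary":
            record["alpha"] = alpha_schedule(epoch, cfg.loss.total_epochs)
        history.append(record)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def train_ensemble(
    subjects: dict[str, Subject], plan: SplitPlan, cfg: TrainConfig
) -> tuple[dict[str, UNet], list[dict]]:
    """Train the three orientation-specialized networks on a shared split."""
    cfg.validate()
    models: dict[str, UNet] = {}
    history: list[dict] = []
    for i, orientation in enumerate(ORIENTATIONS):
        # distinct init per orientation; data slicing differs anyway
        model = build_network(replace(cfg.network, seed=cfg.network.seed + i))
        model, h = train_orientation(model, subjects, plan, orientation, cfg)
        models[orientation] = model
        history += h
    return models, history
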