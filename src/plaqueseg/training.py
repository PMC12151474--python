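"""Cross-validation training harness.

Replicates the study protocol at configurable scale: per-plaque-class
binary segmentation models trained with RMSprop on the combined
BCE + dice loss, evaluated by grouped k-fold cross-validation (default
ten folds, learning rate 1e-4, 120 epochs, batch size 32).  Folds are cut
at the level of *parent originals*, never individual images, so augmented
copies of one phantom can never straddle a train/test boundary.

Each epoch logs the mean training loss and the held-out dice coefficient,
giving the per-class dice-vs-epoch curves; histories export to CSV.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, sigmoid
from .network import DACNet, NetworkConfig, save_checkpoint
from .objectives import MetricsReport, soft_loss_tensor
from .phantom import DatasetManifest, load_sample

__all__ = ["TrainConfig", "FoldPlan", "TrainingHistory", "CVReport",
           "RMSprop", "make_folds", "load_arrays", "train_one_fold",
           "cross_validate"]

logger = logging.getLogger("plaqueseg.training")


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the full-scale protocol."""

    learning_rate: float = 1e-4
    epochs: int = 120
    batch_size: int = 32
    optimizer: str = "rmsprop"
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    folds: int = 10
    seed: int = 0
    device: str = "cpu"
    plaque_class: str = "calcified"
    threshold: float = 0.5

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class FoldPlan:
    """Assignment of each split group (parent original) to one fold."""

    assignment: dict[str, int]
    folds: int

    def groups_in_fold(self, fold: int) -> set[str]:
        return {g for g, f in self.assignment.items() if f == fold}

    def validate(self) -> None:
        sizes = np.bincount(list(self.assignment.values()), minlength=self.folds)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than one group")


@dataclass
class TrainingHistory:
    """Per-epoch records of one fold; epoch 0 is the untrained model."""

    fold: int
    plaque_class: str
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_dice: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)
    final_metrics: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss", "dice"])
            for e, l, d in zip(self.epochs, self.train_loss, self.test_dice):
                w.writerow([e, f"{l:.6f}", f"{d:.6f}"])


def make_folds(manifest: DatasetManifest, k: int,
               seed: int) -> FoldPlan:
    """Shuffle the parent groups and deal them round-robin into k folds."""
    groups = manifest.groups
    if len(groups) < k:
        raise ValueError(f"{len(groups)} groups cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(groups))
    plan = FoldPlan(assignment={g: i % k for i, g in enumerate(order)}, folds=k)
    plan.validate()
    return plan


def load_arrays(manifest: DatasetManifest, entries: list[dict],
                plaque_class: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack entries into (N, 3, H, W) images and (N, H, W) binary masks."""
    imgs, masks = [], []
    for e in entries:
        s = load_sample(manifest, e)
        imgs.append(s.image.transpose(2, 0, 1))
        masks.append(s.masks[plaque_class])
    return (np.stack(imgs).astype(np.float32),
            np.stack(masks).astype(np.float32))


class RMSprop:
    """Root-mean-square propagation: w -= lr * g / (sqrt(E[g^2]) + eps)."""

    def __init__(self, params: list[Tensor], lr: float,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.square_avg = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, sq in zip(self.params, self.square_avg):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)


_FG_WEIGHT = np.array([-1.0, 1.0], np.float32).reshape(1, 2, 1, 1)


def _foreground_prob(logits: Tensor) -> Tensor:
    """Softmax foreground probability of 2-channel logits, shape (N, H, W).

    softmax(z)_1 = sigmoid(z_1 - z_0); the difference is taken with a
    fixed +/-1 channel weighting so it stays on the gradient tape.
    """
    diff = (logits * Tensor(_FG_WEIGHT)).sum(axis=1)
    return sigmoid(diff)


def _eval_dice(model: DACNet, images: np.ndarray, masks: np.ndarray,
               threshold: float, batch: int) -> tuple[float, MetricsReport]:
    pairs = []
    for lo in range(0, len(images), batch):
        prob = model.predict_proba(images[lo:lo + batch])
        pred = (prob >= threshold).astype(np.uint8)
        pairs.extend(zip(pred, masks[lo:lo + batch].astype(np.uint8)))
    report = MetricsReport.from_pairs(pairs)
    return report.mean()["dice"], report


def train_one_fold(fold: int, plan: FoldPlan, manifest: DatasetManifest,
                   net_cfg: NetworkConfig, train_cfg: TrainConfig
                   ) -> tuple[DACNet, TrainingHistory]:
    """Train on every fold but ``fold``; evaluate dice on ``fold`` per epoch.

    Deterministic given the seeds in both configs.  Raises ``RuntimeError``
    if the loss diverges to NaN.
    """
    test_groups = plan.groups_in_fold(fold)
    train_entries = [e for e in manifest.entries if e["group"] not in test_groups]
    test_entries = [e for e in manifest.entries if e["group"] in test_groups]
    if not train_entries or not test_entries:
        raise ValueError(f"fold {fold} leaves an empty train or test set")
    x_train, y_train = load_arrays(manifest, train_entries, train_cfg.plaque_class)
    x_test, y_test = load_arrays(manifest, test_entries, train_cfg.plaque_class)

    model = DACNet(net_cfg)
    opt = RMSprop(model.parameters(), train_cfg.learning_rate,
                  train_cfg.rmsprop_alpha, train_cfg.rmsprop_eps)
    rng = np.random.default_rng([train_cfg.seed, fold])
    history = TrainingHistory(fold=fold, plaque_class=train_cfg.plaque_class)

    # epoch 0: the untrained model, the baseline the dice curve starts from
    dice0, _ = _eval_dice(model, x_test, y_test, train_cfg.threshold,
                          train_cfg.batch_size)
    history.epochs.append(0)
    history.train_loss.append(float("nan"))
    history.test_dice.append(dice0)
    history.seconds.append(0.0)
    logger.info("fold=%d epoch=0 dice=%.4f (untrained)", fold, dice0)

    for epoch in range(1, train_cfg.epochs + 1):
        t0 = time.perf_counter()
        model.set_training(True)
        order = rng.permutation(len(x_train))
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            logits = model(Tensor(x_train[idx]))
            loss = soft_loss_tensor(_foreground_prob(logits), y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"loss diverged (fold {fold}, epoch {epoch}): {loss.data}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        dice, report = _eval_dice(model, x_test, y_test, train_cfg.threshold,
                                  train_cfg.batch_size)
        dt = time.perf_counter() - t0
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.test_dice.append(dice)
        history.seconds.append(dt)
        history.final_metrics = report.mean()
        logger.info("fold=%d epoch=%d loss=%.4f dice=%.4f (%.1fs)",
                    fold, epoch, history.train_loss[-1], dice, dt)
    return model, history


@dataclass
class CVReport:
    """Aggregated cross-validation outcome for one plaque class."""

    plaque_class: str
    histories: list[TrainingHistory]

    @property
    def fold_metrics(self) -> list[dict[str, float]]:
        return [h.final_metrics for h in self.histories]

    def mean(self) -> dict[str, float]:
        keys = ("dice", "precision", "recall", "iou")
        return {k: float(np.mean([m[k] for m in self.fold_metrics]))
                for k in keys}

    def std(self) -> dict[str, float]:
        keys = ("dice", "precision", "recall", "iou")
        return {k: float(np.std([m[k] for m in self.fold_metrics]))
                for k in keys}


def cross_validate(manifest: DatasetManifest, net_cfg: NetworkConfig,
                   train_cfg: TrainConfig, checkpoint_dir=None
                   ) -> tuple[CVReport, list[DACNet]]:
    """Run grouped k-fold CV; returns the report and one model per fold."""
    plan = make_folds(manifest, train_cfg.folds, train_cfg.seed)
    models, histories = [], []
    for fold in range(train_cfg.folds):
        model, history = train_one_fold(fold, plan, manifest, net_cfg, train_cfg)
        models.append(model)
        histories.append(history)
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, path /
                            f"{train_cfg.plaque_class}_fold{fold}.npz")
            history.to_csv(path / f"{train_cfg.plaque_class}_fold{fold}.csv")
    return CVReport(plaque_class=train_cfg.plaque_class,
                    histories=histories), models
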