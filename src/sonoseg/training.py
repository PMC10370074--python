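"""Dataset splitting, the training loop, checkpointing and inference.

Training minimizes the BCE + soft-Dice compound loss with Adam
(learning rate 0.001, beta1 0.9, beta2 0.9 as configured — note the
unconventional beta2, kept as the reference setting with an override —
epsilon 1e-7), evaluates the validation set every epoch, and keeps the
parameter state of the best epoch according to a monitored validation
quantity (validation loss by default, validation soft Dice selectable).
Augmentation, when enabled, is sampled on the fly per epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .augment import AugmentConfig, apply_transform, sample_params
from .autodiff import Adam
from .components import LossConfig, bce_dice_grad, bce_dice_loss, dice_coefficient
from .imaging import SegSample
from .models import SegmentationModel

logger = logging.getLogger(__name__)

MONITORS = ("val_loss", "val_dice")


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.9
    adam_epsilon: float = 1e-7
    monitor: str = "val_loss"
    early_stopping_patience: int | None = None
    stop_at_val_dice: float | None = None  # optional early success cutoff
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.monitor not in MONITORS:
            raise ValueError(f"monitor must be one of {MONITORS}")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of sample identifiers."""

    train: list
    validation: list
    test: list


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)  # per-epoch metric records
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


def split_dataset(
    samples: Sequence,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle and partition into train/validation/test.

    Train gets floor(n * f_train) items, validation floor(n * f_val), and the
    remainder goes to test; with fractions 80/10/10 and n = 780 this gives
    the 624/78/78 partition sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    items = list(samples)
    n = len(items)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    return DatasetSplit(
        train=[items[i] for i in idx_train],
        validation=[items[i] for i in idx_val],
        test=[items[i] for i in idx_test],
    )


def _stack(samples: Sequence[SegSample]):
    x = np.stack([s.image for s in samples]).astype(np.float32)[..., None]
    y = np.stack([s.mask for s in samples]).astype(np.float32)[..., None]
    return x, y


def predict(
    model: SegmentationModel, images: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    """Deterministic inference (dropout off); returns probability maps."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[..., None]
    outs = []
    for start in range(0, len(images), batch_size):
        outs.append(model.forward(images[start : start + batch_size]).data)
    return np.concatenate(outs, axis=0)


def evaluate_loss_dice(
    model: SegmentationModel,
    samples: Sequence[SegSample],
    loss_cfg: LossConfig,
    batch_size: int = 32,
) -> tuple[float, float]:
    """(BCEDice loss, soft Dice) over a sample set, pooled over all pixels."""
    x, y = _stack(samples)
    p = predict(model, x, batch_size)
    return (
        bce_dice_loss(y, p, loss_cfg),
        dice_coefficient(y, p, loss_cfg),
    )


def train(
    model: SegmentationModel,
    split: DatasetSplit,
    train_cfg: TrainConfig = TrainConfig(),
    loss_cfg: LossConfig = LossConfig(),
    augment_cfg: AugmentConfig | None = None,
) -> TrainHistory:
    """Fit the model on split.train, monitoring split.validation.

    On return the model carries the best-epoch parameters (restored from the
    in-memory checkpoint). The history records per-epoch train/validation
    loss and soft Dice.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    if not all(isinstance(s, SegSample) for s in split.train):
        raise TypeError("train() expects a DatasetSplit of SegSample objects")
    aug_cfg = augment_cfg or AugmentConfig()
    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(
        model.parameters(),
        lr=train_cfg.learning_rate,
        beta1=train_cfg.beta1,
        beta2=train_cfg.beta2,
        eps=train_cfg.adam_epsilon,
    )
    history = TrainHistory()
    best_value = np.inf
    sign = 1.0 if train_cfg.monitor == "val_loss" else -1.0
    best_state = model.state_dict()
    since_best = 0
    n_train = len(split.train)
    for epoch in range(train_cfg.epochs):
        # derived per-epoch seed keeps shuffling & augmentation reproducible
        epoch_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        order = epoch_rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, train_cfg.batch_size):
            batch = [split.train[i] for i in order[start : start + train_cfg.batch_size]]
            if train_cfg.augment:
                batch = [
                    apply_transform(s, sample_params(aug_cfg, epoch_rng))
                    for s in batch
                ]
            x, y = _stack(batch)
            pred = model.forward(x, training=True, rng=epoch_rng)
            loss = bce_dice_loss(y, pred.data, loss_cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}"
                )
            epoch_losses.append(loss)
            optimizer.zero_grad()
            pred.backward(bce_dice_grad(y, pred.data, loss_cfg).astype(pred.data.dtype))
            optimizer.step()
        val_loss, val_dice = evaluate_loss_dice(
            model, split.validation, loss_cfg, train_cfg.batch_size
        )
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_dice": val_dice,
        }
        history.epochs.append(record)
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f val_dice=%.4f",
            epoch, record["train_loss"], val_loss, val_dice,
        )
        monitored = sign * (val_loss if train_cfg.monitor == "val_loss" else val_dice)
        if monitored < best_value:
            best_value = monitored
            history.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
        if (
            train_cfg.early_stopping_patience is not None
            and since_best >= train_cfg.early_stopping_patience
        ):
            logger.info("early stopping at epoch %d", epoch)
            break
        if (
            train_cfg.stop_at_val_dice is not None
            and val_dice > train_cfg.stop_at_val_dice
        ):
            logger.info("validation Dice target reached at epoch %d", epoch)
            break
    model.load_state_dict(best_state)
    return history
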