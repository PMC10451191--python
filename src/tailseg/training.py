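"""Weighted per-pixel loss and a seeded training loop.

The loss is weighted categorical cross-entropy normalized by the sum of
the per-pixel weights,

    L = sum_p w[y_p] * (-log softmax(s_p)[y_p]) / sum_p w[y_p],

so it is invariant under rescaling all class weights by a positive
constant and reduces exactly to plain mean cross-entropy when the
weights are equal.  Class weights are computed once from the training
split's statistics before training, not per batch.

The optimizer is Adam (lr 1e-3 by default, no schedule) — a stable
desk-scale default recorded in the run configuration for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .metrics import accumulate_confusion, per_class_metrics
from .network import WAResUNet, predict_mask
from .nn import Adam, tape
from .weights import WeightVector

OPTIMIZERS = ("adam",)
WEIGHT_MODES = ("uniform", "pixel_based", "image_based")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    weight_mode: str = "image_based"
    seed: int = 0
    device: str = "cpu"          # hint only; execution is NumPy on CPU
    eval_interval: int = 0       # 0 = metrics at the final epoch only
    precision: str = "float32"   # training compute precision

    def validate(self) -> None:
        problems = []
        if self.epochs < 0:
            problems.append("epochs must be >= 0")
        if self.batch_size < 1:
            problems.append("batch_size must be >= 1")
        if self.learning_rate <= 0:
            problems.append("learning_rate must be > 0")
        if self.optimizer_name not in OPTIMIZERS:
            problems.append(f"optimizer_name must be one of {OPTIMIZERS}")
        if self.weight_mode not in WEIGHT_MODES:
            problems.append(f"weight_mode must be one of {WEIGHT_MODES}")
        if self.precision not in ("float32", "float64"):
            problems.append("precision must be float32 or float64")
        if problems:
            raise ConfigError("; ".join(problems))


def weighted_cross_entropy(scores, targets, weights) -> float:
    """Normalized weighted cross-entropy of raw score maps.

    ``scores``: (B, C+1, H, W) array; ``targets``: (B, H, W) integer labels;
    ``weights``: a :class:`WeightVector` (background weight applied to
    label 0) or a plain length-(C+1) array of per-label weights.
    """
    if isinstance(weights, WeightVector):
        w = weights.full_weights()
    else:
        w = np.asarray(weights, dtype=np.float64)
    with tape.no_grad():
        loss = tape.weighted_cross_entropy_loss(
            tape.Tensor(np.asarray(scores, dtype=np.float64)),
            np.asarray(targets), w)
    return float(loss.data)


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    metrics: dict | None = None


def _dataset_arrays(dataset: Sequence):
    imgs = np.stack([np.asarray(d.image, dtype=np.float64) for d in dataset])
    masks = np.stack([np.asarray(d.mask) for d in dataset])
    return imgs[:, None], masks


def evaluate_model(model: WAResUNet, dataset: Sequence, batch_size: int = 8):
    """Micro-accumulated per-class metrics of model predictions on a dataset."""
    C = model.config.num_foreground_classes
    imgs, masks = _dataset_arrays(dataset)
    tally = None
    for i in range(0, len(dataset), batch_size):
        pred = predict_mask(imgs[i:i + batch_size], model)
        for p, t in zip(pred, masks[i:i + batch_size]):
            tally = accumulate_confusion(p, t, C, tally)
    return per_class_metrics(tally)


def train_model(model: WAResUNet, dataset: Sequence, train_config: TrainConfig,
                weights: WeightVector):
    """Train in place; returns ``(model, history)``.

    ``history`` holds one :class:`EpochRecord` per epoch with the mean
    batch loss; per-class metrics on the training data are attached at
    the final epoch and every ``eval_interval`` epochs when set.
    ``epochs=0`` returns the model untouched with an empty history.
    """
    train_config.validate()
    if len(dataset) == 0:
        raise DataError("training dataset is empty")
    if train_config.epochs == 0:
        return model, []

    C = model.config.num_foreground_classes
    full_w = weights.full_weights()
    if full_w.shape[0] != C + 1:
        raise DataError(
            f"weight vector covers {full_w.shape[0]} labels, model has {C + 1}")
    imgs, masks = _dataset_arrays(dataset)
    if masks.max() > C or masks.min() < 0:
        raise DataError(f"mask labels outside 0..{C}")

    dtype = np.dtype(train_config.precision)
    model.astype(dtype)
    imgs = imgs.astype(dtype)
    rng = np.random.default_rng(train_config.seed)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    model.train()
    history: List[EpochRecord] = []
    n = len(dataset)
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            sel = order[start:start + train_config.batch_size]
            scores = model(tape.Tensor(imgs[sel]))
            loss = tape.weighted_cross_entropy_loss(scores, masks[sel], full_w)
            if not np.isfinite(loss.data):
                raise DataError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = EpochRecord(epoch=epoch, loss=float(np.mean(losses)))
        want_eval = (epoch == train_config.epochs or
                     (train_config.eval_interval and
                      epoch % train_config.eval_interval == 0))
        if want_eval:
            report = evaluate_model(model, dataset,
                                    batch_size=train_config.batch_size)
            record.metrics = {
                "iou": report.iou.tolist(),
                "sensitivity": report.sensitivity.tolist(),
                "precision": report.precision.tolist(),
                "overall_foreground_iou": report.overall_foreground["iou"],
            }
            model.train()
        history.append(record)
    model.eval()
    return model, history
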