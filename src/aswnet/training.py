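"""Loss, RMSProp optimization loop, early stopping and save-best.

Training minimizes a weighted cross-entropy over the three semantic
classes; the per-pixel weight is the weight of the pixel's true class
and the loss is normalized by the summed weights so its scale is
comparable across class-imbalance settings.  The optimizer is RMSProp,
whose per-parameter adaptive scaling provides the dynamic learning-rate
behaviour.  Training stops early when the validation loss has not
improved (strict decrease by more than 1e-6) for ``patience_epochs``
consecutive epochs, and the best-validation weights are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _autodiff as ad
from .errors import DivergenceError, EmptyDataset, ShapeError
from .network import ModelHandle
from .preprocess import ClassWeights

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopping",
    "RMSProp",
    "weighted_cross_entropy",
    "train",
]

_MIN_DELTA = 1e-6  # "did not reduce" threshold for early stopping


@dataclass
class TrainConfig:
    max_epochs: int = 50
    batch_size: int = 4
    initial_learning_rate: float = 1e-3
    patience_epochs: int = 10
    weights: ClassWeights = field(default_factory=ClassWeights)
    rng_seed: int = 0

    def __post_init__(self):
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0            # 0-based index into the loss lists
    stopped_early: bool = False


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement.

    An epoch improves only if its loss is lower than the best so far by
    more than ``min_delta``.
    """

    def __init__(self, patience: int, min_delta: float = _MIN_DELTA):
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self._stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record an epoch's validation loss; returns True to stop."""
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = epoch
            self._stale = 0
        else:
            self._stale += 1
        return self._stale >= self.patience


class RMSProp:
    """RMSProp with the usual running mean of squared gradients."""

    def __init__(self, params: dict, lr: float, rho: float = 0.9,
                 eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self):
        for k, t in self.params.items():
            if t.grad is None:
                continue
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * t.grad * t.grad
            t.data -= self.lr * t.grad / (np.sqrt(c) + self.eps)


def weighted_cross_entropy(probs: np.ndarray, target: np.ndarray,
                           weights: ClassWeights | np.ndarray) -> float:
    """Weighted cross-entropy of class probabilities against int targets.

    loss = -(sum_p w[c(p)] log probs[p, c(p)]) / sum_p w[c(p)], with
    probabilities clipped below at 1e-7.  Accepts (3, H, W) or
    (N, 3, H, W) probabilities with matching (H, W) / (N, H, W) targets.
    """
    w = weights.as_array() if isinstance(weights, ClassWeights) else np.asarray(weights)
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.ndim == 3:
        probs = probs[None]
        target = target[None]
    if probs.ndim != 4 or probs.shape[1] != len(w) or probs.shape[0] != target.shape[0] \
            or probs.shape[2:] != target.shape[1:]:
        raise ShapeError("probability/target shapes do not match")
    p_true = np.take_along_axis(probs, target[:, None], axis=1)[:, 0]
    wmap = w[target]
    return float(-(wmap * np.log(np.clip(p_true, 1e-7, None))).sum() / wmap.sum())


def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _epoch_loss(model: ModelHandle, images: np.ndarray, targets: np.ndarray,
                w: np.ndarray, batch_size: int) -> float:
    total, wtot = 0.0, 0.0
    for idx in _batches(len(images), batch_size, np.arange(len(images))):
        logits = model.forward_logits(images[idx][:, None], training=False)
        probs = ad.softmax(logits.data, axis=1)
        wsum = w[targets[idx]].sum()
        total += weighted_cross_entropy(probs, targets[idx], w) * wsum
        wtot += wsum
    return total / wtot


def train(model: ModelHandle,
          train_set: Sequence[tuple[np.ndarray, np.ndarray]],
          val_set: Sequence[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig,
          augmenter: Callable | None = None,
          log: Callable[[str], None] | None = None,
          ) -> tuple[ModelHandle, TrainHistory]:
    """Optimize ``model`` on (image, 3-class target) pairs.

    ``train_set``/``val_set`` are sequences of ``(image, target)`` 2-D
    array pairs (normalized image, int class map).  ``augmenter``, if
    given, is called per training sample per epoch as
    ``augmenter(image, target, rng)`` and must return a transformed pair.
    Returns the model carrying the best-validation-epoch weights and the
    full history.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise EmptyDataset("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    w = config.weights.as_array()
    opt = RMSProp(model.parameters(), lr=config.initial_learning_rate)
    stopper = EarlyStopping(config.patience_epochs)
    history = TrainHistory()

    val_images = np.stack([im for im, _ in val_set]).astype(np.float32)
    val_targets = np.stack([t for _, t in val_set]).astype(np.int64)
    best_state = model.state_dict()

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_total, epoch_wtot = 0.0, 0.0
        for idx in _batches(len(train_set), config.batch_size, order):
            ims, tgts = [], []
            for i in idx:
                im, tgt = train_set[i]
                if augmenter is not None:
                    im, tgt = augmenter(im, tgt, rng)
                ims.append(np.asarray(im, dtype=np.float32))
                tgts.append(np.asarray(tgt, dtype=np.int64))
            x = np.stack(ims)[:, None]
            t = np.stack(tgts)
            model.zero_grad()
            logits = model.forward_logits(x, training=True)
            loss = ad.weighted_softmax_cross_entropy(logits, t, w)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise DivergenceError(epoch)
            loss.backward()
            opt.step()
            wsum = w[t].sum()
            epoch_total += loss_val * wsum
            epoch_wtot += wsum
        history.train_loss.append(epoch_total / epoch_wtot)
        val_loss = _epoch_loss(model, val_images, val_targets, w, config.batch_size)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history.val_loss.append(val_loss)
        if log:
            log(f"epoch {epoch:3d}  train {history.train_loss[-1]:.4f}  "
                f"val {val_loss:.4f}")
        improved = val_loss < stopper.best_loss - stopper.min_delta
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.state_dict()
        if stop:
            history.stopped_early = True
            break

    history.best_epoch = max(stopper.best_epoch, 0)
    model.load_state_dict(best_state)
    return model, history
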