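"""Training harness: binary cross-entropy, Adam, early stopping on training loss.

The optimization protocol is fixed and simple: minibatches of 512, Adam with
learning rate 0.001, and early stopping that halts when the *training* loss
has not improved for 25 consecutive units (epochs by default).  The parameter
state with the smallest recorded training loss is the one returned.  Monitoring
training loss for early stopping is unusual — most pipelines monitor a
validation loss — but it is the protocol this harness implements; a
validation-monitored mode is available through ``monitor='val'``.

Class balancing is deliberately *not* done here: the trainer consumes exactly
the windows it is given, and resampling decisions belong to the evaluation
protocol (see :mod:`splitbench.evaluate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import nn
from .models import TrainedModel, encode_inputs


class TrainingError(RuntimeError):
    """Degenerate inputs or a diverging loss."""


@dataclass
class TrainConfig:
    """Optimization settings.

    ``patience_unit`` selects whether the 25-unit early-stopping window is
    counted in epochs (default) or in minibatches.  ``monitor`` selects the
    loss stream driving early stopping and checkpoint selection: the training
    loss (default) or a held-out validation loss.
    """

    learning_rate: float = 1e-3
    batch_size: int = 512
    patience: int = 25
    patience_unit: str = "epoch"  # or "batch"
    min_delta: float = 0.0  # smallest loss decrease counted as improvement
    max_epochs: int = 500
    seed: int = 0
    monitor: str = "train"  # or "val"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.patience_unit not in ("epoch", "batch"):
            raise ValueError(f"bad patience_unit {self.patience_unit!r}")
        if self.monitor not in ("train", "val"):
            raise ValueError(f"bad monitor {self.monitor!r}")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class EarlyStopper:
    """Best-so-far tracker with a fixed patience window.

    ``update`` returns True when the monitored loss has failed to improve by
    more than ``min_delta`` for ``patience`` consecutive updates since the
    last improvement.  ``best``/``best_index`` always track the strict
    minimum (the checkpointing target) regardless of ``min_delta``.
    """

    def __init__(self, patience: int, min_delta: float = 0.0) -> None:
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_index: int | None = None
        self._since_best = 0
        self._count = 0

    def update(self, loss: float) -> bool:
        improved = loss < self.best - self.min_delta
        if loss < self.best:
            self.best = loss
            self.best_index = self._count
        if improved:
            self._since_best = 0
        else:
            self._since_best += 1
        self._count += 1
        return self._since_best >= self.patience


def train(
    model: TrainedModel,
    positives,
    negatives,
    config: TrainConfig,
    validation: tuple | None = None,
) -> TrainedModel:
    """Fit a fresh copy of ``model``; returns the best-loss checkpoint.

    ``positives`` / ``negatives`` are window collections (sequences,
    SequenceWindow objects, EncodedWindow lists or ready arrays).  They must
    be non-empty and, when given as sequences, disjoint.  The returned model's
    ``training_history`` holds one loss value per unit (epoch by default).
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise TrainingError("both classes must be non-empty")
    _assert_disjoint(positives, negatives)
    if config.monitor == "val" and validation is None:
        raise TrainingError("monitor='val' requires a validation set")

    xp = encode_inputs(model.spec, positives)
    xn = encode_inputs(model.spec, negatives)
    x = np.concatenate([xp, xn])
    y = np.concatenate([np.ones(len(xp), dtype=np.float32),
                        np.zeros(len(xn), dtype=np.float32)])
    if validation is not None:
        xv = np.concatenate([encode_inputs(model.spec, validation[0]),
                             encode_inputs(model.spec, validation[1])])
        yv = np.concatenate([np.ones(len(validation[0]), dtype=np.float32),
                             np.zeros(len(validation[1]), dtype=np.float32)])

    fitted = model.copy()
    fitted.training_history = []
    if config.max_epochs == 0:
        return fitted

    net = fitted.net
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(net, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience, config.min_delta)
    per_batch = config.patience_unit == "batch"
    best_state = net.get_state()
    history: list[float] = []
    stop = False

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x))
        batch_losses, batch_sizes = [], []
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            net.zero_grads()
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch + 1}")
            if per_batch and config.monitor == "train":
                # the recorded loss belongs to the *pre-update* parameters, so
                # checkpoint before stepping: returned state = argmin history
                history.append(loss)
                if loss < stopper.best:
                    best_state = net.get_state()
                stop = stopper.update(loss)
            net.backward(dlogits)
            optimizer.step()
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
            if per_batch and config.monitor == "val":
                unit_loss = _eval_loss(net, xv, yv, config.batch_size)
                history.append(unit_loss)
                if unit_loss < stopper.best:
                    best_state = net.get_state()
                stop = stopper.update(unit_loss)
            if stop:
                break
        if stop:
            break
        if not per_batch:
            epoch_loss = float(np.average(batch_losses, weights=batch_sizes))
            if config.monitor == "val":
                epoch_loss = _eval_loss(net, xv, yv, config.batch_size)
            history.append(epoch_loss)
            if epoch_loss < stopper.best:
                best_state = net.get_state()
            if stopper.update(epoch_loss):
                break

    net.set_state(best_state)
    fitted.training_history = history
    return fitted


def _eval_loss(net: nn.Network, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _ = nn.bce_with_logits(logits, y[i:i + batch_size])
        total += loss * len(logits)
        n += len(logits)
    return total / n


def _assert_disjoint(positives, negatives) -> None:
    def seqs(ws):
        out = set()
        for w in ws:
            s = getattr(w, "sequence", w if isinstance(w, str) else None)
            if s is not None:
                out.add(s)
        return out

    if isinstance(positives, np.ndarray) or isinstance(negatives, np.ndarray):
        return
    shared = seqs(positives) & seqs(negatives)
    if shared:
        raise TrainingError(
            f"{len(shared)} window sequences appear in both classes"
        )
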