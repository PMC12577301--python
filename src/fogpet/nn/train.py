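"""Training loop: Adam, mini-batches, early stopping on validation performance.

The selected model is the one with the highest validation accuracy (lowest
validation MSE for regression) over epochs, earliest epoch on ties. Training
stops when the validation metric has not improved for ``patience``
consecutive epochs or after ``max_epochs``. For classification, once
validation accuracy reaches 1.0 no later epoch can displace the selected
model under first-best tie-breaking, so training halts there as well (set
``stop_when_perfect=False`` to disable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .layers import mse_loss, nll_loss
from .model import Sequential
from .optim import Adam

__all__ = ["TrainConfig", "TrainHistory", "train_model", "predict"]


class TrainConfig(BaseModel):
    """Optimization hyperparameters (defaults: Adam, lr 3e-3, weight decay
    2e-3, batch 16 train / 1 test, up to 300 epochs, patience 100)."""

    model_config = ConfigDict(extra="forbid")

    learning_rate: float = Field(default=3e-3, gt=0)
    weight_decay: float = Field(default=2e-3, ge=0)
    batch_train: int = Field(default=16, ge=1)
    batch_test: int = Field(default=1, ge=1)
    max_epochs: int = Field(default=300, ge=1)
    patience: int = Field(default=100, ge=1)
    stop_when_perfect: bool = True
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)  # accuracy or MSE
    best_epoch: int = -1
    best_val: float = np.nan
    stopped_early: bool = False


def _as_batch_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim in (3, 4) and X.shape[1] != 1:
        # add channel axis for (B, *spatial) input
        X = X[:, None]
    return X


def _val_metric(model: Sequential, X_val, y_val, task: str, batch: int) -> float:
    outs = []
    for i in range(0, len(X_val), batch):
        outs.append(model.forward(X_val[i:i + batch]))
    out = np.concatenate(outs, axis=0)
    if task == "classify":
        return float((out.argmax(axis=1) == np.asarray(y_val)).mean())
    return float(((out.reshape(-1) - np.asarray(y_val, dtype=np.float64)) ** 2).mean())


def train_model(model: Sequential, X_train, y_train, X_val, y_val,
                cfg: TrainConfig | None = None) -> tuple[Sequential, TrainHistory]:
    """Train with Adam and early stopping; returns the epoch-best model.

    ``X_*`` are (B, 1, *spatial) float arrays (a missing channel axis is
    added); classification targets are integer class labels in {0, 1},
    regression targets are scalars.
    """
    cfg = cfg or TrainConfig()
    task = getattr(model, "task", "classify")
    X_train = _as_batch_array(X_train)
    X_val = _as_batch_array(X_val)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    hist = TrainHistory()
    better = (lambda new, best: new > best) if task == "classify" else (lambda new, best: new < best)
    best_params = model.get_params()
    hist.best_val = -np.inf if task == "classify" else np.inf
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_train):
            idx = order[start:start + cfg.batch_train]
            out = model.forward(X_train[idx])
            if task == "classify":
                loss, dout = nll_loss(out, y_train[idx])
            else:
                loss, dout = mse_loss(out, y_train[idx])
            model.backward(dout.astype(np.float32))
            opt.step()
            epoch_loss += loss * len(idx)
        hist.train_loss.append(epoch_loss / len(order))

        metric = _val_metric(model, X_val, y_val, task, cfg.batch_train)
        hist.val_metric.append(metric)
        if better(metric, hist.best_val):
            hist.best_val = metric
            hist.best_epoch = epoch
            best_params = model.get_params()
            since_best = 0
        else:
            since_best += 1

        if task == "classify" and cfg.stop_when_perfect and hist.best_val >= 1.0:
            hist.stopped_early = True
            break
        if since_best >= cfg.patience:
            hist.stopped_early = True
            break

    model.set_params(best_params)
    return model, hist


def predict(model: Sequential, X, batch_size: int = 1) -> np.ndarray:
    """Per-sample class probabilities (classification) or scalars (regression).

    Evaluation uses ``batch_size`` 1 by default, matching the test-time
    protocol; the result is batch-size-invariant since inference is
    deterministic.
    """
    X = _as_batch_array(np.asarray(X, dtype=np.float32))
    outs = []
    for i in range(0, len(X), batch_size):
        out = model.forward(X[i:i + batch_size])
        outs.append(out)
    out = np.concatenate(outs, axis=0)
    if getattr(model, "task", "classify") == "classify":
        return np.exp(out)  # log-probabilities -> probabilities
    return out.reshape(-1)
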