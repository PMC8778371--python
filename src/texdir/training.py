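"""Training protocol for the orientation-classification networks.

Categorical cross-entropy over 180 one-hot direction classes, Adam,
batches of 32, with per-epoch training/validation loss curves and
best-validation-loss weight retention. Replicates restart from
independent Glorot draws.

Input tiles enter the network as float32 intensities divided by 65,535,
identically at training and inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Model, Adam
from .synthesis import DatasetSplits, TileSet

N_CLASSES = 180
EPS = 1e-12  # clamp for log of the predicted true-class probability
INTENSITY_SCALE = 65535.0


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range for one-hot encoding")
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def cross_entropy_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, natural log.

    ``predictions``: (N, C) class probabilities. ``labels``: (N, C) one-hot
    rows or (N,) integer class indices. Probabilities are clamped at 1e-12
    before the log, so an exactly-zero true-class probability stays finite.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if labels.ndim == 1:
        idx = labels.astype(np.int64)
    else:
        if labels.shape != predictions.shape:
            raise ValueError("prediction and label batches differ in shape")
        idx = labels.argmax(axis=1)
    if len(idx) != len(predictions):
        raise ValueError("prediction and label batches differ in length")
    p_true = predictions[np.arange(len(idx)), idx]
    return float(-np.mean(np.log(np.maximum(p_true, EPS))))


def prepare_inputs(pixels: np.ndarray) -> np.ndarray:
    """16-bit tiles -> network input: float32 / 65535, channels-last."""
    x = pixels.astype(np.float32) / INTENSITY_SCALE
    if x.ndim == 3:
        x = x[..., None]
    return x


@dataclass
class TrainingRun:
    """One training replicate: loss curves plus the retained best weights."""

    architecture_id: str
    activation: str
    replicate_seed: int
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    best_weights: list[np.ndarray] | None = None

    @property
    def epochs_completed(self) -> int:
        return len(self.train_loss)


def _epoch_losses(model: Model, x: np.ndarray, labels: np.ndarray,
                  batch_size: int = 256) -> float:
    probs = model.predict_proba(x, batch_size=batch_size)
    return cross_entropy_loss(probs, labels)


def train(
    model: Model,
    splits: DatasetSplits,
    batch_size: int = 32,
    epochs: int = 200,
    replicates: int = 3,
    seed: int = 0,
    learning_rate: float = 1e-3,
    architecture_id: str = "",
    activation: str = "",
    verbose: bool = False,
) -> list[TrainingRun]:
    """Train ``model`` on the splits; returns one TrainingRun per replicate.

    Each replicate reinitializes the model from its own seed (derived from
    ``seed``), shuffles the training set every epoch, and keeps the weights
    with the lowest validation loss. After the call the model carries the
    best weights of the last replicate.
    """
    if len(splits.train) == 0 or len(splits.validation) == 0:
        raise ValueError("training requires non-empty train and validation splits")
    for ts in (splits.train, splits.validation):
        if ts.pixels is None:
            raise ValueError("splits must be materialized (pixels present) for training")

    x_train = prepare_inputs(splits.train.pixels)
    y_train = splits.train.labels.astype(np.int64)
    x_val = prepare_inputs(splits.validation.pixels)
    y_val = splits.validation.labels.astype(np.int64)
    t_train = one_hot(y_train)

    runs: list[TrainingRun] = []
    master = np.random.SeedSequence(seed)
    for rep, child in enumerate(master.spawn(replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        model.reinitialize(rep_seed)
        rng = np.random.default_rng(rep_seed)
        optimizer = Adam(model.params, lr=learning_rate)
        run = TrainingRun(architecture_id, activation, rep_seed)

        for epoch in range(epochs):
            order = rng.permutation(len(x_train))
            epoch_loss = 0.0
            for start in range(0, len(order), batch_size):
                sel = order[start:start + batch_size]
                xb, tb = x_train[sel], t_train[sel]
                probs = model.forward(xb, training=True, rng=rng)
                idx = tb.argmax(axis=1)
                p_true = probs[np.arange(len(idx)), idx]
                epoch_loss += float(-np.log(np.maximum(p_true, EPS)).sum())
                model.backward((probs - tb) / len(xb))
                optimizer.step(model.grads)
            run.train_loss.append(epoch_loss / len(order))
            run.val_loss.append(_epoch_losses(model, x_val, y_val))
            if run.val_loss[-1] < run.best_val_loss:
                run.best_val_loss = run.val_loss[-1]
                run.best_epoch = epoch
                run.best_weights = model.get_weights()
            if verbose:
                print(f"replicate {rep} epoch {epoch + 1}/{epochs}: "
                      f"train {run.train_loss[-1]:.4f} val {run.val_loss[-1]:.4f}")
        if run.best_weights is not None:
            model.set_weights(run.best_weights)
        runs.append(run)
    return runs


def predict_labels(model: Model, tiles: TileSet | np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    """Argmax direction class for each 16-bit tile."""
    pixels = tiles.pixels if isinstance(tiles, TileSet) else tiles
    probs = model.predict_proba(prepare_inputs(pixels), batch_size=batch_size)
    return probs.argmax(axis=1)
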