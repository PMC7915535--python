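"""Per-subject supervised training.

Model selection follows a repeated stratified 5-fold cross-validation: the
epochs are split into 5 folds (stratified by the merged articulation class,
so every fold keeps the 2:2:2:1 class ratio), 4 folds train and 1
validates, and the whole procedure is repeated 3 times with fresh weight
initialisations to average out initialisation luck.  Optimisation uses Adam
with label-smoothed categorical cross-entropy; training stops early once
the validation loss has failed to decrease for ``patience`` consecutive
epochs, restoring the best-validation weights.

Supervision is per chunk: each of the four 0.25 s decisions inside a 1 s
training epoch receives that epoch's class label, with the LSTM state reset
at the epoch boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epoching import LABELS4, EpochSet, chunk_epoch
from .model import EncoderConfig, ModelConfig, MovementIntentNet
from .nn import log_softmax, softmax

__all__ = [
    "Adam",
    "CVResult",
    "TrainConfig",
    "DEFAULT_GRID",
    "epochs_to_arrays",
    "fit",
    "grid_search",
    "run_cv",
    "smoothed_crossentropy",
    "stratified_folds",
]

# Searched axes and values of the hyperparameter grid; the remaining
# TrainConfig fields were fixed by design (see TrainConfig defaults).
DEFAULT_GRID: dict[str, tuple] = {
    "z_dim": (512, 256, 128),
    "lstm_hidden": (32, 64, 128),
    "lr": (1e-3, 1e-4, 1e-5),
    "smoothing": (0.0, 0.2, 0.4),
}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (defaults = deployed configuration)."""

    batch_size: int = 1024
    z_dim: int = 128
    lstm_hidden: int = 64
    conv1_channels: int = 16
    conv2_channels: int = 32
    conv1_kernel: tuple[int, int, int] = (5, 2, 2)
    conv2_kernel: tuple[int, int, int] = (5, 1, 1)
    lstm_depth: int = 1
    conv_depth: int = 2
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    lstm_dropout: float = 0.0
    smoothing: float = 0.2
    l2_penalty: float = 0.0
    max_epochs: int = 100
    patience: int = 10
    n_folds: int = 5
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.smoothing < 1:
            raise ValueError("smoothing must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.lstm_depth != 1 or self.conv_depth != 2:
            raise ValueError("architecture is fixed at 2 conv layers + 1 LSTM layer")
        if self.lstm_dropout != 0.0:
            raise ValueError("LSTM dropout is fixed at 0 in this architecture")

    def model_config(self, seed: int | None = None) -> ModelConfig:
        enc = EncoderConfig(
            conv1_channels=self.conv1_channels,
            conv2_channels=self.conv2_channels,
            conv1_kernel=self.conv1_kernel,
            conv2_kernel=self.conv2_kernel,
            z_dim=self.z_dim,
        )
        return ModelConfig(
            encoder=enc,
            lstm_hidden=self.lstm_hidden,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class CVResult:
    """Per-(repeat, fold) validation outcomes plus training curves."""

    table: pd.DataFrame  # repeat, fold, val_accuracy, val_loss, stopped_epoch
    curves: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.table["val_accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.table["val_accuracy"].std(ddof=1))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "n_models": int(len(self.table)),
        }


def smoothed_crossentropy(probs: np.ndarray, label: int, smoothing: float = 0.2,
                          n_classes: int | None = None, floor: float = 1e-12) -> float:
    """Label-smoothed categorical cross-entropy for one probability vector.

    The target is ``(1 - smoothing) * onehot(label) + smoothing / K``; with
    ``smoothing=0`` this is the standard cross-entropy.  ``floor`` guards
    the logarithm against zero probabilities.
    """
    probs = np.asarray(probs, dtype=np.float64)
    k = n_classes or probs.shape[-1]
    if not 0 <= smoothing < 1:
        raise ValueError("smoothing must be in [0, 1)")
    q = np.full(k, smoothing / k)
    q[label] += 1.0 - smoothing
    return float(-(q * np.log(np.maximum(probs, floor))).sum())


def _smooth_targets(labels: np.ndarray, k: int, smoothing: float) -> np.ndarray:
    q = np.full((len(labels), k), smoothing / k)
    q[np.arange(len(labels)), labels] += 1.0 - smoothing
    return q


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray, smoothing: float):
    """Mean smoothed CE over all (epoch, chunk) decisions; gradient wrt logits."""
    n, t, k = logits.shape
    logp = log_softmax(logits, axis=-1)
    q = _smooth_targets(labels, k, smoothing)[:, None, :]  # same target every chunk
    loss = float(-(q * logp).sum() / (n * t))
    dlogits = (softmax(logits, axis=-1) - q) / (n * t)
    return loss, dlogits


class EarlyStopper:
    """Stop when the monitored loss fails to decrease ``patience`` times in a row."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.since_best = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's validation loss; True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience

    @property
    def improved(self) -> bool:
        return self.since_best == 0


class Adam:
    """Adam optimiser over a list of :class:`~emid.nn.Param`."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def epochs_to_arrays(epochs: EpochSet, chunk_len: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """EpochSet -> (X: (n, n_chunks, chunk_len, rows, cols), y: class indices)."""
    x = np.stack([chunk_epoch(f, chunk_len) for f in epochs.frames]).astype(np.float64)
    y = np.array([LABELS4.index(lab) for lab in epochs.labels4], dtype=np.intp)
    return x, y


def _eval_model(model: MovementIntentNet, x: np.ndarray, y: np.ndarray,
                smoothing: float, block: int = 256) -> tuple[float, float]:
    """(validation loss, chunk-level accuracy) in eval mode."""
    losses, correct, total = 0.0, 0, 0
    for i in range(0, len(x), block):
        xb, yb = x[i : i + block], y[i : i + block]
        logits = model.forward_epochs(xb, train=False)
        n, t, k = logits.shape
        logp = log_softmax(logits, axis=-1)
        q = _smooth_targets(yb, k, smoothing)[:, None, :]
        losses += float(-(q * logp).sum())
        correct += int((logits.argmax(-1) == yb[:, None]).sum())
        total += n * t
    return losses / total, correct / total


def fit(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    init_seed: int | None = None,
) -> tuple[MovementIntentNet, dict]:
    """Train one model with early stopping on the validation loss.

    Returns the model (restored to its best-validation weights) and a
    record with per-epoch losses, the stopping epoch and the validation
    accuracy at the restored optimum.
    """
    model = MovementIntentNet(cfg.model_config(seed=init_seed))
    opt = Adam(model.parameters(), cfg.lr, cfg.beta1, cfg.beta2, weight_decay=cfg.l2_penalty)
    rng = np.random.default_rng(None if init_seed is None else init_seed + 1)
    batch = min(cfg.batch_size, len(x_train))
    stopper = EarlyStopper(cfg.patience)
    best_state, best_acc, best_epoch = None, 0.0, 0
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        train_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            if len(idx) < 2:  # train-mode batch norm needs real batch statistics
                continue
            model.zero_grad()
            logits = model.forward_epochs(x_train[idx], train=True)
            loss, dlogits = _loss_and_grad(logits, y_train[idx], cfg.smoothing)
            model.backward(dlogits)
            opt.step()
            train_loss += loss
            n_batches += 1
        val_loss, val_acc = _eval_model(model, x_val, y_val, cfg.smoothing)
        history.append(
            {"epoch": epoch, "train_loss": train_loss / max(n_batches, 1),
             "val_loss": val_loss, "val_accuracy": val_acc}
        )
        stop = stopper.update(val_loss)
        if stopper.improved:
            best_acc, best_epoch = val_acc, epoch
            best_state = [p.value.copy() for p in model.parameters()]
        if stop:
            break
    if best_state is not None:
        for p, v in zip(model.parameters(), best_state):
            p.value[...] = v
    record = {
        "history": history,
        "stopped_epoch": history[-1]["epoch"],
        "best_epoch": best_epoch,
        "val_loss": stopper.best,
        "val_accuracy": best_acc,
    }
    return model, record


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per sample; each class spread evenly over folds."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=np.intp)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} epochs, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def run_cv(x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> CVResult:
    """Repeated stratified k-fold cross-validation (fresh init per repeat)."""
    rows, curves = [], []
    for repeat in range(cfg.n_repeats):
        split_seed = cfg.seed + 1000 * repeat
        folds = stratified_folds(y, cfg.n_folds, seed=split_seed)
        for fold in range(cfg.n_folds):
            val = folds == fold
            init_seed = cfg.seed + 1000 * repeat + fold
            _, rec = fit(x[~val], y[~val], x[val], y[val], cfg, init_seed=init_seed)
            rows.append(
                {"repeat": repeat, "fold": fold, "val_accuracy": rec["val_accuracy"],
                 "val_loss": rec["val_loss"], "stopped_epoch": rec["stopped_epoch"]}
            )
            curves.append({"repeat": repeat, "fold": fold, "history": rec["history"]})
    return CVResult(table=pd.DataFrame(rows), curves=curves)


def expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of the grid axes, in deterministic order."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    x: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    base: TrainConfig = TrainConfig(),
) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive grid search; winner = best mean validation accuracy.

    Ties on the mean accuracy go to the configuration with the fewest model
    parameters (then to grid order), making selection deterministic.
    """
    combos = expand_grid(DEFAULT_GRID if grid is None else grid)
    rows = []
    for i, combo in enumerate(combos):
        cfg = replace(base, **combo)
        result = run_cv(x, y, cfg)
        n_params = MovementIntentNet(cfg.model_config()).n_parameters()
        rows.append(
            {**combo, "mean_accuracy": result.mean_accuracy,
             "sd_accuracy": result.sd_accuracy, "n_parameters": n_params, "order": i}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_accuracy", "n_parameters", "order"], ascending=[False, True, True]
    ).iloc[0]
    best_cfg = replace(base, **{k: best[k] for k in combos[0]})
    return best_cfg, table.drop(columns="order")
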