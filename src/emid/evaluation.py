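"""Decoder evaluation.

Two complementary views of performance:

* **Epoch-averaged accuracy** — the classifier emits one decision per
  0.25 s chunk; over a 1 s pre-onset epoch that is four decisions, each
  scored against the epoch's class, then averaged over chunks and trials.
  Chance level for four balanced classes is 25%.
* **Time-wise accuracy** — trials are synchronized at the detected
  movement onset (t = 0) and the model consumes each trial as a continuous
  chunk stream across a window around onset (default -3 s to +3 s), the
  LSTM state carried from the window start.  Accuracy per chunk offset
  shows when, relative to onset, the decoder's belief becomes reliable.
  Offsets label each chunk by its *end* time, so offset 0 is the last
  chunk entirely before movement.  The state-reset point is configurable:
  resetting at -1 s instead makes the window's last four decisions exactly
  reproduce the epoch-averaged protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epoching import LABELS4, chunk_epoch
from .io import Recording
from .model import MovementIntentNet
from .montage import Montage

__all__ = [
    "TimewiseCurve",
    "aligned_streams",
    "epoch_accuracy",
    "paired_accuracy_test",
    "timewise_accuracy",
]

CHUNK_S = 0.25


def epoch_accuracy(model: MovementIntentNet, x: np.ndarray, y: np.ndarray,
                   block: int = 256) -> float:
    """Chunk-level accuracy over a batch of epochs (state reset per epoch).

    x : (n, n_chunks, chunk_len, rows, cols); y : class indices.
    """
    correct, total = 0, 0
    for i in range(0, len(x), block):
        logits = model.forward_epochs(x[i : i + block], train=False)
        correct += int((logits.argmax(-1) == y[i : i + block, None]).sum())
        total += logits.shape[0] * logits.shape[1]
    return correct / total


@dataclass
class TimewiseCurve:
    """Accuracy per chunk offset around movement onset."""

    offsets_s: np.ndarray  # chunk end time relative to onset
    accuracy: np.ndarray
    per_class: pd.DataFrame  # one column per class label
    n_trials: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"offset_s": self.offsets_s, "accuracy": self.accuracy,
                            "n_trials": self.n_trials})
        return pd.concat([out, self.per_class.reset_index(drop=True)], axis=1)

    def mean_accuracy(self, start_s: float, stop_s: float) -> float:
        """Mean accuracy over offsets in the half-open interval (start, stop]."""
        sel = (self.offsets_s > start_s + 1e-9) & (self.offsets_s <= stop_s + 1e-9)
        return float(self.accuracy[sel].mean())


def aligned_streams(
    recording128: Recording,
    montage: Montage,
    onsets: np.ndarray,
    labels4: list[str],
    window_s: tuple[float, float] = (-3.0, 3.0),
    chunk_len: int = 32,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut onset-aligned chunk streams from a continuous recording.

    Returns (streams (n, n_chunks, chunk_len, rows, cols), y, kept_index).
    Trials whose window would run off the record are skipped with a warning.
    """
    fs = recording128.fs
    lo = int(round(window_s[0] * fs))
    hi = int(round(window_s[1] * fs))
    if (hi - lo) % chunk_len:
        raise ValueError("window length must be a whole number of chunks")
    streams, ys, kept = [], [], []
    for i, (onset, lab) in enumerate(zip(onsets, labels4)):
        a, b = int(onset) + lo, int(onset) + hi
        if a < 0 or b > recording128.n_samples:
            warnings.warn(f"trial {i} shorter than the analysis window; skipped")
            continue
        frames = montage.frames(recording128.signal[:, a:b], recording128.labels)
        streams.append(chunk_epoch(frames, chunk_len))
        ys.append(LABELS4.index(lab))
        kept.append(i)
    if not streams:
        raise ValueError("no trial covers the analysis window")
    return np.stack(streams), np.array(ys, dtype=np.intp), np.array(kept, dtype=np.intp)


def timewise_accuracy(
    model: MovementIntentNet,
    streams: np.ndarray,
    y: np.ndarray,
    window_s: tuple[float, float] = (-3.0, 3.0),
    reset_offset_s: float | None = None,
) -> TimewiseCurve:
    """Accuracy per chunk offset across onset-aligned trials.

    The LSTM state starts fresh at the window start; if ``reset_offset_s``
    is given, the state is re-initialised at the chunk boundary closest to
    that offset (e.g. -1.0 to mimic epoch-wise evaluation).
    """
    n, t = streams.shape[:2]
    offsets = window_s[0] + CHUNK_S * (np.arange(t) + 1)
    reset_chunk = None
    if reset_offset_s is not None:
        reset_chunk = int(round((reset_offset_s - window_s[0]) / CHUNK_S))
    codes = model.encoder.forward(
        streams.reshape(n * t, *streams.shape[2:]), train=False
    ).reshape(n, t, -1)
    state = model.init_state(n)
    preds = np.empty((n, t), dtype=np.intp)
    for step in range(t):
        if reset_chunk is not None and step == reset_chunk:
            state = model.init_state(n)
        probs, state = model.classify_step(codes[:, step, :], state)
        preds[:, step] = np.atleast_2d(probs).argmax(-1)
    correct = preds == y[:, None]
    per_class = {}
    for k, lab in enumerate(LABELS4):
        sel = y == k
        per_class[lab] = correct[sel].mean(axis=0) if sel.any() else np.full(t, np.nan)
    return TimewiseCurve(
        offsets_s=offsets,
        accuracy=correct.mean(axis=0),
        per_class=pd.DataFrame(per_class),
        n_trials=np.full(t, n),
    )


def paired_accuracy_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired t-test between two per-subject accuracy vectors.

    Also reports a Shapiro-Wilk normality check of the paired differences,
    mirroring the usual sanity check before a paired t-test.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    t = stats.ttest_rel(a, b)
    sw = stats.shapiro(a - b)
    return {
        "t": float(t.statistic),
        "df": int(len(a) - 1),
        "p": float(t.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "normality_p": float(sw.pvalue),
    }
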