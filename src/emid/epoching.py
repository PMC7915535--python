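"""Movement-onset detection and pre-onset epoch extraction.

Training examples are the 1 s of EEG immediately *preceding* each detected
movement onset, so epochs contain motor-preparation activity only and no
movement-period data.  Onset is read from the synchronized kinematic trace,
never from the EEG itself.

Onset detection is threshold-based with a model-fit refinement.  Stage one
(detection): the motion trace is low-pass filtered (causal, 2 Hz), its
absolute first difference forms a speed envelope, baseline statistics
(mu0, sigma0) are taken from the second before the cue, and the trial is
accepted once the envelope stays above ``mu0 + threshold_sigmas * sigma0``
for ``min_duration_s``; the crossing is back-tracked to the last
sub-threshold sample.  Stage two (localisation): around the crossing, a
flat-baseline-plus-smoothstep movement model is least-squares fitted to the
*raw* trace over a grid of candidate onsets and rise times, and the
best-fitting changepoint becomes the onset.  The refinement removes the
smoothing filter's group delay bias from the estimate; on a noise-free
trace stage one is already exact and stage two is skipped.  Trials with no
sustained crossing raise :class:`NoOnsetError` and are dropped by the
pipeline (an automated stand-in for manual trial review); "rest" trials
have no kinematic event, so their nominal onset is placed at a fixed
latency after the cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording
from .montage import Montage

__all__ = [
    "LABELS4",
    "LABELS7",
    "Epoch",
    "EpochSet",
    "NoOnsetError",
    "OnsetParams",
    "chunk_epoch",
    "detect_onset",
    "epoch_subject",
    "extract_epoch",
    "merge_class",
]

LABELS7 = [
    "elbow_flexion",
    "elbow_extension",
    "wrist_pronation",
    "wrist_supination",
    "hand_open",
    "hand_close",
    "rest",
]
LABELS4 = ["elbow", "wrist", "hand", "rest"]

_MERGE = {
    "elbow_flexion": "elbow",
    "elbow_extension": "elbow",
    "wrist_pronation": "wrist",
    "wrist_supination": "wrist",
    "hand_open": "hand",
    "hand_close": "hand",
    "rest": "rest",
}

CHUNK_LEN = 32  # samples per classifier decision at 128 Hz (0.25 s)


class NoOnsetError(RuntimeError):
    """No sustained threshold crossing in the search window."""


@dataclass(frozen=True)
class OnsetParams:
    """Tunables of the kinematic onset detector.

    threshold_sigmas : multiples of the baseline SD above the baseline mean
    min_duration_s : how long the crossing must be sustained (debounce)
    lowpass_hz : cutoff of the causal smoother behind the speed envelope
    baseline_s : length of the pre-cue segment used for mu0/sigma0
    search_s : post-cue window searched for movement
    rest_latency_s : nominal onset after the cue for "rest" trials
    refine : fit the changepoint model around the threshold crossing
    rise_min_s / rise_max_s : rise-time grid bounds of the movement model
    """

    threshold_sigmas: float = 5.0
    min_duration_s: float = 0.1
    lowpass_hz: float = 2.0
    baseline_s: float = 1.0
    search_s: float = 4.0
    rest_latency_s: float = 1.5
    refine: bool = True
    rise_min_s: float = 0.1
    rise_max_s: float = 0.8


def _envelope(motion: np.ndarray, fs: float, lowpass_hz: float) -> np.ndarray:
    """Causal motion-speed envelope: low-pass filter, then |first difference|.

    Smoothing *before* rectification lets the zero-mean sensor noise cancel,
    so the envelope's pre-movement baseline is near zero and slow movement
    ramps stand out; rectifying first would leave a large noise-floor mean
    that can swamp them.
    """
    sos = sps.butter(2, lowpass_hz, btype="lowpass", output="sos", fs=fs)
    smooth = sps.sosfilt(sos, np.asarray(motion, dtype=np.float64))
    return np.abs(np.diff(smooth, prepend=smooth[0])) * fs


def _fit_changepoint(
    seg: np.ndarray, lo_tau: int, hi_tau: int, rise_grid: np.ndarray, step: int
) -> int | None:
    """Least-squares changepoint of a flat-baseline + smoothstep-rise model.

    For each candidate onset tau (stride ``step``) and rise time T, the
    model b + a * s((t - tau) / T) — s the cubic smoothstep, clipped to
    [0, 1] — is fitted in closed form; returns the tau of the best fit.
    """
    n = len(seg)
    t = np.arange(n, dtype=np.float64)
    seg_mean = seg.mean()
    centered = seg - seg_mean
    best_sse, best_tau = np.inf, None
    for tau in range(lo_tau, hi_tau, step):
        for rise in rise_grid:
            u = np.clip((t - tau) / rise, 0.0, 1.0)
            s = u * u * (3.0 - 2.0 * u)
            sm = s - s.mean()
            denom = float(sm @ sm)
            if denom < 1e-12:
                continue
            a = float(sm @ centered) / denom
            resid = centered - a * sm
            sse = float(resid @ resid)
            if sse < best_sse:
                best_sse, best_tau = sse, tau
    return best_tau


def detect_onset(
    motion: np.ndarray,
    fs: float,
    cue_sample: int,
    params: OnsetParams = OnsetParams(),
) -> int:
    """First sample of sustained post-cue motion (index into ``motion``)."""
    motion = np.asarray(motion, dtype=np.float64)
    n_base = int(round(params.baseline_s * fs))
    if cue_sample < n_base:
        raise ValueError("insufficient pre-cue baseline for onset detection")
    env = _envelope(motion, fs, params.lowpass_hz)
    base = env[cue_sample - n_base : cue_sample]
    mu0, sd0 = base.mean(), base.std()
    thresh = mu0 + params.threshold_sigmas * sd0
    stop = min(len(env), cue_sample + int(round(params.search_s * fs)))
    above = env[cue_sample:stop] > thresh
    need = max(1, int(round(params.min_duration_s * fs)))
    # first run of >= need consecutive supra-threshold samples
    run = 0
    hit = -1
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            hit = i - need + 1
            break
    if hit < 0:
        raise NoOnsetError("no sustained motion in the search window")
    hit += cue_sample
    onset = hit
    while onset > 0 and env[onset - 1] > thresh:  # back-track to last quiet sample
        onset -= 1
    if not params.refine or sd0 <= 1e-12 * max(1.0, mu0):
        return int(onset)  # noise-free envelope: the crossing is already exact
    # changepoint refinement on the raw trace around the crossing
    w0 = max(cue_sample - n_base, onset - int(round(0.8 * fs)))
    w1 = min(len(motion), hit + int(round(1.2 * fs)))
    seg = motion[w0:w1]
    lo_tau = max(1, cue_sample - int(round(0.1 * fs)) - w0)
    hi_tau = min(len(seg) - int(round(0.2 * fs)), hit + int(round(0.2 * fs)) - w0)
    if hi_tau <= lo_tau:
        return int(onset)
    rise_grid = np.arange(params.rise_min_s, params.rise_max_s + 1e-9, 0.05) * fs
    coarse_step = max(1, int(round(fs / 170.0)))
    tau = _fit_changepoint(seg, lo_tau, hi_tau, rise_grid, coarse_step)
    if tau is None:
        return int(onset)
    if coarse_step > 1:  # fine pass around the coarse optimum
        fine = _fit_changepoint(
            seg,
            max(lo_tau, tau - coarse_step),
            min(hi_tau, tau + coarse_step + 1),
            rise_grid,
            1,
        )
        tau = fine if fine is not None else tau
    return int(w0 + tau)


def merge_class(label7: str) -> str:
    """Collapse the 7 protocol classes onto the 4 articulation classes."""
    try:
        return _MERGE[label7]
    except KeyError:
        raise ValueError(f"unknown movement class {label7!r}") from None


@dataclass
class Epoch:
    """One labeled 1 s pre-onset window as a sequence of grid frames.

    ``frames`` has shape (fs * 1 s, grid_rows, grid_cols) and covers the
    half-open window [onset - fs, onset): the onset sample itself, and
    everything after it, is excluded.
    """

    frames: np.ndarray
    label7: str
    label4: str = ""
    subject_id: str = ""
    run: int = -1
    trial: int = -1
    onset_sample: int = -1

    def __post_init__(self) -> None:
        if not self.label4:
            self.label4 = merge_class(self.label7)


def extract_epoch(
    recording128: Recording,
    montage: Montage,
    onset: int,
    duration_s: float = 1.0,
    **meta,
) -> Epoch:
    """Tensorize the ``duration_s`` of signal ending at ``onset`` (exclusive)."""
    n = int(round(duration_s * recording128.fs))
    if onset < n:
        raise ValueError(f"insufficient pre-onset history: onset {onset} < {n} samples")
    if onset > recording128.n_samples:
        raise ValueError("onset beyond record length")
    window = recording128.signal[:, onset - n : onset]
    frames = montage.frames(window, recording128.labels)
    return Epoch(frames=frames, onset_sample=int(onset), **meta)


def chunk_epoch(frames: np.ndarray, chunk_len: int = CHUNK_LEN) -> np.ndarray:
    """Split (T, H, W) frames into consecutive (T/chunk_len, chunk_len, H, W)."""
    frames = np.asarray(frames)
    t = frames.shape[0]
    if t % chunk_len:
        raise ValueError(f"frame count {t} not divisible by chunk length {chunk_len}")
    return frames.reshape(t // chunk_len, chunk_len, *frames.shape[1:])


@dataclass
class EpochSet:
    """Stacked epochs of one subject plus their manifest."""

    frames: np.ndarray  # (n_epochs, T, H, W)
    manifest: pd.DataFrame  # subject, run, trial, label7, label4, onset_sample

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def labels4(self) -> np.ndarray:
        return self.manifest["label4"].to_numpy()

    def class_counts(self, merged: bool = True) -> dict[str, int]:
        col = "label4" if merged else "label7"
        return self.manifest[col].value_counts().to_dict()

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames.astype(np.float32), compression="gzip")
            for col in self.manifest.columns:
                vals = self.manifest[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                f.create_dataset(f"manifest/{col}", data=vals)

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            cols = {}
            for col in f["manifest"]:
                vals = f[f"manifest/{col}"][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
        return cls(frames=frames, manifest=pd.DataFrame(cols))


def epoch_subject(
    recording128: Recording,
    montage: Montage,
    params: OnsetParams = OnsetParams(),
    subject_id: str = "synthetic",
) -> tuple[EpochSet, pd.DataFrame]:
    """Run onset detection + epoch extraction over every marked trial.

    Returns the epoch set and a QC table; QC flags trials whose detected
    onset precedes the cue or falls beyond ``cue + search_s``, and records
    dropped trials (no onset, or too little pre-onset history).
    """
    fs = recording128.fs
    rows, frames, qc = [], [], []
    for marker in recording128.markers.itertuples():
        cue = int(marker.cue_sample)
        label7 = str(marker.label7)
        status = "ok"
        try:
            if label7 == "rest":
                onset = cue + int(round(params.rest_latency_s * fs))
            else:
                onset = detect_onset(recording128.motion, fs, cue, params)
            ep = extract_epoch(
                recording128,
                montage,
                onset,
                label7=label7,
                subject_id=subject_id,
                run=int(marker.run),
                trial=int(marker.trial),
            )
        except (NoOnsetError, ValueError) as exc:
            qc.append({"trial": marker.trial, "status": f"dropped: {exc}"})
            continue
        if onset < cue or onset > cue + params.search_s * fs:
            status = "suspicious onset"
        qc.append({"trial": marker.trial, "status": status})
        frames.append(ep.frames.astype(np.float32))
        rows.append(
            {
                "subject": subject_id,
                "run": ep.run,
                "trial": ep.trial,
                "label7": ep.label7,
                "label4": ep.label4,
                "onset_sample": ep.onset_sample,
            }
        )
    if not frames:
        raise NoOnsetError("no epochs could be extracted from this recording")
    return (
        EpochSet(frames=np.stack(frames), manifest=pd.DataFrame(rows)),
        pd.DataFrame(qc),
    )
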