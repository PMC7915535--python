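"""Recording container and file round-trips.

Continuous recordings travel either as EDF (read through :mod:`mne` when it
is installed) or as delimited text matrices with a channel-name header row,
one column per channel.  Trial markers live in a sidecar CSV with columns
``trial, run, label7, cue_sample`` (plus optional ``true_onset`` for
simulated data, which carries the ground-truth movement-start sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording", "read_recording", "write_recording", "read_markers", "write_markers"]

MOTION_COLUMN = "MOTION"

MARKER_COLUMNS = ["trial", "run", "label7", "cue_sample"]


@dataclass
class Recording:
    """Continuous multichannel EEG with an optional synchronized motion trace.

    signal : (n_channels, n_samples) array, microvolts
    fs : sampling rate in Hz
    labels : channel names, one per signal row
    motion : optional kinematic trace on the same time base (arbitrary units)
    markers : per-trial table (trial, run, label7, cue_sample[, true_onset]);
        sample indices refer to this recording's time base
    """

    signal: np.ndarray
    fs: float
    labels: list[str]
    motion: np.ndarray | None = None
    markers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MARKER_COLUMNS))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2D (channels x samples)")
        if self.signal.shape[0] != len(self.labels):
            raise ValueError("one label per signal row required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion)
            if self.motion.shape[-1] != self.n_samples:
                raise ValueError("motion and signal must share one time base")
        if len(self.markers) and (self.markers["cue_sample"] >= self.n_samples).any():
            raise ValueError("marker sample beyond record length")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray, fs: float | None = None) -> "Recording":
        return replace(self, signal=signal, fs=self.fs if fs is None else fs)


def write_recording(rec: Recording, path: str | Path, fmt: str = "%.6g") -> None:
    """Write signal (+ motion as a ``MOTION`` column) as tab-delimited text."""
    path = Path(path)
    columns = list(rec.labels)
    data = rec.signal
    if rec.motion is not None:
        columns.append(MOTION_COLUMN)
        data = np.vstack([rec.signal, rec.motion[None, :]])
    header = "\t".join(columns)
    np.savetxt(path, data.T, fmt=fmt, delimiter="\t", header=header, comments="")


def _read_text(path: Path, fs: float) -> Recording:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=np.float64).T
    if data.ndim == 1:
        data = data[None, :]
    motion = None
    if MOTION_COLUMN in header:
        idx = header.index(MOTION_COLUMN)
        motion = data[idx]
        keep = [i for i in range(len(header)) if i != idx]
        data = data[keep]
        header = [header[i] for i in keep]
    return Recording(signal=data, fs=fs, labels=header, motion=motion)


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne returns volts
    motion = None
    if MOTION_COLUMN in labels:
        idx = labels.index(MOTION_COLUMN)
        motion = data[idx]
        data = np.delete(data, idx, axis=0)
        labels = [lab for i, lab in enumerate(labels) if i != idx]
    return Recording(signal=data, fs=float(raw.info["sfreq"]), labels=labels, motion=motion)


def read_recording(
    path: str | Path,
    fs: float | None = None,
    markers_path: str | Path | None = None,
) -> Recording:
    """Read an EDF or delimited-text recording; attach markers if given.

    ``fs`` is required for text input (text matrices carry no rate); EDF
    headers provide their own rate and ``fs`` is ignored.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        if fs is None:
            raise ValueError("fs is required for delimited-text recordings")
        rec = _read_text(path, fs)
    if markers_path is not None:
        rec.markers = read_markers(markers_path)
        if len(rec.markers) and (rec.markers["cue_sample"] >= rec.n_samples).any():
            raise ValueError("marker sample beyond record length")
    return rec


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    return df


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, index=False)
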