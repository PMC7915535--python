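"""Real-time-capable signal conditioning.

The conditioning chain deliberately stays minimal so it can run online on an
incoming sample stream: a 50 Hz mains notch, a 5th-order Butterworth
bandpass (0.5-60 Hz) and decimation from 512 Hz to 128 Hz.  The 60 Hz upper
edge keeps the signal band-limited below the 64 Hz post-decimation Nyquist,
so no separate anti-alias stage is needed.

Filters default to causal (forward-only) IIR application, matching online
use; ``filter_mode="zero_phase"`` switches to forward-backward filtering for
offline analyses where phase distortion matters more than causality.
:class:`StreamingPreprocessor` carries filter state and decimation phase
across blocks so that blockwise and whole-record causal processing agree
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "PreprocessConfig",
    "StreamingPreprocessor",
    "bandpass_filter",
    "downsample",
    "notch_filter",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    notch_freq: float = 50.0
    notch_q: float = 30.0
    bp_low: float = 0.5
    bp_high: float = 60.0
    bp_order: int = 5
    downsample_factor: int = 4
    filter_mode: str = "causal"  # or "zero_phase"

    def __post_init__(self) -> None:
        if self.filter_mode not in ("causal", "zero_phase"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")


def _design_notch(fs: float, f0: float, q: float) -> tuple[np.ndarray, np.ndarray]:
    if not 0 < f0 < fs / 2:
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist={fs / 2} Hz)")
    return sps.iirnotch(f0, q, fs=fs)


def _design_bandpass(fs: float, low: float, high: float, order: int) -> np.ndarray:
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={fs} Hz")
    return sps.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)


def _apply_ba(rec: Recording, b: np.ndarray, a: np.ndarray, mode: str) -> Recording:
    out = np.empty_like(rec.signal, dtype=np.float64)
    for ch in range(rec.n_channels):  # channel loop keeps peak memory flat
        x = rec.signal[ch].astype(np.float64, copy=False)
        out[ch] = sps.filtfilt(b, a, x) if mode == "zero_phase" else sps.lfilter(b, a, x)
    return rec.with_signal(out.astype(rec.signal.dtype, copy=False))


def _apply_sos(rec: Recording, sos: np.ndarray, mode: str) -> Recording:
    out = np.empty_like(rec.signal, dtype=np.float64)
    for ch in range(rec.n_channels):
        x = rec.signal[ch].astype(np.float64, copy=False)
        out[ch] = sps.sosfiltfilt(sos, x) if mode == "zero_phase" else sps.sosfilt(sos, x)
    return rec.with_signal(out.astype(rec.signal.dtype, copy=False))


def notch_filter(
    rec: Recording, f0: float = 50.0, q: float = 30.0, mode: str = "causal"
) -> Recording:
    """Second-order IIR notch at ``f0`` (mains rejection)."""
    b, a = _design_notch(rec.fs, f0, q)
    return _apply_ba(rec, b, a, mode)


def bandpass_filter(
    rec: Recording,
    low: float = 0.5,
    high: float = 60.0,
    order: int = 5,
    mode: str = "causal",
) -> Recording:
    """Butterworth bandpass, applied as second-order sections."""
    sos = _design_bandpass(rec.fs, low, high, order)
    return _apply_sos(rec, sos, mode)


def downsample(rec: Recording, factor: int = 4) -> Recording:
    """Decimate by keeping every ``factor``-th sample.

    The caller is responsible for prior band-limiting below the new Nyquist
    (automatic when the 60 Hz bandpass precedes a 512->128 Hz decimation).
    Markers and the motion trace are re-indexed onto the new time base.
    """
    if factor != int(factor) or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    n_out = rec.n_samples // factor
    sl = slice(0, n_out * factor, factor)
    markers = rec.markers.copy()
    for col in ("cue_sample", "true_onset"):
        if col in markers.columns:
            markers[col] = markers[col] // factor
    return replace(
        rec,
        signal=rec.signal[:, sl],
        fs=rec.fs / factor,
        motion=None if rec.motion is None else rec.motion[..., sl],
        markers=markers,
    )


def preprocess(rec: Recording, config: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Full chain: notch -> bandpass -> decimate."""
    out = notch_filter(rec, config.notch_freq, config.notch_q, config.filter_mode)
    out = bandpass_filter(out, config.bp_low, config.bp_high, config.bp_order, config.filter_mode)
    return downsample(out, config.downsample_factor)


class StreamingPreprocessor:
    """Causal chain with per-block state, for sample-stream use.

    Feeding a recording block by block yields bit-identical output to
    processing it in one call, because IIR filter state and the decimation
    phase persist across blocks.
    """

    def __init__(self, fs: float, n_channels: int, config: PreprocessConfig = PreprocessConfig()):
        if config.filter_mode != "causal":
            raise ValueError("streaming mode is causal by construction")
        self.fs = fs
        self.config = config
        self._b, self._a = _design_notch(fs, config.notch_freq, config.notch_q)
        self._sos = _design_bandpass(fs, config.bp_low, config.bp_high, config.bp_order)
        self._zi_notch = np.zeros((n_channels, max(len(self._a), len(self._b)) - 1))
        self._zi_bp = np.zeros((self._sos.shape[0], n_channels, 2))
        self._phase = 0  # samples seen modulo the decimation factor

    def process(self, block: np.ndarray) -> np.ndarray:
        """Condition one (channels, samples) block; returns decimated samples."""
        block = np.asarray(block, dtype=np.float64)
        y, self._zi_notch = sps.lfilter(self._b, self._a, block, axis=1, zi=self._zi_notch)
        y, self._zi_bp = sps.sosfilt(self._sos, y, axis=1, zi=self._zi_bp)
        factor = self.config.downsample_factor
        offset = (-self._phase) % factor
        self._phase = (self._phase + block.shape[1]) % factor
        return y[:, offset::factor]
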