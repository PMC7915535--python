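"""Protocol-faithful synthetic EEG + kinematics.

Emulates the structure of a cued upper-limb motor-execution session: 10
runs of 42 trials balanced over 7 classes (elbow flexion/extension, wrist
pronation/supination, hand open/close, rest).  Each trial plays out as
beep at 0 s, cue at 2 s, a subject-chosen waiting time, ~3 s of movement,
then 2-3 s of rest before the next trial, sampled at 512 Hz over 61 grid
channels plus one kinematic trace.

The EEG is 1/f ("pink") background noise per channel, a spatially shared
slow drift, 50 Hz line interference, and a class-dependent pre-movement
signature: a slow negative potential ramping over the second before
movement start on a small set of left-central electrodes, emulating the
readiness (MRCP-like) activity that precedes voluntary movement.  The three
articulations load disjoint electrode groups (elbow near C1/FCC1, wrist
near C3/CCP3, hand near C5/CP5); rest has no signature.  Templates are
statistical stand-ins, not biophysical forward models.

The kinematic trace is flat during rest and preparation and rises with a
smoothstep of fixed 0.3 s rise time at movement start, giving a sharp,
known ground-truth onset for validating the detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoching import LABELS7
from .io import Recording
from .montage import Montage, build_montage, default_placement

__all__ = [
    "SynthConfig",
    "TEMPLATE_CELLS",
    "class_template",
    "filtered_template_peak",
    "generate_subject",
]

# Per-class electrode groups of the pre-movement signature.  The two classes
# of one articulation share their core electrode but emphasise different
# anterior/posterior neighbours; articulations are pairwise disjoint.
TEMPLATE_CELLS: dict[str, tuple[str, ...]] = {
    "elbow_flexion": ("FFC1", "FC1", "FCC1", "C1"),
    "elbow_extension": ("C1", "CCP1", "CP1", "CPP1"),
    "wrist_pronation": ("FFC3", "FC3", "FCC3", "C3"),
    "wrist_supination": ("C3", "CCP3", "CP3", "CPP3"),
    "hand_open": ("FFC5", "FC5", "FCC5", "C5"),
    "hand_close": ("C5", "CCP5", "CP5", "CPP5"),
    "rest": (),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-protocol and signal parameters of the simulator.

    ``snr_db`` is the decoder-visible template-to-noise ratio: the peak
    amplitude that the pre-onset signature retains after the standard
    conditioning chain (50 Hz notch + 0.5-60 Hz bandpass, which strongly
    attenuates the slow ramp), over the noise SD in that same band,
    expressed as 20*log10(peak / noise_sd).  Defining the ratio on the
    band-limited signal keeps ``snr_db`` meaningful for the downstream
    classifier regardless of how much out-of-band power the raw drift and
    1/f background carry.  ``math.inf`` disables noise entirely.
    """

    n_runs: int = 10
    trials_per_run: int = 42
    fs: float = 512.0
    class_set: tuple[str, ...] = tuple(LABELS7)
    snr_db: float = 10.0
    template_amp: float = 8.0  # uV, raw signature magnitude at movement start
    line_amp: float = 5.0  # uV, 50 Hz interference
    line_freq: float = 50.0
    drift_rel: float = 1.0  # shared slow drift, as a multiple of the noise SD
    pre_cue_s: float = 2.0
    wait_min_s: float = 0.5  # subject waiting time after the cue
    wait_max_s: float = 1.5
    movement_s: float = 3.0
    rest_min_s: float = 2.0
    rest_max_s: float = 3.0
    motion_rise_s: float = 0.3
    motion_noise_sd: float = 0.02  # motion units; movement plateau is 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.trials_per_run < 1 or self.fs <= 0:
            raise ValueError("runs, trials and fs must be positive")
        if self.trials_per_run % len(self.class_set):
            raise ValueError(
                f"{self.trials_per_run} trials per run cannot be balanced over "
                f"{len(self.class_set)} classes"
            )
        if not (self.snr_db == math.inf or math.isfinite(self.snr_db)):
            raise ValueError("snr_db must be finite or +inf")


def class_template(label7: str, montage: Montage, amp: float, n_frames: int = 128) -> np.ndarray:
    """Spatio-temporal pre-onset signature as (n_frames, rows, cols) frames.

    A linear negative ramp reaching magnitude ``amp`` on the class's
    electrode group at the last frame before onset; all-zero for rest.
    """
    if label7 not in TEMPLATE_CELLS:
        raise ValueError(f"unknown movement class {label7!r}")
    out = np.zeros((n_frames, montage.grid_rows, montage.grid_cols))
    cells = TEMPLATE_CELLS[label7]
    if not cells:
        return out
    ramp = -amp * np.arange(1, n_frames + 1) / n_frames
    rows, cols = montage.coordinates(cells)
    out[:, rows, cols] = ramp[:, None]
    return out


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise, one independent trace per channel."""
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for ch in range(n_channels):  # per channel to keep peak memory flat
        spec = scale * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
        x = np.fft.irfft(spec, n=n_samples)
        out[ch] = (x / x.std()).astype(np.float32)
    return out


# Band-limited power fraction of the 1/f background inside 0.5-60 Hz,
# estimated from the spectrum shape; converts the raw pink-noise SD into
# the in-band SD that snr_db is defined against.
def _inband_fraction(n_samples: int, fs: float, low: float = 0.5, high: float = 60.0) -> float:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    power = np.zeros_like(freqs)
    power[1:] = 1.0 / freqs[1:]
    band = (freqs >= low) & (freqs <= high)
    return float(power[band].sum() / power[1:].sum())


def filtered_template_peak(amp: float, fs: float, movement_s: float = 3.0) -> float:
    """Peak amplitude the pre-onset ramp retains after the conditioning chain.

    Simulates one isolated signature (1 s linear ramp to ``amp``, held
    through the movement) through the 50 Hz notch + 0.5-60 Hz causal
    Butterworth bandpass and returns the largest magnitude inside the
    pre-onset second — the signal scale the decoder actually sees.
    """
    from scipy import signal as sps

    n_pre, n_ramp = int(4 * fs), int(fs)
    ramp = -amp * np.arange(1, n_ramp + 1) / n_ramp
    hold = np.full(int(movement_s * fs), -amp)
    x = np.concatenate([np.zeros(n_pre), ramp, hold, np.zeros(int(fs))])
    b, a = sps.iirnotch(50.0, 30.0, fs=fs)
    x = sps.lfilter(b, a, x)
    sos = sps.butter(5, [0.5, 60.0], btype="bandpass", output="sos", fs=fs)
    x = sps.sosfilt(sos, x)
    return float(np.max(np.abs(x[n_pre : n_pre + n_ramp])))


def _smoothstep(n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n, endpoint=True)
    return t * t * (3.0 - 2.0 * t)


def generate_subject(config: SynthConfig = SynthConfig()) -> Recording:
    """Simulate one subject's full session as a continuous recording.

    Returns a :class:`Recording` whose markers table carries, per trial,
    the run index, 7-class label, cue sample and the ground-truth movement
    start (``true_onset``, identical to the cue-latency sample for rest
    trials so every trial has a defined epoch anchor).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    montage = build_montage(list(default_placement()))
    labels = montage.labels
    n_ch = len(labels)
    ch_index = {lab: i for i, lab in enumerate(labels)}

    # --- schedule all trials first so the total length is known
    per_class = config.trials_per_run // len(config.class_set)
    schedule = []  # (run, trial, label7, wait_s, rest_s)
    trial_no = 0
    for run in range(config.n_runs):
        order = np.repeat(np.arange(len(config.class_set)), per_class)
        rng.shuffle(order)
        for k in order:
            schedule.append(
                (
                    run,
                    trial_no,
                    config.class_set[k],
                    rng.uniform(config.wait_min_s, config.wait_max_s),
                    rng.uniform(config.rest_min_s, config.rest_max_s),
                )
            )
            trial_no += 1

    trial_lens = [
        int(round((config.pre_cue_s + wait + config.movement_s + rest) * fs))
        for _, _, _, wait, rest in schedule
    ]
    n_total = int(sum(trial_lens))

    # --- background: per-channel pink noise + shared drift + line tone
    if config.snr_db == math.inf:
        signal = np.zeros((n_ch, n_total), dtype=np.float32)
    else:
        peak = filtered_template_peak(config.template_amp, fs, config.movement_s)
        inband_target = peak * 10.0 ** (-config.snr_db / 20.0)
        noise_sd = inband_target / math.sqrt(_inband_fraction(n_total, fs))
        signal = _pink_noise(rng, n_ch, n_total)
        signal *= np.float32(noise_sd)
        drift = _pink_noise(rng, 1, n_total)[0] * np.float32(config.drift_rel * noise_sd)
        signal += drift[None, :]
    if config.line_amp > 0:
        t = np.arange(n_total) / fs
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        tone = np.sin(2 * np.pi * config.line_freq * t[None, :] + phases[:, None])
        signal += np.float32(config.line_amp) * tone.astype(np.float32)

    motion = rng.normal(0.0, config.motion_noise_sd, n_total).astype(np.float32)

    # --- per-trial signature + kinematics
    n_rise = int(round(config.motion_rise_s * fs))
    n_ramp = int(round(1.0 * fs))  # signature builds over the last pre-onset second
    n_move = int(round(config.movement_s * fs))
    rows = []
    start = 0
    for (run, trial, label7, wait_s, _), length in zip(schedule, trial_lens):
        cue = start + int(round(config.pre_cue_s * fs))
        onset = cue + int(round(wait_s * fs))
        if label7 != "rest":
            cells = TEMPLATE_CELLS[label7]
            idx = [ch_index[c] for c in cells]
            ramp = -config.template_amp * np.arange(1, n_ramp + 1) / n_ramp
            signal[idx, onset - n_ramp : onset] += ramp[None, :].astype(np.float32)
            # signature holds through the movement, then releases
            hold_end = min(onset + n_move, n_total)
            signal[idx, onset:hold_end] += np.float32(-config.template_amp)
            rel = _smoothstep(n_rise)[::-1] * config.template_amp
            rel_end = min(hold_end + n_rise, n_total)
            signal[idx, hold_end:rel_end] += -rel[: rel_end - hold_end].astype(np.float32)
            # kinematics: smoothstep up at onset, plateau, smoothstep down
            up = _smoothstep(n_rise)
            motion[onset : onset + n_rise] += up.astype(np.float32)
            motion[onset + n_rise : hold_end] += np.float32(1.0)
            motion[hold_end:rel_end] += (1.0 - _smoothstep(rel_end - hold_end)).astype(np.float32)
        rows.append(
            {
                "trial": trial,
                "run": run,
                "label7": label7,
                "cue_sample": cue,
                "true_onset": onset,
            }
        )
        start += length

    return Recording(
        signal=signal,
        fs=fs,
        labels=labels,
        motion=motion,
        markers=pd.DataFrame(rows),
    )
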