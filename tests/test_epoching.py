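"""Onset detection, pre-onset epoch extraction, class merging, chunking."""

import numpy as np
import pytest

from emid.epoching import (
    LABELS7,
    NoOnsetError,
    OnsetParams,
    chunk_epoch,
    detect_onset,
    epoch_subject,
    extract_epoch,
    merge_class,
)
from emid.io import Recording


def test_noiseless_ramp_onset_within_one_sample():
    fs = 512
    x = np.zeros(3 * fs)
    x[1000:] = np.arange(3 * fs - 1000) / fs
    onset = detect_onset(x, fs, cue_sample=768)
    assert abs(onset - 1000) <= 1


def test_flat_trace_raises_no_onset():
    with pytest.raises(NoOnsetError):
        detect_onset(np.zeros(3 * 512), 512, cue_sample=768)


def test_insufficient_baseline_rejected():
    with pytest.raises(ValueError, match="baseline"):
        detect_onset(np.zeros(2048), 512, cue_sample=100)


def test_onset_translation_equivariance():
    """Shifting the motion trace (and cue) by k samples shifts the onset by k."""
    fs = 512
    onsets = []
    for shift in (0, 64, 257):
        x = np.zeros(4 * fs)
        start = 1200 + shift
        x[start:] = np.arange(4 * fs - start) / fs
        onsets.append(detect_onset(x, fs, cue_sample=768 + shift) - shift)
    assert onsets[0] == onsets[1] == onsets[2]


def test_noisy_onset_precision_monte_carlo(motion_fixture):
    """>= 95% of detections within +/-25 ms of the true ramp start at 20 dB SNR."""
    fs = 512
    hits = 0
    n = 200
    for seed in range(n):
        x, start = motion_fixture(seed, fs=fs)
        onset = detect_onset(x, fs, cue_sample=2 * fs)
        hits += abs(onset - start) / fs <= 0.025
    assert hits / n >= 0.95


@pytest.mark.parametrize(
    "label7,expected",
    [
        ("elbow_flexion", "elbow"),
        ("elbow_extension", "elbow"),
        ("wrist_pronation", "wrist"),
        ("wrist_supination", "wrist"),
        ("hand_open", "hand"),
        ("hand_close", "hand"),
        ("rest", "rest"),
    ],
)
def test_class_merging(label7, expected):
    assert merge_class(label7) == expected


def test_merge_rejects_unknown_class():
    with pytest.raises(ValueError):
        merge_class("shoulder_shrug")


def test_extract_epoch_window_is_half_open(montage):
    fs = 128
    signal = np.tile(np.arange(600, dtype=float), (61, 1))
    rec = Recording(signal=signal, fs=fs, labels=montage.labels)
    ep = extract_epoch(rec, montage, onset=500, label7="rest")
    assert ep.frames.shape == (128, 10, 9)
    # covers samples [372, 500): first frame holds 372, last 499; 500 excluded
    assert ep.frames[0, 4, 4] == 372
    assert ep.frames[-1, 4, 4] == 499


def test_extract_epoch_needs_full_pre_onset_history(montage):
    rec = Recording(signal=np.zeros((61, 600)), fs=128, labels=montage.labels)
    with pytest.raises(ValueError, match="history"):
        extract_epoch(rec, montage, onset=100)


def test_chunking_partitions_epoch_exactly():
    frames = np.random.default_rng(0).normal(size=(128, 10, 9))
    chunks = chunk_epoch(frames)
    assert chunks.shape == (4, 32, 10, 9)
    np.testing.assert_array_equal(chunks.reshape(128, 10, 9), frames)
    with pytest.raises(ValueError):
        chunk_epoch(frames[:100])


def test_epoch_pipeline_one_trial_per_marker(small_epochs, small_config):
    n_trials = small_config.n_runs * small_config.trials_per_run
    assert len(small_epochs) == n_trials
    counts7 = small_epochs.class_counts(merged=False)
    assert set(counts7) == set(LABELS7)
    assert all(v == n_trials // 7 for v in counts7.values())
    merged = small_epochs.class_counts()
    per7 = n_trials // 7
    assert merged == {"elbow": 2 * per7, "wrist": 2 * per7, "hand": 2 * per7, "rest": per7}


def test_detected_onsets_track_ground_truth(small_epochs, small_subject_128):
    """Detected onsets sit within ~2 samples (16 ms) of the true movement start,
    so the [onset-128, onset) windows contain essentially no movement data."""
    truth = small_subject_128.markers.set_index("trial")["true_onset"]
    errs = np.array(
        [
            row.onset_sample - truth.loc[row.trial]
            for row in small_epochs.manifest.itertuples()
            if row.label7 != "rest"
        ]
    )
    assert np.abs(errs).max() <= 2


def test_epoch_set_round_trip(small_epochs, tmp_path):
    path = tmp_path / "epochs.h5"
    small_epochs.save(path)
    from emid.epoching import EpochSet

    again = EpochSet.load(path)
    np.testing.assert_allclose(again.frames, small_epochs.frames, atol=1e-6)
    assert list(again.manifest["label4"]) == list(small_epochs.manifest["label4"])


def test_rest_onset_uses_configured_latency(small_epochs, small_subject_128):
    params = OnsetParams()
    cues = small_subject_128.markers.set_index("trial")["cue_sample"]
    rest = small_epochs.manifest[small_epochs.manifest["label7"] == "rest"]
    fs = small_subject_128.fs
    for row in rest.itertuples():
        assert row.onset_sample == cues.loc[row.trial] + int(params.rest_latency_s * fs)
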