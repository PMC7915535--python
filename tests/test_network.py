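"""Forward operators against brute-force scalar-loop oracles; model surface."""

import numpy as np
import pytest

from emid.model import EncoderConfig, ModelConfig, MovementIntentNet
from emid.nn import (
    LSTM,
    BatchNorm,
    conv3d_forward,
    lstm_step,
    maxpool3d,
    sigmoid,
    softmax,
)

RNG = np.random.default_rng(2024)


# ---------------------------------------------------------------- oracles
def conv3d_loops(x, w, b):
    n, ci, t, h, wd = x.shape
    co, _, kt, kh, kw = w.shape
    out = np.zeros((n, co, t - kt + 1, h - kh + 1, wd - kw + 1))
    for ni in range(n):
        for o in range(co):
            for ti in range(out.shape[2]):
                for hi in range(out.shape[3]):
                    for wi in range(out.shape[4]):
                        acc = b[o]
                        for c in range(ci):
                            for dt in range(kt):
                                for dh in range(kh):
                                    for dw in range(kw):
                                        acc += (
                                            w[o, c, dt, dh, dw]
                                            * x[ni, c, ti + dt, hi + dh, wi + dw]
                                        )
                        out[ni, o, ti, hi, wi] = acc
    return out


def maxpool_loops(x, kernel):
    n, c, t, h, w = x.shape
    kt, kh, kw = kernel
    out = np.empty((n, c, t // kt, h // kh, w // kw))
    for ni in range(n):
        for ci in range(c):
            for ti in range(out.shape[2]):
                for hi in range(out.shape[3]):
                    for wi in range(out.shape[4]):
                        out[ni, ci, ti, hi, wi] = x[
                            ni, ci,
                            ti * kt : (ti + 1) * kt,
                            hi * kh : (hi + 1) * kh,
                            wi * kw : (wi + 1) * kw,
                        ].max()
    return out


def lstm_step_scalar(x, h, c, wx, wh, b):
    hid = h.shape[-1]
    hn = np.empty_like(h)
    cn = np.empty_like(c)
    for j in range(hid):
        zi = b[j] + x @ wx[:, j] + h @ wh[:, j]
        zf = b[hid + j] + x @ wx[:, hid + j] + h @ wh[:, hid + j]
        zg = b[2 * hid + j] + x @ wx[:, 2 * hid + j] + h @ wh[:, 2 * hid + j]
        zo = b[3 * hid + j] + x @ wx[:, 3 * hid + j] + h @ wh[:, 3 * hid + j]
        i = 1.0 / (1.0 + np.exp(-zi))
        f = 1.0 / (1.0 + np.exp(-zf))
        g = np.tanh(zg)
        o = 1.0 / (1.0 + np.exp(-zo))
        cn[j] = f * c[j] + i * g
        hn[j] = o * np.tanh(cn[j])
    return hn, cn


# ---------------------------------------------------------------- conv3d
def test_conv3d_matches_loop_oracle():
    x = RNG.normal(size=(1, 1, 8, 4, 4))
    w = RNG.normal(size=(2, 1, 3, 2, 2))
    b = RNG.normal(size=2)
    np.testing.assert_allclose(conv3d_forward(x, w, b), conv3d_loops(x, w, b), atol=1e-6)


def test_conv3d_zero_weights_give_constant_bias():
    x = RNG.normal(size=(2, 3, 6, 5, 4))
    w = np.zeros((4, 3, 2, 2, 2))
    b = np.array([1.0, -2.0, 0.5, 3.0])
    out = conv3d_forward(x, w, b)
    for o, bo in enumerate(b):
        np.testing.assert_allclose(out[:, o], bo)


def test_conv3d_unit_kernel_scales_input():
    x = RNG.normal(size=(1, 1, 4, 3, 3))
    w = np.full((1, 1, 1, 1, 1), 2.5)
    out = conv3d_forward(x, w, np.zeros(1))
    np.testing.assert_allclose(out, 2.5 * x, atol=1e-12)


def test_conv3d_rejects_small_input_and_channel_mismatch():
    with pytest.raises(ValueError):
        conv3d_forward(np.zeros((1, 1, 2, 2, 2)), np.zeros((1, 1, 3, 2, 2)), np.zeros(1))
    with pytest.raises(ValueError):
        conv3d_forward(np.zeros((1, 2, 5, 5, 5)), np.zeros((1, 1, 3, 2, 2)), np.zeros(1))


# ---------------------------------------------------------------- pooling
def test_maxpool_matches_exhaustive_oracle():
    x = RNG.normal(size=(1, 1, 6, 4, 4))
    np.testing.assert_array_equal(maxpool3d(x), maxpool_loops(x, (3, 2, 2)))


def test_maxpool_constant_and_monotone_inputs():
    const = np.full((1, 2, 6, 4, 4), 7.0)
    np.testing.assert_array_equal(maxpool3d(const), np.full((1, 2, 2, 2, 2), 7.0))
    ramp = np.arange(12.0)[None, None, :, None, None] * np.ones((1, 1, 12, 2, 2))
    out = maxpool3d(ramp)
    np.testing.assert_array_equal(out[0, 0, :, 0, 0], [2.0, 5.0, 8.0, 11.0])


def test_maxpool_rejects_too_small_input():
    with pytest.raises(ValueError):
        maxpool3d(np.zeros((1, 1, 2, 4, 4)))


# ---------------------------------------------------------------- batch norm
def test_batchnorm_train_standardizes_features():
    bn = BatchNorm(8)
    x = RNG.normal(loc=3.0, scale=2.0, size=(16, 8))
    y = bn.forward(x, train=True)
    np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-7)
    np.testing.assert_allclose(y.var(axis=0), 1.0, atol=1e-3)


def test_batchnorm_gamma_beta_scale_and_shift():
    bn = BatchNorm(4)
    bn.gamma.value[...] = 2.0
    bn.beta.value[...] = 3.0
    x = RNG.normal(size=(32, 4))
    y = bn.forward(x, train=True)
    xhat = (x - x.mean(0)) / np.sqrt(x.var(0) + bn.eps)
    np.testing.assert_allclose(y, 2.0 * xhat + 3.0, atol=1e-10)


def test_batchnorm_matches_two_pass_reference():
    bn = BatchNorm(8)
    x = RNG.normal(size=(16, 8))
    y = bn.forward(x, train=True)
    mean = x.sum(0) / 16
    var = ((x - mean) ** 2).sum(0) / 16
    ref = (x - mean) / np.sqrt(var + 1e-5)
    np.testing.assert_allclose(y, ref, atol=1e-6)


def test_batchnorm_eval_uses_running_stats():
    bn = BatchNorm(3)
    x = RNG.normal(loc=5.0, size=(64, 3))
    for _ in range(50):
        bn.forward(x, train=True)
    y = bn.forward(x, train=False)
    np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=0.05)


def test_batchnorm_rejects_batch_of_one_in_train_mode():
    with pytest.raises(ValueError, match="batch size"):
        BatchNorm(4).forward(np.zeros((1, 4)), train=True)


# ---------------------------------------------------------------- LSTM
def test_lstm_step_zero_params_closed_form():
    hid = 4
    c = RNG.normal(size=(1, hid))
    h, c_new = lstm_step(
        np.zeros((1, 6)), np.zeros((1, hid)), c,
        np.zeros((6, 4 * hid)), np.zeros((hid, 4 * hid)), np.zeros(4 * hid),
    )
    np.testing.assert_allclose(c_new, 0.5 * c, atol=1e-12)
    np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c), atol=1e-12)


def test_lstm_step_matches_scalar_loop():
    hid, din = 5, 7
    wx = RNG.normal(size=(din, 4 * hid))
    wh = RNG.normal(size=(hid, 4 * hid))
    b = RNG.normal(size=4 * hid)
    x = RNG.normal(size=din)
    h0 = RNG.normal(size=hid)
    c0 = RNG.normal(size=hid)
    h, c = lstm_step(x, h0, c0, wx, wh, b)
    h_ref, c_ref = lstm_step_scalar(x, h0, c0, wx, wh, b)
    np.testing.assert_allclose(h, h_ref, atol=1e-6)
    np.testing.assert_allclose(c, c_ref, atol=1e-6)


def test_default_lstm_state_sizes():
    model = MovementIntentNet()
    h, c = model.init_state(1)
    assert h.shape == (1, 64) and c.shape == (1, 64)
    assert not h.any() and not c.any()
    assert model.classifier.lstm.input_size == 128


# ---------------------------------------------------------------- heads
def test_softmax_closed_forms():
    np.testing.assert_allclose(softmax(np.zeros(4)), 0.25)
    probs = softmax(np.array([np.log(2.0), 0.0, 0.0, 0.0]))
    np.testing.assert_allclose(probs, [0.4, 0.2, 0.2, 0.2], atol=1e-12)


def test_sigmoid_is_stable_for_large_inputs():
    x = np.array([-1000.0, 0.0, 1000.0])
    np.testing.assert_allclose(sigmoid(x), [0.0, 0.5, 1.0], atol=1e-12)


# ---------------------------------------------------------------- encoder/model
def test_encoder_shapes_and_feature_counts():
    cfg = EncoderConfig()
    assert cfg.input_features == 2880  # 32 x 10 x 9 per chunk
    assert cfg.flat_features == int(np.prod(cfg.shapes()["pooled"]))
    model = MovementIntentNet()
    codes = model.encoder.forward(RNG.normal(size=(3, 32, 10, 9)))
    assert codes.shape == (3, 128)


def test_encoder_flat_size_follows_configured_kernels():
    table = EncoderConfig(conv2_kernel=(5, 1, 1))
    text = EncoderConfig(conv2_kernel=(5, 2, 2))
    assert table.flat_features == 4096
    assert text.flat_features == 3072
    model = MovementIntentNet(ModelConfig(encoder=text))
    assert model.encoder.forward(RNG.normal(size=(2, 32, 10, 9))).shape == (2, 128)


def test_encoder_rejects_wrong_chunk_shape():
    model = MovementIntentNet()
    with pytest.raises(ValueError, match="shape"):
        model.encoder.forward(RNG.normal(size=(2, 16, 10, 9)))


def test_encoder_eval_is_deterministic():
    model = MovementIntentNet()
    x = RNG.normal(size=(2, 32, 10, 9))
    np.testing.assert_array_equal(model.encoder.forward(x), model.encoder.forward(x))


def test_stream_outputs_are_probability_vectors():
    model = MovementIntentNet(ModelConfig(seed=7))
    chunks = RNG.normal(size=(4, 32, 10, 9))
    probs = model.stream_classify(chunks)
    assert probs.shape == (4, 4)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_stream_replay_identical_but_state_matters():
    model = MovementIntentNet(ModelConfig(seed=3))
    chunks = RNG.normal(size=(6, 32, 10, 9))
    a = model.stream_classify(chunks)
    b = model.stream_classify(chunks)
    np.testing.assert_array_equal(a, b)
    # feeding the tail with a carried state differs from a fresh-state run
    state = model.init_state(1)
    _, state = model.classify_step(model.encoder.forward(chunks[:3])[0], state)
    carried = model.stream_classify(chunks[3:], state=state, reset=False)
    fresh = model.stream_classify(chunks[3:])
    assert not np.allclose(carried, fresh)


def test_checkpoint_round_trip(tmp_path):
    model = MovementIntentNet(ModelConfig(seed=11))
    x = RNG.normal(size=(2, 32, 10, 9))
    before = model.stream_classify(x)
    path = tmp_path / "model.npz"
    model.save(path)
    again = MovementIntentNet.load(path)
    np.testing.assert_array_equal(again.stream_classify(x), before)
    assert (tmp_path / "model.json").exists()


def test_lstm_sequence_equals_stepwise():
    lstm = LSTM(6, 5, RNG)
    x = RNG.normal(size=(2, 4, 6))
    hs = lstm.forward(x)
    state = lstm.init_state(2)
    for t in range(4):
        h, state = lstm.step(x[:, t, :], state)
        np.testing.assert_allclose(hs[:, t, :], h, atol=1e-12)
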