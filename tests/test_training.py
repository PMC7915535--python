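"""Loss, folds, early stopping, gradient descent and grid enumeration."""

import numpy as np
import pytest

from emid.model import ModelConfig
from emid.training import (
    DEFAULT_GRID,
    Adam,
    EarlyStopper,
    TrainConfig,
    expand_grid,
    fit,
    grid_search,
    run_cv,
    smoothed_crossentropy,
    stratified_folds,
)
from emid.nn import Param


REDUCED = dict(batch_size=64, z_dim=16, lstm_hidden=8, conv1_channels=2,
               conv2_channels=4, lr=1e-3)


def test_uniform_probs_give_ln4_for_any_smoothing():
    for alpha in (0.0, 0.2, 0.4):
        loss = smoothed_crossentropy(np.full(4, 0.25), label=2, smoothing=alpha)
        np.testing.assert_allclose(loss, np.log(4.0), atol=1e-12)


def test_smoothed_target_vector_value():
    # alpha=0.2, K=4: true-class target 0.85, others 0.05
    probs = np.array([0.85, 0.05, 0.05, 0.05])
    expected = -(0.85 * np.log(0.85) + 3 * 0.05 * np.log(0.05))
    np.testing.assert_allclose(
        smoothed_crossentropy(probs, label=0, smoothing=0.2), expected, atol=1e-12
    )


def test_zero_smoothing_equals_plain_crossentropy():
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.dirichlet(np.ones(4))
        lab = int(rng.integers(4))
        np.testing.assert_allclose(
            smoothed_crossentropy(p, lab, smoothing=0.0), -np.log(p[lab]), atol=1e-12
        )


def test_perfect_onehot_prediction_loss_vanishes():
    probs = np.array([1.0, 0.0, 0.0, 0.0])
    assert smoothed_crossentropy(probs, 0, smoothing=0.0) < 1e-10


def test_invalid_smoothing_rejected():
    with pytest.raises(ValueError):
        smoothed_crossentropy(np.full(4, 0.25), 0, smoothing=1.0)
    with pytest.raises(ValueError):
        TrainConfig(smoothing=-0.1)


def test_table_defaults_of_train_config():
    cfg = TrainConfig()
    assert cfg.batch_size == 1024
    assert cfg.beta1 == 0.9 and cfg.beta2 == 0.999
    assert cfg.smoothing == 0.2
    assert cfg.max_epochs == 100 and cfg.patience == 10
    assert cfg.n_folds == 5 and cfg.n_repeats == 3
    assert cfg.lstm_dropout == 0.0 and cfg.l2_penalty == 0.0


def test_stratified_folds_cover_each_class_and_are_seeded():
    y = np.array([0] * 20 + [1] * 20 + [2] * 20 + [3] * 10)
    folds = stratified_folds(y, 5, seed=1)
    assert folds.shape == y.shape
    for f in range(5):
        sel = folds == f
        assert set(y[sel]) == {0, 1, 2, 3}
    np.testing.assert_array_equal(folds, stratified_folds(y, 5, seed=1))
    assert not np.array_equal(folds, stratified_folds(y, 5, seed=2))


def test_stratification_error_when_class_too_small():
    y = np.array([0] * 20 + [1] * 3)
    with pytest.raises(ValueError, match="fewer than"):
        stratified_folds(y, 5, seed=0)


def test_adam_descends_on_a_quadratic():
    p = Param(np.array([5.0, -3.0]))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        p.grad[...] = 2.0 * p.value  # d/dx of ||x||^2
        opt.step()
    assert np.abs(p.value).max() < 1e-2


def test_grid_expansion_covers_cartesian_product():
    combos = expand_grid(DEFAULT_GRID)
    assert len(combos) == 81  # 3 z_dims x 3 hidden sizes x 3 lrs x 3 smoothings
    assert len({tuple(sorted(c.items())) for c in combos}) == 81
    with pytest.raises(ValueError):
        expand_grid({})


def _toy_data(n_per_class=10, seed=0):
    """Four classes with strong, distinct spatial means; trivially learnable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for k in range(4):
        x = rng.normal(0.0, 0.3, size=(n_per_class, 4, 32, 10, 9))
        r, c = divmod(k, 2)
        x[:, :, :, r * 4 : r * 4 + 3, c * 4 : c * 4 + 3] += 3.0
        xs.append(x)
        ys.append(np.full(n_per_class, k))
    return np.concatenate(xs), np.concatenate(ys)


def test_fit_learns_separable_toy_data_and_is_seeded():
    x, y = _toy_data()
    cfg = TrainConfig(max_epochs=15, patience=14, n_folds=2, n_repeats=1,
                      **{**REDUCED, "batch_size": 8, "lr": 3e-3})
    folds = stratified_folds(y, 2, seed=0)
    val = folds == 0
    _, rec_a = fit(x[~val], y[~val], x[val], y[val], cfg, init_seed=3)
    _, rec_b = fit(x[~val], y[~val], x[val], y[val], cfg, init_seed=3)
    assert rec_a["val_accuracy"] == rec_b["val_accuracy"]
    assert rec_a["history"] == rec_b["history"]
    assert rec_a["val_accuracy"] >= 0.9


def test_early_stopping_rules():
    # strictly decreasing loss: never stops
    s = EarlyStopper(patience=10)
    assert not any(s.update(loss) for loss in np.linspace(1.0, 0.1, 100))
    # constant loss: stops after exactly `patience` non-improving epochs
    s = EarlyStopper(patience=3)
    outcomes = [s.update(1.0) for _ in range(5)]
    assert outcomes == [False, False, False, True, True]
    # a dip resets the counter
    s = EarlyStopper(patience=2)
    assert [s.update(v) for v in (1.0, 1.0, 0.5, 0.5, 0.5)] == [
        False, False, False, False, True
    ]


def test_run_cv_produces_folds_times_repeats_models():
    x, y = _toy_data(n_per_class=6, seed=2)
    cfg = TrainConfig(max_epochs=2, patience=1, n_folds=3, n_repeats=2, **REDUCED)
    result = run_cv(x, y, cfg)
    assert len(result.table) == 6
    assert result.summary()["n_models"] == 6
    assert set(result.table["repeat"]) == {0, 1}
    again = run_cv(x, y, cfg)
    assert result.table.equals(again.table)


def test_single_point_grid_returns_that_config():
    x, y = _toy_data(n_per_class=6, seed=3)
    base = TrainConfig(max_epochs=2, patience=1, n_folds=2, n_repeats=1, **REDUCED)
    best, table = grid_search(x, y, grid={"lr": [1e-3]}, base=base)
    assert best.lr == 1e-3
    assert len(table) == 1
    assert {"mean_accuracy", "sd_accuracy", "n_parameters"} <= set(table.columns)


def test_architecture_depths_are_fixed():
    with pytest.raises(ValueError):
        TrainConfig(lstm_depth=2)


def test_model_config_reflects_train_config():
    cfg = TrainConfig(z_dim=256, lstm_hidden=32, conv1_channels=8, conv2_channels=64)
    mc = cfg.model_config()
    assert isinstance(mc, ModelConfig)
    assert mc.encoder.z_dim == 256 and mc.lstm_hidden == 32
    assert mc.encoder.conv1_channels == 8 and mc.encoder.conv2_channels == 64
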