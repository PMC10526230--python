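"""Loss, learning-rate schedule, weight averaging, and the training loop."""

import math

import numpy as np
import pytest

from hsnet3d.models import ArchConfig, build_model
from hsnet3d.train import (TrainConfig, multitask_loss, clr_schedule,
                           swa_update, train, run_comparison_grid,
                           COMPARISON_RUNS, TrainingDiverged)

TINY_ARCH = dict(patch_size=8, conv_blocks_per_branch=2,
                 filters_per_block=(2, 3), branch_feature_dim=4,
                 dropout_rate=0.1, malignancy_head_dims=(5,))


def tiny_data(n=24, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8, 8, 8)).astype(np.float32)
    y = rng.integers(0, 2, size=(n, 6)).astype(np.float32)
    return X, y


# ---------------------------------------------------------------------------
# multi-task loss
# ---------------------------------------------------------------------------

def test_loss_zero_for_perfect_predictions():
    y = np.array([[1, 0, 1, 0, 1, 1]], dtype=float)
    loss, _ = multitask_loss(y, y)
    assert loss == pytest.approx(0.0, abs=1e-5)


def test_loss_at_half_is_six_ln_two():
    probs = np.full((3, 6), 0.5)
    labels = np.random.default_rng(0).integers(0, 2, (3, 6))
    loss, dlog = multitask_loss(probs, labels)
    assert loss == pytest.approx(6 * math.log(2))


def test_loss_respects_weights():
    probs = np.full((2, 6), 0.5)
    labels = np.ones((2, 6))
    loss, _ = multitask_loss(probs, labels, np.zeros(6))
    assert loss == 0.0
    loss_m, _ = multitask_loss(probs, labels, [0, 0, 0, 0, 0, 2.0])
    assert loss_m == pytest.approx(2 * math.log(2))
    with pytest.raises(ValueError):
        multitask_loss(probs, labels, [1.0] * 5)


def test_loss_gradient_is_weighted_residual():
    rng = np.random.default_rng(2)
    probs = rng.random((4, 6))
    labels = rng.integers(0, 2, (4, 6))
    w = np.array([1, 2, 0, 1, 0.5, 3.0])
    _, dlog = multitask_loss(probs, labels, w)
    assert np.allclose(dlog, (probs - labels) * w / 4, atol=1e-6)


# ---------------------------------------------------------------------------
# cyclical learning rate
# ---------------------------------------------------------------------------

def test_clr_triangular_waypoints():
    assert clr_schedule(0, 1e-3, 6e-3, 10) == pytest.approx(1e-3)
    assert clr_schedule(10, 1e-3, 6e-3, 10) == pytest.approx(6e-3)
    assert clr_schedule(20, 1e-3, 6e-3, 10) == pytest.approx(1e-3)
    assert clr_schedule(5, 1e-3, 6e-3, 10) == pytest.approx(3.5e-3)
    assert clr_schedule(15, 1e-3, 6e-3, 10) == pytest.approx(3.5e-3)


def test_clr_periodicity_and_bounds():
    lrs = [clr_schedule(i, 2e-4, 1e-2, 7) for i in range(70)]
    assert lrs[:14] == pytest.approx(lrs[14:28])
    assert min(lrs) >= 2e-4 and max(lrs) <= 1e-2
    with pytest.raises(ValueError):
        clr_schedule(0, 1e-2, 1e-3, 5)
    with pytest.raises(ValueError):
        clr_schedule(0, 1e-3, 1e-2, 0)


# ---------------------------------------------------------------------------
# stochastic weight averaging
# ---------------------------------------------------------------------------

def test_swa_running_mean_equals_direct_average():
    rng = np.random.default_rng(0)
    snapshots = [{"w": rng.normal(size=(3, 2)), "b": rng.normal(size=4)}
                 for _ in range(7)]
    avg, n = None, 0
    for snap in snapshots:
        avg = swa_update(avg, n, snap)
        n += 1
    for key in ("w", "b"):
        direct = np.mean([s[key] for s in snapshots], axis=0)
        assert np.allclose(avg[key], direct, atol=1e-12)


def test_swa_scalar_sequence_and_fixed_point():
    seq = [{"w": np.array(float(v))} for v in (1.0, 2.0, 3.0)]
    avg, n = None, 0
    for s in seq:
        avg = swa_update(avg, n, s)
        n += 1
    assert avg["w"] == pytest.approx(2.0)
    w = {"w": np.array([1.5])}
    assert swa_update(w, 5, w)["w"] == pytest.approx(1.5)
    assert swa_update(None, 0, w)["w"] is not w["w"]  # copy, not alias


def test_swa_name_mismatch_rejected():
    with pytest.raises(KeyError):
        swa_update({"a": np.zeros(2)}, 1, {"b": np.zeros(2)})


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def small_cfg(**kw):
    base = dict(epochs=2, batch_size=8, base_lr=1e-3, max_lr=3e-3,
                clr_step_epochs=1.0, use_clr=True, use_swa=False,
                early_stop=False, seed=0)
    base.update(kw)
    return TrainConfig(**base)


def test_zero_epochs_returns_initial_weights():
    X, y = tiny_data()
    net = build_model(ArchConfig(**TINY_ARCH), seed=3)
    before = net.snapshot()
    net, hist = train(net, (X, y), (X[:4], y[:4]), small_cfg(epochs=0))
    assert hist.epochs == []
    after = net.snapshot()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_history_is_complete_and_loop_deterministic():
    X, y = tiny_data()
    cfg = small_cfg(epochs=3)
    outs = []
    for _ in range(2):
        net = build_model(ArchConfig(**TINY_ARCH), seed=3)
        net, hist = train(net, (X, y), (X[:4], y[:4]), cfg)
        assert len(hist.epochs) == 3
        assert len(hist.learning_rates) == 3 * 3  # ceil(24/8) batches/epoch
        outs.append((net.predict_proba(X[:4]), hist.epochs[-1]["train_loss"]))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert outs[0][1] == outs[1][1]


def test_clr_learning_rates_follow_schedule():
    X, y = tiny_data()
    net = build_model(ArchConfig(**TINY_ARCH), seed=0)
    cfg = small_cfg(epochs=2, clr_step_epochs=1.0)
    _, hist = train(net, (X, y), (X[:4], y[:4]), cfg)
    expected = [clr_schedule(i, cfg.base_lr, cfg.max_lr, 3) for i in range(6)]
    assert hist.learning_rates == pytest.approx(expected)


def test_loss_at_init_is_optimizer_agnostic():
    X, y = tiny_data()
    losses = {}
    for opt in ("sgd", "adam", "rmsprop"):
        net = build_model(ArchConfig(**TINY_ARCH), seed=7)
        _, hist = train(net, (X, y), (X[:4], y[:4]),
                        small_cfg(optimizer=opt, epochs=1))
        losses[opt] = hist.epochs[0]["train_loss"]
    # identical init and identical first forward pass before any update
    # would give identical batch-0 loss; epoch aggregates diverge after the
    # first step, so compare only loosely
    vals = list(losses.values())
    assert max(vals) - min(vals) < 1.0


def test_swa_folding_identical_snapshots_is_identity():
    X, y = tiny_data(16)
    net = build_model(ArchConfig(**TINY_ARCH), seed=1)
    # zero learning rate: weights never move, SWA average must equal them
    cfg = small_cfg(epochs=3, base_lr=0.0, max_lr=0.0, use_clr=False,
                    use_swa=True, swa_start_epoch=0)
    before = {k: v.copy() for k, v in net.parameters().items()}
    net, _ = train(net, (X, y), (X[:4], y[:4]), cfg)
    after = net.parameters()
    for k in before:
        assert np.allclose(before[k], after[k], atol=1e-7)


def test_early_stop_returns_best_validation_checkpoint():
    X, y = tiny_data(32, seed=5)
    net = build_model(ArchConfig(**TINY_ARCH), seed=2)
    cfg = small_cfg(epochs=4, early_stop=True)
    net, hist = train(net, (X, y), (X[8:16], y[8:16]), cfg)
    accs = [e["val_acc_malignancy"] for e in hist.epochs]
    assert hist.checkpoint_epoch == int(np.argmax(accs))
    # returned weights achieve the best recorded validation accuracy
    probs = net.predict_proba(X[8:16])
    acc = float(((probs[:, 5] >= 0.5) == (y[8:16, 5] > 0.5)).mean())
    assert acc >= max(accs) - 1e-9


def test_divergence_aborts_with_epoch_index():
    X, y = tiny_data(16)
    net = build_model(ArchConfig(**TINY_ARCH), seed=0)
    cfg = small_cfg(epochs=3, base_lr=1e6, max_lr=1e6, use_clr=False)
    with pytest.raises(TrainingDiverged):
        train(net, (X, y), (X[:4], y[:4]), cfg)


def test_comparison_grid_covers_all_five_published_runs():
    assert set(COMPARISON_RUNS) == {"Run1", "Run2", "Run3", "Run4", "Run5"}
    assert COMPARISON_RUNS["Run4"] == dict(optimizer="sgd", use_clr=True,
                                           use_swa=True)
    # every run configuration is constructible as a TrainConfig
    for overrides in COMPARISON_RUNS.values():
        TrainConfig(**overrides)


def test_comparison_grid_single_run_equals_direct_training():
    X, y = tiny_data(24, seed=8)
    arch = ArchConfig(**TINY_ARCH)
    base = small_cfg(epochs=1, use_swa=False)
    out = run_comparison_grid((X[:16], y[:16]), (X[16:20], y[16:20]),
                              (X[20:], y[20:]), arch, base,
                              runs={"only": dict(optimizer="sgd")})
    net = build_model(arch, seed=base.seed)
    cfg = TrainConfig(**{**base.as_dict(), "optimizer": "sgd"})
    net, _ = train(net, (X[:16], y[:16]), (X[16:20], y[16:20]), cfg)
    probs = net.predict_proba(X[20:])
    acc = float(((probs[:, 5] >= 0.5) == (y[20:, 5] > 0.5)).mean())
    assert out["only"]["test_accuracy"]["malignancy"] == pytest.approx(acc)
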