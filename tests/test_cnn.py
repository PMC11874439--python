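import math

import numpy as np
import pytest

from minidock.cnn_models import (
    GridScorer,
    ModelSpec,
    PoseScoreOutput,
    TrainConfig,
    TrainingExample,
    build_model,
    ensemble_score,
    hinged_affinity_loss,
    load_checkpoint,
    make_synthetic_pose_dataset,
    pose_classification_loss,
    save_checkpoint,
    stack_grids,
    train_model,
)
from minidock.errors import InputError

SMALL = ModelSpec(family="default2018", width=2, seed=0, n_channels=8, grid_points=12)


def test_conv_layer_counts_match_families():
    assert build_model(
        ModelSpec(family="default2018", width=4, n_channels=8)
    ).conv_layer_count == 5
    assert build_model(
        ModelSpec(family="dense", width=4, n_channels=8)
    ).conv_layer_count == 12


def test_same_seed_gives_identical_initialization():
    a = build_model(SMALL)
    b = build_model(SMALL)
    for (wa, _), (wb, _) in zip(a.parameters(), b.parameters()):
        assert np.array_equal(wa, wb)


def test_channel_mismatch_rejected():
    model = build_model(SMALL)
    with pytest.raises(InputError):
        model.forward_batch(np.zeros((1, 5, 12, 12, 12)))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_cross_entropy_closed_forms():
    out = PoseScoreOutput(logits=np.array([0.3, 0.3]), pose_score=0.5, affinity=0.0)
    assert pose_classification_loss(out, True) == pytest.approx(math.log(2))
    assert pose_classification_loss(out, False) == pytest.approx(math.log(2))
    confident = PoseScoreOutput(
        logits=np.array([-20.0, 20.0]), pose_score=1.0, affinity=0.0
    )
    assert pose_classification_loss(confident, True) < 1e-8
    rng = np.random.default_rng(0)
    for _ in range(50):
        logits = rng.normal(scale=3, size=2)
        assert pose_classification_loss(
            PoseScoreOutput(logits=logits, pose_score=0.5, affinity=0), bool(rng.integers(2))
        ) >= 0.0


def test_hinged_affinity_loss_cases():
    assert hinged_affinity_loss(6.0, 6.0, True) == 0.0
    assert hinged_affinity_loss(5.0, 6.0, False) == 0.0   # under-prediction, bad pose
    assert hinged_affinity_loss(7.0, 6.0, False) == pytest.approx(1.0)
    assert hinged_affinity_loss(7.0, 6.0, True) == pytest.approx(1.0)
    assert hinged_affinity_loss(5.0, 6.0, True) == pytest.approx(1.0)


def test_training_example_label_consistency():
    grid = np.zeros((8, 4, 4, 4))
    TrainingExample(grid=grid, pose_label=True, true_affinity=6.0, rmsd=1.0)
    with pytest.raises(InputError):
        TrainingExample(grid=grid, pose_label=True, true_affinity=6.0, rmsd=3.0)


# ---------------------------------------------------------------------------
# gradient correctness of the NumPy backend
# ---------------------------------------------------------------------------

def test_backprop_matches_finite_differences():
    rng = np.random.default_rng(0)
    model = build_model(
        ModelSpec(family="dense", width=2, seed=3, n_channels=2, grid_points=6)
    )
    x = rng.normal(size=(2, 2, 6, 6, 6))
    labels = np.array([True, False])
    true_aff = np.array([5.0, 7.0])

    def loss():
        logits, affinity = model.forward_batch(x)
        from minidock.cnn_models import _batch_losses

        ce, aff, dlogits, daff = _batch_losses(logits, affinity, labels, true_aff)
        return ce + aff, dlogits, daff

    value, dlogits, daff = loss()
    model.backward_batch(dlogits, daff)
    params = model.parameters()
    # probe a few parameters across layers
    rng2 = np.random.default_rng(1)
    h = 1e-6
    for w, g in [params[0], params[len(params) // 2], params[-2]]:
        idx = tuple(rng2.integers(s) for s in w.shape)
        orig = w[idx]
        w[idx] = orig + h
        up, _, _ = loss()
        w[idx] = orig - h
        dn, _, _ = loss()
        w[idx] = orig
        assert g[idx] == pytest.approx((up - dn) / (2 * h), rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

def test_zero_epochs_returns_initialized_model(separable_dataset):
    before = build_model(SMALL)
    snapshot = [w.copy() for w, _ in before.parameters()]
    model, history = train_model(before, separable_dataset[:8],
                                 TrainConfig(epochs=0))
    assert history["pose_loss"] == []
    for w_snap, (w, _) in zip(snapshot, model.parameters()):
        assert np.array_equal(w_snap, w)


def test_training_is_seed_reproducible(separable_dataset):
    subset = separable_dataset[:24]
    cfg = TrainConfig(epochs=2, lr=0.01, seed=5, batch_size=8)
    _, h1 = train_model(ModelSpec(width=2, seed=1, n_channels=8, grid_points=12),
                        subset, cfg)
    _, h2 = train_model(ModelSpec(width=2, seed=1, n_channels=8, grid_points=12),
                        subset, cfg)
    assert h1["pose_loss"][-1] == pytest.approx(h2["pose_loss"][-1], abs=1e-6)


def test_separable_set_reaches_95_percent_accuracy(separable_dataset):
    spec = ModelSpec(family="default2018", width=8, seed=1,
                     n_channels=8, grid_points=12)
    model, _ = train_model(spec, separable_dataset,
                           TrainConfig(epochs=10, lr=0.01, seed=0))
    grids, labels, _ = stack_grids(separable_dataset)
    logits, _ = model.forward_batch(grids)
    accuracy = ((logits[:, 1] > logits[:, 0]) == labels).mean()
    assert accuracy >= 0.95


def test_both_families_overfit_small_set(separable_dataset):
    subset = separable_dataset[:32]
    for family, width, epochs in (("default2018", 8, 30), ("dense", 3, 20)):
        spec = ModelSpec(family=family, width=width, seed=2,
                         n_channels=8, grid_points=12)
        _, history = train_model(
            spec, subset,
            TrainConfig(epochs=epochs, lr=0.05, seed=0, batch_size=16,
                        affinity_weight=0.1),
        )
        assert history["pose_loss"][-1] < 0.1, family


# ---------------------------------------------------------------------------
# ensembles / outputs
# ---------------------------------------------------------------------------

def test_pose_score_in_unit_interval_even_on_zero_grid():
    model = build_model(SMALL)
    out = model.score_grid(np.zeros((8, 12, 12, 12)))
    assert 0.0 < out.pose_score < 1.0


def test_ensemble_mean_and_symmetry(separable_dataset):
    grid = separable_dataset[0].grid
    members = [
        build_model(ModelSpec(width=2, seed=s, n_channels=8, grid_points=12))
        for s in range(3)
    ]
    single = ensemble_score(members[:1], grid)
    alone = members[0].score_grid(grid)
    assert single.pose_score == pytest.approx(alone.pose_score)
    fwd = ensemble_score(members, grid)
    rev = ensemble_score(members[::-1], grid)
    assert fwd.pose_score == pytest.approx(rev.pose_score)
    assert fwd.affinity == pytest.approx(rev.affinity)
    expected = np.mean([m.score_grid(grid).pose_score for m in members])
    assert fwd.pose_score == pytest.approx(expected)
    with pytest.raises(InputError):
        ensemble_score([], grid)


def test_checkpoint_roundtrip(tmp_path, separable_dataset):
    model, _ = train_model(SMALL, separable_dataset[:16],
                           TrainConfig(epochs=1, seed=0))
    path = str(tmp_path / "model.npz")
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    grid = separable_dataset[0].grid
    assert back.score_grid(grid).pose_score == pytest.approx(
        model.score_grid(grid).pose_score
    )
    assert back.spec == model.spec
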