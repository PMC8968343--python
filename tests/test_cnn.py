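"""Grader model: presets, loss closed forms, schedule, augmentation,
transfer initialisation, prediction and saliency contracts."""
import dataclasses

import numpy as np
import pytest

from vfgrade import nn
from vfgrade.cnn import (ModelConfig, PRESET_HFA, PRESET_OCTOPUS, TrainConfig,
                         augment_minority, build_model, evaluate_model,
                         fields_to_arrays, learning_rate_at, load_checkpoint,
                         loss, predict_proba, saliency, save_checkpoint,
                         stratified_split, train, transfer_init)
from vfgrade.simulate import generate_dataset
from vfgrade.voronoi import mask_array


@pytest.fixture(scope="module")
def small32():
    return build_model(ModelConfig.small(32), seed=0)


@pytest.fixture(scope="module")
def tiny_data():
    fields = generate_dataset(6, "HFA24_2", noise_sd=0.0, seed=40)
    X, y = fields_to_arrays(fields, size=32)
    return X, y


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_resnet34_preset_structure():
    model = build_model(ModelConfig.resnet34(), seed=0)
    blocks = [l for l in model.layers if isinstance(l, nn.ResidualBlock)]
    assert len(blocks) == 16
    assert blocks[0].conv1.cin == 64 and blocks[-1].conv2.cout == 512
    feats = np.zeros((1, 1, 224, 224), dtype=np.float32)
    for layer in model.layers[:-2]:
        feats = layer.forward(feats, training=False)
    assert feats.shape == (1, 512, 7, 7)


def test_resnet34_rejects_bad_input_size():
    with pytest.raises(ValueError, match="divisible by 32"):
        build_model(ModelConfig.resnet34(100))


def test_probabilities_sum_to_one(small32, tiny_data):
    X, _ = tiny_data
    p = predict_proba(small32, X[:7])
    assert p.shape == (7, 5)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# loss and schedule
# ---------------------------------------------------------------------------

def test_loss_closed_forms():
    y = np.array([[1.0, 0, 0, 0, 0]])
    assert loss(np.array([[1.0, 0, 0, 0, 0]]), y) == 0.0
    p = np.array([[0.5, 0.5, 0, 0, 0]])
    assert loss(p, y) == pytest.approx(np.log(2))
    # pure regularizer: lambda/2 * sum w^2
    w = [np.array([1.0, 1.0]), np.array([0.0])]  # sum of squares = 2
    assert loss(np.array([[1.0, 0, 0, 0, 0]]), y, lam=1e-4, weights=w) \
        == pytest.approx(1e-4)


def test_loss_clamps_zero_probability_with_warning():
    y = np.array([[0.0, 1, 0, 0, 0]])
    p = np.array([[1.0, 0, 0, 0, 0]])
    with pytest.warns(UserWarning, match="clamped"):
        value = loss(p, y)
    assert np.isfinite(value)


def test_loss_matches_scalar_loop_oracle():
    rng = np.random.default_rng(13)
    p = rng.dirichlet(np.ones(5), size=20)
    labels = rng.integers(0, 5, 20)
    y = np.zeros((20, 5))
    y[np.arange(20), labels] = 1
    total = 0.0
    for i in range(20):
        for c in range(5):
            total += y[i, c] * np.log(p[i, c])
    assert loss(p, y) == pytest.approx(-total / 20)


def test_learning_rate_schedule_probe_epochs():
    # 1-based probe epochs 1/41/81 under the Humphrey preset
    for epoch, lr in [(1, 1e-3), (41, 1e-4), (81, 1e-5)]:
        assert learning_rate_at(PRESET_HFA, epoch - 1) == pytest.approx(lr)
    assert learning_rate_at(PRESET_OCTOPUS, 0) == pytest.approx(1e-6)
    assert learning_rate_at(PRESET_OCTOPUS, 50) == pytest.approx(1e-7)


def test_training_presets_match_published_schedules():
    assert (PRESET_HFA.epochs, PRESET_HFA.batch_size, PRESET_HFA.lr0,
            PRESET_HFA.lr_step_epochs, PRESET_HFA.l2_lambda) \
        == (150, 8, 1e-3, 40, 1e-6)
    assert (PRESET_OCTOPUS.epochs, PRESET_OCTOPUS.batch_size,
            PRESET_OCTOPUS.lr0, PRESET_OCTOPUS.lr_step_epochs,
            PRESET_OCTOPUS.l2_lambda) == (500, 8, 1e-6, 50, 1e-4)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_balanced_input_returned_unchanged(tiny_data):
    X, y = tiny_data
    Xa, ya = augment_minority(X, y, target_count=6, seed=0)
    assert np.array_equal(Xa, X) and np.array_equal(ya, y)


def test_minority_upsampled_to_target_with_labels_kept(tiny_data):
    X, y = tiny_data
    keep = np.concatenate([np.flatnonzero(y == c)[:2 if c == 3 else 6]
                           for c in range(1, 6)])
    Xs, ys = X[keep], y[keep]
    Xa, ya = augment_minority(Xs, ys, target_count=6, seed=1)
    counts = {c: int((ya == c).sum()) for c in range(1, 6)}
    assert counts == {c: 6 for c in range(1, 6)}
    assert len(ya) == len(ys) + 4
    assert np.all(ya[len(ys):] == 3)


def test_augmented_images_keep_circular_mask(tiny_data):
    X, y = tiny_data
    keep = np.flatnonzero(y == 2)[:1]
    Xa, _ = augment_minority(X[keep], y[keep], target_count=30, seed=2)
    size = Xa.shape[-1]
    i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    outside = (i + 0.5 - size / 2) ** 2 + (j + 0.5 - size / 2) ** 2 \
        > (size / 2) ** 2
    for img in Xa[:, 0]:
        assert np.all(img[outside] == 0.0)


# ---------------------------------------------------------------------------
# training and transfer
# ---------------------------------------------------------------------------

def test_train_errors_on_missing_class(small32, tiny_data):
    X, y = tiny_data
    sel = y != 4
    cfg = TrainConfig(epochs=1, batch_size=8, lr0=1e-3, lr_step_epochs=10,
                      l2_lambda=0.0, seed=0)
    with pytest.raises(ValueError, match=r"\[4\]"):
        train(small32, (X[sel], y[sel]), (X, y), cfg)


def test_training_learns_separable_data_and_history_contract(tiny_data):
    X, y = tiny_data
    model = build_model(ModelConfig.small(32), seed=3)
    cfg = TrainConfig(epochs=20, batch_size=10, lr0=1e-3, lr_step_epochs=40,
                      l2_lambda=1e-6, seed=3)
    model, hist = train(model, (X, y), (X, y), cfg)
    assert len(hist["train_loss"]) == cfg.epochs
    assert hist["val_acc"][-1] >= 0.95
    # smoothed loss decreases over training on separable noiseless data
    smooth = np.convolve(hist["train_loss"], np.ones(5) / 5, mode="valid")
    assert smooth[-1] < smooth[0]
    assert hist["lr"][0] == pytest.approx(1e-3)


def test_transfer_init_copies_bit_exactly():
    a = build_model(ModelConfig.small(32), seed=4)
    b = build_model(ModelConfig.small(32), seed=5)
    transfer_init(b, a)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)
    # self-transfer is the identity
    before = [p.value.copy() for p in a.params()]
    transfer_init(a, a)
    for p, old in zip(a.params(), before):
        assert np.array_equal(p.value, old)


def test_transfer_init_rejects_mismatched_architectures():
    small = build_model(ModelConfig.small(32), seed=0)
    wide = build_model(ModelConfig("small", 32, 5, 24), seed=0)
    with pytest.raises(ValueError, match="mismatch"):
        transfer_init(small, wide)


def test_stratified_split_fractions():
    y = np.repeat([1, 2, 3, 4, 5], 20)
    tr, va, te = stratified_split(y, seed=0)
    assert len(tr) + len(va) + len(te) == 100
    assert sorted(np.concatenate([tr, va, te])) == list(range(100))
    for c in range(1, 6):
        assert 13 <= int((y[tr] == c).sum()) <= 15


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def test_predict_rejects_wrong_image_size(small32):
    with pytest.raises(ValueError, match="32x32"):
        predict_proba(small32, np.zeros((1, 1, 64, 64), dtype=np.float32))


def test_saliency_shape_range_and_gradient(small32, tiny_data):
    X, _ = tiny_data
    sal = saliency(small32, X[:1])
    assert sal.shape == (32, 32)
    assert sal.min() >= 0.0 and sal.max() <= 1.0
    assert sal.max() == pytest.approx(1.0)


def test_saliency_matches_finite_difference_on_tiny_model():
    rng = np.random.default_rng(14)
    model = nn.Sequential([
        nn.Conv2d(1, 2, 3, rng=rng, dtype=np.float64),
        nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Linear(2, 3, rng=rng, dtype=np.float64),
    ])
    model.config = ModelConfig("small", 8, 3, 2)
    x = rng.normal(size=(1, 1, 8, 8))
    logits = model.forward(x, training=False)
    c = int(np.argmax(logits[0]))
    dlogits = np.zeros_like(logits)
    dlogits[0, c] = 1.0
    dx = model.backward(dlogits)[0, 0]
    for idx in [(2, 3), (5, 5), (0, 7)]:
        h = 1e-6
        xp = x.copy()
        xp[0, 0][idx] += h
        lp = model.forward(xp, training=False)[0, c]
        xm = x.copy()
        xm[0, 0][idx] -= h
        lm = model.forward(xm, training=False)[0, c]
        fd = (lp - lm) / (2 * h)
        assert fd == pytest.approx(dx[idx], rel=1e-3, abs=1e-9)


def test_checkpoint_round_trip(tmp_path, small32, tiny_data):
    X, _ = tiny_data
    before = predict_proba(small32, X[:3])
    save_checkpoint(small32, tmp_path / "m.npz", train_config=PRESET_HFA,
                    metrics={"val_acc": 1.0}, seed=0)
    back = load_checkpoint(tmp_path / "m.npz")
    after = predict_proba(back, X[:3])
    assert np.allclose(before, after, atol=1e-6)
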