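"""Trainable residual grader: architecture presets, loss, training loop,
minority-class augmentation, transfer initialisation and saliency maps.

Two architecture presets are provided. ``resnet34`` is the classical
ResNet-34 layout: a 7x7 stride-2 stem convolution and 3x3 stride-2 max pool,
then 16 residual blocks growing the channels 64 -> 512 while the feature map
shrinks to 7x7 at input 224, then global average pooling, a fully connected
layer and softmax over the five severity categories. ``small`` is a
desk-scale variant (3x3 stride-1 stem at input 64, four residual blocks,
channels 16 -> 64) with the same block types, used for fast CPU experiments.

The loss is cross-entropy with an L2 term,
``-1/N sum_i sum_c y_ic log p_ic + lambda/2 sum_j w_j^2`` (natural log),
where the regularised weights are the convolution and fully connected
kernels. Two named training presets mirror the two-stage transfer workflow:
``hfa`` (150 epochs, batch 8, lr 1e-3 decayed x0.1 every 40 epochs, lambda
1e-6) for the large Humphrey corpus, and ``octopus`` (500 epochs, batch 8,
lr 1e-6 decayed x0.1 every 50 epochs, lambda 1e-4) for fine-tuning on the
smaller Octopus corpus after initialising from the Humphrey model.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .simulate import LabeledField
from .voronoi import VoronoiImage, mask_array, rasterize

LOG_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    depth_preset: str = "small"     # "resnet34" or "small"
    input_size: int = 64
    n_classes: int = 5
    channel_start: int = 16

    @staticmethod
    def resnet34(input_size: int = 224) -> "ModelConfig":
        return ModelConfig("resnet34", input_size, 5, 64)

    @staticmethod
    def small(input_size: int = 64) -> "ModelConfig":
        return ModelConfig("small", input_size, 5, 16)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int
    batch_size: int
    lr0: float
    lr_step_epochs: int
    l2_lambda: float
    lr_decay_factor: float = 0.1
    optimizer: str = "adam"
    seed: int = 0


#: training schedule for the large Humphrey dataset
PRESET_HFA = TrainConfig(epochs=150, batch_size=8, lr0=1e-3,
                         lr_step_epochs=40, l2_lambda=1e-6)
#: fine-tuning schedule for the smaller Octopus dataset
PRESET_OCTOPUS = TrainConfig(epochs=500, batch_size=8, lr0=1e-6,
                             lr_step_epochs=50, l2_lambda=1e-4)


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Learning rate for a 0-based epoch index: lr0 * decay^floor(e/step)."""
    return config.lr0 * config.lr_decay_factor ** (epoch // config.lr_step_epochs)


def build_model(config: ModelConfig, seed: int = 0,
                dtype=np.float32) -> nn.Sequential:
    """Construct a residual network per the preset; softmax applied downstream."""
    rng = np.random.default_rng(seed)
    c0 = config.channel_start
    if config.depth_preset == "resnet34":
        if config.input_size % 32:
            raise ValueError(
                f"resnet34 preset needs input_size divisible by 32, got "
                f"{config.input_size}")
        layers: list[nn.Layer] = [
            nn.Conv2d(1, c0, 7, stride=2, pad=3, rng=rng, dtype=dtype),
            nn.BatchNorm2d(c0, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        ]
        cin = c0
        for stage, n_blocks in enumerate([3, 4, 6, 3]):
            cout = c0 * 2 ** stage
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                layers.append(nn.ResidualBlock(cin, cout, stride, rng, dtype))
                cin = cout
    elif config.depth_preset == "small":
        if config.input_size % 4:
            raise ValueError(
                f"small preset needs input_size divisible by 4, got "
                f"{config.input_size}")
        layers = [
            nn.Conv2d(1, c0, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            nn.BatchNorm2d(c0, dtype=dtype),
            nn.ReLU(),
            nn.ResidualBlock(c0, c0, 1, rng, dtype),
            nn.ResidualBlock(c0, 2 * c0, 2, rng, dtype),
            nn.ResidualBlock(2 * c0, 4 * c0, 2, rng, dtype),
            nn.ResidualBlock(4 * c0, 4 * c0, 1, rng, dtype),
        ]
        cin = 4 * c0
    else:
        raise ValueError(f"unknown depth preset: {config.depth_preset}")
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Linear(cin, config.n_classes, rng=rng, dtype=dtype))
    model = nn.Sequential(layers)
    model.config = config
    return model


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def loss(p: np.ndarray, y: np.ndarray, lam: float = 0.0,
         weights: list[np.ndarray] | None = None) -> float:
    """Cross-entropy over predicted probabilities plus lambda/2 sum w^2.

    ``p`` is (N, M) with rows summing to 1, ``y`` the (N, M) one-hot labels.
    Probabilities at the true class equal to 0 are clamped at 1e-12 with a
    warning so the loss stays finite.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    true_p = (p * y).sum(axis=1)
    if np.any(true_p <= 0):
        warnings.warn("zero probability at the true class clamped at 1e-12",
                      stacklevel=2)
        true_p = np.maximum(true_p, LOG_EPS)
    value = -float(np.mean(np.log(true_p)))
    if lam and weights:
        value += lam / 2.0 * float(sum(np.sum(w.astype(float) ** 2)
                                       for w in weights))
    return value


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def fields_to_arrays(fields: list[LabeledField], size: int = 64
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize labelled fields into (N, 1, S, S) float32 in [0, 1] and
    integer category labels 1-5."""
    X = np.stack([rasterize(f.record, size=size).pixels for f in fields])
    y = np.array([f.label.category for f in fields], dtype=int)
    return (X[:, None, :, :].astype(np.float32) / 255.0), y


def stratified_split(y: np.ndarray, fractions=(0.7, 0.15, 0.15), seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified train/val/test index split."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y))
    train, rest = train_test_split(
        idx, test_size=1 - fractions[0], stratify=y, random_state=seed)
    rel = fractions[2] / (fractions[1] + fractions[2])
    val, test = train_test_split(
        rest, test_size=rel, stratify=y[rest], random_state=seed)
    return np.sort(train), np.sort(val), np.sort(test)


def augment_minority(X: np.ndarray, y: np.ndarray, target_count: int,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Upsample under-represented classes by vertical flip and +/-15 deg
    rotation until each class reaches ``target_count`` (training split only).

    Rotated rasters are zero-filled outside and re-masked so the
    out-of-circle-zero invariant is preserved; labels are unchanged. Classes
    already at or above the target are left untouched.
    """
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls in np.unique(y):
        have = int((y == cls).sum())
        if have >= target_count:
            continue
        pool = np.flatnonzero(y == cls)
        picks = rng.choice(pool, size=target_count - have, replace=True)
        for i in picks:
            img = X[i, 0]
            if rng.random() < 0.5:
                img = img[::-1, :]          # vertical flip (superior/inferior)
            angle = rng.uniform(-15.0, 15.0)
            img = ndimage.rotate(img, angle, reshape=False, order=1,
                                 mode="constant", cval=0.0)
            img = mask_array(np.clip(img, 0.0, 1.0))
            new_X.append(img[None, None].astype(X.dtype))
            new_y.append(np.array([cls]))
    return np.concatenate(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_loss_grad(model, Xb, yb, n_classes):
    logits = model.forward(Xb, training=True)
    probs = nn.softmax(logits)
    onehot = _one_hot(yb, n_classes)
    data_loss = -float(np.mean(np.log(
        np.maximum((probs * onehot).sum(axis=1), LOG_EPS))))
    dlogits = (probs - onehot).astype(logits.dtype) / len(yb)
    return data_loss, dlogits


def evaluate_model(model, X, y, batch_size: int = 64) -> tuple[float, float, np.ndarray]:
    """(mean data loss, accuracy, (N, M) probabilities) in eval mode."""
    n_classes = model.config.n_classes
    probs = predict_proba(model, X, batch_size=batch_size)
    onehot = _one_hot(np.asarray(y) - 1, n_classes)
    l = -float(np.mean(np.log(np.maximum((probs * onehot).sum(axis=1), LOG_EPS))))
    acc = float(np.mean(probs.argmax(axis=1) + 1 == np.asarray(y)))
    return l, acc, probs


def train(model, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray],
          config: TrainConfig) -> tuple[nn.Sequential, dict]:
    """Train with Adam on the Eq.-style cross-entropy + L2 objective.

    ``train_data``/``val_data`` are (X, y) with X of shape (N, 1, S, S) in
    [0, 1] and y integer categories 1..n_classes. Returns the model with its
    final-epoch weights and a history dict (per-epoch train loss, val loss,
    val accuracy, learning rate) that also records the best-validation
    epoch's weights.
    """
    Xtr, ytr = train_data
    Xva, yva = val_data
    n_classes = model.config.n_classes
    present = set(np.unique(ytr).tolist())
    missing = [c for c in range(1, n_classes + 1) if c not in present]
    if missing or len(ytr) == 0:
        raise ValueError(f"training data has no samples for class(es) {missing}")
    ytr0 = np.asarray(ytr) - 1
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), weight_decay=config.l2_lambda)
    history: dict = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best = (-1.0, None, -1)
    for epoch in range(config.epochs):
        lr = learning_rate_at(config, epoch)
        order = rng.permutation(len(ytr0))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            model.zero_grad()
            data_loss, dlogits = _forward_loss_grad(
                model, Xtr[sel], ytr0[sel], n_classes)
            model.backward(dlogits)
            opt.step(lr)
            losses.append(data_loss)
        val_loss, val_acc, _ = evaluate_model(model, Xva, yva)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(lr)
        if val_acc > best[0]:
            best = (val_acc, {k: v.copy() for k, v in model.state_arrays().items()},
                    epoch)
    history["best_val_acc"] = best[0]
    history["best_epoch"] = best[2]
    history["best_state"] = best[1]
    return model, history


def transfer_init(target: nn.Sequential, source: nn.Sequential) -> nn.Sequential:
    """Copy every parameter tensor (and batch-norm buffer) source -> target.

    Architectures must match exactly; any shape mismatch raises with the full
    list of offending tensors.
    """
    sp, tp = source.params(), target.params()
    mismatches = []
    if len(sp) != len(tp):
        raise ValueError(
            f"architectures differ: {len(sp)} vs {len(tp)} parameter tensors")
    for i, (s, t) in enumerate(zip(sp, tp)):
        if s.value.shape != t.value.shape:
            mismatches.append(f"param{i} ({s.name}): {s.value.shape} vs {t.value.shape}")
    if mismatches:
        raise ValueError("parameter shape mismatch: " + "; ".join(mismatches))
    target.load_state_arrays(source.state_arrays())
    return target


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _as_batch(image) -> np.ndarray:
    if isinstance(image, VoronoiImage):
        arr = np.asarray(image.pixels, dtype=np.float32) / 255.0
        return arr[None, None]
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return arr


def predict_proba(model, images, batch_size: int = 64) -> np.ndarray:
    """(N, n_classes) class probabilities (softmax over logits, eval mode)."""
    X = _as_batch(images)
    s = model.config.input_size
    if X.shape[-2:] != (s, s):
        raise ValueError(f"expected {s}x{s} images, got {X.shape[-2:]}")
    out = []
    for start in range(0, len(X), batch_size):
        logits = model.forward(X[start:start + batch_size], training=False)
        out.append(nn.softmax(logits))
    return np.concatenate(out)


def saliency(model, image) -> np.ndarray:
    """Input-gradient saliency of the predicted class.

    Absolute gradient of the predicted-class logit with respect to the input
    pixels, max-normalised to [0, 1]; same shape as the input image.
    """
    X = _as_batch(image)
    if len(X) != 1:
        raise ValueError("saliency takes a single image")
    s = model.config.input_size
    if X.shape[-2:] != (s, s):
        raise ValueError(f"expected {s}x{s} image, got {X.shape[-2:]}")
    logits = model.forward(X, training=False)
    c = int(np.argmax(logits[0]))
    dlogits = np.zeros_like(logits)
    dlogits[0, c] = 1.0
    dx = model.backward(dlogits)
    sal = np.abs(dx[0, 0])
    peak = sal.max()
    return (sal / peak if peak > 0 else sal).astype(np.float64)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, train_config: TrainConfig | None = None,
                    metrics: dict | None = None, seed: int | None = None) -> None:
    """Native .npz weights plus a JSON sidecar with config, seed and metrics."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_arrays())
    sidecar = {
        "model_config": asdict(model.config),
        "train_config": asdict(train_config) if train_config else None,
        "seed": seed,
        "metrics": metrics or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> nn.Sequential:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelConfig(**sidecar["model_config"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays(dict(data))
    return model
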