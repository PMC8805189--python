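"""Patch classifiers: architecture, augmentation, training and evaluation.

Two CNN classifiers drive the pipeline: a *first* classifier on 40x40
patches (sliding-window probability map) and a *refinement* classifier on
80x80 patches (second look at every candidate detection).  Both share the
same topology — four 7x7 convolutions (inputs padded by two zeros per
side), one 2x2 max pool, three fully connected layers, ReLU throughout,
dropout between the last two convolutions and between the FC layers —
trained with softmax cross-entropy and Adam (learning rate 2e-4 for the
first classifier, 4e-4 for the refinement one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from . import nn
from .synthetic import PatchDataset

__all__ = [
    "ClassifierConfig",
    "AugmentationSpec",
    "TrainHistory",
    "build_classifier",
    "augment_patch",
    "train_classifier",
    "select_best_epoch",
    "evaluate_patch_classifier",
    "predict_proba",
    "save_classifier",
    "load_classifier",
    "cross_validate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimization settings for one patch classifier.

    The defaults reproduce the published topology: 7x7 kernels, zero
    padding of 2, 16-32-64-128 filters, learning rate 2e-4 for a 40 px
    input and 4e-4 for an 80 px input.  FC widths, dropout rates, batch
    size and epoch count are artifact choices (not published) and are all
    exposed here.
    """

    input_side_px: int = 40
    kernel_size: int = 7
    conv_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    conv_zero_padding: int = 2
    fc_sizes: tuple[int, int, int] = (512, 128, 2)
    dropout_fc: float = 0.5
    dropout_conv: float = 0.25
    learning_rate: float | None = None
    batch_size: int = 64
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.input_side_px not in (40, 80):
            raise ValueError(f"input_side_px must be 40 or 80, got {self.input_side_px}")
        if len(self.conv_channels) != 4:
            raise ValueError("conv_channels must name four convolutional layers")
        if len(self.fc_sizes) != 3 or self.fc_sizes[-1] != 2:
            raise ValueError("fc_sizes must be three integers ending in 2")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def effective_learning_rate(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.0002 if self.input_side_px == 40 else 0.0004

    def conv_output_sides(self) -> list[int]:
        """Spatial side after each convolution: s -> s + 2*pad - k + 1."""
        sides = []
        s = self.input_side_px
        for _ in self.conv_channels:
            s = s + 2 * self.conv_zero_padding - self.kernel_size + 1
            sides.append(s)
        return sides

    @property
    def pooled_side(self) -> int:
        return self.conv_output_sides()[-1] // 2

    @property
    def flattened_size(self) -> int:
        return self.conv_channels[-1] * self.pooled_side ** 2

    @classmethod
    def published(cls, input_side_px: int = 40, **kwargs) -> "ClassifierConfig":
        return cls(input_side_px=input_side_px, **kwargs)

    @classmethod
    def desk_scale(cls, input_side_px: int = 40, **kwargs) -> "ClassifierConfig":
        """A narrow configuration that trains from scratch on one CPU in
        minutes; same topology, fewer filters."""
        defaults = dict(
            conv_channels=(6, 12, 12, 12),
            fc_sizes=(64, 32, 2),
            batch_size=64 if input_side_px == 40 else 16,
            max_epochs=8 if input_side_px == 40 else 5,
        )
        defaults.update(kwargs)
        return cls(input_side_px=input_side_px, **defaults)

    def with_(self, **kwargs) -> "ClassifierConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AugmentationSpec:
    """Training-time augmentation: rotation, brightness/contrast jitter and
    additive Gaussian noise components applied with given probabilities.

    ``rotation_amount`` is interpreted as a maximum rotation of +-10 degrees
    (reflect padding); ``jitter_amount`` 0.2 means up to 20% variation in
    brightness and contrast.  Saturation jitter is inert on single-channel
    images and is therefore not modeled.
    """

    rotation_amount_deg: float = 10.0
    jitter_amount: float = 0.2
    noise_components: tuple[tuple[float, float], ...] = ((0.1, 0.2), (0.05, 0.1))

    def __post_init__(self):
        for sigma, prob in self.noise_components:
            if sigma < 0 or not (0 <= prob <= 1):
                raise ValueError(f"invalid noise component (sigma={sigma}, p={prob})")

    @classmethod
    def first_default(cls) -> "AugmentationSpec":
        return cls()

    @classmethod
    def refine_default(cls) -> "AugmentationSpec":
        return cls(noise_components=((0.1, 0.1),))

    @classmethod
    def none(cls) -> "AugmentationSpec":
        return cls(rotation_amount_deg=0.0, jitter_amount=0.0, noise_components=())


@dataclass
class TrainHistory:
    """Per-epoch training diagnostics (metrics measured on the test set)."""

    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def build_classifier(config: ClassifierConfig) -> nn.Sequential:
    """Instantiate the CNN and verify the flattened feature size by an
    actual forward pass on a zero patch."""
    rng = np.random.default_rng(config.seed)
    c = config.conv_channels
    k, p = config.kernel_size, config.conv_zero_padding
    layers = [
        nn.Conv2D(1, c[0], k, p, rng), nn.ReLU(),
        nn.Conv2D(c[0], c[1], k, p, rng), nn.ReLU(),
        nn.Conv2D(c[1], c[2], k, p, rng), nn.ReLU(),
        nn.Dropout(config.dropout_conv),
        nn.Conv2D(c[2], c[3], k, p, rng), nn.ReLU(),
        nn.MaxPool2x2(),
        nn.Flatten(),
    ]
    model_head = nn.Sequential(layers)
    zero = np.zeros((1, 1, config.input_side_px, config.input_side_px), dtype=np.float32)
    measured = model_head.forward(zero).shape[1]
    if measured != config.flattened_size:
        raise ValueError(
            f"flattened feature size mismatch: computed {config.flattened_size}, "
            f"forward pass measured {measured}"
        )
    layers += [
        nn.Dense(config.flattened_size, config.fc_sizes[0], rng), nn.ReLU(),
        nn.Dropout(config.dropout_fc),
        nn.Dense(config.fc_sizes[0], config.fc_sizes[1], rng), nn.ReLU(),
        nn.Dropout(config.dropout_fc),
        nn.Dense(config.fc_sizes[1], config.fc_sizes[2], rng),
    ]
    meta = {
        "input_side_px": config.input_side_px,
        "kernel_size": k,
        "conv_channels": list(c),
        "conv_zero_padding": p,
        "fc_sizes": list(config.fc_sizes),
        "dropout_fc": config.dropout_fc,
        "dropout_conv": config.dropout_conv,
        "seed": config.seed,
    }
    return nn.Sequential(layers, meta=meta)


def config_from_meta(meta: dict) -> ClassifierConfig:
    return ClassifierConfig(
        input_side_px=meta["input_side_px"],
        kernel_size=meta["kernel_size"],
        conv_channels=tuple(meta["conv_channels"]),
        conv_zero_padding=meta["conv_zero_padding"],
        fc_sizes=tuple(meta["fc_sizes"]),
        dropout_fc=meta["dropout_fc"],
        dropout_conv=meta["dropout_conv"],
        seed=meta.get("seed", 0),
    )


def save_classifier(model: nn.Sequential, path) -> None:
    nn.save_model(model, path)


def load_classifier(path) -> nn.Sequential:
    return nn.load_model(path, lambda meta: build_classifier(config_from_meta(meta)))


# ---------------------------------------------------------------------------
# augmentation


def augment_patch(patch: np.ndarray, spec: AugmentationSpec, rng) -> np.ndarray:
    """Apply one random draw of the augmentation pipeline to a single patch.

    Deterministic given the generator state; a degenerate spec is the
    identity.  Output is clipped to [0, 1].
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = np.asarray(patch, dtype=np.float32)
    if spec.rotation_amount_deg > 0:
        angle = rng.uniform(-spec.rotation_amount_deg, spec.rotation_amount_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="reflect")
    if spec.jitter_amount > 0:
        j = spec.jitter_amount
        brightness = rng.uniform(1 - j, 1 + j)
        contrast = rng.uniform(1 - j, 1 + j)
        out = out * brightness
        mean = out.mean()
        out = mean + contrast * (out - mean)
    for sigma, prob in spec.noise_components:
        if rng.random() < prob:
            out = out + rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _augment_batch(batch: np.ndarray, spec: AugmentationSpec, rng) -> np.ndarray:
    return np.stack([augment_patch(p, spec, rng) for p in batch])


# ---------------------------------------------------------------------------
# training


def predict_proba(model: nn.Sequential, patches: np.ndarray,
                  batch_size: int | None = None) -> np.ndarray:
    """Positive-class probability for each patch (n, side, side).

    The default batch size keeps the im2col scratch buffers modest even
    for 80 px patches (they grow with batch x side^2).
    """
    patches = np.asarray(patches, dtype=np.float32)
    if patches.ndim == 2:
        patches = patches[None]
    if batch_size is None:
        side = patches.shape[-1]
        batch_size = max(8, min(256, int(2.6e8 / (4 * 600 * side * side))))
    out = np.empty(len(patches), dtype=np.float64)
    for i in range(0, len(patches), batch_size):
        chunk = patches[i : i + batch_size][:, None, :, :]
        out[i : i + len(chunk)] = nn.softmax(model.forward(chunk))[:, 1]
    return out


def _binary_metrics(labels: np.ndarray, predicted: np.ndarray):
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    accuracy = float(np.mean(labels == predicted))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return accuracy, precision, recall, f1


def train_classifier(
    model: nn.Sequential,
    train_set: PatchDataset,
    test_set: PatchDataset,
    config: ClassifierConfig,
    spec: AugmentationSpec | None = None,
    keep_snapshots: bool = True,
):
    """Train with Adam + cross-entropy, recording per-epoch history.

    Returns ``(history, snapshots)`` where ``snapshots[e]`` are the weights
    after epoch ``e`` (empty when ``keep_snapshots`` is False).  Combine
    with :func:`select_best_epoch` and ``model.set_weights`` to restore the
    selected epoch.  Fully seeded via ``config.seed``.
    """
    if spec is None:
        spec = AugmentationSpec.first_default()
    if len(np.unique(train_set.labels)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.effective_learning_rate)
    history = TrainHistory()
    snapshots: list[list[np.ndarray]] = []
    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _augment_batch(train_set.patches[idx], spec, rng)
            labels = train_set.labels[idx]
            logits = model.forward(batch[:, None, :, :], train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels)
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        # evaluation (no augmentation, no dropout)
        proba = predict_proba(model, test_set.patches)
        test_logloss = float(
            -np.mean(
                np.where(test_set.labels == 1, np.log(proba + 1e-12),
                         np.log(1 - proba + 1e-12))
            )
        )
        accuracy, precision, recall, f1 = _binary_metrics(
            test_set.labels, (proba >= 0.5).astype(int)
        )
        history.train_loss.append(float(np.mean(losses)))
        history.test_loss.append(test_logloss)
        history.accuracy.append(accuracy)
        history.precision.append(precision)
        history.recall.append(recall)
        history.f1.append(f1)
        if keep_snapshots:
            snapshots.append(model.get_weights())
        log.info(
            "epoch %d: train_loss=%.4f test_loss=%.4f f1=%.4f",
            epoch, history.train_loss[-1], test_logloss, f1,
        )
    return history, snapshots


def select_best_epoch(history: TrainHistory) -> int:
    """Epoch with the highest test F1 among epochs followed by three
    consecutive test-loss increases; falls back to the global F1 maximum
    (earliest on ties) with a warning if no epoch qualifies."""
    if len(history) == 0:
        raise ValueError("empty training history")
    f1 = np.asarray(history.f1)
    loss = np.asarray(history.test_loss)
    candidates = [
        e
        for e in range(len(history) - 3)
        if loss[e + 1] > loss[e] and loss[e + 2] > loss[e + 1] and loss[e + 3] > loss[e + 2]
    ]
    if candidates:
        best = max(candidates, key=lambda e: (f1[e], -e))
        return int(best)
    fallback = int(np.argmax(f1))
    log.warning(
        "no epoch followed by three consecutive loss increases; "
        "falling back to global-max-F1 epoch %d", fallback,
    )
    return fallback


def restore_best_epoch(model: nn.Sequential, history: TrainHistory,
                       snapshots: list[list[np.ndarray]]) -> int:
    epoch = select_best_epoch(history)
    if snapshots:
        model.set_weights(snapshots[epoch])
    return epoch


# ---------------------------------------------------------------------------
# evaluation


def auc_from_scores(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties get average ranks)."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_patch_classifier(model: nn.Sequential, test_set: PatchDataset) -> dict:
    """Accuracy/precision/recall/F1 at probability cutoff 0.5, plus AUC.

    AUC is reported as NaN for a single-class test set.
    """
    proba = predict_proba(model, test_set.patches)
    accuracy, precision, recall, f1 = _binary_metrics(
        test_set.labels, (proba >= 0.5).astype(int)
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": auc_from_scores(test_set.labels, proba),
    }


def cross_validate(
    dataset: PatchDataset,
    config: ClassifierConfig,
    spec: AugmentationSpec | None = None,
    n_folds: int = 4,
    seed: int = 0,
) -> list[dict]:
    """75/25-style k-fold cross-validation over a patch dataset."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    folds = np.array_split(order, n_folds)
    results = []
    for i, hold in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = build_classifier(config.with_(seed=config.seed + i))
        history, snaps = train_classifier(
            model, dataset.subset(train_idx), dataset.subset(hold), config, spec
        )
        restore_best_epoch(model, history, snaps)
        results.append(evaluate_patch_classifier(model, dataset.subset(hold)))
    return results
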