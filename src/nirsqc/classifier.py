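"""Segment-quality classification with a subject-wise training protocol.

The image classifier is a compact from-scratch CNN (see :mod:`nirsqc.nn`);
the protocol around it mirrors standard practice for subject-structured
data: subjects are first split into a development and a hold-out set,
cross-validation folds are formed over development subjects with greedy
stratification on each subject's low-quality fraction, and no subject's
samples ever span a train/evaluation boundary. Training uses Adam with
weighted cross-entropy, L2 weight decay, on-the-fly augmentation
(translation, scaling, random crop) and early stopping on validation
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from nirsqc.imageops import bilinear_resize, resize_rgb
from nirsqc.nn import Adam, SmallCNN, softmax, weighted_cross_entropy

LABELS = ("high", "low")  # class index 0 = high, 1 = low


@dataclass
class LabeledSample:
    image: np.ndarray  # (H, W, 3) in [0, 1]
    label: str
    subject_id: str
    channel_index: int
    segment_index: int


@dataclass
class SplitPlan:
    holdout_subjects: list[str]
    folds: list[list[str]]  # validation subjects per fold; union = development set

    @property
    def development_subjects(self) -> list[str]:
        return [s for fold in self.folds for s in fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for k, f in enumerate(self.folds) if k != fold for s in f]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch: int = 32
    max_epochs: int = 50
    l2: float = 1e-4
    patience: int = 15
    input_size: int = 112
    channels: tuple[int, ...] = (8, 16, 32)
    translate_x_px: int = 8
    translate_y_px: int = 2
    scale_range: tuple[float, float] = (0.9, 1.1)
    augment: bool = True
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.batch, self.max_epochs, self.l2, self.patience) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainLogEntry:
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainedModel:
    net: SmallCNN
    config: TrainConfig
    log: list[TrainLogEntry] = field(default_factory=list)
    train_subjects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _subject_low_fractions(samples: list[LabeledSample]) -> dict[str, float]:
    counts: dict[str, list[int]] = {}
    for s in samples:
        total = counts.setdefault(s.subject_id, [0, 0])
        total[0] += 1
        total[1] += int(s.label == "low")
    return {sid: lo / tot for sid, (tot, lo) in counts.items()}


def _stratified_order(samples: list[LabeledSample], seed: int) -> list[str]:
    """Subjects ordered by low-quality fraction, seeded jitter breaking ties."""
    fracs = _subject_low_fractions(samples)
    rng = np.random.default_rng(seed)
    jitter = {sid: rng.random() for sid in sorted(fracs)}
    return sorted(fracs, key=lambda sid: (fracs[sid], jitter[sid]))


def make_split(
    samples: list[LabeledSample], k: int, holdout_frac: float = 0.1, seed: int = 0
) -> SplitPlan:
    """Deterministic subject-wise stratified split plan.

    The stratification variable is each subject's low-quality fraction:
    subjects are sorted on it and dealt round-robin into holdout slots
    and folds, so every fold sees the full quality spectrum.
    """
    order = _stratified_order(samples, seed)
    n_holdout = int(round(len(order) * holdout_frac)) if holdout_frac > 0 else 0
    if len(order) - n_holdout < k:
        raise ValueError(
            f"{len(order)} subjects (minus {n_holdout} holdout) cannot form {k} folds"
        )
    holdout: list[str] = []
    if n_holdout:
        step = len(order) / n_holdout
        picks = {int(i * step + step / 2) for i in range(n_holdout)}
        holdout = [sid for i, sid in enumerate(order) if i in picks]
        while len(holdout) < n_holdout:  # collision guard
            extras = [sid for sid in order if sid not in holdout]
            holdout.append(extras[0])
    dev = [sid for sid in order if sid not in holdout]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, sid in enumerate(dev):
        # snake order keeps fold class balance close under sorted input
        cycle, pos = divmod(i, k)
        folds[pos if cycle % 2 == 0 else k - 1 - pos].append(sid)
    return SplitPlan(holdout_subjects=holdout, folds=folds)


def split_80_10_10(
    samples: list[LabeledSample], seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Subject-wise stratified train/val/test partition at 80:10:10."""
    order = _stratified_order(samples, seed)
    n = len(order)
    if n < 10:
        raise ValueError(f"need >= 10 subjects for an 80:10:10 split, got {n}")
    n_val = max(1, int(round(0.1 * n)))
    n_test = max(1, int(round(0.1 * n)))
    val, test, train = [], [], []
    for i, sid in enumerate(order):
        slot = i % 10
        if slot == 4 and len(val) < n_val:
            val.append(sid)
        elif slot == 9 and len(test) < n_test:
            test.append(sid)
        else:
            train.append(sid)
    # top up from train if rounding starved val/test
    while len(val) < n_val:
        val.append(train.pop())
    while len(test) < n_test:
        test.append(train.pop(0))
    return train, val, test


def class_weights(labels: list[str]) -> dict[str, float]:
    """Inverse-frequency weights, w_c = N / (2 * N_c); mean 1 when balanced."""
    n = len(labels)
    out = {}
    for cls in LABELS:
        n_c = sum(1 for label in labels if label == cls)
        if n_c == 0:
            raise ValueError(f"class {cls!r} absent; cannot weight a single class")
        out[cls] = n / (2.0 * n_c)
    return out


# ---------------------------------------------------------------------------
# tensors and augmentation
# ---------------------------------------------------------------------------


def _to_batch(samples: list[LabeledSample], size: int) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack(
        [
            img if img.shape[0] == size else resize_rgb(img, (size, size))
            for img in (s.image for s in samples)
        ]
    )
    y = np.array([LABELS.index(s.label) for s in samples])
    return imgs.transpose(0, 3, 1, 2), y  # NCHW


def _augment(img_chw: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Random scale, crop back to size, then translate (zero fill)."""
    size = img_chw.shape[1]
    out = img_chw
    scale = rng.uniform(*cfg.scale_range)
    new = max(8, int(round(size * scale)))
    if new != size:
        scaled = np.stack([bilinear_resize(c, (new, new)) for c in out])
        if new > size:  # random crop
            oy = rng.integers(0, new - size + 1)
            ox = rng.integers(0, new - size + 1)
            out = scaled[:, oy : oy + size, ox : ox + size]
        else:  # pad and place randomly
            canvas = np.zeros((out.shape[0], size, size))
            oy = rng.integers(0, size - new + 1)
            ox = rng.integers(0, size - new + 1)
            canvas[:, oy : oy + new, ox : ox + new] = scaled
            out = canvas
    # translations scale with the input size (defaults refer to 224 px)
    max_dx = max(1, round(cfg.translate_x_px * size / 224))
    max_dy = round(cfg.translate_y_px * size / 224)
    dx = int(rng.integers(-max_dx, max_dx + 1))
    dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy > 0 else 0
    if dx or dy:
        shifted = np.zeros_like(out)
        ys = slice(max(0, dy), size + min(0, dy))
        xs = slice(max(0, dx), size + min(0, dx))
        ys_src = slice(max(0, -dy), size + min(0, -dy))
        xs_src = slice(max(0, -dx), size + min(0, -dx))
        shifted[:, ys, xs] = out[:, ys_src, xs_src]
        out = shifted
    return out


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _evaluate(net: SmallCNN, x: np.ndarray, y: np.ndarray, weights: np.ndarray,
              batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for a in range(0, len(y), batch):
        xb, yb = x[a : a + batch], y[a : a + batch]
        logits = net.forward(xb, train=False)
        loss, _ = weighted_cross_entropy(logits, yb, weights)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(y)), correct / len(y)


def train(
    train_samples: list[LabeledSample],
    val_samples: list[LabeledSample],
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train the compact CNN with the full regularization protocol.

    Subject-leakage is asserted: a subject present in both the train and
    validation lists is an error.
    """
    config = config or TrainConfig()
    if not train_samples:
        raise ValueError("empty train fold")
    overlap = {s.subject_id for s in train_samples} & {
        s.subject_id for s in val_samples
    }
    if overlap:
        raise ValueError(f"subject leakage between train and validation: {sorted(overlap)}")

    rng = np.random.default_rng(config.seed)
    x_train, y_train = _to_batch(train_samples, config.input_size)
    x_val, y_val = _to_batch(val_samples, config.input_size)
    if config.class_weighting:
        cw = class_weights([s.label for s in train_samples])
        weights = np.array([cw[LABELS[0]], cw[LABELS[1]]])
    else:
        weights = np.ones(2)

    net = SmallCNN(config.input_size, channels=config.channels, seed=config.seed)
    opt = Adam(lr=config.lr, weight_decay=config.l2)

    best_acc = -1.0
    best_loss = math.inf
    best_state = None
    best_epoch = -1
    log: list[TrainLogEntry] = []
    n = len(y_train)

    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for a in range(0, n, config.batch):
            idx = perm[a : a + config.batch]
            xb = x_train[idx]
            if config.augment:
                xb = np.stack([_augment(img, config, rng) for img in xb])
            logits = net.forward(xb, train=True)
            loss, grad = weighted_cross_entropy(logits, y_train[idx], weights)
            net.backward(grad)
            opt.step(net.layers)
            epoch_losses.append(loss * len(idx))
        train_loss = float(np.sum(epoch_losses) / n)
        val_loss, val_acc = _evaluate(net, x_val, y_val, weights)
        log.append(TrainLogEntry(epoch, train_loss, val_loss, val_acc))
        improved = val_acc > best_acc or (val_acc == best_acc and val_loss < best_loss)
        if improved:
            best_acc, best_loss, best_epoch = val_acc, val_loss, epoch
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}
        elif epoch - best_epoch >= config.patience:
            break

    if best_state is not None:
        for li, layer in enumerate(net.layers):
            for name in getattr(layer, "params", {}):
                layer.params[name][...] = best_state[f"layer{li}_{name}"]
            if hasattr(layer, "running_mean"):
                layer.running_mean[...] = best_state[f"layer{li}_running_mean"]
                layer.running_var[...] = best_state[f"layer{li}_running_var"]

    return TrainedModel(
        net=net,
        config=config,
        log=log,
        train_subjects=sorted({s.subject_id for s in train_samples}),
    )


def predict(model: TrainedModel, images: list[np.ndarray] | np.ndarray,
            batch: int = 64) -> list[tuple[str, float]]:
    """(label, p_low) per image; deterministic given the model."""
    size = model.config.input_size
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    prepared = []
    for img in images:
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
        if img.shape[0] != size:
            img = resize_rgb(img, (size, size))
        prepared.append(img.transpose(2, 0, 1))
    x = np.stack(prepared)
    out: list[tuple[str, float]] = []
    for a in range(0, len(x), batch):
        p = softmax(model.net.forward(x[a : a + batch], train=False))
        for row in p:
            out.append((LABELS[int(row.argmax())], float(row[1])))
    return out


def predict_samples(model: TrainedModel, samples: list[LabeledSample]) -> list[str]:
    return [label for label, _ in predict(model, [s.image for s in samples])]


def channel_quality_percentage(predictions: dict[int, list[str]]) -> dict[int, float]:
    """100 * (#predicted high) / (#segments) per channel, exact before float."""
    out = {}
    for ch, labels in predictions.items():
        if not labels:
            raise ValueError(f"channel {ch} has no segments")
        n_high = sum(1 for label in labels if label == "high")
        out[ch] = float(Fraction(100 * n_high, len(labels)))
    return out
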