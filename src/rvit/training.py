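"""Dataset loading, stratified splitting, Adam training loop, evaluation.

Training hyperparameters default to the reference configuration: Adam with
learning rate 1e-3 and weight decay 1e-2, batch size 32, 25 epochs, and an
80/20 stratified train/validation split. All randomness (split, shuffling,
dropout) is driven by the config seed, so a run is reproducible on one
device.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .metrics import ConfusionMatrix
from .models import RViT
from .nn import Adam, cross_entropy
from .synthetic import confusion_from_predictions

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "LabelledImages", "load_image_folder",
           "split_train_val", "train", "evaluate", "write_history_csv"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 32
    epochs: int = 25
    split_fraction: float = 0.8
    grad_clip: float = 1.0   # global gradient-norm ceiling; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")


@dataclass
class LabelledImages:
    """Images (n, S, S, C) in [0, 1] with integer labels and class names."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    files: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "LabelledImages":
        files = tuple(self.files[i] for i in idx) if self.files else ()
        return LabelledImages(self.images[idx], self.labels[idx],
                              self.class_names, files)


def load_image_folder(root, image_size: int, channels: int = 3
                      ) -> LabelledImages:
    """Load a directory-per-class image tree into memory.

    Class subdirectories and the files inside them are taken in
    lexicographic order, so repeated loads give identical ordering and
    labelling. Images are decoded with Pillow, converted to grayscale or
    RGB according to ``channels``, resized (bilinear, aspect not
    preserved) to ``image_size`` square, and scaled to [0, 1]. Unreadable
    files are skipped with a warning; an empty class directory is an error.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    mode = "L" if channels == 1 else "RGB"
    images, labels, files = [], [], []
    for label, cdir in enumerate(class_dirs):
        entries = sorted(
            f for f in cdir.iterdir()
            if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not entries:
            raise ValueError(f"class directory {cdir} contains no images")
        for f in entries:
            try:
                with Image.open(f) as im:
                    im = im.convert(mode).resize(
                        (image_size, image_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float32) / 255.0
            except Exception as exc:  # corrupt file: skip, keep going
                logger.warning("skipping unreadable image %s: %s", f, exc)
                warnings.warn(f"skipping unreadable image {f}: {exc}")
                continue
            if channels == 1:
                arr = arr[:, :, None]
            images.append(arr)
            labels.append(label)
            files.append(str(f.relative_to(root)))
    return LabelledImages(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        class_names=tuple(d.name for d in class_dirs),
        files=tuple(files),
    )


def split_train_val(labels: np.ndarray, fraction: float, seed: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, seeded index split; train gets floor(fraction*n) per class.

    Returns (train_idx, val_idx): disjoint, exhaustive, and reproducible
    for a fixed seed. Classes with fewer than two members cannot be split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 items; cannot split")
        perm = rng.permutation(idx)
        n_train = int(np.floor(fraction * len(idx)))
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_parts))
    val_idx = np.sort(np.concatenate(val_parts))
    return train_idx, val_idx


def _clip_gradients(model: RViT, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most ``max_norm``.

    Tiny-batch transformer training from a cold start occasionally produces
    a gradient spike large enough to throw Adam out of a learned basin;
    capping the global norm removes those excursions without changing
    well-scaled steps.
    """
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in model.parameters()))
    if total > max_norm:
        scale = max_norm / total
        for p in model.parameters():
            p.grad *= scale


def _epoch_pass(model: RViT, images, labels, batch_size, optimizer=None,
                shuffle_rng=None, grad_clip: float = 0.0):
    """One pass over the data; trains when an optimizer is given."""
    n = len(labels)
    order = (shuffle_rng.permutation(n) if shuffle_rng is not None
             else np.arange(n))
    total_loss, correct = 0.0, 0
    training = optimizer is not None
    for start in range(0, n, batch_size):
        sel = order[start:start + batch_size]
        logits = model.forward(images[sel], training=training)
        loss, dlogits = cross_entropy(logits, labels[sel])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss {loss} at samples "
                f"{sel[:5]}..."
            )
        total_loss += loss * len(sel)
        correct += int(np.sum(np.argmax(logits, axis=1) == labels[sel]))
        if training:
            model.zero_grad()
            model.backward(dlogits)
            if grad_clip > 0:
                _clip_gradients(model, grad_clip)
            optimizer.step()
    model.clear_caches()  # release the last batch's activations
    return total_loss / n, correct / n


@dataclass
class History:
    """Per-epoch training curves plus the best-validation checkpoint."""

    rows: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0
    best_state: dict | None = None

    def append(self, **row) -> None:
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)


def train(model: RViT, train_set: LabelledImages, val_set: LabelledImages,
          config: TrainConfig, verbose: bool = False) -> History:
    """Minimize cross-entropy with Adam; returns per-epoch history.

    The model state with the best validation accuracy is kept in
    ``history.best_state`` and restored into the model at the end, so the
    returned model is the best-validation checkpoint (the final-epoch
    metrics remain in the history).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    model.reseed_dropout(config.seed)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = History()
    for epoch in range(config.epochs):
        train_loss, train_acc = _epoch_pass(
            model, train_set.images, train_set.labels, config.batch_size,
            optimizer=optimizer, shuffle_rng=shuffle_rng,
            grad_clip=config.grad_clip)
        val_loss, val_acc = _epoch_pass(
            model, val_set.images, val_set.labels, config.batch_size)
        history.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss,
                       train_acc=train_acc, val_acc=val_acc)
        if val_acc > history.best_val_acc:
            history.best_val_acc = val_acc
            history.best_epoch = epoch
            history.best_state = model.state_dict()
        if verbose:
            logger.info(
                "epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                epoch, train_loss, train_acc, val_loss, val_acc)
    if history.best_state is not None:
        model.load_state_dict(history.best_state)
    return history


def evaluate(model: RViT, dataset: LabelledImages, batch_size: int = 32,
             positive_label: int = 1) -> ConfusionMatrix:
    """Argmax predictions over the dataset, tallied into a confusion matrix.

    The model runs in eval mode (dropout off). ``positive_label`` names the
    tumor class index (1 under the package's class-naming convention).
    """
    preds = []
    for start in range(0, len(dataset), batch_size):
        logits = model.forward(dataset.images[start:start + batch_size],
                               training=False)
        preds.append(np.argmax(logits, axis=1))
    if hasattr(model, "clear_caches"):
        model.clear_caches()
    preds = np.concatenate(preds)
    if positive_label == 1:
        return confusion_from_predictions(preds, dataset.labels)
    return confusion_from_predictions(1 - preds, 1 - dataset.labels)


def write_history_csv(history: History, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "train_loss", "val_loss",
                            "train_acc", "val_acc"])
        writer.writeheader()
        for row in history.rows:
            writer.writerow(row)
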