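"""Axial slice segmentation at the L1 and L3 vertebral levels.

The L1 slice is windowed to [-1024, 500] HU (bone contrast) and fed to
a 3-class U-Net (background / trabecular / cortical).  The L3 slice is
windowed to [-1024, 2048] (full contrast), [-190, -30] (fat) and
[40, 100] (muscle) HU, stacked as three channels, and fed to a 4-class
U-Net (background / SMA / VAT / SAT).  Classes are mutually exclusive
via a single channel softmax; masks are the per-pixel argmax with ties
resolved toward the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .nn import UNet, ce_dice_loss, predict_batched, train_model
from .volume_io import AIR_HU

L1_WINDOW: tuple[float, float] = (-1024, 500)
L3_WINDOWS: tuple[tuple[float, float], ...] = ((-1024, 2048), (-190, -30), (40, 100))
DEFAULT_SLICE_GRID = 512

L1_CLASSES: tuple[str, ...] = ("background", "trabecular", "cortical")
L3_CLASSES: tuple[str, ...] = ("background", "sma", "vat", "sat")
CLASS_VOCAB = {"L1": L1_CLASSES, "L3": L3_CLASSES}


@dataclass
class SlabSlice:
    """One axial CT slice prepared for segmentation (square, /16 grid)."""

    hu: np.ndarray
    spacing: tuple[float, float]
    level: str  # "L1" | "L3"
    subject_id: str = ""

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=np.float32)
        if self.level not in CLASS_VOCAB:
            raise ValueError(f"level must be 'L1' or 'L3', got {self.level!r}")
        if self.hu.ndim != 2 or self.hu.shape[0] != self.hu.shape[1]:
            raise ValueError(f"slice must be square 2D, got {self.hu.shape}")
        if self.hu.shape[0] % 16 != 0:
            raise ValueError(f"slice size {self.hu.shape[0]} not divisible by 16")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("pixel spacing must be positive")


@dataclass
class LabelMask:
    """Per-pixel class mask over one slice; classes from the level vocabulary."""

    labels: np.ndarray
    level: str
    subject_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        vocab = CLASS_VOCAB.get(self.level)
        if vocab is None:
            raise ValueError(f"unknown level {self.level!r}")
        if self.labels.min() < 0 or self.labels.max() >= len(vocab):
            raise ValueError(f"labels outside {self.level} vocabulary {vocab}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return CLASS_VOCAB[self.level]

    def class_index(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in {self.level} vocabulary") from None

    def binary(self, name: str) -> np.ndarray:
        return self.labels == self.class_index(name)


def to_grid(hu: np.ndarray, size: int = DEFAULT_SLICE_GRID, fill: float = AIR_HU) -> np.ndarray:
    """Center-pad (with air) or center-crop a slice to `size` x `size`."""
    out = np.full((size, size), fill, dtype=np.float32)
    h, w = hu.shape
    # source and destination windows
    sy, dy = (max(0, (h - size) // 2), max(0, (size - h) // 2))
    sx, dx = (max(0, (w - size) // 2), max(0, (size - w) // 2))
    ch, cw = min(h, size), min(w, size)
    out[dy:dy + ch, dx:dx + cw] = hu[sy:sy + ch, sx:sx + cw]
    return out


def _apply_windows(hu: np.ndarray, windows) -> np.ndarray:
    chans = [np.clip((hu - lo) / (hi - lo), 0.0, 1.0) for lo, hi in windows]
    return np.stack(chans, axis=-1).astype(np.float32)


def preprocess_l1(slc: SlabSlice) -> np.ndarray:
    """L1 slice -> 1-channel [0,1] bone-window image."""
    if slc.level != "L1":
        raise ValueError(f"preprocess_l1 expects an L1 slice, got {slc.level}")
    return _apply_windows(slc.hu, [L1_WINDOW])


def preprocess_l3(slc: SlabSlice) -> np.ndarray:
    """L3 slice -> 3-channel [0,1] image (full-contrast, fat, muscle windows)."""
    if slc.level != "L3":
        raise ValueError(f"preprocess_l3 expects an L3 slice, got {slc.level}")
    return _apply_windows(slc.hu, L3_WINDOWS)


def predict_mask(model, image: np.ndarray, level: str, subject_id: str = "") -> LabelMask:
    """Argmax class mask from a trained segmentation model.

    `image` is the preprocessed (H, W, C) input.  np.argmax resolves
    exact probability ties toward the lower class index.
    """
    probs = predict_batched(model, image.transpose(2, 0, 1)[None])[0]
    if probs.shape[1:] != image.shape[:2]:
        raise ValueError("model output shape does not match the input slice")
    labels = np.argmax(probs, axis=0).astype(np.int32)
    return LabelMask(labels=labels, level=level, subject_id=subject_id)


def vdsc(pred: LabelMask, truth: LabelMask, class_name: str) -> float:
    """Dice similarity 2|P∩T|/(|P|+|T|) for one class; both-empty -> 1."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError("mask shapes differ")
    p = pred.binary(class_name)
    t = truth.binary(class_name)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


class SliceSegmenter(BaseEstimator):
    """sklearn-style estimator segmenting one vertebral level's slices.

    ``level="L1"`` trains the 3-class bone model; ``level="L3"`` the
    4-class tissue model.  `fit` takes lists of SlabSlice and LabelMask.
    """

    def __init__(self, level: str = "L3", base_filters: int = 8, epochs: int = 40,
                 batch_size: int = 4, lr: float = 2e-3, val_fraction: float = 0.0,
                 patience: int = 0, seed: int = 0):
        self.level = level
        self.base_filters = base_filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    def _preprocess(self, slc: SlabSlice) -> np.ndarray:
        return preprocess_l1(slc) if self.level == "L1" else preprocess_l3(slc)

    @property
    def classes_(self) -> tuple[str, ...]:
        return CLASS_VOCAB[self.level]

    def fit(self, X, y):
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        n_classes = len(CLASS_VOCAB[self.level])
        inputs = np.stack([self._preprocess(s).transpose(2, 0, 1) for s in X])
        onehot = np.stack([
            np.eye(n_classes, dtype=np.float32)[m.labels].transpose(2, 0, 1) for m in y
        ])
        self.model_ = UNet(in_ch=inputs.shape[1], n_classes=n_classes,
                           base_filters=self.base_filters, seed=self.seed)
        self.history_ = train_model(
            self.model_, inputs, onehot, ce_dice_loss,
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            seed=self.seed, val_fraction=self.val_fraction, patience=self.patience)
        return self

    def predict_one(self, slc: SlabSlice) -> LabelMask:
        return predict_mask(self.model_, self._preprocess(slc), self.level,
                            subject_id=slc.subject_id)

    def predict(self, X):
        return [self.predict_one(s) for s in X]
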