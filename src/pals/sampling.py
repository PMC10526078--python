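"""Pixel-level dataset assembly, class balancing and block-wise splits."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pals.core_io import (
    ABLATED,
    NON_ABLATED,
    STATE_MAX_NORMALIZED,
    UNLABELED,
    Frame,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class PixelDataset:
    """Labeled pixels as rows: normalized spectra + binary labels + provenance."""

    features: np.ndarray  # N x Lambda, in [0, 1]
    labels: np.ndarray  # N, 1 = ablated, 0 = non-ablated
    block_ids: np.ndarray  # N object/str
    frame_ids: np.ndarray  # N int

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.block_ids) == len(self.frame_ids) == n):
            raise ValidationError("dataset columns must share length")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights: non-ablated fixed at 1, unlabeled at 0."""

    w_ablated: float
    w_nonablated: float = 1.0
    w_unlabeled: float = 0.0


def extract_pixels(frames: list[Frame]) -> PixelDataset:
    """One row per labeled (non-unlabeled) pixel of each preprocessed frame."""
    feats, labels, blocks, frame_ids = [], [], [], []
    for i, frame in enumerate(frames):
        if frame.cube.state != STATE_MAX_NORMALIZED:
            raise ValidationError(
                f"frame {i} not preprocessed (state {frame.cube.state!r})"
            )
        codes = frame.mask.codes
        labeled = codes != UNLABELED
        if not labeled.any():
            continue
        feats.append(frame.cube.intensities[labeled])
        labels.append((codes[labeled] == ABLATED).astype(np.int8))
        n = int(labeled.sum())
        blocks.append(np.full(n, frame.block_id, dtype=object))
        frame_ids.append(np.full(n, i, dtype=np.int64))
    if not feats:
        empty = np.empty((0, 0))
        return PixelDataset(empty, np.empty(0, np.int8), np.empty(0, object),
                            np.empty(0, np.int64))
    return PixelDataset(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        block_ids=np.concatenate(blocks),
        frame_ids=np.concatenate(frame_ids),
    )


def balance(dataset: PixelDataset, seed: int = 0) -> PixelDataset:
    """Per-frame under-sampling of the non-ablated class.

    All ablated rows are kept; for each frame an equal number of non-ablated
    rows is drawn without replacement.  Frames with no ablated pixels
    contribute nothing (logged).
    """
    if not np.any(dataset.labels == 1):
        raise ValidationError("balance requires at least one ablated pixel")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for fid in np.unique(dataset.frame_ids):
        in_frame = np.nonzero(dataset.frame_ids == fid)[0]
        pos = in_frame[dataset.labels[in_frame] == 1]
        neg = in_frame[dataset.labels[in_frame] == 0]
        if pos.size == 0:
            log.info("frame %s has no ablated pixels; skipped in balancing", fid)
            continue
        if neg.size <= pos.size:
            log.info(
                "frame %s has fewer non-ablated (%d) than ablated (%d) pixels",
                fid, neg.size, pos.size,
            )
            chosen_neg = neg
        else:
            chosen_neg = rng.choice(neg, size=pos.size, replace=False)
        keep.append(pos)
        keep.append(np.sort(chosen_neg))
    idx = np.concatenate(keep)
    return PixelDataset(
        features=dataset.features[idx],
        labels=dataset.labels[idx],
        block_ids=dataset.block_ids[idx],
        frame_ids=dataset.frame_ids[idx],
    )


def subsample(dataset: PixelDataset, n_max: int, seed: int = 0) -> PixelDataset:
    """Random row subsample without replacement (identity if already small)."""
    if len(dataset) <= n_max:
        return dataset
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(dataset), size=n_max, replace=False))
    return PixelDataset(
        features=dataset.features[idx],
        labels=dataset.labels[idx],
        block_ids=dataset.block_ids[idx],
        frame_ids=dataset.frame_ids[idx],
    )


def split_blocks(
    frames: list[Frame], n_train: int, n_test: int, seed: int = 0
) -> tuple[list[Frame], list[Frame]]:
    """Partition frames by tissue block: all frames of a block land on the
    same side of the split."""
    blocks = sorted({f.block_id for f in frames})
    if n_train + n_test != len(blocks):
        raise ValidationError(
            f"n_train + n_test = {n_train + n_test} != {len(blocks)} blocks"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(blocks))
    train_blocks = set(order[:n_train])
    train = [f for f in frames if f.block_id in train_blocks]
    test = [f for f in frames if f.block_id not in train_blocks]
    return train, test


def class_weights(frames: list[Frame]) -> ClassWeights:
    """Loss weights: ablated weight is the non-ablated:ablated pixel ratio
    over the whole frame set."""
    n_abl = sum(f.mask.count(ABLATED) for f in frames)
    n_non = sum(f.mask.count(NON_ABLATED) for f in frames)
    if n_abl == 0:
        raise ValidationError("class_weights requires at least one ablated pixel")
    return ClassWeights(w_ablated=n_non / n_abl)
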