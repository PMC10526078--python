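"""Segmentation metrics restricted to labeled pixels.

recall = TP / (TP + FN), precision = TP / (TP + FP),
F1 = 2 * recall * precision / (recall + precision);
degenerate zero denominators yield 0.  An algorithm's score is the
unweighted mean of its per-frame F1 over test frames that contain at least
one ablated labeled pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pals.core_io import ABLATED, NON_ABLATED, LabelMask, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Confusion:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_labeled(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    recall: float
    precision: float
    f1: float


def confusion(decision: np.ndarray, mask: LabelMask) -> Confusion:
    """Pixel confusion counts; unlabeled pixels are excluded entirely."""
    decision = np.asarray(decision)
    if decision.shape != mask.codes.shape:
        raise ValidationError(
            f"prediction shape {decision.shape} != mask shape {mask.codes.shape}"
        )
    pred = decision.astype(bool)
    is_abl = mask.codes == ABLATED
    is_non = mask.codes == NON_ABLATED
    return Confusion(
        tp=int(np.count_nonzero(is_abl & pred)),
        tn=int(np.count_nonzero(is_non & ~pred)),
        fp=int(np.count_nonzero(is_non & pred)),
        fn=int(np.count_nonzero(is_abl & ~pred)),
    )


def metrics(c: Confusion) -> Metrics:
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    f1 = (
        2.0 * recall * precision / (recall + precision)
        if (recall + precision) > 0
        else 0.0
    )
    return Metrics(recall=recall, precision=precision, f1=f1)


def frame_f1(decision: np.ndarray, mask: LabelMask) -> float:
    return metrics(confusion(decision, mask)).f1


def score_algorithm(decisions: list[np.ndarray], masks: list[LabelMask]) -> float:
    """Mean per-frame F1 over frames with at least one ablated labeled pixel."""
    if len(decisions) != len(masks):
        raise ValidationError("decisions and masks must pair up")
    scores = []
    for i, (dec, mask) in enumerate(zip(decisions, masks)):
        if mask.count(ABLATED) == 0:
            log.info("frame %d has no ablated labeled pixels; skipped", i)
            continue
        scores.append(frame_f1(dec, mask))
    if not scores:
        raise ValidationError("no evaluable frames (none contain ablated pixels)")
    return float(np.mean(scores))


def grid_table(
    scores: dict[int, dict[str, float]], percent: bool = True
) -> pd.DataFrame:
    """Model x wavelength-count F1 grid, rows sorted by descending count."""
    rows = sorted(scores, reverse=True)
    df = pd.DataFrame.from_dict(scores, orient="index").loc[rows]
    df.index.name = "n_wavelengths"
    if percent:
        df = (df * 100.0).round(2)
    return df


def decrease_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-row F1 decreases (row k minus row k+1)."""
    counts = list(grid.index)
    rows = {}
    for a, b in zip(counts[:-1], counts[1:]):
        rows[f"from {a} to {b}"] = grid.loc[a] - grid.loc[b]
    return pd.DataFrame.from_dict(rows, orient="index")
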