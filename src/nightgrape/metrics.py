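"""Evaluation arithmetic: area percentages, confusion tables, error bins.

Segmentation quality is scored per image by the percentage of correct
area, PCA = 100 * tp / (tp + fn) (fruit pixels recovered over all true
fruit pixels), and the percentage of false area, PFA = 100 * fp /
(tp + fp) (false fruit pixels over all pixels predicted fruit).  Batches
are summarized by binning PCA into >90 / 70-90 / <70 and PFA into <5 /
5-15 / >15 percent.  A picking point is successful when its horizontal
distance to the true stem at the point's row is at most 5 pixels; batches
are binned into exact / 1-5 px / >5 px errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .levelset import BinaryMask
from .picking import LineSegment, PickingResult
from .preprocessing import InvalidInputError

SUCCESS_PIXELS = 5.0  # inclusive horizontal-error bound for a valid point


@dataclass(frozen=True)
class SegmentationEval:
    """Pixel confusion counts and the two area percentages for one image."""

    tp: int
    fp: int
    fn: int
    tn: int
    pca: float
    pfa: float
    empty_prediction: bool = False

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, tn: int = 0
    ) -> "SegmentationEval":
        pca = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        empty = (tp + fp) == 0
        pfa = 0.0 if empty else 100.0 * fp / (tp + fp)
        return cls(tp, fp, fn, tn, pca, pfa, empty_prediction=empty)


@dataclass(frozen=True)
class PickingEval:
    horizontal_error: float
    success: bool

    @property
    def error_bin(self) -> str:
        """Table-style bin: '0', '1-5' or '>5'."""
        if self.horizontal_error <= 0.5:
            return "0"
        if self.horizontal_error <= SUCCESS_PIXELS:
            return "1-5"
        return ">5"


def evaluate_segmentation(pred: BinaryMask, truth: BinaryMask) -> SegmentationEval:
    """Exhaustive pixel comparison of predicted vs. true fruit masks."""
    if pred.labels.shape != truth.labels.shape:
        raise InvalidInputError(
            f"shape mismatch: {pred.labels.shape} vs {truth.labels.shape}"
        )
    p, t = pred.labels, truth.labels
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return SegmentationEval.from_counts(tp, fp, fn, tn)


def iou(pred: BinaryMask, truth: BinaryMask) -> float:
    """Intersection over union of the foregrounds."""
    p, t = pred.labels, truth.labels
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union


def confusion_row_rates(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Row-normalized confusion percentages (fruit row, background row).

    This is the presentation used for pixel-level detection tables:
    each true class row is normalized by its own total, so the fruit row
    carries PCA and the background row the background false/correct rates.
    """
    fruit_total = tp + fn
    bg_total = fp + tn
    return {
        "fruit_correct_pct": 100.0 * tp / fruit_total if fruit_total else 0.0,
        "fruit_missed_pct": 100.0 * fn / fruit_total if fruit_total else 0.0,
        "background_false_pct": 100.0 * fp / bg_total if bg_total else 0.0,
        "background_correct_pct": 100.0 * tn / bg_total if bg_total else 0.0,
    }


def classification_accuracy(tp: int, fn: int, fp: int, tn: int) -> float:
    """Fraction of correctly classified items in a 2x2 confusion table."""
    n = tp + fn + fp + tn
    if n == 0:
        raise InvalidInputError("empty confusion table")
    return (tp + tn) / n


def bin_pca_pfa(evals: Sequence[SegmentationEval]) -> dict:
    """Batch summary: PCA bins >90 / 70-90 / <70, PFA bins <5 / 5-15 / >15.

    Boundary closure: PCA >= 90 lands in the top bin and 70 <= PCA < 90 in
    the middle one; PFA <= 5 lands in the best bin and 5 < PFA <= 15 in
    the middle one.
    """
    n = len(evals)
    pca_bins = [0, 0, 0]
    pfa_bins = [0, 0, 0]
    for e in evals:
        if e.pca >= 90.0:
            pca_bins[0] += 1
        elif e.pca >= 70.0:
            pca_bins[1] += 1
        else:
            pca_bins[2] += 1
        if e.pfa <= 5.0:
            pfa_bins[0] += 1
        elif e.pfa <= 15.0:
            pfa_bins[1] += 1
        else:
            pfa_bins[2] += 1
    return {
        "n": n,
        "pca_counts": {">90": pca_bins[0], "70-90": pca_bins[1], "<70": pca_bins[2]},
        "pfa_counts": {"<5": pfa_bins[0], "5-15": pfa_bins[1], ">15": pfa_bins[2]},
        "pca_ratios_pct": bin_ratios_pct(pca_bins, n),
        "pfa_ratios_pct": bin_ratios_pct(pfa_bins, n),
    }


def bin_ratios_pct(counts: Sequence[int], n: int | None = None) -> list[float]:
    """Percentages of bin counts over the batch size, 2-dp rounded."""
    total = n if n is not None else sum(counts)
    if total == 0:
        return [0.0 for _ in counts]
    return [round(100.0 * c / total, 2) for c in counts]


def evaluate_picking(
    result: PickingResult, truth_stem: LineSegment
) -> PickingEval:
    """Horizontal distance between the computed point and the true stem.

    The error is |x_point - x_stem(y_point)| with the stem's x evaluated
    at the point's row (clamped to the segment's span).  Success is an
    error of at most 5 pixels, boundary inclusive.  A result without a
    point counts as a failure in the >5 px bin.
    """
    if result.point is None:
        return PickingEval(horizontal_error=float("inf"), success=False)
    x, y = result.point
    err = abs(x - truth_stem.x_at(y))
    return PickingEval(horizontal_error=err, success=err <= SUCCESS_PIXELS)


def picking_accuracy_pct(evals: Sequence[PickingEval]) -> float:
    """Success rate (error <= 5 px) as a percentage of the batch."""
    if not evals:
        raise InvalidInputError("empty batch")
    return 100.0 * sum(e.success for e in evals) / len(evals)


def picking_bins(evals: Sequence[PickingEval]) -> dict:
    counts = {"0": 0, "1-5": 0, ">5": 0}
    for e in evals:
        counts[e.error_bin] += 1
    return counts


def picking_accuracy_from_bins(
    exact: int, one_to_five: int, over_five: int, n: int | None = None
) -> float:
    """Accuracy percentage from error-bin counts (exact and 1-5 succeed).

    ``n`` defaults to the bin sum; pass it explicitly when the batch size
    is known independently (published tables occasionally drop an item
    from the bins while keeping the full batch in the denominator).
    """
    total = n if n is not None else exact + one_to_five + over_five
    if total == 0:
        raise InvalidInputError("empty bins")
    return 100.0 * (exact + one_to_five) / total
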