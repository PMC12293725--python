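"""Segmentation evaluation and issue-detection evaluation.

Segmentation metrics: global accuracy, per-class accuracy (recall against the
reference) with macro mean, per-class IoU with mean and frequency-weighted
IoU, and a boundary F1 score (BFScore) that matches predicted and reference
class boundaries within a pixel-distance tolerance.

Issue-detection evaluation compares the boolean mask of pixels flagged by
confident learning with the mask of authentic annotator disagreements,
yielding a 2x2 pixel-count confusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .cja import IssueMask
from .schema import LabelMask

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Bundle of segmentation scores; per-class arrays hold NaN for skipped
    classes (absent from both masks)."""

    global_accuracy: float
    class_accuracy: np.ndarray
    mean_class_accuracy: float
    iou: np.ndarray
    mean_iou: float
    weighted_iou: float
    bf_score: np.ndarray
    mean_bf_score: float
    boundary_tolerance: int


@dataclass
class IssueConfusion:
    """2x2 pixel counts comparing a detected issue mask to a true issue mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")


def default_boundary_tolerance(shape: tuple[int, int]) -> int:
    """ceil(0.75% of the image diagonal), the common BF-score convention."""
    return math.ceil(0.0075 * math.hypot(*shape))


def _class_boundary(binary: np.ndarray) -> np.ndarray:
    """Pixels of a binary region with a 4-neighbor outside the region; the
    image border counts as outside, so region pixels on the border are
    boundary."""
    padded = np.pad(binary, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return binary & ~interior


def _bf_score(pred_bin: np.ndarray, truth_bin: np.ndarray, tol: int) -> float:
    pb = _class_boundary(pred_bin)
    tb = _class_boundary(truth_bin)
    n_pb, n_tb = int(pb.sum()), int(tb.sum())
    if n_pb == 0 and n_tb == 0:
        return float("nan")  # class absent from both; caller skips
    if n_pb == 0 or n_tb == 0:
        return 0.0
    dist_to_tb = distance_transform_edt(~tb)
    dist_to_pb = distance_transform_edt(~pb)
    precision = float((dist_to_tb[pb] <= tol).mean())
    recall = float((dist_to_pb[tb] <= tol).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_segmentation(
    pred: LabelMask, truth: LabelMask, tolerance: int | None = None
) -> MetricsReport:
    """Score a predicted mask against a reference mask.

    ``tolerance`` is the boundary-match distance in pixels; ``None`` uses
    :func:`default_boundary_tolerance`.  Classes absent from both masks are
    skipped (NaN) in the per-class arrays and macro means.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.schema != truth.schema:
        raise ValueError("prediction and reference use different schemas")
    m = pred.schema.m
    tol = default_boundary_tolerance(pred.shape) if tolerance is None else int(tolerance)
    if tol < 0:
        raise ValueError("boundary tolerance must be nonnegative")

    confusion = np.bincount(
        truth.grid.ravel() * m + pred.grid.ravel(), minlength=m * m
    ).reshape(m, m)
    total = confusion.sum()
    diag = np.diag(confusion).astype(np.float64)
    truth_counts = confusion.sum(axis=1).astype(np.float64)  # per-class N_c
    pred_counts = confusion.sum(axis=0).astype(np.float64)

    class_acc = np.full(m, np.nan)
    iou = np.full(m, np.nan)
    bf = np.full(m, np.nan)
    present = (truth_counts > 0) | (pred_counts > 0)
    if (~present).any():
        log.info("classes %s absent from both masks; skipped in macro means",
                 [pred.schema.names[i] for i in np.flatnonzero(~present)])
    for c in np.flatnonzero(present):
        tp = diag[c]
        fn = truth_counts[c] - tp
        fp = pred_counts[c] - tp
        if truth_counts[c] > 0:
            class_acc[c] = tp / (tp + fn)
        iou[c] = tp / (tp + fp + fn)
        bf[c] = _bf_score(pred.grid == c, truth.grid == c, tol)

    weights = truth_counts / total
    defined_iou = ~np.isnan(iou) & (weights > 0)
    weighted_iou = float((weights[defined_iou] * iou[defined_iou]).sum())
    return MetricsReport(
        global_accuracy=float(diag.sum() / total),
        class_accuracy=class_acc,
        mean_class_accuracy=float(np.nanmean(class_acc)),
        iou=iou,
        mean_iou=float(np.nanmean(iou)),
        weighted_iou=weighted_iou,
        bf_score=bf,
        mean_bf_score=float(np.nanmean(bf)),
        boundary_tolerance=tol,
    )


def mean_bf_score_over_images(
    preds: list[LabelMask], truths: list[LabelMask], tolerance: int | None = None
) -> float:
    """Dataset-level boundary F1: per-image class-mean first, then the mean
    over images."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, nonzero numbers of predictions and references")
    per_image = [
        evaluate_segmentation(p, t, tolerance).mean_bf_score for p, t in zip(preds, truths)
    ]
    return float(np.mean(per_image))


def true_issue_mask(observed: LabelMask, reference: LabelMask) -> IssueMask:
    """Authentic disagreements between two annotation sets as an issue mask."""
    if observed.shape != reference.shape:
        raise ValueError(
            f"misaligned masks: observed {observed.shape} vs reference {reference.shape}"
        )
    flags = observed.grid != reference.grid
    return IssueMask(flags, observed.grid[flags].copy(), reference.grid[flags].copy())


def evaluate_issue_detection(
    observed_issues: IssueMask, true_issues: IssueMask
) -> IssueConfusion:
    """2x2 confusion between a detected issue mask and the true issue mask."""
    a = observed_issues.flags
    b = true_issues.flags
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    conf = IssueConfusion(
        tp=int((a & b).sum()),
        fp=int((a & ~b).sum()),
        fn=int((~a & b).sum()),
        tn=int((~a & ~b).sum()),
    )
    log.info("issue detection: precision=%.4f recall=%.4f (derived)",
             conf.precision, conf.recall)
    return conf
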