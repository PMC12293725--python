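"""Confident-learning core: thresholds, confident joint, noise transition.

The central object is the confident joint, an ``m x m`` count matrix
``C[i][j]`` of pixels observed as class ``i`` whose model probabilities make
class ``j`` both *confident* (probability at or above the class-j threshold)
and *most probable among the eligible classes*.  Pixels whose probability
vector clears no class threshold are out of distribution: they are excluded
from the joint (and counted) rather than forced into a cell.

Class-wise thresholds are self-confidence means: ``t_j`` is the mean
predicted class-j probability over pixels observed as class ``j``, pooled
over the calibration set so every pixel carries equal weight.

A noise transition matrix ``T[i][j] = P(observed=i | true=j)`` is estimated
from paired annotation sets by column-normalized co-occurrence counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .schema import ClassSchema, LabelMask, ProbMap, UNASSIGNED

log = logging.getLogger(__name__)


@dataclass
class ThresholdVector:
    """Per-class self-confidence thresholds; NaN marks an undefined class.

    A class is undefined when the calibration set contains no pixel observed
    as that class; undefined classes are ineligible for confident assignment.
    """

    values: np.ndarray
    schema: ClassSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.schema.m,):
            raise ValueError(
                f"threshold vector has shape {self.values.shape}, expected ({self.schema.m},)"
            )
        defined = ~np.isnan(self.values)
        if ((self.values[defined] < 0) | (self.values[defined] > 1)).any():
            raise ValueError("defined thresholds must lie in [0, 1]")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class AssignmentGrid:
    """Per-pixel confidently inferred class id, or UNASSIGNED (-1)."""

    grid: np.ndarray
    schema: ClassSchema

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        valid = (self.grid == UNASSIGNED) | ((self.grid >= 0) & (self.grid < self.schema.m))
        if not valid.all():
            raise ValueError("assignment grid contains values outside schema ids / UNASSIGNED")

    @property
    def unassigned(self) -> np.ndarray:
        """Boolean grid of out-of-distribution pixels."""
        return self.grid == UNASSIGNED


@dataclass
class ConfidentJoint:
    """Confident joint counts, rows = observed label, columns = inferred label.

    Published reports often print the transpose (rows labeled by the inferred
    "true" class); use :meth:`from_true_by_observed` / :meth:`to_true_by_observed`
    for that layout.
    """

    counts: np.ndarray
    excluded: int
    thresholds: ThresholdVector | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        m = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape != (m, m):
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if (self.counts < 0).any() or self.excluded < 0:
            raise ValueError("counts and excluded must be nonnegative")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def total_pixels(self) -> int:
        """Pixels processed: confidently counted plus excluded."""
        return int(self.counts.sum()) + self.excluded

    @classmethod
    def from_true_by_observed(
        cls,
        matrix: np.ndarray | Sequence[Sequence[int]],
        excluded: int = 0,
        thresholds: ThresholdVector | None = None,
    ) -> "ConfidentJoint":
        """Build from a matrix whose rows are inferred (true) labels and
        columns observed labels — the layout used in printed reports."""
        return cls(np.asarray(matrix, dtype=np.int64).T.copy(), excluded, thresholds)

    def to_true_by_observed(self) -> np.ndarray:
        return self.counts.T.copy()

    def __add__(self, other: "ConfidentJoint") -> "ConfidentJoint":
        if other.counts.shape != self.counts.shape:
            raise ValueError("cannot accumulate joints of different sizes")
        return ConfidentJoint(self.counts + other.counts,
                              self.excluded + other.excluded, self.thresholds)


@dataclass
class NoiseTransition:
    """Column-stochastic matrix T[i][j] = P(observed = i | true = j).

    Columns for reference classes with no pixels are NaN (undefined).
    """

    matrix: np.ndarray
    schema: ClassSchema | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        m = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape != (m, m):
            raise ValueError(f"transition matrix must be square, got {self.matrix.shape}")
        for j in range(m):
            col = self.matrix[:, j]
            if np.isnan(col).all():
                continue
            if np.isnan(col).any():
                raise ValueError(f"column {j} mixes defined and undefined entries")
            if ((col < 0) | (col > 1)).any():
                raise ValueError("transition probabilities must lie in [0, 1]")
            if abs(col.sum() - 1.0) > 1e-9:
                raise ValueError(f"column {j} sums to {col.sum()!r}, expected 1")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _as_sequences(
    probs: ProbMap | Sequence[ProbMap], masks: LabelMask | Sequence[LabelMask]
) -> tuple[list[ProbMap], list[LabelMask]]:
    prob_list = [probs] if isinstance(probs, ProbMap) else list(probs)
    mask_list = [masks] if isinstance(masks, LabelMask) else list(masks)
    if len(prob_list) != len(mask_list):
        raise ValueError(f"{len(prob_list)} probability maps vs {len(mask_list)} masks")
    for p, mk in zip(prob_list, mask_list):
        if p.shape != mk.shape:
            raise ValueError(f"shape mismatch: probmap {p.shape} vs mask {mk.shape}")
        if p.schema is not mk.schema and p.schema != mk.schema:
            raise ValueError("probability map and mask use different schemas")
    return prob_list, mask_list


def compute_thresholds(
    probs: ProbMap | Sequence[ProbMap], masks: LabelMask | Sequence[LabelMask]
) -> ThresholdVector:
    """Class-wise self-confidence thresholds pooled over a calibration set.

    ``t_j`` is the mean predicted class-j probability over every pixel
    observed as class ``j``; pooling weights pixels, not images.  Classes
    with no observed pixels get NaN and a warning.
    """
    prob_list, mask_list = _as_sequences(probs, masks)
    schema = mask_list[0].schema
    m = schema.m
    sums = np.zeros(m)
    counts = np.zeros(m, dtype=np.int64)
    for p, mk in zip(prob_list, mask_list):
        flat_labels = mk.grid.ravel()
        self_prob = np.take_along_axis(
            p.stack.reshape(-1, m), flat_labels[:, None], axis=1
        ).ravel()
        sums += np.bincount(flat_labels, weights=self_prob, minlength=m)
        counts += np.bincount(flat_labels, minlength=m)
    values = np.full(m, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    if (~nz).any():
        missing = [schema.names[i] for i in np.flatnonzero(~nz)]
        log.warning("no labeled pixels for classes %s; thresholds undefined", missing)
    return ThresholdVector(values, schema)


# ---------------------------------------------------------------------------
# confident assignment and joint
# ---------------------------------------------------------------------------

def confident_assignment(p: Sequence[float] | np.ndarray, t: ThresholdVector) -> int:
    """Confidently inferred class for one probability vector, or UNASSIGNED.

    The eligible set is ``{l : p_l >= t_l}`` over classes with defined
    thresholds (ties at the threshold count as eligible); the result is the
    argmax of ``p`` over that set, lowest id winning ties.  An empty eligible
    set marks the pixel out of distribution.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (t.schema.m,):
        raise ValueError(f"probability vector has shape {p.shape}, expected ({t.schema.m},)")
    thr = np.where(np.isnan(t.values), np.inf, t.values)
    eligible = p >= thr
    if not eligible.any():
        return UNASSIGNED
    masked = np.where(eligible, p, -np.inf)
    return int(np.argmax(masked))


def _assign_grid(prob: ProbMap, t: ThresholdVector) -> np.ndarray:
    thr = np.where(np.isnan(t.values), np.inf, t.values)
    eligible = prob.stack >= thr  # (h, w, m)
    masked = np.where(eligible, prob.stack, -np.inf)
    assigned = np.argmax(masked, axis=2)
    none = ~eligible.any(axis=2)
    assigned[none] = UNASSIGNED
    # ties among eligible maxima resolve to the lowest id; log if any occurred
    with np.errstate(invalid="ignore"):
        n_max = (masked == masked.max(axis=2, keepdims=True)).sum(axis=2)
    ties = int(((n_max > 1) & ~none).sum())
    if ties:
        log.info("argmax ties at %d pixels broken toward the lowest class id", ties)
    return assigned


def compute_confident_joint(
    prob: ProbMap, mask: LabelMask, t: ThresholdVector
) -> tuple[ConfidentJoint, AssignmentGrid]:
    """Confident joint and per-pixel assignment grid for one image."""
    if prob.shape != mask.shape:
        raise ValueError(f"shape mismatch: probmap {prob.shape} vs mask {mask.shape}")
    if t.schema.m != mask.schema.m:
        raise ValueError("threshold vector schema does not match mask schema")
    m = mask.schema.m
    assigned = _assign_grid(prob, t)
    ok = assigned != UNASSIGNED
    counts = np.bincount(
        mask.grid[ok].ravel() * m + assigned[ok].ravel(), minlength=m * m
    ).reshape(m, m)
    excluded = int((~ok).sum())
    return ConfidentJoint(counts, excluded, t), AssignmentGrid(assigned, mask.schema)


def compute_confident_joint_multi(
    probs: Sequence[ProbMap], masks: Sequence[LabelMask], t: ThresholdVector
) -> tuple[ConfidentJoint, list[AssignmentGrid]]:
    """Accumulate one confident joint over a collection of images."""
    prob_list, mask_list = _as_sequences(list(probs), list(masks))
    joint: ConfidentJoint | None = None
    grids: list[AssignmentGrid] = []
    for p, mk in zip(prob_list, mask_list):
        j, g = compute_confident_joint(p, mk, t)
        joint = j if joint is None else joint + j
        grids.append(g)
    assert joint is not None
    return joint, grids


# ---------------------------------------------------------------------------
# noise transition from paired annotations
# ---------------------------------------------------------------------------

def estimate_noise_transition(
    observed: LabelMask | Sequence[LabelMask],
    reference: LabelMask | Sequence[LabelMask],
) -> NoiseTransition:
    """Estimate T[i][j] = P(observed=i | reference=j) from paired mask sets.

    Counts co-occurrences pixel-for-pixel across all pairs and normalizes each
    reference-class column; columns with no reference pixels are NaN.
    """
    obs_list = [observed] if isinstance(observed, LabelMask) else list(observed)
    ref_list = [reference] if isinstance(reference, LabelMask) else list(reference)
    if len(obs_list) != len(ref_list):
        raise ValueError("observed and reference collections differ in length")
    schema = obs_list[0].schema
    m = schema.m
    co = np.zeros((m, m), dtype=np.int64)
    for ob, rf in zip(obs_list, ref_list):
        if ob.shape != rf.shape:
            raise ValueError(f"misaligned pair: observed {ob.shape} vs reference {rf.shape}")
        co += np.bincount(
            ob.grid.ravel() * m + rf.grid.ravel(), minlength=m * m
        ).reshape(m, m)
    col_totals = co.sum(axis=0)
    T = np.full((m, m), np.nan)
    nz = col_totals > 0
    T[:, nz] = co[:, nz] / col_totals[nz]
    if (~nz).any():
        log.warning("reference classes %s absent; transition columns undefined",
                    [schema.names[j] for j in np.flatnonzero(~nz)])
    return NoiseTransition(T, schema)
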