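"""Prune by Noise Rate: normalized-margin scoring, ranking and refinement.

The normalized margin of a pixel is ``(p_obs - max_{l != obs} p_l + 1) / 2``:
0 when the model puts everything on another class, 0.5 when the observed
label ties the best alternative, 1 when the observed label has all the mass.
Pixels ranked by ascending margin put the most suspicious labels first.

The production refinement mode ranks but removes nothing ("retain all");
classic pruning — relabeling the lowest-margin pixels per ordered class pair,
as many as the confident joint's off-diagonal count — is an explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cja import IssueMask
from .confidence import AssignmentGrid, ConfidentJoint
from .schema import LabelMask, ProbMap, UNASSIGNED


@dataclass
class RankedIssueTable:
    """Pixels ordered by ascending normalized margin (ties by pixel index).

    ``frame`` columns: ``pixel_index`` (row-major linear index), ``score``,
    ``observed``; plus ``reference`` and ``true_issue`` when a reference mask
    was supplied.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        scores = self.frame["score"].to_numpy()
        if len(scores) > 1 and (np.diff(scores) < 0).any():
            raise ValueError("ranked table scores must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path, one_based: bool = True) -> None:
        """Write report-style CSV (Observation Index, Score, Observed Label,
        True Label, True Issue); labels print 1-based in report mode."""
        out = pd.DataFrame({"Observation Index": self.frame["pixel_index"]})
        out["Score"] = self.frame["score"]
        shift = 1 if one_based else 0
        out["Observed Label"] = self.frame["observed"] + shift
        if "reference" in self.frame:
            out["True Label"] = self.frame["reference"] + shift
            out["True Issue"] = self.frame["true_issue"].astype(int)
        out.to_csv(path, index=False)


def normalized_margin(p: Sequence[float] | np.ndarray, observed: int) -> float:
    """Normalized margin of one probability vector for its observed label."""
    p = np.asarray(p, dtype=np.float64)
    m = p.shape[0]
    if m < 2:
        raise ValueError("normalized margin needs at least two classes")
    if not 0 <= observed < m:
        raise ValueError(f"observed class {observed} out of range")
    others = np.delete(p, observed)
    score = (p[observed] - others.max() + 1.0) / 2.0
    return float(min(1.0, max(0.0, score)))  # clamp only against fp drift


def margin_map(prob: ProbMap, mask: LabelMask) -> np.ndarray:
    """Vectorized normalized margin for every pixel (H x W float array)."""
    if prob.shape != mask.shape:
        raise ValueError(f"shape mismatch: probmap {prob.shape} vs mask {mask.shape}")
    m = prob.schema.m
    flat = prob.stack.reshape(-1, m)
    obs = mask.grid.ravel()
    p_obs = np.take_along_axis(flat, obs[:, None], axis=1).ravel()
    masked = flat.copy()
    np.put_along_axis(masked, obs[:, None], -np.inf, axis=1)
    p_max = masked.max(axis=1)
    scores = (p_obs - p_max + 1.0) / 2.0
    return np.clip(scores, 0.0, 1.0).reshape(mask.shape)


def rank_pixels_by_margin(
    prob: ProbMap,
    mask: LabelMask,
    scope: str = "all",
    issues: IssueMask | None = None,
    reference: LabelMask | None = None,
) -> RankedIssueTable:
    """Rank pixels by ascending normalized margin.

    ``scope='all'`` ranks every pixel; ``scope='issues_only'`` restricts to
    the flagged pixels of ``issues``.  With a reference mask each record also
    carries the reference label and a true-issue flag (observed != reference).
    """
    if scope not in {"all", "issues_only"}:
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "issues_only" and issues is None:
        raise ValueError("scope='issues_only' requires an issue mask")
    scores = margin_map(prob, mask).ravel()
    if scope == "issues_only":
        assert issues is not None
        idx = np.flatnonzero(issues.flags.ravel())
    else:
        idx = np.arange(scores.size)
    order = np.lexsort((idx, scores[idx]))  # score ascending, then pixel index
    idx = idx[order]
    frame = pd.DataFrame(
        {"pixel_index": idx, "score": scores[idx], "observed": mask.grid.ravel()[idx]}
    )
    if reference is not None:
        if reference.shape != mask.shape:
            raise ValueError("reference mask dimensions differ from observed mask")
        ref = reference.grid.ravel()[idx]
        frame["reference"] = ref
        frame["true_issue"] = frame["observed"].to_numpy() != ref
    return RankedIssueTable(frame)


def prune_counts_from_joint(joint: ConfidentJoint) -> dict[tuple[int, int], int]:
    """Per ordered class pair (observed i, inferred j), i != j, the number of
    pixels classic pruning would remove: the off-diagonal joint counts."""
    return {
        (i, j): int(joint.counts[i, j])
        for i in range(joint.m)
        for j in range(joint.m)
        if i != j
    }


def refine_mask_pbnr(
    mask: LabelMask,
    table: RankedIssueTable,
    assignment: AssignmentGrid | None = None,
    mode: str = "rank_only",
) -> tuple[LabelMask, pd.DataFrame]:
    """Rank-guided refinement.

    ``rank_only`` (default) changes no labels and returns the ranked report —
    every sample is retained and the ordering guides downstream (human)
    refinement.  ``prune_topk`` relabels, for each ordered class pair, the
    flagged pixels to their confidently inferred class, lowest margins first.
    """
    if mode not in {"rank_only", "prune_topk"}:
        raise ValueError(f"unknown mode {mode!r}")
    report = table.frame.copy()
    if mode == "rank_only":
        return mask.copy(), report

    if assignment is None:
        raise ValueError("mode='prune_topk' requires an assignment grid")
    refined = mask.grid.copy()
    flat_assign = assignment.grid.ravel()
    idx = report["pixel_index"].to_numpy()
    inferred = flat_assign[idx]
    observed = report["observed"].to_numpy()
    relabel = (inferred != UNASSIGNED) & (inferred != observed)
    refined.ravel()[idx[relabel]] = inferred[relabel]
    report["relabeled"] = relabel
    return LabelMask(refined, mask.schema), report
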