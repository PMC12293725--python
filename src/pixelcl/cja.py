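"""Confident Joint Analysis: issue detection, class summaries, relabeling.

A pixel is a *label issue* when it has a confident class assignment that
disagrees with its observed label; out-of-distribution pixels are never
flagged — they carry no confident evidence against the annotation and are
routed to a machine-readable review report for human refinement instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .confidence import AssignmentGrid, ConfidentJoint
from .schema import LabelMask, UNASSIGNED

#: overlay colors for the per-class review rendering
TP_COLOR = (0, 0, 139)      # dark blue: observed c, confirmed c
FP_COLOR = (173, 216, 230)  # light blue: observed other, inferred c
FN_COLOR = (144, 238, 144)  # light green: observed c, inferred other


@dataclass
class IssueMask:
    """Boolean grid of flagged pixels plus per-pixel (observed, inferred) pairs."""

    flags: np.ndarray
    observed: np.ndarray  # observed label at flagged pixels, aligned with pairs()
    inferred: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("issue flags must be a 2-D grid")

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def pairs(self) -> pd.DataFrame:
        """Flagged pixels as a table (row-major pixel index, observed, inferred)."""
        idx = np.flatnonzero(self.flags.ravel())
        return pd.DataFrame(
            {"pixel_index": idx, "observed": self.observed, "inferred": self.inferred}
        )


class ClassSummary(NamedTuple):
    """Per-class decomposition of the confident joint."""

    tp: int
    fp: int
    fn: int


def detect_label_issues_cja(mask: LabelMask, assignment: AssignmentGrid) -> IssueMask:
    """Flag every confidently assigned pixel whose inferred class differs from
    its observed label; unassigned pixels are never flagged."""
    if mask.shape != assignment.grid.shape:
        raise ValueError(
            f"shape mismatch: mask {mask.shape} vs assignment {assignment.grid.shape}"
        )
    flags = (assignment.grid != UNASSIGNED) & (assignment.grid != mask.grid)
    return IssueMask(flags, mask.grid[flags].copy(), assignment.grid[flags].copy())


def summarize_class_from_joint(joint: ConfidentJoint, c: int) -> ClassSummary:
    """TP/FP/FN pixel counts for class ``c`` read off the confident joint.

    TP: observed c, confirmed c (diagonal).  FP: observed as another class but
    confidently inferred c.  FN: observed c but confidently inferred another
    class.
    """
    if not 0 <= c < joint.m:
        raise ValueError(f"class id {c} out of range for a {joint.m}-class joint")
    tp = int(joint.counts[c, c])
    fp = int(joint.counts[:, c].sum() - joint.counts[c, c])
    fn = int(joint.counts[c, :].sum() - joint.counts[c, c])
    return ClassSummary(tp, fp, fn)


def refine_mask_cja(
    mask: LabelMask, assignment: AssignmentGrid, policy: str = "relabel"
) -> tuple[LabelMask, pd.DataFrame]:
    """Apply (or just report) the confident relabeling.

    ``relabel`` replaces each flagged pixel's label with its confidently
    inferred class; ``flag_only`` changes nothing.  Either way the returned
    review report lists flagged pixels (action ``relabel``/``flag``) and
    out-of-distribution pixels (action ``review``) for human refinement —
    unassigned pixels always keep their original label.
    """
    if policy not in {"relabel", "flag_only"}:
        raise ValueError(f"unknown policy {policy!r}")
    issues = detect_label_issues_cja(mask, assignment)
    refined = mask.grid.copy()
    if policy == "relabel":
        refined[issues.flags] = assignment.grid[issues.flags]

    report = issues.pairs()
    report["action"] = "relabel" if policy == "relabel" else "flag"
    ood_idx = np.flatnonzero(assignment.unassigned.ravel())
    if ood_idx.size:
        ood = pd.DataFrame(
            {
                "pixel_index": ood_idx,
                "observed": mask.grid.ravel()[ood_idx],
                "inferred": UNASSIGNED,
                "action": "review",
            }
        )
        report = pd.concat([report, ood], ignore_index=True)
    report = report.sort_values("pixel_index", ignore_index=True)
    return LabelMask(refined, mask.schema), report


def render_review_overlay(mask: LabelMask, issues: IssueMask, c: int) -> np.ndarray:
    """RGB overlay of the class-c TP/FP/FN decomposition (uint8 H x W x 3).

    TP (observed c, not flagged away) in dark blue, FP (flagged toward c) in
    light blue, FN (observed c, flagged elsewhere) in light green; everything
    else black.  Deterministic — suitable for pixel-exact comparison.
    """
    if not 0 <= c < mask.schema.m:
        raise ValueError(f"class id {c} out of range")
    if mask.shape != issues.flags.shape:
        raise ValueError("mask and issue mask dimensions differ")
    overlay = np.zeros(mask.shape + (3,), dtype=np.uint8)
    flagged_to_c = np.zeros(mask.shape, dtype=bool)
    flagged_to_c.ravel()[
        np.flatnonzero(issues.flags.ravel())[issues.inferred == c]
    ] = True
    fn = issues.flags & (mask.grid == c)
    tp = (mask.grid == c) & ~issues.flags
    overlay[tp] = TP_COLOR
    overlay[flagged_to_c] = FP_COLOR
    overlay[fn] = FN_COLOR
    return overlay
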