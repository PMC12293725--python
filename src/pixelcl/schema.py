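"""Class schemas and the core in-memory containers for segmentation data.

A :class:`ClassSchema` fixes the ordered set of semantic classes shared by
every label mask and probability map in a run.  Two ready-made schemas cover
the common retinal settings: a five-class anatomy schema (background, retina,
fovea, vessel, optic disc) and a two-class vessel/background schema.

Conventions
-----------
* Class ids are contiguous integers ``0..m-1`` in schema order.  Writers that
  mirror published tables may print 1-based labels; internally everything is
  0-based.
* Masks are 2-D integer grids, row-major, 0-based pixel coordinates.  The
  linear pixel index used in ranked tables is the row-major flat index.
* Probability maps are ``height x width x m`` float stacks whose per-pixel
  channel sums equal 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

Color = tuple[int, int, int]

#: marker for a pixel with no confident class assignment (out of distribution)
UNASSIGNED: int = -1


@dataclass(frozen=True)
class ClassSchema:
    """Ordered class names, implicit contiguous ids and a display palette."""

    names: tuple[str, ...]
    palette: tuple[Color, ...]
    background_id: int = 0

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("schema needs at least one class")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        if len(self.palette) != len(self.names):
            raise ValueError(
                f"palette has {len(self.palette)} entries for {len(self.names)} classes"
            )
        if not 0 <= self.background_id < len(self.names):
            raise ValueError(f"background_id {self.background_id} out of range")
        for color in self.palette:
            if len(color) != 3 or any(not 0 <= v <= 255 for v in color):
                raise ValueError(f"palette entry {color!r} is not an RGB triplet")

    @property
    def m(self) -> int:
        """Number of classes."""
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def id_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class name {name!r}") from None


#: five-class retinal anatomy schema (fundus masks)
RETINA_SCHEMA = ClassSchema(
    names=("background", "retina", "fovea", "vessel", "optic_disc"),
    palette=((0, 0, 0), (128, 64, 64), (255, 255, 0), (255, 0, 0), (0, 255, 255)),
    background_id=0,
)

#: two-class vessel segmentation schema
VESSEL_SCHEMA = ClassSchema(
    names=("background", "vessel"),
    palette=((0, 0, 0), (255, 255, 255)),
    background_id=0,
)


@dataclass
class LabelMask:
    """2-D grid of observed (or reference) class ids over pixels."""

    grid: np.ndarray
    schema: ClassSchema

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError(f"mask grid must be 2-D and non-empty, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError(f"mask grid must be integer, got dtype {self.grid.dtype}")
        bad = (self.grid < 0) | (self.grid >= self.schema.m)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"mask value {int(self.grid[r, c])} at (row={r}, col={c}) is not a valid "
                f"class id for a {self.schema.m}-class schema"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def copy(self) -> "LabelMask":
        return LabelMask(self.grid.copy(), self.schema)


@dataclass
class ProbMap:
    """Per-pixel class-probability stack, shape (height, width, m)."""

    stack: np.ndarray
    schema: ClassSchema
    #: allowed deviation of per-pixel sums from 1
    _SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 3:
            raise ValueError(f"probability stack must be 3-D, got shape {self.stack.shape}")
        if self.stack.shape[2] != self.schema.m:
            raise ValueError(
                f"probability stack has {self.stack.shape[2]} channels, "
                f"schema has {self.schema.m} classes"
            )
        if (self.stack < -self._SUM_TOL).any() or (self.stack > 1 + self._SUM_TOL).any():
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.stack.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=self._SUM_TOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"per-pixel probability sums deviate from 1 by up to {worst:.3g} "
                f"(tolerance {self._SUM_TOL:g})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[:2]  # type: ignore[return-value]


def resize_mask_nn(mask: LabelMask, height: int, width: int) -> LabelMask:
    """Nearest-neighbor resize of a label mask.

    Each output pixel takes the id of the input pixel whose cell contains the
    output pixel's center, so no new ids are ever introduced and resizing to
    the input size is the identity.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"target size must be positive, got {height}x{width}")
    h_in, w_in = mask.shape
    rows = np.floor((np.arange(height) + 0.5) * h_in / height).astype(np.intp)
    cols = np.floor((np.arange(width) + 0.5) * w_in / width).astype(np.intp)
    rows = np.clip(rows, 0, h_in - 1)
    cols = np.clip(cols, 0, w_in - 1)
    return LabelMask(mask.grid[np.ix_(rows, cols)], mask.schema)
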