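"""Readers and writers for masks, probability maps and run configuration.

Masks travel as indexed PNG (palette matched against the schema palette) or
single-channel TIFF/PNG with raw class ids.  Probability maps travel as
multi-channel 32-bit float TIFF with one channel per class in schema order;
a CSV dialect of per-pixel probability vectors is provided for tiny fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .schema import ClassSchema, LabelMask, ProbMap, RETINA_SCHEMA, VESSEL_SCHEMA

log = logging.getLogger(__name__)

#: per-pixel sum deviations up to this are silently renormalized on load
PROB_RENORM_TOL = 1e-4


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _ids_from_values(values: np.ndarray, schema: ClassSchema, path: Path) -> np.ndarray:
    bad = (values < 0) | (values >= schema.m)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: pixel value {int(values[r, c])} at (row={r}, col={c}) does not map "
            f"onto any id of the {schema.m}-class schema"
        )
    return values.astype(np.int64)


def load_mask(path: str | Path, schema: ClassSchema) -> LabelMask:
    """Load a label mask from an indexed PNG or single-channel TIFF/PNG.

    Indexed PNGs whose palette entries match the schema palette are remapped
    so each stored index receives the id of the matching palette color; the
    mapping is logged.  Grayscale images are interpreted as raw class ids.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel TIFF, got shape {arr.shape}")
        return LabelMask(_ids_from_values(np.asarray(arr), schema, path), schema)

    with Image.open(path) as img:
        if img.mode == "P":
            raw = np.asarray(img)
            palette = img.getpalette() or []
            stored_colors = {
                idx: tuple(palette[3 * idx : 3 * idx + 3]) for idx in np.unique(raw)
            }
            mapping: dict[int, int] = {}
            for idx, color in stored_colors.items():
                try:
                    mapping[int(idx)] = schema.palette.index(color)  # type: ignore[arg-type]
                except ValueError:
                    raise ValueError(
                        f"{path}: stored palette color {color} (index {idx}) matches no "
                        f"schema palette entry"
                    ) from None
            log.info("%s: palette index -> class id mapping %s", path, mapping)
            lut = np.zeros(max(mapping) + 1, dtype=np.int64)
            for idx, cid in mapping.items():
                lut[idx] = cid
            return LabelMask(lut[raw], schema)
        arr = np.asarray(img.convert("I"))
        return LabelMask(_ids_from_values(arr, schema, path), schema)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as indexed PNG (with the schema palette) or uint TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.grid.astype(np.uint8 if mask.schema.m <= 256 else np.uint16))
        return
    img = Image.fromarray(mask.grid.astype(np.uint8), mode="P")
    flat_palette: list[int] = []
    for color in mask.schema.palette:
        flat_palette.extend(color)
    img.putpalette(flat_palette)
    img.save(path)


# ---------------------------------------------------------------------------
# probability maps
# ---------------------------------------------------------------------------

def load_probmap(path: str | Path, schema: ClassSchema) -> ProbMap:
    """Load an m-channel float TIFF probability map.

    Per-pixel sums deviating from 1 by at most ``PROB_RENORM_TOL`` are
    renormalized (count logged); larger deviations raise.
    """
    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    if arr.ndim == 3 and arr.shape[0] == schema.m and arr.shape[2] != schema.m:
        arr = np.moveaxis(arr, 0, 2)  # planar layout
    if arr.ndim != 3 or arr.shape[2] != schema.m:
        raise ValueError(
            f"{path}: expected {schema.m} channels, got array of shape {arr.shape}"
        )
    sums = arr.sum(axis=2)
    dev = np.abs(sums - 1.0)
    if (dev > PROB_RENORM_TOL).any():
        raise ValueError(
            f"{path}: per-pixel probability sums deviate from 1 by up to "
            f"{float(dev.max()):.3g} (limit {PROB_RENORM_TOL:g})"
        )
    off = dev > ProbMap._SUM_TOL
    if off.any():
        log.warning("%s: renormalized %d pixels with sum deviation <= %g",
                    path, int(off.sum()), PROB_RENORM_TOL)
        arr = arr / sums[:, :, None]
    return ProbMap(arr, schema)


def save_probmap(prob: ProbMap, path: str | Path) -> None:
    """Write a probability map as a contiguous float32 multi-channel TIFF."""
    tifffile.imwrite(Path(path), prob.stack.astype(np.float32), photometric="minisblack",
                     planarconfig="contig")


def probmap_to_csv(prob: ProbMap, path: str | Path) -> None:
    """CSV export of per-pixel probability vectors (row, col, one column per class)."""
    h, w = prob.shape
    rows, cols = np.divmod(np.arange(h * w), w)
    frame = pd.DataFrame(prob.stack.reshape(-1, prob.schema.m), columns=list(prob.schema.names))
    frame.insert(0, "col", cols)
    frame.insert(0, "row", rows)
    frame.to_csv(path, index=False)


def probmap_from_csv(path: str | Path, schema: ClassSchema) -> ProbMap:
    frame = pd.read_csv(path)
    h = int(frame["row"].max()) + 1
    w = int(frame["col"].max()) + 1
    stack = np.zeros((h, w, schema.m))
    stack[frame["row"], frame["col"]] = frame[list(schema.names)].to_numpy()
    return ProbMap(stack, schema)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_BUILTIN_SCHEMAS = {"retina": RETINA_SCHEMA, "vessel": VESSEL_SCHEMA}


@dataclass
class RunConfig:
    """Configuration shared by all CLI subcommands."""

    schema: ClassSchema = RETINA_SCHEMA
    threshold_mode: str = "dataset"  # or "per_image"
    boundary_tolerance: int | None = None  # None -> diagonal-based default
    margin_scope: str = "all"  # or "issues_only"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"dataset", "per_image"}:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.margin_scope not in {"all", "issues_only"}:
            raise ValueError(f"unknown margin_scope {self.margin_scope!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    ``schema`` may be a builtin name (``retina``, ``vessel``) or a mapping with
    ``names``, ``palette`` and optional ``background_id``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schema_spec = raw.get("schema", "retina")
    if isinstance(schema_spec, str):
        try:
            schema = _BUILTIN_SCHEMAS[schema_spec]
        except KeyError:
            raise ValueError(f"unknown builtin schema {schema_spec!r}") from None
    else:
        schema = ClassSchema(
            names=tuple(schema_spec["names"]),
            palette=tuple(tuple(c) for c in schema_spec["palette"]),
            background_id=int(schema_spec.get("background_id", 0)),
        )
    return RunConfig(
        schema=schema,
        threshold_mode=raw.get("threshold_mode", "dataset"),
        boundary_tolerance=raw.get("boundary_tolerance"),
        margin_scope=raw.get("margin_scope", "all"),
        seed=int(raw.get("seed", 42)),
    )
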