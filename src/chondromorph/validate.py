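"""Segmentation agreement metrics and file-driven manual verification.

The Dice similarity coefficient DSC = 2A / (B + C) compares two
segmentations, where A is the count of commonly segmented voxels and B, C
the voxel counts of each segmentation. Masks with different offsets are
compared in the shared parent frame (zero-padded), so sub-VOI masks are
directly comparable to whole-VOI ground truth.

Manual verification is non-interactive: the pipeline exports an orthogonal
three-plane montage per chondron, a human records verdicts in a decision
CSV (columns: id, verdict approve|reject, classification single|cluster),
and :func:`ingest_verification` applies the decisions to the record table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    EmptyObjectError,
    UndefinedMetricError,
    VerificationConflictError,
    VerificationReferenceError,
)
from .volio import BinaryMask, ChondronRecord, VoxelGrid


@dataclass
class DiceResult:
    """Dice similarity between two masks: A common, B and C per-mask counts."""

    A: int
    B: int
    C: int

    @property
    def dsc(self) -> float:
        return 2.0 * self.A / (self.B + self.C)


def dice(m1: BinaryMask, m2: BinaryMask) -> DiceResult:
    """DSC = 2A/(B+C) of two masks resolved to their common parent frame."""
    B, C = m1.voxel_count, m2.voxel_count
    if B == 0 and C == 0:
        raise UndefinedMetricError("Dice of two empty masks is undefined")
    lo = np.maximum(m1.offset_voxels, m2.offset_voxels)
    hi = np.minimum(np.array(m1.offset_voxels) + m1.data.shape,
                    np.array(m2.offset_voxels) + m2.data.shape)
    A = 0
    if np.all(hi > lo):
        s1 = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, m1.offset_voxels))
        s2 = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, m2.offset_voxels))
        A = int((m1.data[s1] & m2.data[s2]).sum())
    return DiceResult(A=A, B=B, C=C)


def _outline(mask_plane: np.ndarray) -> np.ndarray:
    """Boundary voxels of a 2D mask slice (mask minus its erosion)."""
    if not mask_plane.any():
        return np.zeros_like(mask_plane)
    return mask_plane & ~ndimage.binary_erosion(mask_plane, border_value=0)


def export_orthogonal_views(grid: VoxelGrid, mask: BinaryMask,
                            out_path: str | Path) -> Path:
    """Export a montage of the three orthogonal planes through the mask
    centroid, with the mask outline overlaid in red.

    The montage concatenates the z-, y- and x-planes horizontally (padded to
    a common height), mirroring the orthogonal-view inspection used to
    verify segmentations.
    """
    if mask.voxel_count == 0:
        raise EmptyObjectError("cannot export views of an empty mask")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    full = mask.to_global(grid.shape)
    cz, cy, cx = (int(round(c)) for c in mask.centroid_global())
    planes = [
        (grid.data[cz, :, :], full[cz, :, :]),
        (grid.data[:, cy, :], full[:, cy, :]),
        (grid.data[:, :, cx], full[:, :, cx]),
    ]
    tiles = []
    max_h = max(p.shape[0] for p, _ in planes)
    for img, m in planes:
        g = np.clip(img, 0.0, 1.0)
        rgb = np.stack([g, g, g], axis=-1)
        edge = _outline(m)
        rgb[edge] = (1.0, 0.0, 0.0)
        pad_h = max_h - rgb.shape[0]
        if pad_h:
            rgb = np.pad(rgb, ((0, pad_h), (0, 0), (0, 0)))
        tiles.append(rgb)
    montage = (np.concatenate(tiles, axis=1) * 255).astype(np.uint8)
    iio.imwrite(out_path, montage)
    return out_path


VERDICTS = ("approve", "reject")
CLASSIFICATIONS = ("single", "cluster")


def ingest_verification(records: Sequence[ChondronRecord],
                        decisions: pd.DataFrame | str | Path) -> list[ChondronRecord]:
    """Apply manual-verification decisions to the record table.

    ``decisions`` has columns id, verdict (approve|reject) and optional
    classification (single|cluster). Approved records get status
    ``approved`` (and the classification when given); rejected ones get
    ``rejected_manual``. Records without a decision are returned unchanged.
    """
    if not isinstance(decisions, pd.DataFrame):
        decisions = pd.read_csv(decisions)
    known = {r.id for r in records}
    by_id: dict[int, tuple[str, str | None]] = {}
    for row in decisions.itertuples(index=False):
        rid = int(row.id)
        verdict = str(row.verdict).strip().lower()
        if rid not in known:
            raise VerificationReferenceError(f"decision for unknown record id {rid}")
        if verdict not in VERDICTS:
            raise VerificationReferenceError(f"id {rid}: unknown verdict {verdict!r}")
        cls = getattr(row, "classification", None)
        cls = None if cls is None or pd.isna(cls) or str(cls) == "" else str(cls).strip().lower()
        if cls is not None and cls not in CLASSIFICATIONS:
            raise VerificationReferenceError(f"id {rid}: unknown classification {cls!r}")
        if rid in by_id and by_id[rid][0] != verdict:
            raise VerificationConflictError(f"conflicting verdicts for record id {rid}")
        by_id[rid] = (verdict, cls if cls is not None else by_id.get(rid, (None, None))[1])
    out = []
    for rec in records:
        if rec.id in by_id:
            verdict, cls = by_id[rec.id]
            rec = replace(rec,
                          status="approved" if verdict == "approve" else "rejected_manual",
                          classification=cls if cls is not None else rec.classification)
        out.append(rec)
    return out
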