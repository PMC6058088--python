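"""Automatic chondron candidate selection.

Candidates are found by global automatic thresholding (Otsu) on the chosen
polarity — chondrons are the dark phase in dried-tissue micro-CT — followed
by 3D connected-component labeling. Each surviving candidate yields a
sub-VOI (its bounding box dilated by a margin) that the segmentation module
refines; the margin default leaves room for the largest probe spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters

from .errors import BoundsError, DegenerateInputError, ParameterError
from .volio import BinaryMask, Box, VoxelGrid

Connectivity = Literal[6, 18, 26]
_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class CandidateObject:
    """One connected component proposed as a possible chondron."""

    label_id: int
    bbox: Box  # half-open (z0, y0, x0, z1, y1, x1) in the parent frame
    voxel_count: int
    seed_voxel: tuple[int, int, int]  # centroid snapped to nearest in-mask voxel


@dataclass
class SubVOI:
    """Per-candidate crop: the candidate bbox dilated by a margin."""

    grid: VoxelGrid
    offset_voxels: tuple[int, int, int]
    seed_local: tuple[int, int, int]

    def seed_global(self) -> tuple[int, int, int]:
        return tuple(s + o for s, o in zip(self.seed_local, self.offset_voxels))  # type: ignore[return-value]


def binarize(grid: VoxelGrid, polarity: Literal["dark", "bright"] = "dark") -> BinaryMask:
    """Threshold a grid with the Otsu criterion (maximal between-class
    variance over a 256-bin histogram); ``dark`` selects voxels below the
    threshold, ``bright`` above."""
    data = grid.data
    if np.ptp(data) == 0:
        raise DegenerateInputError("constant grid cannot be thresholded")
    thr = filters.threshold_otsu(data, nbins=256)
    fg = data < thr if polarity == "dark" else data > thr
    return BinaryMask(fg, offset_voxels=(0, 0, 0), voxel_size_um=grid.voxel_size_um)


def label_components(mask: BinaryMask, connectivity: Connectivity = 26) -> list[CandidateObject]:
    """3D connected components of the foreground under 6/18/26-connectivity.

    Every foreground voxel lands in exactly one component; the seed voxel is
    the component centroid snapped to the nearest voxel of the component
    (the centroid itself can fall outside concave clusters).
    """
    structure = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[connectivity])
    labels, n = ndimage.label(mask.data, structure=structure)
    objects = ndimage.find_objects(labels)
    oz, oy, ox = mask.offset_voxels
    out: list[CandidateObject] = []
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        region = labels[sl] == lab
        coords = np.argwhere(region)
        centroid = coords.mean(axis=0)
        seed_local = coords[np.argmin(np.square(coords - centroid).sum(axis=1))]
        origin = np.array([sl[0].start, sl[1].start, sl[2].start])
        seed = tuple(int(v) for v in (seed_local + origin + np.array([oz, oy, ox])))
        bbox = (sl[0].start + oz, sl[1].start + oy, sl[2].start + ox,
                sl[0].stop + oz, sl[1].stop + oy, sl[2].stop + ox)
        out.append(CandidateObject(label_id=lab, bbox=bbox,
                                   voxel_count=int(region.sum()), seed_voxel=seed))
    return out


def filter_candidates(cands: Sequence[CandidateObject], min_voxels: int = 25,
                      max_voxels: int = 10 ** 6) -> list[CandidateObject]:
    """Cheap size pre-screen before the expensive per-candidate segmentation.

    This discards single-voxel noise and tissue-scale components; the actual
    morphological exclusion rule (the 400 um^3 minimum volume) is applied to
    the segmented masks downstream.
    """
    if not (0 < min_voxels <= max_voxels):
        raise ParameterError(f"need 0 < min_voxels <= max_voxels, got [{min_voxels}, {max_voxels}]")
    return [c for c in cands if min_voxels <= c.voxel_count <= max_voxels]


def candidates_to_frame(cands: Sequence[CandidateObject]):
    """Candidate table (label, bbox, count, seed) as a pandas DataFrame."""
    import pandas as pd

    rows = [{"label_id": c.label_id,
             "z0": c.bbox[0], "y0": c.bbox[1], "x0": c.bbox[2],
             "z1": c.bbox[3], "y1": c.bbox[4], "x1": c.bbox[5],
             "voxel_count": c.voxel_count,
             "seed_z": c.seed_voxel[0], "seed_y": c.seed_voxel[1],
             "seed_x": c.seed_voxel[2]} for c in cands]
    return pd.DataFrame(rows, columns=["label_id", "z0", "y0", "x0", "z1", "y1", "x1",
                                       "voxel_count", "seed_z", "seed_y", "seed_x"])


def extract_subvoi(grid: VoxelGrid, cand: CandidateObject, margin_voxels: int = 20) -> SubVOI:
    """Crop the candidate bbox dilated by ``margin_voxels`` per face, clipped
    to the grid bounds; the seed is carried over in local coordinates."""
    if margin_voxels < 0:
        raise ParameterError(f"margin_voxels must be >= 0, got {margin_voxels}")
    z0, y0, x0, z1, y1, x1 = cand.bbox
    Z, Y, X = grid.shape
    m = margin_voxels
    c0 = (max(z0 - m, 0), max(y0 - m, 0), max(x0 - m, 0))
    c1 = (min(z1 + m, Z), min(y1 + m, Y), min(x1 + m, X))
    if any(s < 0 or e > d for s, e, d in zip(c0, c1, (Z, Y, X))):
        raise BoundsError(f"candidate bbox {cand.bbox} outside grid {grid.shape}")
    sub = replace(grid, data=grid.data[c0[0]:c1[0], c0[1]:c1[1], c0[2]:c1[2]].copy())
    seed_local = tuple(int(s - o) for s, o in zip(cand.seed_voxel, c0))
    return SubVOI(grid=sub, offset_voxels=c0, seed_local=seed_local)
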