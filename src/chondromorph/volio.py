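"""Voxel-grid containers and slice-stack / table I/O.

The whole pipeline works on reconstructed micro-CT slice stacks with isotropic
voxels (the instrument this targets exports 1.6 um voxels). Axis order is
fixed as ``(z, y, x)`` with ``z`` the slice index increasing from the
articular surface toward the bone. Voxel coordinates are 0-based and boxes
are half-open, so crops compose without off-by-one ambiguity.

8- and 16-bit integer inputs are normalized to floating intensities in
``[0, 1]`` on read; every downstream module assumes that contract.
"""

from __future__ import annotations

import glob as _glob
import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BoundsError,
    EmptyObjectError,
    FormatError,
    MissingInputError,
)

SLICE_EXTENSIONS = (".tif", ".tiff", ".png", ".bmp")

#: half-open voxel box (z0, y0, x0, z1, y1, x1)
Box = tuple[int, int, int, int, int, int]


@dataclass
class VoxelGrid:
    """A 3D scalar intensity grid with a physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(z, y, x)``; intensities in ``[0, 1]`` by convention.
    voxel_size_um
        Isotropic voxel edge length in micrometres; must be positive.
    z_axis_is_depth
        True when ``z`` increases from the articular surface toward bone.
    """

    data: np.ndarray
    voxel_size_um: float
    z_axis_is_depth: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"grid must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise FormatError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("grid intensities must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along (z, y, x) in micrometres."""
        return tuple(s * self.voxel_size_um for s in self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A boolean 3D grid positioned inside a parent :class:`VoxelGrid`.

    ``offset_voxels`` is the (z, y, x) position of the mask's origin in the
    parent frame; it lets sub-VOI masks be compared against whole-VOI masks.
    """

    data: np.ndarray
    offset_voxels: tuple[int, int, int] = (0, 0, 0)
    voxel_size_um: float = 1.6

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3D, got shape {self.data.shape}")
        if any(o < 0 for o in self.offset_voxels):
            raise FormatError(f"mask offset must be non-negative, got {self.offset_voxels}")
        self.offset_voxels = tuple(int(o) for o in self.offset_voxels)  # type: ignore[assignment]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def bbox_global(self) -> Box:
        """Tight half-open bounding box of the foreground in the parent frame."""
        if self.voxel_count == 0:
            raise EmptyObjectError("empty mask has no bounding box")
        idx = np.argwhere(self.data)
        lo = idx.min(axis=0) + np.array(self.offset_voxels)
        hi = idx.max(axis=0) + 1 + np.array(self.offset_voxels)
        return (*map(int, lo), *map(int, hi))  # type: ignore[return-value]

    def centroid_global(self) -> tuple[float, float, float]:
        """Foreground centroid in parent-frame (z, y, x) voxel coordinates."""
        if self.voxel_count == 0:
            raise EmptyObjectError("empty mask has no centroid")
        idx = np.argwhere(self.data)
        c = idx.mean(axis=0) + np.array(self.offset_voxels)
        return tuple(float(v) for v in c)  # type: ignore[return-value]

    def to_global(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Embed the mask into a full parent-frame boolean array."""
        z0, y0, x0 = self.offset_voxels
        dz, dy, dx = self.data.shape
        if z0 + dz > shape[0] or y0 + dy > shape[1] or x0 + dx > shape[2]:
            raise BoundsError(f"mask at offset {self.offset_voxels} with shape "
                              f"{self.data.shape} does not fit in parent {shape}")
        out = np.zeros(shape, dtype=bool)
        out[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] = self.data
        return out


@dataclass
class ChondronRecord:
    """One row of per-chondron morphometry.

    Volume ``V`` (um^3) is voxel count times voxel volume, surface area ``S``
    (um^2) comes from the smoothed isosurface mesh, and Wadell sphericity is
    ``pi^(1/3) (6V)^(2/3) / S``. Depth is the percent distance of the
    centroid z-coordinate from the articular surface; zones are the standard
    cartilage depth bands 0-10 / 10-40 / 40-100 %.
    """

    id: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float
    z_c: float
    y_c: float
    x_c: float
    depth_percent: float = float("nan")
    zone: int | None = None
    classification: str = "unverified"  # single | cluster | unverified
    status: str = "approved"  # approved | rejected_volume | rejected_duplicate | rejected_manual

    COLUMNS = ("id", "volume_um3", "surface_area_um2", "sphericity",
               "z_c", "y_c", "x_c", "depth_percent", "zone",
               "classification", "status")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.COLUMNS}


def _natural_key(path: Path) -> tuple:
    """Sort key treating digit runs numerically (slice_2 before slice_10)."""
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _normalize(data: np.ndarray) -> np.ndarray:
    """Map integer intensities to floats in [0, 1]; floats pass through."""
    if data.dtype == np.uint8:
        return data.astype(np.float32) / 255.0
    if data.dtype == np.uint16:
        return data.astype(np.float32) / 65535.0
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return (data.astype(np.float64) - info.min) / (info.max - info.min)
    return data.astype(np.float32)


def list_slice_files(path_pattern: str | Path) -> list[Path]:
    """Resolve a directory or glob pattern to a sorted list of slice files."""
    p = Path(path_pattern)
    if p.is_dir():
        files = [f for f in p.iterdir() if f.suffix.lower() in SLICE_EXTENSIONS]
    else:
        files = [Path(f) for f in _glob.glob(str(path_pattern))]
        files = [f for f in files if f.suffix.lower() in SLICE_EXTENSIONS]
    if not files:
        raise MissingInputError(f"no slice images found under {path_pattern!s}")
    return sorted(files, key=_natural_key)


def read_stack(path_pattern: str | Path, voxel_size_um: float) -> VoxelGrid:
    """Read a slice stack (directory, glob, or multi-page TIFF) as a VoxelGrid.

    Slices are ordered by natural filename sort. All slices must share shape
    and dtype; 8/16-bit integers are normalized to [0, 1].
    """
    p = Path(path_pattern)
    if p.is_file() and p.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
        return VoxelGrid(_normalize(data), voxel_size_um)
    files = list_slice_files(path_pattern)
    slices = []
    ref_shape = ref_dtype = None
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:  # collapse trivially-stacked grayscale channels
            if img.shape[-1] in (3, 4) and np.array_equal(img[..., 0], img[..., 1]):
                img = img[..., 0]
            elif img.shape[-1] == 1:
                img = img[..., 0]
            else:
                raise FormatError(f"{f.name}: expected grayscale slice, got shape {img.shape}")
        if ref_shape is None:
            ref_shape, ref_dtype = img.shape, img.dtype
        elif img.shape != ref_shape:
            raise FormatError(f"{f.name}: slice shape {img.shape} != first slice {ref_shape}")
        elif img.dtype != ref_dtype:
            raise FormatError(f"{f.name}: slice dtype {img.dtype} != first slice {ref_dtype}")
        slices.append(img)
    return VoxelGrid(_normalize(np.stack(slices)), voxel_size_um)


def write_stack(grid: VoxelGrid, path: str | Path, bit_depth: int = 16) -> Path:
    """Write a grid as a multi-page TIFF at the given integer bit depth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(grid.data, 0.0, 1.0)
    if bit_depth == 8:
        out = np.round(data * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(data * 65535.0).astype(np.uint16)
    else:
        raise FormatError(f"unsupported bit depth {bit_depth}")
    tifffile.imwrite(path, out)
    return path


def crop_voi(grid: VoxelGrid, bbox: Box) -> VoxelGrid:
    """Crop a half-open (z0, y0, x0, z1, y1, x1) box out of a grid."""
    z0, y0, x0, z1, y1, x1 = (int(v) for v in bbox)
    if not (z1 > z0 and y1 > y0 and x1 > x0):
        raise BoundsError(f"degenerate box {bbox}: upper bounds must exceed lower bounds")
    Z, Y, X = grid.shape
    if z0 < 0 or y0 < 0 or x0 < 0 or z1 > Z or y1 > Y or x1 > X:
        raise BoundsError(f"box {bbox} exceeds grid bounds {grid.shape}")
    return replace(grid, data=grid.data[z0:z1, y0:y1, x0:x1].copy())


def write_records(records: Sequence[ChondronRecord], path: str | Path) -> Path:
    """Write chondron records as CSV; empty input yields a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not records:
        warnings.warn(f"writing empty record table to {path}", stacklevel=2)
        pd.DataFrame(columns=list(ChondronRecord.COLUMNS)).to_csv(path, index=False)
        return path
    df = pd.DataFrame([r.as_dict() for r in records], columns=list(ChondronRecord.COLUMNS))
    df.to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> list[ChondronRecord]:
    """Read a record CSV written by :func:`write_records`."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"record table {path} does not exist")
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        zone = getattr(row, "zone")
        out.append(ChondronRecord(
            id=int(row.id),
            volume_um3=float(row.volume_um3),
            surface_area_um2=float(row.surface_area_um2),
            sphericity=float(row.sphericity),
            z_c=float(row.z_c), y_c=float(row.y_c), x_c=float(row.x_c),
            depth_percent=float(row.depth_percent),
            zone=None if pd.isna(zone) else int(zone),
            classification=str(row.classification),
            status=str(row.status),
        ))
    return out


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit multi-page TIFF (0 / 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.data.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, voxel_size_um: float,
              offset_voxels: tuple[int, int, int] = (0, 0, 0)) -> BinaryMask:
    """Read a binary mask stack written by :func:`write_mask`."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"mask stack {path} does not exist")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return BinaryMask(data > 0, offset_voxels=offset_voxels, voxel_size_um=voxel_size_um)


def write_label_stack(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label volume (chondron id per voxel) as 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels; cannot write uint16 stack")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path
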