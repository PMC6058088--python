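"""Per-chondron 3D morphometry and zone-wise summaries.

Volume is exact voxel counting; surface area comes from a level-0.5
isosurface mesh of the binary mask. Raw marching cubes on binary voxel data
systematically overestimates the area of smooth objects (the staircase
surface is longer than the underlying smooth one; about +8% for a
24-voxel-radius ball), which would bias Wadell sphericity low for every
round object. The mesh is therefore relaxed with a Humphrey filter
(shrinkage-resistant Laplacian smoothing) before the area is measured, which
brings a voxelized ball within ~1% of the analytic sphere area while keeping
a cube within ~5% of its exact area. ``smooth_iterations=0`` gives the raw
marching-cubes area.

Wadell sphericity: Sph = pi^(1/3) (6V)^(2/3) / S, with Sph = 1 for a perfect
sphere and values below 1 for elongated or complex objects.

Depth is measured along z from a single flat articular-surface plane and
expressed as a percentage of cartilage thickness; zones are the standard
depth bands zone 1: [0, 10)%, zone 2: [10, 40)%, zone 3: [40, 100]%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import trimesh
import trimesh.smoothing
from scipy import stats
from skimage import filters, measure

from .errors import (
    EmptyObjectError,
    NoTissueError,
    OutOfTissueError,
    ParameterError,
)
from .volio import BinaryMask, ChondronRecord, VoxelGrid

ZONE_BOUNDS_PERCENT: dict[int, tuple[float, float]] = {
    1: (0.0, 10.0),
    2: (10.0, 40.0),
    3: (40.0, 100.0),
}


def volume_um3(mask: BinaryMask) -> float:
    """Object volume: voxel count times voxel volume (um^3)."""
    n = mask.voxel_count
    if n == 0:
        raise EmptyObjectError("cannot compute volume of an empty mask")
    return n * mask.voxel_size_um ** 3


def mesh_surface_area(mask: BinaryMask, smooth_iterations: int = 20,
                      smooth_alpha: float = 0.2, smooth_beta: float = 0.5) -> float:
    """Surface area (um^2) of the level-0.5 isosurface mesh of the mask.

    The mask is zero-padded by one voxel so that objects touching the array
    boundary still produce a closed surface. With ``smooth_iterations > 0``
    the mesh is relaxed with a Humphrey filter before measurement to remove
    the staircase-area bias of binary marching cubes.
    """
    if mask.voxel_count == 0:
        raise EmptyObjectError("cannot mesh an empty mask")
    vs = mask.voxel_size_um
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(vs, vs, vs))
    if smooth_iterations <= 0:
        return float(measure.mesh_surface_area(verts, faces))
    mesh = trimesh.Trimesh(verts, faces, process=False)
    trimesh.smoothing.filter_humphrey(mesh, alpha=smooth_alpha, beta=smooth_beta,
                                      iterations=smooth_iterations)
    return float(mesh.area)


def sphericity(V: float, S: float) -> float:
    """Wadell sphericity pi^(1/3) (6V)^(2/3) / S; 1 for a perfect sphere."""
    if not (V > 0 and S > 0):
        raise ParameterError(f"sphericity needs V > 0 and S > 0, got V={V}, S={S}")
    return math.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / S


@dataclass
class TissueFrame:
    """Flat-plane tissue frame: surface and bottom slice of the cartilage slab."""

    z_surface: int
    z_bottom: int  # half-open: first slice past the cartilage
    voxel_size_um: float
    voi_cross_section_mm2: float

    def __post_init__(self) -> None:
        if not self.z_surface < self.z_bottom:
            raise ParameterError(f"z_surface {self.z_surface} must precede z_bottom {self.z_bottom}")

    @property
    def thickness_um(self) -> float:
        return (self.z_bottom - self.z_surface) * self.voxel_size_um


def detect_tissue_frame(grid: VoxelGrid, tissue_fraction_threshold: float = 0.5) -> TissueFrame:
    """Locate the cartilage slab along z.

    A global Otsu threshold separates air from tissue; the surface is the
    first slice whose tissue-area fraction reaches the threshold and the
    bottom is one past the last such slice. Override the result manually for
    stacks with irregular surfaces.
    """
    data = grid.data
    if np.ptp(data) == 0:
        raise NoTissueError("constant volume contains no tissue/air contrast")
    thr = filters.threshold_otsu(data, nbins=256)
    fractions = (data > thr).mean(axis=(1, 2))
    passing = np.flatnonzero(fractions >= tissue_fraction_threshold)
    if passing.size == 0:
        raise NoTissueError(f"no slice reaches tissue fraction {tissue_fraction_threshold}")
    _, Y, X = grid.shape
    cross_mm2 = (Y * grid.voxel_size_um * 1e-3) * (X * grid.voxel_size_um * 1e-3)
    return TissueFrame(z_surface=int(passing[0]), z_bottom=int(passing[-1]) + 1,
                       voxel_size_um=grid.voxel_size_um, voi_cross_section_mm2=cross_mm2)


def depth_percent(z_c: float, frame: TissueFrame) -> float:
    """Percent depth of a centroid z-coordinate from the articular surface."""
    if not (frame.z_surface <= z_c <= frame.z_bottom):
        raise OutOfTissueError(f"centroid z={z_c} outside tissue [{frame.z_surface}, {frame.z_bottom}]")
    return 100.0 * (z_c - frame.z_surface) / (frame.z_bottom - frame.z_surface)


def assign_zone(depth: float) -> int:
    """Map a percent depth to zone 1 [0,10), 2 [10,40) or 3 [40,100]."""
    if not (0.0 <= depth <= 100.0):
        raise OutOfTissueError(f"depth {depth}% outside [0, 100]")
    if depth < 10.0:
        return 1
    if depth < 40.0:
        return 2
    return 3


def build_record(rec_id: int, mask: BinaryMask, frame: TissueFrame | None = None,
                 classification: str = "unverified", status: str = "approved",
                 smooth_iterations: int = 20) -> ChondronRecord:
    """Measure one mask into a :class:`ChondronRecord`.

    A centroid outside the tissue frame yields zone=None and NaN depth (the
    record is kept but flagged, so nothing is dropped silently).
    """
    V = volume_um3(mask)
    S = mesh_surface_area(mask, smooth_iterations=smooth_iterations)
    z_c, y_c, x_c = mask.centroid_global()
    rec = ChondronRecord(id=rec_id, volume_um3=V, surface_area_um2=S,
                         sphericity=sphericity(V, S), z_c=z_c, y_c=y_c, x_c=x_c,
                         classification=classification, status=status)
    if frame is not None:
        try:
            rec.depth_percent = depth_percent(z_c, frame)
            rec.zone = assign_zone(rec.depth_percent)
        except OutOfTissueError:
            rec.depth_percent = float("nan")
            rec.zone = None
    return rec


def zone_volume_mm3(frame: TissueFrame, zone: int) -> float:
    """Tissue volume of a depth zone: VOI cross-section x zone thickness."""
    lo, hi = ZONE_BOUNDS_PERCENT[zone]
    thickness_mm = frame.thickness_um * 1e-3 * (hi - lo) / 100.0
    return frame.voi_cross_section_mm2 * thickness_mm


def chondron_density(records: Sequence[ChondronRecord], frame: TissueFrame, zone: int) -> float:
    """Chondrons per mm^3 of tissue in one depth zone."""
    vol = zone_volume_mm3(frame, zone)
    if vol <= 0:
        raise ParameterError(f"zone {zone} has non-positive volume {vol}")
    n = sum(1 for r in records if r.zone == zone)
    return n / vol


def random_subsample(records: Sequence[ChondronRecord], n: int, seed: int) -> list[ChondronRecord]:
    """Uniform sample of n records without replacement, input order preserved."""
    if n < 0:
        raise ParameterError(f"subsample size must be >= 0, got {n}")
    if n >= len(records):
        return list(records)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in sorted(idx)]


@dataclass
class ZoneSummary:
    """Descriptive statistics for one depth zone (and optional group label).

    For each of volume and sphericity: mean, SD, median, interquartile range
    and a t-based 95% CI on the mean. With fewer than two records SD, IQR
    and CI are NaN markers.
    """

    zone: int
    group: str | None
    depth_bounds_percent: tuple[float, float]
    n_chondrons: int
    density_per_mm3: float
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict:
        row: dict = {
            "zone": self.zone, "group": self.group,
            "depth_lo_percent": self.depth_bounds_percent[0],
            "depth_hi_percent": self.depth_bounds_percent[1],
            "n_chondrons": self.n_chondrons,
            "density_per_mm3": self.density_per_mm3,
        }
        for param, st in self.stats.items():
            for k, v in st.items():
                row[f"{param}_{k}"] = v
        return row


def _describe(values: np.ndarray) -> dict[str, float]:
    nan = float("nan")
    if values.size == 0:
        return {k: nan for k in ("mean", "sd", "median", "q1", "q3", "iqr", "ci95_lo", "ci95_hi")}
    mean = float(values.mean())
    median = float(np.median(values))
    if values.size < 2:
        return {"mean": mean, "sd": nan, "median": median,
                "q1": nan, "q3": nan, "iqr": nan, "ci95_lo": nan, "ci95_hi": nan}
    sd = float(values.std(ddof=1))
    q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
    half = float(stats.t.ppf(0.975, values.size - 1)) * sd / math.sqrt(values.size)
    return {"mean": mean, "sd": sd, "median": median, "q1": q1, "q3": q3,
            "iqr": q3 - q1, "ci95_lo": mean - half, "ci95_hi": mean + half}


def summarize(records: Sequence[ChondronRecord], frame: TissueFrame | None = None,
              groups: Mapping[int, str] | None = None) -> list[ZoneSummary]:
    """Zone-wise (optionally group-wise) descriptive summaries.

    Only in-tissue records (zone assigned) contribute. Density requires a
    tissue frame; without one it is reported as NaN.
    """
    in_tissue = [r for r in records if r.zone is not None]
    labels = sorted({groups[r.id] for r in in_tissue}) if groups else [None]
    out: list[ZoneSummary] = []
    for label in labels:
        sel = [r for r in in_tissue if groups is None or groups[r.id] == label]
        for zone in (1, 2, 3):
            zr = [r for r in sel if r.zone == zone]
            density = chondron_density(zr, frame, zone) if frame is not None else float("nan")
            out.append(ZoneSummary(
                zone=zone, group=label, depth_bounds_percent=ZONE_BOUNDS_PERCENT[zone],
                n_chondrons=len(zr), density_per_mm3=density,
                stats={
                    "volume_um3": _describe(np.array([r.volume_um3 for r in zr])),
                    "sphericity": _describe(np.array([r.sphericity for r in zr])),
                },
            ))
    return out


def summaries_to_frame(summaries: Sequence[ZoneSummary]):
    """Flatten zone summaries into a pandas DataFrame for CSV export."""
    import pandas as pd

    return pd.DataFrame([s.as_row() for s in summaries])
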