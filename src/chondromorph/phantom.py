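"""Synthetic osteochondral micro-CT phantoms with ground truth.

Emulates HMDS-dried articular cartilage as imaged by desktop micro-CT:
because drying removes the water that fills living chondrocytes, chondrons
appear as hypo-intense (dark) ellipsoidal lacunae inside the brighter
extracellular matrix, with air above the articular surface. The generator
plants depth-dependent chondron density and size following the zone
structure reported for human tibial cartilage, and can fuse 2-4 overlapping
ellipsoids into multi-cell clusters.

Default zone densities and sizes correspond to intact (low-OARSI-grade)
tissue: densities (3418, 5131, 4349) chondrons/mm^3 and mean volumes of
roughly 5.6 / 5.9 / 11.6 x 10^3 um^3 in zones 1-3; the ellipsoid semi-axis
means are derived from those volumes via abc = 3V / (4 pi). An "OA-like"
parameter set (larger, more elongated deep-zone chondrons at slightly lower
superficial density) is provided for group-contrast experiments.

Placement draws the per-zone object count from a Poisson law with rate
density x zone volume, then places each object fully inside the cartilage
slab with a clearance margin between objects and to the lateral faces.
Collisions are resolved by redrawing the position (z restricted to the
zone's feasible band), so realized per-zone counts stay Poisson-consistent
with the planted rates; the cost is that centers close to the articular
surface are slightly under-represented for large objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ConfigError, PlacementError
from .volio import BinaryMask, VoxelGrid

ZONE_FRACTIONS = ((0.0, 0.1), (0.1, 0.4), (0.4, 1.0))

#: intact-tissue semi-axis means per zone (um), from abc = 3V/(4 pi) at the
#: reported zone mean volumes 5578 / 5909 / 11560 um^3
INTACT_SEMI_AXES_UM = ((8.0, 11.0, 15.1), (8.0, 11.0, 16.0), (10.0, 14.0, 20.0))
INTACT_DENSITIES = (3418.0, 5131.0, 4349.0)

#: OA-like set: zone 1-3 volumes up by ~1.5 / 1.9 / 1.7x and deep-zone axes
#: more elongated (analytic sphericity lower by ~0.04-0.05 in zones 2-3),
#: densities slightly lower superficially
OA_SEMI_AXES_UM = ((8.8, 12.1, 18.4), (9.0, 12.7, 23.9), (10.7, 15.7, 28.4))
OA_DENSITIES = (2219.0, 4143.0, 4444.0)


@dataclass
class PhantomSpec:
    """Generator parameters; defaults are the intact-tissue conditions."""

    dims_voxels: tuple[int, int, int] = (230, 160, 160)  # (Z, Y, X)
    voxel_size_um: float = 1.6
    z_surface: int = 10
    z_bottom: int = 220
    zone_densities: tuple[float, float, float] = INTACT_DENSITIES  # chondrons/mm^3
    semi_axes_mean_um: tuple[tuple[float, float, float], ...] = INTACT_SEMI_AXES_UM
    semi_axes_rel_sd: float = 0.15
    min_semi_axis_um: float = 5.0
    cluster_probability: float = 0.3
    ecm_intensity: float = 0.65
    chondron_intensity: float = 0.25
    air_intensity: float = 0.0
    noise_sd: float = 0.03
    chondrons_dark: bool = True  # polarity flag; False inverts the contrast
    clearance_voxels: int = 3
    lateral_margin_voxels: int = 2
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        Z = self.dims_voxels[0]
        if not (0 <= self.z_surface < self.z_bottom <= Z):
            raise ConfigError(f"need 0 <= z_surface < z_bottom <= Z, got "
                              f"{self.z_surface}, {self.z_bottom}, Z={Z}")
        if any(d < 0 for d in self.zone_densities):
            raise ConfigError("zone_densities must be non-negative")
        if not 0.0 <= self.cluster_probability <= 1.0:
            raise ConfigError(f"cluster_probability must be in [0,1], got {self.cluster_probability}")
        for name in ("ecm_intensity", "chondron_intensity", "air_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.ecm_intensity <= self.chondron_intensity:
            raise ConfigError("ecm_intensity must exceed chondron_intensity")
        if self.voxel_size_um <= 0:
            raise ConfigError("voxel_size_um must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown phantom spec fields: {sorted(unknown)}")
        for key in ("dims_voxels", "zone_densities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "semi_axes_mean_um" in raw:
            raw["semi_axes_mean_um"] = tuple(tuple(z) for z in raw["semi_axes_mean_um"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path


@dataclass
class TruthObject:
    """Ground truth for one planted chondron."""

    id: int
    classification: str  # single | cluster
    center: tuple[float, float, float]  # (z, y, x) voxels, parent frame
    zone: int
    semi_axes_um: tuple[float, float, float] | None  # None for clusters
    analytic_volume_um3: float  # 4/3 pi abc for singles, voxel volume for clusters
    voxel_count: int
    mask: BinaryMask


@dataclass
class PhantomTruth:
    """All planted objects plus the frame geometry of the phantom."""

    objects: list[TruthObject]
    z_surface: int
    z_bottom: int
    voxel_size_um: float

    @property
    def masks(self) -> list[BinaryMask]:
        return [o.mask for o in self.objects]

    def records_frame(self):
        import pandas as pd

        rows = [{
            "id": o.id, "classification": o.classification,
            "z_c": o.center[0], "y_c": o.center[1], "x_c": o.center[2],
            "zone": o.zone,
            "analytic_volume_um3": o.analytic_volume_um3,
            "voxel_count": o.voxel_count,
        } for o in self.objects]
        return pd.DataFrame(rows)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()


def _voxelize_ellipsoids(ellipsoids: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a union of rotated ellipsoids into a tight local mask.

    Each ellipsoid is (center_offset_vox, semi_axes_vox, rotation_matrix); a
    voxel belongs to it when ||diag(1/axes) R^T (p - c)|| <= 1.

    Returns (local bool mask, origin offset of the mask relative to the
    nominal object center).
    """
    radius = max(float(np.max(ax)) + float(np.max(np.abs(c))) for c, ax, _ in ellipsoids)
    half = int(np.ceil(radius)) + 1
    coords = np.arange(-half, half + 1, dtype=np.float64)
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    mask = np.zeros(zz.shape, dtype=bool)
    for c, axes, R in ellipsoids:
        local = (pts - c) @ R  # rotate into the ellipsoid frame
        mask |= (np.square(local / axes).sum(axis=-1) <= 1.0)
    # crop to tight bbox
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], lo - half


def _zone_bands(spec: PhantomSpec) -> list[tuple[float, float]]:
    thickness = spec.z_bottom - spec.z_surface
    return [(spec.z_surface + lo * thickness, spec.z_surface + hi * thickness)
            for lo, hi in ZONE_FRACTIONS]


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, PhantomTruth]:
    """Generate a phantom volume and its ground truth.

    Deterministic for a given spec (identical seed -> bit-identical output).
    Raises :class:`PlacementError` when the planted densities are too high
    for non-overlapping placement within the bounded retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    Z, Y, X = spec.dims_voxels
    vs = spec.voxel_size_um

    grid = np.full((Z, Y, X), spec.air_intensity, dtype=np.float32)
    grid[spec.z_surface:spec.z_bottom] = spec.ecm_intensity

    occupied = np.zeros((Z, Y, X), dtype=bool)   # dilated-by-clearance footprint
    clearance_ball = _ball_structure(spec.clearance_voxels)

    cross_mm2 = (Y * vs * 1e-3) * (X * vs * 1e-3)
    bands = _zone_bands(spec)
    objects: list[TruthObject] = []
    next_id = 1

    for zone_idx, ((z_lo, z_hi), density) in enumerate(zip(bands, spec.zone_densities)):
        zone_vol_mm3 = cross_mm2 * (z_hi - z_lo) * vs * 1e-3
        n_objects = int(rng.poisson(density * zone_vol_mm3))
        for _ in range(n_objects):
            obj = _place_object(rng, spec, zone_idx, (z_lo, z_hi), occupied,
                                clearance_ball, next_id)
            objects.append(obj)
            next_id += 1

    lo_i, hi_i = ((spec.chondron_intensity, spec.ecm_intensity) if spec.chondrons_dark
                  else (spec.ecm_intensity, spec.chondron_intensity))
    for obj in objects:
        z0, y0, x0 = obj.mask.offset_voxels
        dz, dy, dx = obj.mask.data.shape
        region = grid[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx]
        region[obj.mask.data] = lo_i
    if not spec.chondrons_dark:
        # invert slab background so chondrons stay the minority phase
        slab = grid[spec.z_surface:spec.z_bottom]
        slab[:] = np.where(np.isclose(slab, spec.ecm_intensity), lo_i, slab)
        for obj in objects:
            z0, y0, x0 = obj.mask.offset_voxels
            dz, dy, dx = obj.mask.data.shape
            grid[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx][obj.mask.data] = hi_i

    if spec.noise_sd > 0:
        grid = np.clip(grid + rng.normal(0.0, spec.noise_sd, grid.shape).astype(np.float32),
                       0.0, 1.0)

    truth = PhantomTruth(objects=objects, z_surface=spec.z_surface,
                         z_bottom=spec.z_bottom, voxel_size_um=vs)
    return VoxelGrid(grid, vs), truth


def _ball_structure(radius: int) -> np.ndarray:
    if radius <= 0:
        return ndimage.generate_binary_structure(3, 1)
    r = int(radius)
    c = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
    return (zz ** 2 + yy ** 2 + xx ** 2) <= r ** 2


def _draw_shape(rng: np.random.Generator, spec: PhantomSpec, zone_idx: int):
    """Draw one object's geometry: ellipsoid union, classification, analytics."""
    vs = spec.voxel_size_um
    mean_axes = np.array(spec.semi_axes_mean_um[zone_idx], dtype=float)
    is_cluster = rng.random() < spec.cluster_probability

    def draw_axes() -> np.ndarray:
        ax = rng.normal(mean_axes, spec.semi_axes_rel_sd * mean_axes)
        return np.maximum(ax, spec.min_semi_axis_um)

    if not is_cluster:
        axes_um = draw_axes()
        ell = [(np.zeros(3), axes_um / vs, _random_rotation(rng))]
        analytic = 4.0 / 3.0 * np.pi * float(np.prod(axes_um))
        return ell, "single", tuple(float(a) for a in axes_um), analytic
    k = int(rng.integers(2, 5))
    ells = [(np.zeros(3), draw_axes() / vs, _random_rotation(rng))]
    for _ in range(k - 1):
        axes_um = draw_axes() * 0.85  # satellite cells slightly smaller
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset_um = direction * rng.uniform(0.5, 1.0) * float(np.min(mean_axes))
        ells.append((offset_um / vs, axes_um / vs, _random_rotation(rng)))
    return ells, "cluster", None, None  # analytic volume filled from voxel count


def _place_object(rng: np.random.Generator, spec: PhantomSpec, zone_idx: int,
                  band: tuple[float, float], occupied: np.ndarray,
                  clearance_ball: np.ndarray, obj_id: int) -> TruthObject:
    Z, Y, X = spec.dims_voxels
    vs = spec.voxel_size_um
    margin = spec.lateral_margin_voxels

    for attempt in range(spec.max_retries):
        ells, classification, axes_um, analytic = _draw_shape(rng, spec, zone_idx)
        local_mask, local_origin = _voxelize_ellipsoids(ells)
        dz, dy, dx = local_mask.shape
        # feasible center band: object fully inside tissue slab and lateral margins
        z_lo = max(band[0], spec.z_surface - local_origin[0])
        z_hi = min(band[1], spec.z_bottom - local_origin[0] - dz)
        y_lo, y_hi = margin - local_origin[1], Y - margin - local_origin[1] - dy
        x_lo, x_hi = margin - local_origin[2], X - margin - local_origin[2] - dx
        if z_hi <= z_lo or y_hi <= y_lo or x_hi <= x_lo:
            continue  # object too large for this zone band; redraw shape
        center = np.array([rng.uniform(z_lo, z_hi), rng.uniform(y_lo, y_hi),
                           rng.uniform(x_lo, x_hi)])
        origin = np.round(center).astype(int) + local_origin
        z0, y0, x0 = origin
        window = occupied[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx]
        if np.any(window & local_mask):
            continue
        # commit: mark a clearance-dilated footprint as occupied
        pad = spec.clearance_voxels
        dil = ndimage.binary_dilation(np.pad(local_mask, pad), structure=clearance_ball)
        gz0, gy0, gx0 = max(z0 - pad, 0), max(y0 - pad, 0), max(x0 - pad, 0)
        gz1, gy1, gx1 = min(z0 + dz + pad, Z), min(y0 + dy + pad, Y), min(x0 + dx + pad, X)
        lz0, ly0, lx0 = gz0 - (z0 - pad), gy0 - (y0 - pad), gx0 - (x0 - pad)
        occupied[gz0:gz1, gy0:gy1, gx0:gx1] |= dil[lz0:lz0 + (gz1 - gz0),
                                                   ly0:ly0 + (gy1 - gy0),
                                                   lx0:lx0 + (gx1 - gx0)]
        mask = BinaryMask(local_mask, offset_voxels=(int(z0), int(y0), int(x0)),
                          voxel_size_um=vs)
        count = int(local_mask.sum())
        if analytic is None:
            analytic = count * vs ** 3
        centroid = mask.centroid_global()
        return TruthObject(id=obj_id, classification=classification,
                           center=centroid, zone=zone_idx + 1,
                           semi_axes_um=axes_um, analytic_volume_um3=float(analytic),
                           voxel_count=count, mask=mask)
    raise PlacementError(f"could not place object {obj_id} in zone {zone_idx + 1} "
                         f"after {spec.max_retries} attempts; densities too high?")


def oa_like_spec(**overrides) -> PhantomSpec:
    """PhantomSpec with the OA-like group conditions (larger, more elongated
    deep-zone chondrons; lower superficial density)."""
    kwargs = dict(zone_densities=OA_DENSITIES, semi_axes_mean_um=OA_SEMI_AXES_UM)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
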