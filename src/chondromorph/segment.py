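"""Per-candidate chondron segmentation.

The segmenter assesses the volumetric continuity of the dark chondron phase
by probing, at every visited voxel, the gray-level distribution on the
surfaces of concentric spheres of several radii (a multiscale, rank-based
reading of spherical local-binary-pattern texture analysis). Each sub-VOI is
first contrast-enhanced by global 3D histogram equalization, which also
makes the scoring invariant to affine intensity transforms of the input.

For a probe sphere of radius ``r`` centred on a voxel, the fraction ``f_r``
of surface samples that are still "chondron-dark" — within a contrast
margin of a reference intensity (the seed's equalized intensity during
region growth) — estimates how interior the voxel is at that scale. The
interiority score pools ``f_r`` over radii with weights proportional to
``r^2`` (surface area). Because probe spheres of radius comparable to the
object radius see mostly matrix even at the interface, the score alone
cannot localize the boundary of small chondrons without a size-dependent
bias; region growth therefore accepts a voxel only when it is itself
chondron-dark (which places the boundary with voxel accuracy) AND its
interiority score clears the threshold (which severs spurious thin bridges
and rejects bright chondrocyte remnants treated as background texture).
Small default radii (1-5 voxels) keep the probes sensitive to single-cell
scale while breadth-first growth from the seed handles arbitrarily large
clusters.

The grown region is closed morphologically (radius 1) to fill pinholes left
by bright chondrocyte remnants inside chondrons, and the single connected
component containing the seed is returned. Masks below the minimum-volume
rule (default 400 um^3, inclusive) are rejected as probable artifacts, and
near-duplicate masks (pairwise Dice above 0.3) are resolved by keeping the
largest object of each overlap group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters

from .detect import SubVOI
from .errors import (
    BoundsError,
    DegenerateInputError,
    ParameterError,
    UndefinedScoreError,
)
from .volio import BinaryMask, VoxelGrid

_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters.

    radii_um
        Ascending probe-sphere radii. ``None`` (default) selects radii per
        candidate as ``radii_fractions`` of its equivalent-sphere radius
        (floored at one voxel), so probes stay below the scale of the object
        being grown; a fixed list pins the scales explicitly.
    radii_fractions
        Fractions of the candidate equivalent radius used when
        ``radii_um`` is None.
    n_surface_samples
        Points per sphere surface (deterministic Fibonacci lattice).
    interiority_threshold
        Region-growth acceptance threshold tau in (0, 1) on the multiscale
        score; growth additionally requires the voxel itself to be
        chondron-dark, so tau controls continuity, not the boundary.
    contrast_margin
        Tolerance, in equalized-intensity units, for counting a sample as
        chondron-dark relative to the reference intensity.
    min_volume_um3
        Segmented masks below this volume are rejected as artifacts
        (inclusive at the boundary).
    """

    radii_um: tuple[float, ...] | None = None
    radii_fractions: tuple[float, ...] = (0.15, 0.3, 0.45, 0.6)
    n_surface_samples: int = 64
    interiority_threshold: float = 0.25
    equalization_bins: int = 256
    contrast_margin: float = 0.1
    min_volume_um3: float = 400.0
    connectivity: int = 26
    closing_radius: int = 1

    def __post_init__(self) -> None:
        if self.radii_um is not None:
            radii = tuple(float(r) for r in self.radii_um)
            if not radii or any(r <= 0 for r in radii) or list(radii) != sorted(radii):
                raise ParameterError(f"radii_um must be positive and ascending, got {radii}")
            self.radii_um = radii
        if not self.radii_fractions or any(f <= 0 for f in self.radii_fractions):
            raise ParameterError("radii_fractions must be positive")
        if self.n_surface_samples < 16:
            raise ParameterError("n_surface_samples must be >= 16")
        if not 0.0 < self.interiority_threshold < 1.0:
            raise ParameterError("interiority_threshold must be in (0, 1)")
        if self.min_volume_um3 <= 0:
            raise ParameterError("min_volume_um3 must be positive")
        if self.connectivity not in _STRUCTURE_RANK:
            raise ParameterError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


def equalize_3d(sub: SubVOI, bins: int = 256) -> SubVOI:
    """Global 3D histogram equalization of a sub-VOI.

    Intensities are mapped through the normalized cumulative histogram
    (monotone non-decreasing), yielding an approximately uniform histogram
    in [0, 1]. A constant sub-VOI has no contrast to enhance and is an error.
    """
    data = sub.grid.data
    if np.ptp(data) == 0:
        raise DegenerateInputError("constant sub-VOI cannot be equalized")
    hist, edges = np.histogram(data, bins=bins)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf /= cdf[-1]
    centers = (edges[:-1] + edges[1:]) / 2.0
    eq = np.interp(data.ravel(), centers, cdf).reshape(data.shape).astype(np.float32)
    grid = _dc_replace(sub.grid, data=eq)
    return SubVOI(grid=grid, offset_voxels=sub.offset_voxels, seed_local=sub.seed_local)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform lattice of n unit vectors on the sphere."""
    i = np.arange(n, dtype=np.float64)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([z, rho * np.cos(theta), rho * np.sin(theta)])


def sphere_profile(grid: VoxelGrid, center: tuple[float, float, float],
                   radius_um: float, n: int) -> np.ndarray:
    """Trilinear-interpolated intensities at n lattice points on a sphere
    surface; the whole sphere must fit inside the grid."""
    r_vox = radius_um / grid.voxel_size_um
    c = np.asarray(center, dtype=np.float64)
    dims = np.array(grid.shape)
    if np.any(c - r_vox < 0) or np.any(c + r_vox > dims - 1):
        raise BoundsError(f"sphere r={radius_um}um at {center} exceeds grid {grid.shape}")
    pts = c + r_vox * fibonacci_sphere(n)
    return ndimage.map_coordinates(grid.data, pts.T, order=1, mode="nearest")


#: fallback probe radii (1-5 voxels at 1.6 um) for standalone scoring
DEFAULT_RADII_UM = (1.6, 3.2, 4.8, 6.4, 8.0)


def _batch_scores(data: np.ndarray, voxels: np.ndarray, reference: float,
                  params: SegmentationParams, voxel_size_um: float,
                  dirs: np.ndarray,
                  radii_um: tuple[float, ...] | None = None) -> np.ndarray:
    """Interiority scores for a (K, 3) batch of voxel coordinates.

    Radii whose sphere does not fit around a given voxel are dropped for
    that voxel and the r^2 weights renormalized; a voxel with no usable
    radius scores NaN.
    """
    if radii_um is None:
        radii_um = params.radii_um if params.radii_um is not None else DEFAULT_RADII_UM
    radii_vox = np.array(radii_um, dtype=np.float64) / voxel_size_um
    weights = np.array(radii_um, dtype=np.float64) ** 2
    K, R, n = len(voxels), len(radii_vox), params.n_surface_samples
    dims = np.array(data.shape, dtype=np.float64)

    # usable[k, r]: sphere of radius r fits inside the grid around voxel k
    margin_lo = voxels.min(axis=1)  # min over axes of distance to low faces
    margin_hi = (dims - 1 - voxels).min(axis=1)
    fit = np.minimum(margin_lo, margin_hi)[:, None] >= radii_vox[None, :]

    # sample coordinates for all voxels x radii x directions
    pts = (voxels[:, None, None, :]
           + radii_vox[None, :, None, None] * dirs[None, None, :, :])  # (K,R,n,3)
    vals = ndimage.map_coordinates(data, pts.reshape(-1, 3).T, order=1,
                                   mode="nearest").reshape(K, R, n)
    dark = vals <= reference + params.contrast_margin
    f = dark.mean(axis=2)  # (K, R)

    w = np.where(fit, weights[None, :], 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (w * f).sum(axis=1) / wsum
    scores[wsum == 0] = np.nan
    return scores


def interiority_score(grid: VoxelGrid, voxel: tuple[int, int, int],
                      params: SegmentationParams,
                      reference_intensity: float | None = None) -> float:
    """Multiscale interiority score in [0, 1] for one voxel.

    1 means every probe-sphere surface is still chondron-dark (deep
    interior), 0 means none is (background). ``reference_intensity``
    anchors "dark"; it defaults to the grid value at the voxel itself, and
    region growth passes the seed's equalized intensity instead.
    """
    v = np.asarray([voxel], dtype=np.float64)
    ref = float(grid.data[tuple(voxel)]) if reference_intensity is None else float(reference_intensity)
    score = _batch_scores(grid.data, v, ref, params, grid.voxel_size_um,
                          fibonacci_sphere(params.n_surface_samples))[0]
    if np.isnan(score):
        raise UndefinedScoreError(f"no probe radius fits around voxel {voxel} in grid {grid.shape}")
    return float(score)


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[connectivity])
    offs = np.argwhere(struct) - 1
    return offs[np.any(offs != 0, axis=1)]


def segment_chondron(sub: SubVOI, params: SegmentationParams | None = None
                     ) -> tuple[BinaryMask | None, str]:
    """Grow a chondron mask from the sub-VOI seed.

    Returns ``(mask, "segmented")`` on success or ``(None, "failed")`` when
    the seed itself is not accepted (a failed candidate, not an exception).
    Growth accepts a voxel when it is chondron-dark (equalized intensity
    within the contrast margin of the seed's, capped at the sub-VOI's Otsu
    split) and its interiority score reaches the threshold. The mask is 26-connected (or the configured
    connectivity), contains the seed, and has been closed with a radius-1
    ball.
    """
    params = params or SegmentationParams()
    eq = equalize_3d(sub, params.equalization_bins)
    data = eq.grid.data
    seed = tuple(int(s) for s in sub.seed_local)
    ref = float(data[seed])
    dirs = fibonacci_sphere(params.n_surface_samples)
    tau = params.interiority_threshold
    offsets = _neighbor_offsets(params.connectivity)
    dims = np.array(data.shape)
    vs = eq.grid.voxel_size_um
    # darkness cut: within the contrast margin of the seed rank, but never
    # past the sub-VOI's own Otsu split (computed on the raw intensities,
    # then expressed as a rank) — otherwise the darkest tail of the matrix
    # noise qualifies and growth can bridge between nearby chondrons
    raw = sub.grid.data
    otsu_raw = filters.threshold_otsu(raw, nbins=params.equalization_bins)
    otsu_rank = float((raw <= otsu_raw).mean())
    if ref > otsu_rank + 1e-6:  # epsilon absorbs float32 equalization rounding
        return None, "failed"  # seed lies in the bright class: false candidate
    dark_cut = min(ref + params.contrast_margin, max(otsu_rank, ref))

    if params.radii_um is not None:
        radii_um = params.radii_um
    else:
        # adapt probe scales to the candidate: fractions of the equivalent
        # radius of the dark component containing the seed
        struct0 = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[params.connectivity])
        labels0, _ = ndimage.label(data <= dark_cut, structure=struct0)
        n_dark = max(int((labels0 == labels0[seed]).sum()), 1)
        r_eq_vox = (3.0 * n_dark / (4.0 * np.pi)) ** (1.0 / 3.0)
        radii_vox = np.unique(np.maximum(1.0, np.array(params.radii_fractions) * r_eq_vox))
        radii_um = tuple(float(r) * vs for r in radii_vox)

    seed_score = _batch_scores(data, np.asarray([seed], dtype=np.float64), ref,
                               params, vs, dirs, radii_um)[0]
    if not seed_score >= tau:  # NaN also fails
        return None, "failed"

    accepted = np.zeros(data.shape, dtype=bool)
    visited = np.zeros(data.shape, dtype=bool)
    accepted[seed] = visited[seed] = True
    frontier = np.asarray([seed], dtype=np.int64)
    while frontier.size:
        cand = (frontier[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        valid = np.all((cand >= 0) & (cand < dims), axis=1)
        cand = cand[valid]
        flat = np.ravel_multi_index(cand.T, data.shape)
        # unique unvisited candidates, stable order
        _, first = np.unique(flat, return_index=True)
        cand = cand[np.sort(first)]
        unseen = ~visited.ravel()[np.ravel_multi_index(cand.T, data.shape)]
        cand = cand[unseen]
        if cand.size == 0:
            break
        visited.ravel()[np.ravel_multi_index(cand.T, data.shape)] = True
        # cheap darkness gate first; score only the dark survivors
        dark = data[tuple(cand.T)] <= dark_cut
        cand = cand[dark]
        if cand.size == 0:
            break
        scores = _batch_scores(data, cand.astype(np.float64), ref, params,
                               vs, dirs, radii_um)
        good = scores >= tau
        accepted.ravel()[np.ravel_multi_index(cand[good].T, data.shape)] = True
        frontier = cand[good]

    if params.closing_radius > 0:
        r = params.closing_radius
        c = np.arange(-r, r + 1)
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        ball = (zz ** 2 + yy ** 2 + xx ** 2) <= r ** 2
        accepted = ndimage.binary_closing(np.pad(accepted, r), structure=ball)[
            tuple(slice(r, -r) for _ in range(3))]

    struct = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[params.connectivity])
    labels, _ = ndimage.label(accepted, structure=struct)
    component = labels == labels[seed]
    return BinaryMask(component, offset_voxels=sub.offset_voxels,
                      voxel_size_um=sub.grid.voxel_size_um), "segmented"


def apply_min_volume(mask: BinaryMask, min_volume_um3: float = 400.0) -> bool:
    """Keep (True) iff voxel count x voxel volume >= min_volume_um3 (inclusive)."""
    return mask.voxel_count * mask.voxel_size_um ** 3 >= min_volume_um3


def _pair_dice(m1: BinaryMask, m2: BinaryMask) -> float:
    """Dice overlap of two masks in their shared parent frame (0 if disjoint)."""
    b1 = np.array(m1.offset_voxels), np.array(m1.offset_voxels) + np.array(m1.data.shape)
    b2 = np.array(m2.offset_voxels), np.array(m2.offset_voxels) + np.array(m2.data.shape)
    lo = np.maximum(b1[0], b2[0])
    hi = np.minimum(b1[1], b2[1])
    B, C = m1.voxel_count, m2.voxel_count
    if B + C == 0:
        return 0.0
    if np.any(hi <= lo):
        return 0.0
    s1 = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, m1.offset_voxels))
    s2 = tuple(slice(l - o, h - o) for l, h, o in zip(lo, hi, m2.offset_voxels))
    A = int((m1.data[s1] & m2.data[s2]).sum())
    return 2.0 * A / (B + C)


def deduplicate(masks: Sequence[BinaryMask], dsc_cutoff: float = 0.3) -> list[BinaryMask]:
    """Drop near-duplicate segmentations.

    Mask pairs with Dice overlap above ``dsc_cutoff`` form overlap groups
    (transitively); only the largest-volume mask of each group is kept.
    Output preserves input order.
    """
    n = len(masks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_dice(masks[i], masks[j]) > dsc_cutoff:
                parent[find(i)] = find(j)
    best: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in best or masks[i].voxel_count > masks[best[root]].voxel_count:
            best[root] = i
    keep = sorted(best.values())
    return [masks[i] for i in keep]
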