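"""Segmentation: equalization, sphere probes, region growth, filters."""

from __future__ import annotations

import numpy as np
import pytest

from chondromorph import segment, validate
from chondromorph.detect import SubVOI
from chondromorph.errors import BoundsError, DegenerateInputError, ParameterError
from chondromorph.segment import SegmentationParams, fibonacci_sphere
from chondromorph.volio import BinaryMask, VoxelGrid


def ball_grid(n=48, radius_vox=12, dark=0.2, bright=0.8, voxel_size=1.6):
    """Dark ball in bright background; returns (grid, truth mask)."""
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[:n, :n, :n]
    ball = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox ** 2
    data = np.where(ball, dark, bright).astype(np.float32)
    return VoxelGrid(data, voxel_size), ball


def as_subvoi(grid, seed):
    return SubVOI(grid=grid, offset_voxels=(0, 0, 0), seed_local=seed)


class TestEqualize:
    def test_two_valued_image_maps_to_cumulative_frequencies(self):
        data = np.zeros((4, 4, 4), dtype=np.float32)
        data.ravel()[:16] = 1.0  # 25% high, 75% low
        sub = as_subvoi(VoxelGrid(data, 1.6), (0, 0, 0))
        eq = segment.equalize_3d(sub, bins=256).grid.data
        low, high = eq[data == 0][0], eq[data == 1][0]
        assert low == pytest.approx(0.75, abs=0.01)
        assert high == pytest.approx(1.0, abs=0.01)
        assert low < high

    def test_order_preserved_for_every_voxel_pair(self):
        rng = np.random.default_rng(3)
        data = rng.random((8, 8, 8)).astype(np.float32)
        eq = segment.equalize_3d(as_subvoi(VoxelGrid(data, 1.6), (0, 0, 0))).grid.data
        flat_in, flat_out = data.ravel(), eq.ravel()
        order = np.argsort(flat_in, kind="stable")
        # input order implies output order (ties allowed)
        assert np.all(np.diff(flat_out[order]) >= -1e-7)
        assert eq.min() >= 0.0 and eq.max() <= 1.0

    def test_uniform_histogram_is_near_fixed_point(self):
        data = np.linspace(0.0, 1.0, 512, dtype=np.float32).reshape(8, 8, 8)
        eq = segment.equalize_3d(as_subvoi(VoxelGrid(data, 1.6), (0, 0, 0)), bins=256).grid.data
        assert np.max(np.abs(eq - data)) <= 1.0 / 256 + 1e-6

    def test_constant_subvoi_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment.equalize_3d(as_subvoi(VoxelGrid(np.full((4, 4, 4), 0.3), 1.6), (0, 0, 0)))


class TestSphereProfile:
    def test_constant_grid_returns_constant_samples(self):
        g = VoxelGrid(np.full((20, 20, 20), 0.42, dtype=np.float32), 1.6)
        vals = segment.sphere_profile(g, (9.5, 9.5, 9.5), radius_um=8.0, n=100)
        assert vals.shape == (100,)
        np.testing.assert_allclose(vals, 0.42, atol=1e-6)

    def test_dark_ball_oracle(self):
        g, _ = ball_grid(n=48, radius_vox=12)
        center = ((48 - 1) / 2.0,) * 3
        inside = segment.sphere_profile(g, center, radius_um=8 * 1.6, n=200)
        assert np.all(inside < 0.5)  # all samples in the dark phase
        outside = segment.sphere_profile(g, center, radius_um=18 * 1.6, n=200)
        assert np.all(outside > 0.5)  # fully in the bright phase
        straddle = segment.sphere_profile(g, center, radius_um=12 * 1.6, n=200)
        assert (straddle < 0.5).any() and (straddle > 0.5).any()

    def test_sphere_exceeding_bounds_raises(self):
        g = VoxelGrid(np.zeros((10, 10, 10), dtype=np.float32) + 0.5, 1.6)
        with pytest.raises(BoundsError):
            segment.sphere_profile(g, (5, 5, 5), radius_um=20.0, n=32)

    def test_fibonacci_lattice_is_unit_and_deterministic(self):
        pts = fibonacci_sphere(64)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(64))


class TestInteriorityScore:
    params = SegmentationParams(radii_um=(1.6, 3.2, 4.8, 6.4, 8.0))

    def test_deep_interior_scores_high(self):
        g, _ = ball_grid(n=48, radius_vox=16)
        c = tuple([24] * 3)
        assert segment.interiority_score(g, c, self.params) >= 0.95

    def test_bright_background_scores_low(self):
        g, _ = ball_grid(n=64, radius_vox=8)
        # far from the ball, with the chondron-dark value as reference
        score = segment.interiority_score(g, (8, 8, 8), self.params, reference_intensity=0.2)
        assert score <= 0.05

    def test_score_is_bounded(self):
        rng = np.random.default_rng(4)
        g = VoxelGrid(rng.random((30, 30, 30)).astype(np.float32), 1.6)
        for _ in range(10):
            v = tuple(rng.integers(8, 22, 3))
            assert 0.0 <= segment.interiority_score(g, v, self.params) <= 1.0


class TestSegmentChondron:
    def ellipsoid_subvoi(self, semi=(10, 7, 5), n=44, noise=0.0, seed=0,
                         a=1.0, b=0.0):
        rng = np.random.default_rng(seed)
        c = (n - 1) / 2.0
        z, y, x = np.mgrid[:n, :n, :n]
        truth = ((z - c) / semi[0]) ** 2 + ((y - c) / semi[1]) ** 2 + ((x - c) / semi[2]) ** 2 <= 1
        data = np.where(truth, 0.25, 0.65).astype(np.float32)
        if noise:
            data = np.clip(data + rng.normal(0, noise, data.shape).astype(np.float32), 0, 1)
        data = a * data + b
        grid = VoxelGrid(data, 1.6)
        return as_subvoi(grid, (n // 2, n // 2, n // 2)), BinaryMask(truth, voxel_size_um=1.6)

    def test_noise_free_ellipsoid_dsc(self):
        sub, truth = self.ellipsoid_subvoi()
        mask, status = segment.segment_chondron(sub, SegmentationParams())
        assert status == "segmented"
        assert validate.dice(mask, truth).dsc >= 0.90

    def test_mask_contract_connected_and_contains_seed(self):
        sub, _ = self.ellipsoid_subvoi(noise=0.03, seed=2)
        mask, status = segment.segment_chondron(sub, SegmentationParams())
        assert status == "segmented"
        assert mask.data[sub.seed_local]
        from scipy import ndimage
        labels, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), bool))
        assert n == 1

    def test_affine_intensity_invariance(self):
        base, _ = self.ellipsoid_subvoi(noise=0.02, seed=5)
        scaled, _ = self.ellipsoid_subvoi(noise=0.02, seed=5, a=0.7, b=0.2)
        m1, _ = segment.segment_chondron(base, SegmentationParams())
        m2, _ = segment.segment_chondron(scaled, SegmentationParams())
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_lowering_tau_never_shrinks_mask(self):
        sub, _ = self.ellipsoid_subvoi(noise=0.03, seed=7)
        params_hi = SegmentationParams(radii_um=(1.6, 3.2, 4.8), interiority_threshold=0.5)
        params_lo = SegmentationParams(radii_um=(1.6, 3.2, 4.8), interiority_threshold=0.2)
        hi, _ = segment.segment_chondron(sub, params_hi)
        lo, _ = segment.segment_chondron(sub, params_lo)
        assert hi is None or np.all(lo.data[hi.data])

    def test_background_seed_fails_without_exception(self):
        n = 40
        data = np.full((n, n, n), 0.65, dtype=np.float32)
        data[:4, :4, :4] = 0.25  # a far-away dark corner sets some contrast
        sub = as_subvoi(VoxelGrid(data, 1.6), (n // 2, n // 2, n // 2))
        mask, status = segment.segment_chondron(sub, SegmentationParams())
        assert mask is None and status == "failed"


class TestMinVolume:
    def test_exact_threshold_arithmetic_at_16um(self):
        # 97 voxels x 1.6^3 = 397.3 um^3 < 400; 98 voxels = 401.4 um^3
        def mask_with(n):
            data = np.zeros((5, 5, 5), bool)
            data.ravel()[:n] = True
            return BinaryMask(data, voxel_size_um=1.6)
        assert not segment.apply_min_volume(mask_with(97), 400.0)
        assert segment.apply_min_volume(mask_with(98), 400.0)

    def test_exactly_at_threshold_is_kept(self):
        data = np.zeros((8, 8, 8), bool)
        data.ravel()[:400] = True
        assert segment.apply_min_volume(BinaryMask(data, voxel_size_um=1.0), 400.0)


class TestDeduplicate:
    def box_mask(self, lo, hi, shape=(20, 20, 20)):
        data = np.zeros(shape, bool)
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return BinaryMask(data, voxel_size_um=1.6)

    def test_identical_masks_keep_one(self):
        m = self.box_mask((2, 2, 2), (6, 6, 6))
        assert len(segment.deduplicate([m, m])) == 1

    def test_disjoint_masks_keep_both(self):
        a = self.box_mask((0, 0, 0), (4, 4, 4))
        b = self.box_mask((10, 10, 10), (14, 14, 14))
        kept = segment.deduplicate([a, b])
        assert len(kept) == 2 and kept[0] is a and kept[1] is b

    def test_overlapping_pair_keeps_larger(self):
        small = self.box_mask((0, 0, 0), (5, 5, 5))      # 125 voxels
        large = self.box_mask((2, 0, 0), (9, 5, 5))      # 175 voxels, DSC 0.5
        d = validate.dice(small, large).dsc
        assert 0.3 < d < 1.0
        kept = segment.deduplicate([small, large])
        assert len(kept) == 1 and kept[0] is large

    def test_transitive_group_resolved_to_single_largest(self):
        a = self.box_mask((0, 0, 0), (6, 6, 6))
        b = self.box_mask((2, 0, 0), (8, 6, 6))
        c = self.box_mask((5, 0, 0), (12, 6, 6))
        assert validate.dice(a, c).dsc <= 0.3  # only chained via b
        kept = segment.deduplicate([a, b, c])
        assert len(kept) == 1 and kept[0] is c


def test_invalid_params_rejected():
    with pytest.raises(ParameterError):
        SegmentationParams(radii_um=(4.0, 2.0))
    with pytest.raises(ParameterError):
        SegmentationParams(interiority_threshold=1.5)
    with pytest.raises(ParameterError):
        SegmentationParams(n_surface_samples=4)
    with pytest.raises(ParameterError):
        SegmentationParams(min_volume_um3=0.0)
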