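"""Morphometry: volume, mesh area, sphericity, depth zonation, summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest

from chondromorph import morphometry as mm
from chondromorph.errors import (
    EmptyObjectError,
    NoTissueError,
    OutOfTissueError,
    ParameterError,
)
from chondromorph.volio import BinaryMask, ChondronRecord, VoxelGrid
from conftest import make_ball_mask


class TestVolume:
    def test_voxel_arithmetic(self):
        one = BinaryMask(np.pad(np.ones((1, 1, 1), bool), 1), voxel_size_um=1.6)
        assert mm.volume_um3(one) == pytest.approx(4.096)
        cube = BinaryMask(np.ones((10, 10, 10), bool), voxel_size_um=1.6)
        assert mm.volume_um3(cube) == pytest.approx(4096.0)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyObjectError):
            mm.volume_um3(BinaryMask(np.zeros((3, 3, 3), bool)))


class TestSurfaceArea:
    def test_ball_within_three_percent_of_sphere(self):
        mask = make_ball_mask(24, voxel_size_um=1.6)
        S = mm.mesh_surface_area(mask)
        assert S == pytest.approx(4 * math.pi * (24 * 1.6) ** 2, rel=0.03)

    def test_cube_within_five_percent(self):
        mask = BinaryMask(np.pad(np.ones((20, 20, 20), bool), 2), voxel_size_um=1.6)
        S = mm.mesh_surface_area(mask)
        assert S == pytest.approx(6 * (20 * 1.6) ** 2, rel=0.05)

    def test_single_voxel_is_positive_finite(self):
        mask = BinaryMask(np.pad(np.ones((1, 1, 1), bool), 1), voxel_size_um=1.6)
        S = mm.mesh_surface_area(mask)
        assert np.isfinite(S) and S > 0


class TestSphericity:
    def test_exact_sphere_values_give_one(self):
        r = 7.3
        V, S = 4 / 3 * math.pi * r ** 3, 4 * math.pi * r ** 2
        assert mm.sphericity(V, S) == pytest.approx(1.0, abs=1e-12)

    def test_exact_cube_closed_form(self):
        a = 5.0
        assert mm.sphericity(a ** 3, 6 * a ** 2) == pytest.approx((math.pi / 6) ** (1 / 3), abs=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            mm.sphericity(0.0, 1.0)
        with pytest.raises(ParameterError):
            mm.sphericity(1.0, -1.0)

    def test_scale_invariance_under_voxel_size(self):
        mask_a = make_ball_mask(10, voxel_size_um=1.6)
        mask_b = BinaryMask(mask_a.data, voxel_size_um=3.2)
        sph_a = mm.sphericity(mm.volume_um3(mask_a), mm.mesh_surface_area(mask_a))
        sph_b = mm.sphericity(mm.volume_um3(mask_b), mm.mesh_surface_area(mask_b))
        assert sph_a == pytest.approx(sph_b, rel=1e-9)

    def test_phantom_shapes_respect_isoperimetric_bound(self, small_phantom):
        _, truth = small_phantom
        for obj in truth.objects:
            sph = mm.sphericity(mm.volume_um3(obj.mask), mm.mesh_surface_area(obj.mask))
            assert sph <= 1.02


class TestTissueFrame:
    def test_phantom_slab_boundaries_recovered(self, small_phantom):
        grid, truth = small_phantom
        frame = mm.detect_tissue_frame(grid, 0.5)
        assert frame.z_surface == truth.z_surface
        assert frame.z_bottom == truth.z_bottom
        assert frame.thickness_um == pytest.approx(
            (truth.z_bottom - truth.z_surface) * grid.voxel_size_um)

    def test_all_air_volume_raises(self):
        with pytest.raises(NoTissueError):
            mm.detect_tissue_frame(VoxelGrid(np.zeros((10, 8, 8)) + 0.01, 1.6))


class TestDepthZones:
    frame = mm.TissueFrame(z_surface=20, z_bottom=520, voxel_size_um=1.6,
                           voi_cross_section_mm2=0.23)

    def test_surface_centroid_is_zero_depth_zone_one(self):
        d = mm.depth_percent(20.0, self.frame)
        assert d == 0.0 and mm.assign_zone(d) == 1

    @pytest.mark.parametrize("depth,zone", [(5, 1), (25, 2), (70, 3), (10, 2), (40, 3), (100, 3)])
    def test_zone_band_assignment(self, depth, zone):
        assert mm.assign_zone(depth) == zone

    def test_every_in_tissue_depth_has_exactly_one_zone(self):
        for d in np.linspace(0, 100, 401):
            assert mm.assign_zone(float(d)) in (1, 2, 3)

    def test_out_of_tissue_centroid_flagged(self):
        with pytest.raises(OutOfTissueError):
            mm.depth_percent(10.0, self.frame)


class TestDensity:
    def make_records(self, zones):
        return [ChondronRecord(id=i, volume_um3=1.0, surface_area_um2=1.0, sphericity=0.8,
                               z_c=0, y_c=0, x_c=0, zone=z) for i, z in enumerate(zones)]

    def test_density_arithmetic(self):
        # zone spanning 0.01 mm^3 holding 10 chondrons -> 1000 per mm^3
        frame = mm.TissueFrame(z_surface=0, z_bottom=1000, voxel_size_um=1.0,
                               voi_cross_section_mm2=0.1)
        # zone 1 thickness = 10% of 1 mm = 0.1 mm -> volume 0.01 mm^3
        recs = self.make_records([1] * 10)
        assert mm.chondron_density(recs, frame, 1) == pytest.approx(1000.0)

    def test_zone_counts_partition_total(self):
        recs = self.make_records([1, 2, 2, 3, 3, 3])
        frame = mm.TissueFrame(z_surface=0, z_bottom=100, voxel_size_um=1.6,
                               voi_cross_section_mm2=0.23)
        total = sum(sum(1 for r in recs if r.zone == z) for z in (1, 2, 3))
        assert total == len(recs)
        densities = [mm.chondron_density(recs, frame, z) for z in (1, 2, 3)]
        assert all(d >= 0 for d in densities)


class TestSubsample:
    recs = [ChondronRecord(id=i, volume_um3=1.0, surface_area_um2=1.0, sphericity=0.8,
                           z_c=0, y_c=0, x_c=0) for i in range(20)]

    def test_zero_is_empty_and_full_is_identity(self):
        assert mm.random_subsample(self.recs, 0, seed=1) == []
        assert mm.random_subsample(self.recs, 25, seed=1) == self.recs

    def test_seed_determinism_and_order(self):
        s1 = mm.random_subsample(self.recs, 7, seed=5)
        s2 = mm.random_subsample(self.recs, 7, seed=5)
        assert [r.id for r in s1] == [r.id for r in s2]
        assert [r.id for r in s1] == sorted(r.id for r in s1)
        s3 = mm.random_subsample(self.recs, 7, seed=6)
        assert [r.id for r in s3] != [r.id for r in s1]


class TestSummarize:
    def rec(self, i, vol, zone=2, sph=0.8):
        return ChondronRecord(id=i, volume_um3=vol, surface_area_um2=1.0, sphericity=sph,
                              z_c=0, y_c=0, x_c=0, zone=zone)

    def test_hand_arithmetic(self):
        recs = [self.rec(1, 2.0), self.rec(2, 4.0), self.rec(3, 6.0)]
        summaries = mm.summarize(recs)
        z2 = next(s for s in summaries if s.zone == 2)
        st = z2.stats["volume_um3"]
        assert z2.n_chondrons == 3
        assert st["mean"] == pytest.approx(4.0)
        assert st["median"] == pytest.approx(4.0)
        assert st["sd"] == pytest.approx(2.0)
        assert st["ci95_lo"] < st["mean"] < st["ci95_hi"]

    def test_single_record_has_undefined_sd(self):
        summaries = mm.summarize([self.rec(1, 5.0)])
        st = next(s for s in summaries if s.zone == 2).stats["volume_um3"]
        assert math.isnan(st["sd"]) and math.isnan(st["ci95_lo"])
        assert st["mean"] == pytest.approx(5.0)

    def test_empty_zone_rows_present(self):
        summaries = mm.summarize([self.rec(1, 5.0, zone=3)])
        z1 = next(s for s in summaries if s.zone == 1)
        assert z1.n_chondrons == 0
        assert math.isnan(z1.stats["volume_um3"]["mean"])

    def test_group_labels_split_rows(self):
        recs = [self.rec(1, 5.0), self.rec(2, 10.0)]
        summaries = mm.summarize(recs, groups={1: "intact", 2: "oa"})
        assert {s.group for s in summaries} == {"intact", "oa"}
        assert len(summaries) == 6


def test_measured_volume_tracks_truth_for_resolved_objects(small_phantom):
    """Voxel-count volume vs planted analytic volume within 10% for singles
    with all semi-axes of at least 5 voxels."""
    _, truth = small_phantom
    vs = truth.voxel_size_um
    checked = 0
    for obj in truth.objects:
        if obj.classification != "single" or min(obj.semi_axes_um) < 5 * vs:
            continue
        measured = mm.volume_um3(obj.mask)
        assert measured == pytest.approx(obj.analytic_volume_um3, rel=0.10)
        checked += 1
    assert checked >= 3
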