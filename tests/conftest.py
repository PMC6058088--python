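"""Shared fixtures: compact phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from chondromorph import morphometry, phantom, volio
from chondromorph.pipeline import PipelineConfig, segment_candidates


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    """A compact noise-free phantom spec used by several suites."""
    return phantom.PhantomSpec(dims_voxels=(120, 96, 96), z_surface=8, z_bottom=112,
                               noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return phantom.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The default-condition phantom (noise-free) with its ground truth."""
    spec = phantom.PhantomSpec(noise_sd=0.0, seed=1)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def segmented_small_phantom(small_phantom):
    """Masks + stage counts from running detection/segmentation on the small
    phantom, with offsets in the full-grid frame."""
    grid, truth = small_phantom
    frame = morphometry.detect_tissue_frame(grid)
    tissue = volio.crop_voi(grid, (frame.z_surface, 0, 0,
                                   frame.z_bottom, grid.shape[1], grid.shape[2]))
    config = PipelineConfig(input_path=".", output_dir="unused")
    masks, counts = segment_candidates(tissue, config)
    masks = [volio.BinaryMask(m.data,
                              (m.offset_voxels[0] + frame.z_surface,
                               m.offset_voxels[1], m.offset_voxels[2]),
                              m.voxel_size_um) for m in masks]
    return grid, truth, frame, masks, counts


def make_ball_mask(radius_vox: int, voxel_size_um: float = 1.6,
                   pad: int = 4) -> volio.BinaryMask:
    """Voxelized ball: voxel centers within radius of the grid center."""
    n = 2 * (radius_vox + pad)
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[:n, :n, :n]
    ball = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox ** 2
    return volio.BinaryMask(ball, voxel_size_um=voxel_size_um)
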