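"""End-to-end pipeline: read -> crop -> detect -> segment -> filter ->
deduplicate -> morphometry -> summarize -> export.

Configuration is a YAML/JSON file validated into :class:`PipelineConfig`;
one seed governs every stochastic step so identical config + seed gives
byte-identical outputs. Per-stage object counts are logged and written to
the run metadata, and they obey the conservation law
``candidates = segmented + failed`` and
``segmented = kept + rejected_volume + rejected_duplicate``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect, morphometry, segment, validate, volio
from .errors import ConfigError, MissingInputError
from .segment import SegmentationParams
from .volio import BinaryMask, Box, ChondronRecord, VoxelGrid

log = logging.getLogger("chondromorph")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; every tunable default is exposed."""

    input_path: str
    output_dir: str
    voxel_size_um: float = 1.6
    voi_bbox: Box | None = None  # half-open (z0,y0,x0,z1,y1,x1); None = full stack
    polarity: str = "dark"
    tissue_fraction_threshold: float = 0.5
    z_surface_override: int | None = None
    z_bottom_override: int | None = None
    connectivity: int = 26
    min_candidate_voxels: int = 25
    max_candidate_voxels: int = 10 ** 6
    subvoi_margin_voxels: int = 20
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    subsample_n: int | None = None  # None = keep all records
    export_montages: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ConfigError(f"polarity: must be 'dark' or 'bright', got {self.polarity!r}")
        if self.voxel_size_um <= 0:
            raise ConfigError(f"voxel_size_um: must be positive, got {self.voxel_size_um}")
        if not 0 < self.min_candidate_voxels <= self.max_candidate_voxels:
            raise ConfigError("min_candidate_voxels/max_candidate_voxels: need "
                              f"0 < min <= max, got {self.min_candidate_voxels}, "
                              f"{self.max_candidate_voxels}")
        if self.subvoi_margin_voxels < 0:
            raise ConfigError("subvoi_margin_voxels: must be >= 0")
        if isinstance(self.segmentation, dict):
            try:
                self.segmentation = SegmentationParams(**self.segmentation)
            except TypeError as exc:
                raise ConfigError(f"segmentation: {exc}") from exc
        if self.voi_bbox is not None:
            self.voi_bbox = tuple(int(v) for v in self.voi_bbox)  # type: ignore[assignment]
            if len(self.voi_bbox) != 6:
                raise ConfigError("voi_bbox: must have 6 entries (z0,y0,x0,z1,y1,x1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise MissingInputError(f"config file {path} does not exist")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory result of a pipeline run."""

    records: list[ChondronRecord]
    masks: list[BinaryMask]
    frame: morphometry.TissueFrame
    counts: dict[str, int]
    output_dir: Path


def segment_candidates(grid: VoxelGrid, config: PipelineConfig
                       ) -> tuple[list[BinaryMask], dict[str, int]]:
    """Detect and segment all candidates in a (tissue-cropped) grid.

    Returns the kept masks (volume-filtered, deduplicated) and the stage
    counts dictionary. Use :func:`segment_candidates_detailed` for the
    per-candidate status table.
    """
    masks, _, counts = segment_candidates_detailed(grid, config)
    return masks, counts


def segment_candidates_detailed(grid: VoxelGrid, config: PipelineConfig):
    """Like :func:`segment_candidates` but also returns the per-candidate
    status list: (label_id, status) with status in kept / failed /
    rejected_volume / rejected_duplicate."""
    if config.polarity == "bright":
        # the segmenter grows the dark phase; invert once up front
        grid = VoxelGrid(1.0 - grid.data, grid.voxel_size_um, grid.z_axis_is_depth)
    binary = detect.binarize(grid, polarity="dark")
    cands = detect.label_components(binary, connectivity=config.connectivity)  # type: ignore[arg-type]
    cands = detect.filter_candidates(cands, config.min_candidate_voxels,
                                     config.max_candidate_voxels)
    params = config.segmentation
    segmented: list[tuple[int, BinaryMask]] = []
    statuses: dict[int, str] = {}
    for cand in cands:
        sub = detect.extract_subvoi(grid, cand, config.subvoi_margin_voxels)
        mask, status = segment.segment_chondron(sub, params)
        if mask is None or mask.voxel_count == 0:
            statuses[cand.label_id] = "failed"
            continue
        segmented.append((cand.label_id, mask))
    kept_volume = []
    for label_id, m in segmented:
        if segment.apply_min_volume(m, params.min_volume_um3):
            kept_volume.append((label_id, m))
        else:
            statuses[label_id] = "rejected_volume"
    deduped = segment.deduplicate([m for _, m in kept_volume])
    deduped_ids = {id(m) for m in deduped}
    masks: list[BinaryMask] = []
    for label_id, m in kept_volume:
        if id(m) in deduped_ids:
            statuses[label_id] = "kept"
            masks.append(m)
        else:
            statuses[label_id] = "rejected_duplicate"
    status_table = [(c.label_id, statuses[c.label_id]) for c in cands]
    counts = {
        "candidates": len(cands),
        "segmented": len(segmented),
        "failed": len(cands) - len(segmented),
        "rejected_volume": sum(s == "rejected_volume" for _, s in status_table),
        "rejected_duplicate": sum(s == "rejected_duplicate" for _, s in status_table),
        "kept": len(masks),
    }
    return masks, status_table, counts


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and write the run directory."""
    in_path = Path(config.input_path)
    if not in_path.exists():
        raise MissingInputError(f"input path {in_path} does not exist")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    grid = volio.read_stack(in_path, config.voxel_size_um)
    log.info("read stack %s: shape %s", in_path, grid.shape)
    if config.voi_bbox is not None:
        grid = volio.crop_voi(grid, config.voi_bbox)
        log.info("cropped VOI to %s", grid.shape)

    frame = morphometry.detect_tissue_frame(grid, config.tissue_fraction_threshold)
    if config.z_surface_override is not None:
        frame.z_surface = int(config.z_surface_override)
    if config.z_bottom_override is not None:
        frame.z_bottom = int(config.z_bottom_override)
    log.info("tissue frame: z_surface=%d z_bottom=%d", frame.z_surface, frame.z_bottom)

    # restrict detection/segmentation to the cartilage slab
    tissue = volio.crop_voi(grid, (frame.z_surface, 0, 0,
                                   frame.z_bottom, grid.shape[1], grid.shape[2]))
    masks, status_table, counts = segment_candidates_detailed(tissue, config)
    # shift mask offsets back to the full-grid frame
    masks = [BinaryMask(m.data,
                        offset_voxels=(m.offset_voxels[0] + frame.z_surface,
                                       m.offset_voxels[1], m.offset_voxels[2]),
                        voxel_size_um=m.voxel_size_um) for m in masks]
    log.info("stage counts: %s", counts)

    records = [morphometry.build_record(i + 1, m, frame) for i, m in enumerate(masks)]
    if config.subsample_n is not None:
        kept_records = morphometry.random_subsample(records, config.subsample_n, config.seed)
        id_keep = {r.id for r in kept_records}
        masks = [m for r, m in zip(records, masks) if r.id in id_keep]
        records = kept_records
    summaries = morphometry.summarize(records, frame)

    volio.write_records(records, out_dir / "records.csv")
    morphometry.summaries_to_frame(summaries).to_csv(out_dir / "summary.csv", index=False)
    labels = np.zeros(grid.shape, dtype=np.uint16)
    for rec, mask in zip(records, masks):
        z0, y0, x0 = mask.offset_voxels
        dz, dy, dx = mask.data.shape
        region = labels[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx]
        region[mask.data] = rec.id
    volio.write_label_stack(labels, out_dir / "labels.tif")
    # per-candidate status table; record_id links kept candidates to records
    status_rows = []
    kept_seen = 0
    for label_id, status in status_table:
        rid = None
        if status == "kept":
            kept_seen += 1
            rid = kept_seen
        status_rows.append({"candidate_label": label_id, "status": status,
                            "record_id": rid})
    import pandas as pd

    pd.DataFrame(status_rows, columns=["candidate_label", "status", "record_id"]) \
        .to_csv(out_dir / "status.csv", index=False)

    if config.export_montages:
        mont_dir = out_dir / "montages"
        for rec, mask in zip(records, masks):
            validate.export_orthogonal_views(grid, mask, mont_dir / f"chondron_{rec.id:05d}.png")

    metadata = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "grid_shape": list(grid.shape),
        "voxel_size_um": config.voxel_size_um,
        "z_surface": frame.z_surface,
        "z_bottom": frame.z_bottom,
        "counts": counts,
        "n_records": len(records),
    }
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)

    return RunResult(records=records, masks=masks, frame=frame,
                     counts=counts, output_dir=out_dir)
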