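"""Configuration-driven orchestration of the full analysis.

Stages: simulate/ingest → blockify → localize (or take truth seeds) →
segment → features → classify → evaluate → export. Every stochastic stage
receives a seed derived from the global seed and a fixed per-stage index via
``numpy.random.SeedSequence((global_seed, stage_index))``, so any stage can
be rerun in isolation and a rerun of the whole pipeline is bit-reproducible.
All physical parameters are in μm; voxel conversions happen inside the
modules.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import CellRecord, classify_giant, classify_shape
from .detect import DetectConfig, localize_somata
from .evalmap import density_grid, per_block_report, recall_precision, to_swc
from .grids import VoxelGrid
from .morpho import basic_features, shape_features
from .segment import SegmentConfig, SeedRejected, segment_soma
from .synthgen import (DEFAULT_SEED, FIXTURE_NAMES, RenderConfig,
                       make_fixture, place_cells, render_scene,
                       sample_population)
from .volstore import crop_cube, write_blocks

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "extract_records"]

# fixed stage indices for seed derivation (the counter scheme)
STAGE_INDEX = {
    "simulate": 0, "blockify": 1, "detect": 2, "segment": 3,
    "features": 4, "classify": 5, "evaluate": 6, "export": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence((global_seed, stage_index))."""
    idx = STAGE_INDEX[stage]
    return int(np.random.SeedSequence((global_seed, idx)).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    seed: int = DEFAULT_SEED
    out_dir: str = "pipeline_out"
    # input: one of fixture / tiff / population
    fixture: Optional[str] = None  # fig4_mixture | betz_shapes
    tiff_path: Optional[str] = None
    population: Optional[str] = None  # preset name for a custom small scene
    n_cells: int = 20
    domain_um: tuple[float, float, float] = (160.0, 160.0, 160.0)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    block_edge_um: float = 512.0
    crop_edge_um: float = 128.0
    use_truth_seeds: bool = False  # seed segmentation at ground-truth centers
    min_radius_um: float = 0.0
    match_dist_um: float = 10.0
    density_voxel_um: float = 20.0
    standardize: bool = True

    def validate(self) -> None:
        given = [x for x in (self.fixture, self.tiff_path, self.population) if x]
        if len(given) != 1:
            raise ValueError(
                "config must specify exactly one input: fixture, tiff_path or population"
            )
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("domain_um", "voxel_size"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("domain_um", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def extract_records(
    store,
    centers,
    ids,
    edge_um: float = 128.0,
    seg_config: SegmentConfig = SegmentConfig(),
    with_shape: bool = True,
):
    """Crop, segment and measure one cube per seed center.

    Returns (records, failures); failures are (id, reason) pairs and never
    abort the batch.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    records: list[CellRecord] = []
    failures: list[tuple[int, str]] = []
    half = edge_um / 2.0
    for i, c in enumerate(centers):
        try:
            cube = crop_cube(store, tuple(c), edge_um)
            near = [
                tuple(centers[j]) for j in range(len(centers))
                if j != i and np.all(np.abs(centers[j] - c) < half)
            ]
            mask = segment_soma(cube, tuple(c), seg_config, near, cell_id=ids[i])
            feats = basic_features(mask, cube)
            ratios = shape_features(mask) if with_shape else None
            records.append(CellRecord(
                cell_id=ids[i], center=tuple(c), features=feats, ratios=ratios,
            ))
        except (SeedRejected, ValueError) as exc:
            failures.append((ids[i], str(exc)))
    return records, failures


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"cell_id": r.cell_id, "x_um": r.center[0], "y_um": r.center[1],
               "z_um": r.center[2], "class_label": r.class_label,
               "shape_class": r.shape_class}
        if r.features is not None:
            row.update(volume_um3=r.features.volume, mean_gray=r.features.mean_gray,
                       longest_radius_um=r.features.longest_radius)
        if r.ratios is not None:
            row.update(rect_axial_ratio=r.ratios.rect_axial_ratio,
                       maxsec_distance_ratio=r.ratios.maxsec_distance_ratio,
                       maxsec_axial_ratio=r.ratios.maxsec_axial_ratio)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}
    t_all = time.time()

    def tick(stage, t0, **info):
        report["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    # --- simulate / ingest
    t0 = time.time()
    truth_cells = None
    if config.fixture:
        fx = make_fixture(config.fixture, config.seed)
        grid, labels, truth_cells = fx.grid, fx.labels, fx.cells
    elif config.population:
        sim_seed = stage_seed(config.seed, "simulate")
        cells = sample_population(config.population, config.n_cells, sim_seed)
        cells = place_cells(cells, config.domain_um, min_sep=12.0, seed=sim_seed + 1)
        grid, labels = render_scene(
            cells, RenderConfig(voxel_size=config.voxel_size),
            config.domain_um, seed=sim_seed + 2,
        )
        truth_cells = cells
    else:
        grid = cio.read_volume(config.tiff_path)
        labels = None
    cio.write_volume(out / "volume.tif", grid)
    if truth_cells is not None:
        cio.write_cells_csv(out / "truth_cells.csv", truth_cells)
    tick("simulate", t0, n_truth=len(truth_cells) if truth_cells else 0,
         shape=list(grid.shape))

    # --- blockify
    t0 = time.time()
    store = write_blocks(grid, config.block_edge_um, root=out / "blocks")
    tick("blockify", t0, grid_shape=list(store.grid_shape),
         block_shape=list(store.block_shape))

    # --- localization
    t0 = time.time()
    if config.use_truth_seeds and truth_cells is not None:
        centers = [c.center for c in truth_cells]
        ids = [c.id for c in truth_cells]
        detections = None
    else:
        detections = localize_somata(
            grid, DetectConfig(polarity=grid.polarity,
                               min_radius_um=config.min_radius_um)
        )
        centers = [d.center for d in detections]
        ids = list(range(1, len(detections) + 1))
        cio.write_detections_csv(out / "detections.csv", detections)
    tick("detect", t0, n=len(centers))

    # --- segment + features
    t0 = time.time()
    records, failures = extract_records(
        grid, centers, ids, edge_um=config.crop_edge_um,
    )
    pd.DataFrame(
        [{"cell_id": cid, "reason": why} for cid, why in failures]
    ).to_csv(out / "segment_failures.csv", index=False)
    tick("segment", t0, n_ok=len(records), n_failed=len(failures))

    # --- classify
    t0 = time.time()
    if len(records) >= 2:
        records = classify_giant(records, seed=stage_seed(config.seed, "classify"),
                                 standardize=config.standardize)
        giants = [r for r in records if r.class_label == "giant"]
        giants = classify_shape(giants)
        shaped = {r.cell_id: r for r in giants}
        records = [shaped.get(r.cell_id, r) for r in records]
    table = _records_frame(records)
    table.to_csv(out / "cell_table.csv", index=False)
    shape_counts = table[table.class_label == "giant"].shape_class.value_counts().to_dict()
    tick("classify", t0, n_giant=int((table.class_label == "giant").sum()),
         shape_counts=shape_counts)

    # --- evaluate vs ground truth
    t0 = time.time()
    if truth_cells is not None and len(records):
        rec, prec = recall_precision(
            [r.center for r in records], [c.center for c in truth_cells],
            config.match_dist_um,
        )
        tick("evaluate", t0, recall_pct=round(rec, 2), precision_pct=round(prec, 2))
    else:
        tick("evaluate", t0, skipped=True)

    # --- export
    t0 = time.time()
    (out / "somata.swc").write_text(to_swc(records))
    dens = density_grid(records, config.density_voxel_um, extent_um=grid.extent_um)
    cio.write_volume(out / "density.tif", dens)
    tick("export", t0, n_swc=len(records), density_sum=int(dens.data.sum()))

    report["total_seconds"] = round(time.time() - t_all, 3)
    report["stage_seeds"] = {s: stage_seed(config.seed, s) for s in STAGE_INDEX}
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
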