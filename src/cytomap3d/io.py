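"""Reading and writing the pipeline's on-disk artifacts.

Volumes travel as multi-page TIFF stacks (one page per z-section) with a
JSON sidecar recording voxel size, origin and polarity; tables (cell truth,
detections, features) travel as CSV with a fixed header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import VoxelGrid

SIDECAR_SUFFIX = ".json"


def write_volume(path, grid: VoxelGrid) -> None:
    """Write a grid as a multi-page TIFF (pages = z) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # TIFF pages are (z, y, x); our arrays are (x, y, z)
    tifffile.imwrite(path, np.ascontiguousarray(grid.data.transpose(2, 1, 0)))
    sidecar = {
        "voxel_size_um": list(grid.voxel_size),
        "origin_um": list(grid.origin),
        "polarity": grid.polarity,
        "dtype": str(grid.data.dtype),
        "shape_xyz": list(grid.data.shape),
    }
    path.with_suffix(path.suffix + SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))


def read_volume(path) -> VoxelGrid:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single section
        pages = pages[None]
    data = pages.transpose(2, 1, 0)
    sidecar_path = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    voxel_size, origin, polarity = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), "dark_cells"
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        voxel_size = tuple(meta.get("voxel_size_um", voxel_size))
        origin = tuple(meta.get("origin_um", origin))
        polarity = meta.get("polarity", polarity)
    return VoxelGrid(data, voxel_size, origin, polarity)


CELL_CSV_COLUMNS = [
    "id", "population", "class_label", "shape_class",
    "x_um", "y_um", "z_um", "target_volume_um3",
]


def write_cells_csv(path, cells) -> None:
    rows = [
        {
            "id": c.id, "population": c.population, "class_label": c.class_label,
            "shape_class": c.shape_class, "x_um": c.center[0], "y_um": c.center[1],
            "z_um": c.center[2], "target_volume_um3": c.target_volume,
        }
        for c in cells
    ]
    pd.DataFrame(rows, columns=CELL_CSV_COLUMNS).to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections_csv(path, detections) -> None:
    rows = [
        {"id": i, "x_um": d.center[0], "y_um": d.center[1], "z_um": d.center[2],
         "radius_um": d.radius, "score": d.score}
        for i, d in enumerate(detections)
    ]
    pd.DataFrame(rows, columns=["id", "x_um", "y_um", "z_um", "radius_um", "score"]).to_csv(
        path, index=False
    )
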