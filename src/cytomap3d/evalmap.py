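"""Detection evaluation and brain-wide distribution export.

Recall and precision follow the co-detection definitions: recall =
co-detected / manually detected, precision = co-detected / automatically
detected. Co-detection is established by greedy one-to-one matching in
ascending pair distance within a physical tolerance (default 10 μm).
Soma point clouds export to SWC (one type-1 node per cell, parent −1) and
to a count grid at a coarse resampled resolution (default 20 μm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .grids import VoxelGrid

__all__ = [
    "EvaluationReport", "BlockMetrics", "UndefinedMetricError",
    "match_detections", "recall_precision", "per_block_report", "to_swc",
    "parse_swc", "density_grid",
]


class UndefinedMetricError(ValueError):
    """Recall with no manual cells, or precision with no automatic cells."""


def _as_points(x) -> np.ndarray:
    pts = []
    for item in x:
        if hasattr(item, "center") and item.center is not None:
            pts.append(item.center)
        else:
            pts.append(tuple(item))
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def match_detections(auto, manual, max_dist_um: float) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching by ascending pair distance.

    Returns (auto_index, manual_index, distance) triples; each point is
    matched at most once and only pairs within ``max_dist_um`` are eligible.
    """
    if max_dist_um <= 0:
        raise ValueError("max_dist_um must be > 0")
    a = _as_points(auto)
    m = _as_points(manual)
    if len(a) == 0 or len(m) == 0:
        return []
    tree = cKDTree(m)
    pairs = []
    for i, p in enumerate(a):
        for j in tree.query_ball_point(p, max_dist_um):
            pairs.append((float(np.linalg.norm(p - m[j])), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_m: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_a or j in used_m:
            continue
        used_a.add(i)
        used_m.add(j)
        out.append((i, j, d))
    return out


def recall_precision(auto, manual, max_dist_um: float = 10.0) -> tuple[float, float]:
    """(recall %, precision %) of automatic against manual detections."""
    a = _as_points(auto)
    m = _as_points(manual)
    if len(m) == 0:
        raise UndefinedMetricError("recall undefined: no manual detections")
    if len(a) == 0:
        raise UndefinedMetricError("precision undefined: no automatic detections")
    matched = len(match_detections(a, m, max_dist_um))
    return 100.0 * matched / len(m), 100.0 * matched / len(a)


@dataclass(frozen=True)
class BlockMetrics:
    block: int
    n_manual: int
    n_auto: int
    n_codetected: int
    recall: float  # %
    precision: float  # %


@dataclass
class EvaluationReport:
    blocks: list[BlockMetrics]
    mean_recall: float
    mean_precision: float
    sem_recall: Optional[float]  # None when < 2 usable blocks
    sem_precision: Optional[float]
    excluded_blocks: list[int] = field(default_factory=list)

    def summary(self) -> str:
        sr = "n/a" if self.sem_recall is None else f"{self.sem_recall:.2f}"
        sp = "n/a" if self.sem_precision is None else f"{self.sem_precision:.2f}"
        lines = [
            f"blocks evaluated: {len(self.blocks)}"
            + (f" (excluded: {self.excluded_blocks})" if self.excluded_blocks else ""),
            f"recall    = {self.mean_recall:.2f} ± {sr} %",
            f"precision = {self.mean_precision:.2f} ± {sp} %",
        ]
        return "\n".join(lines)


def per_block_report(
    blocks: Sequence[tuple], max_dist_um: float = 10.0,
) -> EvaluationReport:
    """Per-block recall/precision plus aggregate mean ± SEM.

    ``blocks`` is a sequence of (auto, manual) point sets. Blocks with empty
    manual sets are excluded with a warning and recorded in the report.
    SEM = SD / √(number of usable blocks); reported as None for one block.
    """
    if len(blocks) == 0:
        raise ValueError("need at least one block")
    metrics: list[BlockMetrics] = []
    excluded: list[int] = []
    for b, (auto, manual) in enumerate(blocks):
        a, m = _as_points(auto), _as_points(manual)
        if len(m) == 0:
            warnings.warn(f"block {b} has no manual detections; excluded")
            excluded.append(b)
            continue
        matched = len(match_detections(a, m, max_dist_um)) if len(a) else 0
        rec = 100.0 * matched / len(m)
        prec = 100.0 * matched / len(a) if len(a) else float("nan")
        metrics.append(BlockMetrics(b, len(m), len(a), matched, rec, prec))
    if not metrics:
        raise ValueError("no usable blocks (all manual sets empty)")
    rec = np.array([bm.recall for bm in metrics])
    prec = np.array([bm.precision for bm in metrics])
    nb = len(metrics)
    sem_r = float(rec.std(ddof=1) / math.sqrt(nb)) if nb > 1 else None
    sem_p = float(prec.std(ddof=1) / math.sqrt(nb)) if nb > 1 else None
    return EvaluationReport(
        blocks=metrics, mean_recall=float(rec.mean()), mean_precision=float(prec.mean()),
        sem_recall=sem_r, sem_precision=sem_p, excluded_blocks=excluded,
    )


# ---------------------------------------------------------------------------
# export


def to_swc(cells, comment: str = "soma point cloud") -> str:
    """SWC text with one type-1 (soma) node per cell, parent −1.

    Radius comes from the cell's longest radius when features are present,
    else its detection radius, else 1.
    """
    lines = [f"# {comment}", "# id type x y z radius parent"]
    for i, c in enumerate(cells, start=1):
        center = c.center if hasattr(c, "center") else tuple(c)
        radius = 1.0
        feats = getattr(c, "features", None)
        if feats is not None and getattr(feats, "longest_radius", None):
            radius = feats.longest_radius
        elif getattr(c, "radius", None):
            radius = c.radius
        x, y, z = center
        lines.append(f"{i} 1 {x:.3f} {y:.3f} {z:.3f} {radius:.3f} -1")
    return "\n".join(lines) + "\n"


def parse_swc(text: str) -> np.ndarray:
    """(n, 7) array of SWC rows (id type x y z radius parent)."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    return np.asarray(rows, dtype=float).reshape(-1, 7)


def density_grid(
    cells,
    grid_voxel_um: float = 20.0,
    extent_um: Optional[tuple[float, float, float]] = None,
) -> VoxelGrid:
    """Per-voxel soma counts at a coarse resolution (floor binning).

    The grid sum always equals the cell count: centers outside the declared
    extent are clamped into the edge bins with a warning.
    """
    if grid_voxel_um <= 0:
        raise ValueError("grid_voxel_um must be > 0")
    pts = _as_points(cells)
    if extent_um is None:
        hi = pts.max(axis=0) + 1e-9 if len(pts) else np.ones(3)
        extent_um = tuple(hi)
    shape = tuple(max(1, int(np.ceil(e / grid_voxel_um))) for e in extent_um)
    counts = np.zeros(shape, dtype=np.int32)
    if len(pts):
        idx = np.floor(pts / grid_voxel_um).astype(int)
        outside = np.any((idx < 0) | (idx >= np.asarray(shape)), axis=1)
        if outside.any():
            warnings.warn(f"{int(outside.sum())} cells outside extent; clamped to edge bins")
            idx = np.clip(idx, 0, np.asarray(shape) - 1)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    vs = (grid_voxel_um,) * 3
    return VoxelGrid(counts, vs)
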