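"""Cell typing: K-means giant/other separation and soma-shape assignment.

Giant pyramidal neurons are separated from other cells by k = 2 K-means on
the three morphometric features (volume, mean gray value, longest radius),
z-scored per column; the cluster with the larger mean volume is labeled
giant. Shape classes (pyramidal, spindle, flat, spheroid) are assigned by
nearest archetype signature in z-scored shape-ratio space, where the
archetype signatures are measured from noiseless renders of the generator's
shape archetypes (the flat class carries both its oval and triangular
variants internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .morpho import FeatureVector, ShapeRatios, shape_features

__all__ = [
    "CellRecord", "ArchetypeTable", "kmeans_cluster", "KMeansResult",
    "classify_giant", "classify_shape", "default_archetype_table",
]

SHAPE_CLASSES = ("pyramidal", "spindle", "flat", "spheroid")


@dataclass
class CellRecord:
    cell_id: int
    center: Optional[tuple[float, float, float]] = None
    features: Optional[FeatureVector] = None
    ratios: Optional[ShapeRatios] = None
    class_label: str = "unassigned"  # giant | other | unassigned
    shape_class: str = "unassigned"


@dataclass(frozen=True)
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    inertia_trace: tuple[float, ...]  # per-iteration objective of the best run
    dropped_columns: tuple[int, ...] = ()


def _kmeanspp_init(x: np.ndarray, k: int, rng) -> np.ndarray:
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j:] = x[rng.integers(n, size=k - j)]
            break
        probs = d2 / total
        centers[j] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int):
    k = len(centers)
    labels = None
    trace = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(x)), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean(axis=0)
    return labels, centers, trace


def kmeans_cluster(
    features: np.ndarray,
    k: int,
    seed: int,
    standardize: bool = True,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd's K-means with k-means++ initialization and restarts.

    If ``standardize``, each feature column is z-scored first; zero-variance
    columns are dropped with a warning entry in the result. The returned
    centroids are on the original feature scale. The per-iteration objective
    of the winning restart is exposed for diagnostics (it is non-increasing).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2D (n, d)")
    n = len(x)
    if not 1 <= k <= n:
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    dropped: tuple[int, ...] = ()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if standardize:
        keep = sd > 0
        dropped = tuple(int(i) for i in np.where(~keep)[0])
        if not keep.any():  # all-constant input: everything in one point
            keep = np.zeros(x.shape[1], dtype=bool)
            keep[0] = True
            sd = sd.copy()
            sd[0] = 1.0
        xs = (x[:, keep] - mu[keep]) / sd[keep]
    else:
        keep = np.ones(x.shape[1], dtype=bool)
        xs = x

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centers0 = _kmeanspp_init(xs, k, rng)
        labels, centers, trace = _lloyd(xs, centers0.copy(), max_iter)
        inertia = trace[-1]
        if best is None or inertia < best[3] - 1e-12:
            best = (labels, centers, trace, inertia)
    labels, centers_s, trace, inertia = best

    centroids = np.tile(mu, (k, 1))
    if standardize:
        centroids[:, keep] = centers_s * sd[keep] + mu[keep]
    else:
        centroids = centers_s
    return KMeansResult(
        labels=labels, centroids=centroids, inertia=inertia,
        inertia_trace=tuple(trace), dropped_columns=dropped,
    )


def classify_giant(
    cells: Sequence[CellRecord], seed: int, standardize: bool = True,
) -> list[CellRecord]:
    """Label each cell giant/other by k = 2 K-means on the basic features.

    The cluster with the larger mean volume is the giant cluster. The result
    is invariant to input order (cells are clustered jointly; labels travel
    with cell_id).
    """
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    if any(c.features is None for c in cells):
        raise ValueError("all cells must carry a FeatureVector")
    order = np.argsort([c.cell_id for c in cells], kind="stable")
    x = np.array([cells[i].features.as_array() for i in order])
    res = kmeans_cluster(x, k=2, seed=seed, standardize=standardize)
    vol0 = x[res.labels == 0, 0].mean() if (res.labels == 0).any() else -np.inf
    vol1 = x[res.labels == 1, 0].mean() if (res.labels == 1).any() else -np.inf
    giant_label = 0 if vol0 >= vol1 else 1
    out = list(cells)
    for pos, i in enumerate(order):
        lab = "giant" if res.labels[pos] == giant_label else "other"
        out[i] = replace(cells[i], class_label=lab)
    return out


# ---------------------------------------------------------------------------
# shape archetypes


@dataclass(frozen=True)
class ArchetypeTable:
    """Shape-class signatures in ratio space.

    ``signatures`` maps each of the four shape classes to one or more
    ShapeRatios signatures (flat carries its oval and triangular variants);
    assignment is nearest-signature in z-scored ratio space, and the winning
    signature's class is returned.
    """

    signatures: dict  # class -> tuple[ShapeRatios, ...]

    def __post_init__(self):
        if set(self.signatures) != set(SHAPE_CLASSES):
            raise ValueError(f"table must cover exactly {SHAPE_CLASSES}")

    def flattened(self) -> tuple[list[str], np.ndarray]:
        names, rows = [], []
        for cls in SHAPE_CLASSES:
            for sig in self.signatures[cls]:
                names.append(cls)
                rows.append(sig.as_array())
        return names, np.array(rows)


_ARCHETYPE_RENDER_VOLUME = 4000.0  # μm³, mid-range Betz soma


@lru_cache(maxsize=1)
def default_archetype_table() -> ArchetypeTable:
    """Signatures measured from noiseless axis-aligned archetype renders."""
    from .synthgen import render_archetype
    from .morpho import mask_from_labels

    def sig(shape_name: str, volume: float = _ARCHETYPE_RENDER_VOLUME) -> ShapeRatios:
        labels = render_archetype(shape_name, volume)
        return shape_features(mask_from_labels(labels, 1))

    return ArchetypeTable(
        signatures={
            "pyramidal": (sig("pyramidal"),),
            "spindle": (sig("spindle"),),
            "flat": (sig("flat_oval"), sig("flat_triangular")),
            "spheroid": (sig("spheroid", 1400.0),),
        }
    )


def classify_shape(
    cells: Sequence[CellRecord], table: Optional[ArchetypeTable] = None,
) -> list[CellRecord]:
    """Assign each cell to the nearest shape archetype in z-scored ratio space."""
    if not cells:
        return []
    if any(c.ratios is None for c in cells):
        raise ValueError("all cells must carry ShapeRatios")
    table = table or default_archetype_table()
    names, sigs = table.flattened()
    x = np.array([c.ratios.as_array() for c in cells])
    # z-scoring frame from the archetype signatures themselves, so a single
    # cell classifies identically regardless of batch composition
    mu = sigs.mean(axis=0)
    sd = np.where(sigs.std(axis=0) > 0, sigs.std(axis=0), 1.0)
    xs = (x - mu) / sd
    ss = (sigs - mu) / sd
    d2 = ((xs[:, None, :] - ss[None]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    return [
        replace(c, shape_class=names[j]) for c, j in zip(cells, nearest)
    ]
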