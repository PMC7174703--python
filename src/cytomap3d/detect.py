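"""Foreground extraction and soma localization.

Localization is multiscale blob detection: a scale-normalized Laplacian of
Gaussian over a set of physical radii (anisotropy handled by per-axis sigmas
in voxel units), local-maximum extraction above a response threshold, and
greedy non-maximum suppression at a physical distance. Detections below a
minimum radius are discarded, which is how giant somata are singled out from
the general cell population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import VoxelGrid

__all__ = [
    "Detection", "DetectConfig", "extract_foreground", "localize_somata",
    "filter_giant_candidates",
]


@dataclass(frozen=True)
class Detection:
    center: tuple[float, float, float]  # μm
    radius: float  # μm
    score: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class DetectConfig:
    polarity: str = "dark_cells"
    binarization: str = "otsu"  # or "fixed"
    fixed_threshold: float = 128.0
    min_radius_um: float = 0.0
    # physical blob scales sigma (μm); detection radius = sqrt(2) * sigma
    scale_set: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0, 8.5, 10.0)
    nms_dist_um: float = 15.0
    # response threshold = this multiple of the robust background response
    # SD (MAD-based over the whole response volume)
    response_nsigma: float = 6.0
    # candidates must lie on extracted foreground
    foreground_gate: bool = True
    # and exceed the robust background intensity by this many MAD-SDs
    # (suppresses smooth illumination bumps that fool a histogram split)
    intensity_gate_nsigma: float = 4.0

    def __post_init__(self):
        if self.min_radius_um < 0:
            raise ValueError("min_radius_um must be >= 0")
        if list(self.scale_set) != sorted(self.scale_set):
            raise ValueError("scale_set must be sorted ascending")
        if self.binarization not in ("otsu", "fixed"):
            raise ValueError(f"unknown binarization {self.binarization!r}")


class DegenerateImageWarning(UserWarning):
    """Otsu thresholding requested on a constant image."""


def _signal(grid: VoxelGrid, polarity: str) -> np.ndarray:
    """Float view where stained structure is *bright* regardless of polarity."""
    data = grid.data.astype(np.float32)
    return 255.0 - data if polarity == "dark_cells" else data


def extract_foreground(grid: VoxelGrid, config: DetectConfig) -> np.ndarray:
    """Binary mask of stained voxels.

    Otsu's threshold is computed on the full grid histogram; in fixed mode
    the supplied threshold is used directly. For dark_cells polarity,
    foreground is *below* the threshold.
    """
    data = grid.data
    if config.binarization == "otsu":
        if data.max() == data.min():
            warnings.warn("constant image: no foreground", DegenerateImageWarning)
            return np.zeros(data.shape, dtype=bool)
        thr = threshold_otsu(data)
    else:
        thr = config.fixed_threshold
    if config.polarity == "dark_cells":
        return data <= thr
    return data > thr


def localize_somata(grid: VoxelGrid, config: DetectConfig) -> list[Detection]:
    """Multiscale LoG soma localization (deterministic).

    Returns detections sorted by descending score, then lexicographic center.
    """
    if not config.scale_set:
        raise ValueError("scale_set must not be empty")
    sig = _signal(grid, config.polarity)
    vs = np.asarray(grid.voxel_size)

    best_resp = np.full(sig.shape, -np.inf, dtype=np.float32)
    best_scale = np.zeros(sig.shape, dtype=np.int16)
    noise_sd = 1e-6
    for si, scale in enumerate(config.scale_set):
        sigmas = scale / vs  # per-axis sigma in voxels
        resp = -(scale**2) * ndimage.gaussian_laplace(sig, sigma=sigmas)
        if si == 0:
            # robust background response spread, taken at the smallest
            # (noisiest) scale; somata are rare so the MAD is background
            med = float(np.median(resp))
            mad = float(np.median(np.abs(resp - med)))
            noise_sd = max(1.4826 * mad, 1e-6)
        upd = resp > best_resp
        best_resp[upd] = resp[upd]
        best_scale[upd] = si

    thr = config.response_nsigma * noise_sd

    fp_size = tuple(max(3, int(2 * round(config.scale_set[0] / v) + 1)) for v in vs)
    local_max = best_resp == ndimage.maximum_filter(best_resp, size=fp_size)
    keep = local_max & (best_resp > thr)
    if config.foreground_gate:
        keep &= extract_foreground(grid, config)
    if config.intensity_gate_nsigma > 0:
        smed = float(np.median(sig))
        smad = float(np.median(np.abs(sig - smed)))
        keep &= sig >= smed + config.intensity_gate_nsigma * 1.4826 * max(smad, 1e-6)
    cand = np.argwhere(keep)
    if len(cand) == 0:
        return []
    scores = best_resp[tuple(cand.T)]
    scales = np.array(config.scale_set)[best_scale[tuple(cand.T)]]
    centers = (cand + 0.5) * vs + np.asarray(grid.origin)

    # greedy NMS: higher score wins; ties broken lexicographically by center.
    # Suppression distance adapts to blob size so one elongated soma cannot
    # contribute several maxima, but is never below nms_dist_um.
    radii = np.sqrt(2.0) * scales
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0], -scores))
    kept: list[int] = []
    for i in order:
        c = centers[i]
        ok = True
        for j in kept:
            lim = max(config.nms_dist_um, 0.9 * (radii[i] + radii[j]))
            if np.linalg.norm(c - centers[j]) < lim:
                ok = False
                break
        if ok:
            kept.append(i)

    dets = [
        Detection(center=tuple(centers[i]), radius=float(np.sqrt(2.0) * scales[i]),
                  score=float(scores[i]))
        for i in kept
    ]
    dets = [d for d in dets if d.radius >= config.min_radius_um]
    dets.sort(key=lambda d: (-d.score, d.center))
    return dets


def filter_giant_candidates(
    dets: list[Detection], min_radius_um: float, min_score: float = 0.0,
) -> list[Detection]:
    """Keep detections with radius ≥ min_radius_um and score ≥ min_score."""
    return [d for d in dets if d.radius >= min_radius_um and d.score >= min_score]
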