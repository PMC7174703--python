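"""Volumetric soma segmentation around seed centers.

The built-in segmenter is classical and deterministic: seeded adaptive
region growing (voxels whose intensity lies within k·σ_bg of the running
region mean, connected to the seed), morphological closing and opening in
physical units to remove proximal-dendrite stubs, and marker-controlled
watershed splitting when a grown region swallows a neighbouring seed. A
plugin point admits alternative segmenters (e.g. a trained 3D model) under
the same mask contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .detect import Detection
from .grids import VoxelGrid
from .volstore import BlockStore, crop_cube

__all__ = [
    "SomaMask", "SegmentConfig", "SeedRejected", "segment_soma", "segment_all",
    "SegmentationBatch", "register_segmenter_plugin", "get_segmenter",
    "available_segmenters",
]


class SeedRejected(RuntimeError):
    """The seed does not sit on foreground-like intensity."""


class PluginContractError(RuntimeError):
    """A segmenter plugin returned a mask violating the SomaMask contract."""


@dataclass
class SomaMask:
    """Binary soma mask over a cropped cube, tied to one cell."""

    cell_id: int
    mask: np.ndarray  # bool, cube-shaped
    origin_um: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    seed_um: tuple[float, float, float]
    truncated: bool = False

    def volume_um3(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class SegmentConfig:
    k_sigma: float = 3.0  # growth band half-width in background SDs
    closing_radius_um: float = 1.0
    opening_radius_um: float = 1.5
    max_growth_iters: int = 12
    margin_voxels: int = 2  # shell used for the background noise estimate
    seed_nsigma: float = 4.0  # seed must exceed background by this many SDs
    # growth and morphology run in this sub-box around the seed first; the
    # full cube is used only when the region reaches the sub-box boundary
    working_box_um: float = 80.0
    segmenter: str = "classical"


def _unit_ball(vs) -> np.ndarray:
    """Structuring element: physical ball of radius max(voxel_size)."""
    vs = np.asarray(vs, float)
    r_um = float(vs.max())
    r = np.maximum(1, np.ceil(r_um / vs).astype(int))
    grids = np.meshgrid(*[np.arange(-a, a + 1) * v for a, v in zip(r, vs)],
                        indexing="ij")
    return sum(g**2 for g in grids) <= r_um**2 + 1e-9


def _radius_iterations(radius_um: float, vs) -> int:
    return int(np.floor(radius_um / float(np.asarray(vs).max()) + 1e-9))


def _closing(mask, radius_um, vs):
    k = _radius_iterations(radius_um, vs)
    if k == 0 or not mask.any():
        return mask
    ball = _unit_ball(vs)
    dil = ndimage.binary_dilation(mask, structure=ball, iterations=k)
    return ndimage.binary_erosion(dil, structure=ball, iterations=k)


def _opening(mask, radius_um, vs):
    """Opening by the k-fold dilation of a unit ball (k = radius in units of
    max voxel size).

    The B, B², B³, … family is a true granulometry, so mask volume is
    exactly monotone non-increasing in the opening radius.
    """
    k = _radius_iterations(radius_um, vs)
    if k == 0 or not mask.any():
        return mask
    ball = _unit_ball(vs)
    ero = ndimage.binary_erosion(mask, structure=ball, iterations=k)
    return ndimage.binary_dilation(ero, structure=ball, iterations=k)


def _signal(cube: VoxelGrid) -> np.ndarray:
    data = cube.data.astype(np.float32)
    return 255.0 - data if cube.polarity == "dark_cells" else data


def _margin_stats(sig: np.ndarray, margin: int) -> tuple[float, float]:
    """Robust background level and noise SD from the cube's margin shell.

    Median and scaled MAD are used so somata intersecting the shell do not
    inflate the noise estimate.
    """
    shell = np.ones(sig.shape, dtype=bool)
    inner = tuple(slice(margin, max(margin + 1, n - margin)) for n in sig.shape)
    shell[inner] = False
    vals = sig[shell]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, max(1.4826 * mad, 0.5)


def _component_containing(mask: np.ndarray, idx) -> Optional[np.ndarray]:
    lab, _ = ndimage.label(mask)
    lid = lab[tuple(idx)]
    if lid == 0:
        return None
    return lab == lid


def segment_classical(
    cube: VoxelGrid,
    seed_um,
    config: SegmentConfig = SegmentConfig(),
    other_seeds_um: Sequence = (),
) -> np.ndarray:
    """Built-in deterministic segmenter; returns a boolean cube mask."""
    sig = _signal(cube)
    vs = np.asarray(cube.voxel_size)
    origin = np.asarray(cube.origin)
    seed_idx = np.floor((np.asarray(seed_um, float) - origin) / vs).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= sig.shape):
        raise SeedRejected(f"seed {tuple(seed_um)} outside the cube")
    valid = getattr(cube, "valid_slices", None)
    bg_mean, bg_sd = _margin_stats(sig[valid] if valid else sig, config.margin_voxels)
    if sig[tuple(seed_idx)] < bg_mean + config.seed_nsigma * bg_sd:
        raise SeedRejected(
            f"seed intensity {sig[tuple(seed_idx)]:.1f} not foreground-like "
            f"(background {bg_mean:.1f} ± {bg_sd:.1f})"
        )

    other_idx = [
        np.floor((np.asarray(p, float) - origin) / vs).astype(int)
        for p in other_seeds_um
    ]

    # run in a sub-box around the seed first; fall back to the full cube if
    # the grown region reaches the sub-box boundary
    if config.working_box_um and config.working_box_um < max(
        n * v for n, v in zip(sig.shape, vs)
    ):
        half = np.ceil(config.working_box_um / (2.0 * vs)).astype(int)
        lo = np.maximum(seed_idx - half, 0)
        hi = np.minimum(seed_idx + half + 1, sig.shape)
        sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        sub_mask = _segment_core(
            sig[sub], seed_idx - lo, vs, bg_sd,
            [o - lo for o in other_idx], config,
        )
        interior_edge = any(
            (sub_mask.take(0, axis=a).any() and lo[a] > 0)
            or (sub_mask.take(-1, axis=a).any() and hi[a] < sig.shape[a])
            for a in range(3)
        )
        if not interior_edge:
            mask = np.zeros(sig.shape, dtype=bool)
            mask[sub] = sub_mask
            return mask
    return _segment_core(sig, seed_idx, vs, bg_sd, other_idx, config)


def _segment_core(sig, seed_idx, vs, bg_sd, other_idx, config: SegmentConfig):
    """Adaptive growth + watershed split + morphological cleanup."""
    region_mean = float(sig[tuple(seed_idx)])
    region = None
    for _ in range(config.max_growth_iters):
        band = np.abs(sig - region_mean) <= config.k_sigma * bg_sd
        comp = _component_containing(band, seed_idx)
        if comp is None:
            break
        new_mean = float(sig[comp].mean())
        if region is not None and np.array_equal(comp, region):
            break
        region = comp
        if abs(new_mean - region_mean) < 1e-3:
            break
        region_mean = new_mean
    if region is None:
        raise SeedRejected("region growth collapsed at the seed")

    # split fused neighbours by watershed on the distance transform
    others = [
        o for o in other_idx
        if np.all(o >= 0) and np.all(o < np.asarray(sig.shape))
        and region[tuple(o)] and not np.array_equal(o, seed_idx)
    ]
    if others:
        dist = ndimage.distance_transform_edt(region, sampling=vs)
        markers = np.zeros(region.shape, dtype=np.int32)
        markers[tuple(seed_idx)] = 1
        for m, o in enumerate(others, start=2):
            markers[tuple(o)] = m
        ws = watershed(-dist, markers, mask=region)
        region = ws == 1

    if config.closing_radius_um > 0:
        region = _closing(region, config.closing_radius_um, vs)
    if config.opening_radius_um > 0:
        region = _opening(region, config.opening_radius_um, vs)
    comp = _component_containing(region, seed_idx)
    if comp is None:
        raise SeedRejected("morphological cleanup removed the seed voxel")
    return comp


# ---------------------------------------------------------------------------
# plugin registry

_SEGMENTERS: dict[str, Callable] = {"classical": segment_classical}


def register_segmenter_plugin(name: str, fn: Callable) -> None:
    """Register a segmenter callable (cube, seed_um, config, other_seeds_um) -> bool mask.

    Outputs are validated against the SomaMask contract at call time: a
    single connected component containing the seed voxel. An empty mask maps
    to :class:`SeedRejected`.
    """
    if not callable(fn):
        raise TypeError("segmenter plugin must be callable")
    _SEGMENTERS[name] = fn


def get_segmenter(name: str) -> Callable:
    try:
        return _SEGMENTERS[name]
    except KeyError:
        raise KeyError(f"unknown segmenter {name!r}; registered: {sorted(_SEGMENTERS)}")


def available_segmenters() -> list[str]:
    return sorted(_SEGMENTERS)


def _validate_mask(mask: np.ndarray, cube: VoxelGrid, seed_um) -> None:
    if mask.dtype != bool or mask.shape != cube.data.shape:
        raise PluginContractError("mask must be boolean and cube-shaped")
    if not mask.any():
        raise SeedRejected("segmenter returned an empty mask")
    seed_idx = np.floor(
        (np.asarray(seed_um, float) - np.asarray(cube.origin)) / np.asarray(cube.voxel_size)
    ).astype(int)
    if not mask[tuple(seed_idx)]:
        raise PluginContractError("mask does not contain the seed voxel")
    _, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise PluginContractError(f"mask has {ncomp} connected components, expected 1")


def _touches_boundary(mask: np.ndarray, valid=None) -> bool:
    """True when the mask reaches the edge of the real data.

    ``valid`` (slice triple) restricts the check to the non-padded part of a
    cropped cube, so somata clipped by the source volume are flagged even
    when the padded cube extends further.
    """
    sub = mask[valid] if valid is not None else mask
    return bool(
        sub[0].any() or sub[-1].any()
        or sub[:, 0].any() or sub[:, -1].any()
        or sub[:, :, 0].any() or sub[:, :, -1].any()
    )


def segment_soma(
    cube: VoxelGrid,
    seed_um,
    config: SegmentConfig = SegmentConfig(),
    other_seeds_um: Sequence = (),
    cell_id: int = 0,
) -> SomaMask:
    """Segment one soma around its seed within a cropped cube."""
    fn = get_segmenter(config.segmenter)
    mask = fn(cube, seed_um, config, other_seeds_um)
    _validate_mask(mask, cube, seed_um)
    return SomaMask(
        cell_id=cell_id, mask=mask, origin_um=cube.origin,
        voxel_size=cube.voxel_size, seed_um=tuple(float(v) for v in seed_um),
        truncated=_touches_boundary(mask, getattr(cube, "valid_slices", None)),
    )


@dataclass
class SegmentationBatch:
    masks: list[SomaMask]
    failures: list[tuple[int, str]] = field(default_factory=list)

    def report_rows(self) -> list[dict]:
        rows = [
            {"cell_id": m.cell_id, "status": "ok", "volume_um3": m.volume_um3(),
             "truncated": m.truncated}
            for m in self.masks
        ]
        rows += [
            {"cell_id": cid, "status": f"rejected: {why}", "volume_um3": np.nan,
             "truncated": False}
            for cid, why in self.failures
        ]
        return rows


def segment_all(
    store: Union[VoxelGrid, BlockStore],
    dets: Sequence[Union[Detection, tuple]],
    edge_um: float = 128.0,
    config: SegmentConfig = SegmentConfig(),
    ids: Optional[Sequence[int]] = None,
) -> SegmentationBatch:
    """Crop one cube per detection and segment it; failures never abort the batch.

    Neighbouring detection centers falling inside a cube are passed to the
    segmenter as watershed split markers.
    """
    centers = np.array(
        [d.center if isinstance(d, Detection) else tuple(d) for d in dets], dtype=float
    ).reshape(-1, 3)
    if ids is None:
        ids = list(range(1, len(centers) + 1))
    out = SegmentationBatch(masks=[])
    half = edge_um / 2.0
    for i, c in enumerate(centers):
        try:
            cube = crop_cube(store, tuple(c), edge_um)
            near = [
                tuple(centers[j]) for j in range(len(centers))
                if j != i and np.all(np.abs(centers[j] - c) < half)
            ]
            mask = segment_soma(cube, tuple(c), config, near, cell_id=ids[i])
            out.masks.append(mask)
        except (SeedRejected, ValueError) as exc:
            out.failures.append((ids[i], str(exc)))
    return out
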