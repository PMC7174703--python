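"""Per-cell morphometric features.

Two feature groups are computed from a soma mask:

* the three cell-typing features — soma volume (μm³), mean gray value of the
  masked voxels, and the longest radius, i.e. the maximum distance from the
  intensity-weighted centroid to any surface voxel center;

* the three soma-shape ratios used to separate Betz-cell shape classes —
  the axial ratio of the principal-axes-oriented bounding box
  (``rect_axial_ratio``), and on the largest planar cross-section through
  the centroid (normal to one of the principal axes), the
  centroid-to-boundary max/min distance ratio (``maxsec_distance_ratio``)
  and the major/minor axis ratio of the section's second-moment ellipse
  (``maxsec_axial_ratio``). All ratios are ≥ 1 and rotation-invariant up to
  discretization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import VoxelGrid
from .segment import SomaMask

__all__ = [
    "FeatureVector", "ShapeRatios", "DegenerateMaskError", "basic_features",
    "principal_axes", "shape_features", "mask_from_labels", "masks_from_labels",
]


class DegenerateMaskError(ValueError):
    """Mask empty or without 3D extent (coplanar/collinear voxels)."""


@dataclass(frozen=True)
class FeatureVector:
    volume: float  # μm³
    mean_gray: float
    longest_radius: float  # μm

    def as_array(self) -> np.ndarray:
        return np.array([self.volume, self.mean_gray, self.longest_radius])


@dataclass(frozen=True)
class ShapeRatios:
    rect_axial_ratio: float
    maxsec_distance_ratio: float
    maxsec_axial_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rect_axial_ratio, self.maxsec_distance_ratio, self.maxsec_axial_ratio]
        )


def mask_from_labels(
    labels: VoxelGrid, cell_id: int, pad_um: float = 3.0, bbox: Optional[tuple] = None,
) -> SomaMask:
    """Extract one cell's ground-truth mask as a SomaMask (tight crop + pad).

    ``bbox`` (slice triple from ``scipy.ndimage.find_objects``) avoids a full
    label-volume scan; see :func:`masks_from_labels` for the bulk path.
    """
    if bbox is not None:
        off = np.array([s.start for s in bbox])
        where = np.argwhere(labels.data[bbox] == cell_id) + off
    else:
        where = np.argwhere(labels.data == cell_id)
    if len(where) == 0:
        raise DegenerateMaskError(f"cell {cell_id} absent from label grid")
    vs = np.asarray(labels.voxel_size)
    pad = np.ceil(pad_um / vs).astype(int)
    lo = np.maximum(where.min(axis=0) - pad, 0)
    hi = np.minimum(where.max(axis=0) + pad + 1, labels.data.shape)
    sub = labels.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] == cell_id
    origin = np.asarray(labels.origin) + lo * vs
    centroid = origin + (where.mean(axis=0) + 0.5) * vs
    touches = bool(np.any(where.min(axis=0) == 0)) or bool(
        np.any(where.max(axis=0) == np.asarray(labels.data.shape) - 1)
    )
    return SomaMask(
        cell_id=cell_id, mask=sub, origin_um=tuple(origin),
        voxel_size=tuple(labels.voxel_size), seed_um=tuple(centroid),
        truncated=touches,
    )


def masks_from_labels(labels: VoxelGrid, ids=None, pad_um: float = 3.0) -> dict:
    """Ground-truth SomaMasks for all (or selected) labels in one volume scan."""
    objects = ndimage.find_objects(labels.data)
    out = {}
    for cell_id in (ids if ids is not None else range(1, len(objects) + 1)):
        bbox = objects[cell_id - 1] if cell_id - 1 < len(objects) else None
        if bbox is None:
            continue
        out[cell_id] = mask_from_labels(labels, cell_id, pad_um, bbox=bbox)
    return out


def _mask_points_um(mask: SomaMask) -> np.ndarray:
    """Physical coordinates of mask voxel centers, (n, 3)."""
    idx = np.argwhere(mask.mask)
    return np.asarray(mask.origin_um) + (idx + 0.5) * np.asarray(mask.voxel_size)


def basic_features(mask: SomaMask, cube: Optional[VoxelGrid] = None) -> FeatureVector:
    """Volume, mean gray and longest radius for one soma.

    The centroid is weighted by staining intensity (gray inverted for
    dark-cell polarity) when a cube is given, otherwise unweighted.
    ``mean_gray`` is always reported on the raw stored intensity.
    """
    m = mask.mask
    if not m.any():
        raise DegenerateMaskError("empty mask")
    vs = np.asarray(mask.voxel_size)
    volume = float(m.sum()) * float(np.prod(vs))
    pts = _mask_points_um(mask)
    if cube is not None:
        if cube.data.shape != m.shape:
            raise ValueError("mask and cube must share geometry")
        raw = cube.data[m].astype(float)
        mean_gray = float(raw.mean())
        w = (255.0 - raw) if cube.polarity == "dark_cells" else raw
        w = np.maximum(w, 1e-6)
        centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
    else:
        mean_gray = float("nan")
        centroid = pts.mean(axis=0)
    surface = m & ~ndimage.binary_erosion(m)
    sp = np.asarray(mask.origin_um) + (np.argwhere(surface) + 0.5) * vs
    longest = float(np.linalg.norm(sp - centroid, axis=1).max())
    return FeatureVector(volume=volume, mean_gray=mean_gray, longest_radius=longest)


def principal_axes(mask: SomaMask) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal principal axes and extents (μm) of the mask.

    Axes are eigenvectors of the second-moment tensor of voxel centers in
    physical coordinates; extents are projection ranges along each axis,
    sorted descending.
    """
    pts = _mask_points_um(mask)
    if len(pts) < 4:
        raise DegenerateMaskError("mask needs >= 4 voxels for principal axes")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows = axes, descending variance
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0) + np.mean(mask.voxel_size)
    if extents[2] <= np.mean(mask.voxel_size) * 1e-3:
        raise DegenerateMaskError("mask is coplanar")
    order2 = np.argsort(extents)[::-1]
    return axes[order2], extents[order2]


def _section(mask: SomaMask, center_um, normal_axes, step: float) -> np.ndarray:
    """Sample the planar cross-section through ``center_um`` as a 2D float image.

    ``normal_axes`` is a (2, 3) basis of the section plane; sampling is
    trilinear at ``step`` μm so boundaries resolve at sub-voxel precision.
    """
    e1, e2 = normal_axes
    pts = _mask_points_um(mask)
    half = float(np.linalg.norm(pts - np.asarray(center_um), axis=1).max()) + 2 * step
    n = int(np.ceil(2 * half / step)) + 1
    u = (np.arange(n) - (n - 1) / 2.0) * step
    uu, vv = np.meshgrid(u, u, indexing="ij")
    world = (
        np.asarray(center_um)[None, None]
        + uu[..., None] * np.asarray(e1)[None, None]
        + vv[..., None] * np.asarray(e2)[None, None]
    )
    vox = (world - np.asarray(mask.origin_um)) / np.asarray(mask.voxel_size) - 0.5
    return ndimage.map_coordinates(
        mask.mask.astype(np.float32), vox.transpose(2, 0, 1), order=1, cval=0.0
    )


def shape_features(mask: SomaMask, section_step_factor: float = 0.5) -> ShapeRatios:
    """The three Betz-cell soma shape ratios for one mask.

    The max-section is the largest-area planar cut through the centroid
    normal to one of the three principal axes; boundary distances are taken
    on its sub-voxel marching-squares contour.
    """
    axes, extents = principal_axes(mask)
    rect_ratio = float(extents[0] / extents[2])

    pts = _mask_points_um(mask)
    centroid = pts.mean(axis=0)
    step = float(min(mask.voxel_size)) * section_step_factor

    best_img, best_area = None, -1.0
    for i in range(3):
        plane = np.array([axes[(i + 1) % 3], axes[(i + 2) % 3]])
        img = _section(mask, centroid, plane, step)
        area = float((img >= 0.5).sum()) * step * step
        if area > best_area:
            best_area, best_img = area, img

    binary = best_img >= 0.5
    if binary.sum() < 4:
        raise DegenerateMaskError("max section too small")
    contours = measure.find_contours(best_img, 0.5)
    if not contours:
        raise DegenerateMaskError("no section contour")
    contour = max(contours, key=len)
    center_px = (np.array(best_img.shape) - 1) / 2.0
    d = np.linalg.norm(contour - center_px, axis=1) * step
    dist_ratio = float(d.max() / max(d.min(), step * 1e-3))

    # second-moment ellipse of the section
    sec_pts = (np.argwhere(binary) - center_px) * step
    cov = sec_pts.T @ sec_pts / len(sec_pts)
    evals = np.linalg.eigvalsh(cov)
    axial_ratio = float(np.sqrt(max(evals[1], 1e-12) / max(evals[0], 1e-12)))

    return ShapeRatios(
        rect_axial_ratio=max(rect_ratio, 1.0),
        maxsec_distance_ratio=max(dist_ratio, 1.0),
        maxsec_axial_ratio=max(axial_ratio, 1.0),
    )
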