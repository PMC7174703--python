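"""Implicit 3D soma-shape archetypes.

Each archetype is an implicit solid defined in a cell-local frame (z is the
shape's principal axis) at a dimensionless size scale ``s`` in μm. The four
Betz-cell soma shapes (pyramidal, spindle, flat — oval or triangular — and
spheroid) plus a mildly prolate generic pyramidal-neuron shape are provided:

- ``spheroid``        near-isotropic ellipsoid
- ``other_pyn``       mildly prolate ellipsoid (axis ratio 1.4)
- ``spindle``         prolate, axis ratio 2.6, poles tapered faster than an
                      ellipsoid (cross-section radius ∝ (1 − (z/a)²)^0.75)
- ``flat_oval``       oblate ellipsoid, shortest axis 0.4 × longest
- ``flat_triangular`` flattened triangular prism with rounded edges
- ``pyramidal``       cone–tetrahedron blend (rounded-triangle cross-section
                      shrinking toward the apex) with a thick apical stub

``volume_coef`` gives the approximate solid volume as ``coef · s³`` (used as
an initial guess only; rendering calibrates the scale against the voxelised
volume), and ``bound_coef`` a conservative bounding radius ``coef · s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ShapeSpec", "SHAPES", "SHAPE_NAMES"]


def _tri_sdf(x, y, r):
    """Euclidean signed distance to an equilateral triangle (size r).

    Vertices lie at distance 2r/√3 from the centroid; negative inside.
    """
    k = np.sqrt(3.0)
    px = np.abs(x) - r
    py = y + r / k
    flip = px + k * py > 0.0
    px2 = (px - k * py) / 2.0
    py2 = (-k * px - py) / 2.0
    px = np.where(flip, px2, px)
    py = np.where(flip, py2, py)
    px = px - np.clip(px, -2.0 * r, 0.0)
    return -np.hypot(px, py) * np.sign(py + 1e-12)


def _spheroid(x, y, z, s):
    return (x / (0.95 * s)) ** 2 + (y / s) ** 2 + (z / (1.1 * s)) ** 2 <= 1.0


def _other_pyn(x, y, z, s):
    return (x / s) ** 2 + (y / s) ** 2 + (z / (1.4 * s)) ** 2 <= 1.0


def _spindle(x, y, z, s):
    a = 2.6 * s
    t = np.clip(1.0 - (z / a) ** 2, 0.0, None)
    b = s * t ** 0.75
    return x * x + y * y <= b * b


def _flat_oval(x, y, z, s):
    return (x / s) ** 2 + (y / (0.85 * s)) ** 2 + (z / (0.4 * s)) ** 2 <= 1.0


def _flat_triangular(x, y, z, s):
    h = 0.35 * s  # half thickness
    t = np.clip(1.0 - (z / h) ** 2, 0.0, None)
    # rim rounding goes negative toward the faces -> rounded edges
    return (np.abs(z) <= h) & (_tri_sdf(x, y, 1.0 * s) <= 0.3 * s * (2.0 * np.sqrt(t) - 1.0))


def _pyramidal(x, y, z, s):
    h = 1.1 * s  # half height of the body
    u = np.clip((z + h) / (2.0 * h), 0.0, 1.0)  # 0 at base, 1 at apex
    f = 1.0 - 0.72 * u  # cross-section shrink factor
    body = (np.abs(z) <= h) & (_tri_sdf(x, y, 0.8 * s * f) <= 0.45 * s * f)
    # thick apical stub emerging from the apex
    stub = (z > h) & (z <= h + 0.5 * s) & (x * x + y * y <= (0.25 * s) ** 2)
    return body | stub


@dataclass(frozen=True)
class ShapeSpec:
    name: str
    fn: Callable[..., np.ndarray]
    volume_coef: float
    bound_coef: float


SHAPES: dict[str, ShapeSpec] = {
    "spheroid": ShapeSpec("spheroid", _spheroid, 4.377, 1.15),
    "other_pyn": ShapeSpec("other_pyn", _other_pyn, 5.864, 1.45),
    "spindle": ShapeSpec("spindle", _spindle, 9.622, 2.65),
    "flat_oval": ShapeSpec("flat_oval", _flat_oval, 1.424, 1.05),
    "flat_triangular": ShapeSpec("flat_triangular", _flat_triangular, 2.0, 1.50),
    "pyramidal": ShapeSpec("pyramidal", _pyramidal, 3.42, 1.70),
}

SHAPE_NAMES = tuple(SHAPES)
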