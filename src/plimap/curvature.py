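"""Radius-of-curvature estimation via the SVD-based Taubin circle fit.

Taubin's algebraic circle fit minimizes a normalized algebraic distance and
has much lower essential bias than the Kasa fit.  The implementation follows
the standard numerically-stable route: center the points, scale the squared
radii, and take the smallest right singular vector of the design matrix.
Input points come from 2-D cross sections (e.g. surface traces extracted
from OCT B-scans); extraction itself is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._exceptions import DegenerateGeometryError, InvalidArgumentError


@dataclass(frozen=True)
class CircleFit:
    """Fitted circle: center (x, y), radius and RMS radial residual (same units)."""

    center: tuple[float, float]
    radius: float
    rms_residual: float
    n_points: int


def taubin_circle_fit(points: Iterable) -> CircleFit:
    """Fit a circle to >= 3 non-collinear planar points (Taubin, via SVD).

    Raises DegenerateGeometryError for collinear or coincident points, where
    no finite circle exists.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidArgumentError("points must be finite")

    centroid = pts.mean(axis=0)
    xy = pts - centroid
    if np.allclose(xy, 0.0):
        raise DegenerateGeometryError("all points coincide")
    z = np.sum(xy**2, axis=1)
    zmean = z.mean()
    z0 = (z - zmean) / (2.0 * np.sqrt(zmean))
    design = np.column_stack([z0, xy[:, 0], xy[:, 1]])
    _, svals, vt = np.linalg.svd(design, full_matrices=False)
    v = vt[-1]
    a = v[0] / (2.0 * np.sqrt(zmean))
    b, c = v[1], v[2]
    d = -zmean * a
    # a ~ 0 <=> the best algebraic "circle" is a line
    if abs(a) < 1e-12 * max(1.0, np.abs([b, c]).max()) or (
        svals[-1] < 1e-12 * svals[0] and abs(a) < 1e-9
    ):
        raise DegenerateGeometryError("points are (numerically) collinear")
    center_local = -np.array([b, c]) / (2.0 * a)
    radius = float(np.sqrt(max(b * b + c * c - 4.0 * a * d, 0.0)) / (2.0 * abs(a)))
    if not np.isfinite(radius) or radius <= 0:
        raise DegenerateGeometryError("degenerate circle geometry")
    center = center_local + centroid
    dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return CircleFit(
        center=(float(center[0]), float(center[1])),
        radius=radius,
        rms_residual=rms,
        n_points=int(pts.shape[0]),
    )


def read_points(path) -> np.ndarray:
    """Read an (x, y) point set from delimiter-separated text ('#' comments)."""
    pts = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    if pts.shape[1] < 2:
        raise InvalidArgumentError("point file must have two columns (x, y)")
    return pts[:, :2]
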