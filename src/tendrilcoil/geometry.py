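"""Geometric primitives shared by the simulator and the track-analysis pipeline.

All lengths are in millimetres and all angles in degrees. Points are
array-likes of shape ``(3,)`` (``z = 0`` for planar data); point sets are
``(n, 3)`` arrays.

The key quantity throughout the package is the *bending angle*: the interior
angle at a marker between the rays to its two neighbours. A perfectly
straight tendril has a bending angle of 180 deg at every interior marker;
coiling lowers it. For three consecutive markers spaced at arc length ``s``
on a circle of radius ``R`` the bending angle equals ``180 - (180/pi)*(s/R)``,
which is how a coil diameter manifests in a bending-angle series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "CircleFit",
    "bending_angle",
    "coiling_angle_at",
    "fit_circle_3d",
    "resample_polyline",
]

#: Scale-free collinearity threshold: smallest/largest singular value ratio.
COLLINEARITY_TOL = 1e-6


@dataclass(frozen=True)
class CircleFit:
    """A circle fitted to 3D points.

    Attributes
    ----------
    center : ndarray, shape (3,)
        Circle centre in mm.
    diameter : float
        Circle diameter in mm (> 0).
    plane_normal : ndarray, shape (3,)
        Unit normal of the fitted plane.
    rms_residual : float
        Root-mean-square orthogonal distance (mm) of the plane-projected
        points to the fitted circle.
    """

    center: np.ndarray
    diameter: float
    plane_normal: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise DegenerateGeometryError(
                f"circle diameter must be positive, got {self.diameter}"
            )
        n = np.asarray(self.plane_normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise DegenerateGeometryError("plane_normal must be a unit vector")
        if self.rms_residual < 0:
            raise DegenerateGeometryError("rms_residual must be non-negative")


def _as_point(p, name: str) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


def bending_angle(p_prev, p, p_next) -> float:
    """Interior angle (degrees, in [0, 180]) at vertex ``p``.

    180 means the three points are collinear with ``p`` between its
    neighbours (locally straight tendril); smaller values mean a sharper
    local bend.

    Raises
    ------
    DegenerateGeometryError
        If either neighbour coincides with the vertex (distance <= 1e-9 mm).
    """
    a = _as_point(p_prev, "p_prev")
    b = _as_point(p, "p")
    c = _as_point(p_next, "p_next")
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= 1e-9 or nv <= 1e-9:
        raise DegenerateGeometryError(
            f"coincident points at vertex {b.tolist()}: cannot define a bending angle"
        )
    # atan2 of (|u x v|, u.v) is well conditioned near 0 and 180 deg,
    # unlike arccos of the normalised dot product
    cross = np.linalg.norm(np.cross(u, v))
    return float(np.degrees(np.arctan2(cross, np.dot(u, v))))


def coiling_angle_at(track_frame, contact_index: int) -> float:
    """Coiling angle (degrees) at a marker: ``180 - bending_angle``.

    Zero for a straight tendril, growing as the tendril coils at the
    contact marker. The marker must have both neighbours.
    """
    pts = np.asarray(track_frame, dtype=float)
    if not 1 <= contact_index <= len(pts) - 2:
        raise ValueError(
            f"contact_index {contact_index} needs both neighbours "
            f"(0 < i < {len(pts) - 1})"
        )
    return 180.0 - bending_angle(
        pts[contact_index - 1], pts[contact_index], pts[contact_index + 1]
    )


def _fit_plane(points: np.ndarray):
    """Total-least-squares plane. Returns (centroid, e1, e2, normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0 or s[1] < COLLINEARITY_TOL * s[0]:
        raise DegenerateGeometryError(
            "points are collinear (or coincident): no unique circle"
        )
    return centroid, vt[0], vt[1], vt[2]


def _pratt_circle(x: np.ndarray, y: np.ndarray):
    """Pratt algebraic circle fit in 2D. Returns (cx, cy, r)."""
    z = x * x + y * y
    zm = np.column_stack([z, x, y, np.ones_like(x)])
    m = zm.T @ zm / len(x)
    b = np.zeros((4, 4))
    b[0, 3] = b[3, 0] = -2.0
    b[1, 1] = b[2, 2] = 1.0
    try:
        from scipy.linalg import eig

        w, v = eig(m, b)
        w = np.real(w)
        v = np.real(v)
        mask = np.isfinite(w) & (w > -1e-12)
        if not np.any(mask):
            raise np.linalg.LinAlgError
        idx = np.where(mask)[0][np.argmin(w[mask])]
        a_coef, b_coef, c_coef, d_coef = v[:, idx]
    except (np.linalg.LinAlgError, ValueError):
        # Kasa fallback: linear least squares on x^2+y^2 + Dx + Ey + F = 0
        sol, *_ = np.linalg.lstsq(
            np.column_stack([x, y, np.ones_like(x)]), -z, rcond=None
        )
        a_coef, (b_coef, c_coef, d_coef) = 1.0, sol
    if abs(a_coef) < 1e-14:
        raise DegenerateGeometryError("degenerate (near-linear) circle fit")
    cx = -b_coef / (2 * a_coef)
    cy = -c_coef / (2 * a_coef)
    r2 = cx * cx + cy * cy - d_coef / a_coef
    if r2 <= 0:
        raise DegenerateGeometryError("circle fit produced non-positive radius")
    return cx, cy, float(np.sqrt(r2))


def _gauss_newton_circle(x, y, cx, cy, r):
    """One Gauss-Newton refinement pass on geometric (orthogonal) distance."""
    dx = x - cx
    dy = y - cy
    d = np.hypot(dx, dy)
    if np.any(d < 1e-12):
        return cx, cy, r
    jac = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
    res = d - r
    try:
        delta, *_ = np.linalg.lstsq(jac, -res, rcond=None)
    except np.linalg.LinAlgError:
        return cx, cy, r
    return cx + delta[0], cy + delta[1], r + delta[2]


def fit_circle_3d(points) -> CircleFit:
    """Fit a circle to >= 3 non-collinear 3D points.

    The points are projected onto their total-least-squares plane; a
    Pratt-style algebraic circle fit in that plane is refined by one
    Gauss-Newton pass on the geometric distances.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points, collinear points, or a near-zero radius.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need at least 3 points to fit a circle, got {len(pts)}"
        )
    centroid, e1, e2, normal = _fit_plane(pts)
    centered = pts - centroid
    x = centered @ e1
    y = centered @ e2
    # normalise the scale so the Pratt eigen-selection thresholds are
    # scale-free
    scale = np.sqrt(np.mean(x * x + y * y))
    if scale <= 0:
        raise DegenerateGeometryError("coincident points: no unique circle")
    xs, ys = x / scale, y / scale
    cx, cy, r = _pratt_circle(xs, ys)
    cx, cy, r = _gauss_newton_circle(xs, ys, cx, cy, r)
    cx, cy, r = cx * scale, cy * scale, r * scale
    if r <= 1e-9:
        raise DegenerateGeometryError("fitted circle has near-zero radius")
    resid = np.hypot(x - cx, y - cy) - r
    center3 = centroid + cx * e1 + cy * e2
    return CircleFit(
        center=center3,
        diameter=2.0 * r,
        plane_normal=normal / np.linalg.norm(normal),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def resample_polyline(points, ds: float) -> np.ndarray:
    """Points at arc-length multiples of ``ds`` along a polyline.

    Linear interpolation between input vertices; the first input point is
    always included. If ``ds`` exceeds the total length, only the first
    point is returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) polyline, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline contains non-finite coordinates")
    if ds <= 0:
        raise ValueError(f"ds must be positive, got {ds}")
    if len(pts) < 2:
        return pts[:1].copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    # small epsilon so an exact final multiple survives float rounding
    targets = np.arange(0.0, total + 1e-9, ds)
    out = np.column_stack(
        [np.interp(targets, s, pts[:, k]) for k in range(3)]
    )
    return out
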