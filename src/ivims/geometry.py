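"""Coordinate frames, 3D lines, detector-plane geometry and the PCA vertex solver.

Lab frame convention
--------------------
The origin sits at the treatment isocenter (center of the head phantom) and the
primary beam travels along +Z.  With the default phantom depth of 180.5 mm the
phantom entrance plane is at Z = -90.25 mm and the exit at +90.25 mm.  All
lengths are millimetres.

The interaction vertex of a (fragment line, beam line) pair is the point of
closest approach (PCA): the point ``P`` minimizing the summed squared
distances to both lines,

    cost(P) = d^2(P, L_frag) + d^2(P, L_beam).

For two lines with unit directions ``d_i`` and anchors ``a_i`` the minimizer
solves the 3x3 linear system

    sum_i (I - d_i d_i^T) P = sum_i (I - d_i d_i^T) a_i,

which is the midpoint of the common-perpendicular segment; its distance to
each line is half the line-line distance.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Point3",
    "Line3",
    "DetectorPlane",
    "StackGeometry",
    "Vertex",
    "point_of_closest_approach",
    "pca_batch",
    "project_to_plane",
    "pixelate",
    "pixel_center",
    "make_stack",
]

_UNIT_TOL = 1e-9


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite 3-vector, got {v!r}")
    return a


@dataclass(frozen=True)
class Point3:
    """A point in the lab frame, components in mm."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError("Point3 components must be finite")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3":
        a = _as_vec(a)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class Line3:
    """A 3D line: anchor point plus unit direction."""

    anchor: Point3
    direction: tuple[float, float, float]

    def __post_init__(self):
        d = _as_vec(self.direction)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("Line3 direction must be non-zero")
        if abs(n - 1.0) > _UNIT_TOL:
            raise ValueError(f"Line3 direction must be unit-norm (|d| = {n})")
        object.__setattr__(self, "direction", (float(d[0]), float(d[1]), float(d[2])))

    @classmethod
    def through(cls, anchor, direction) -> "Line3":
        """Build a line, normalizing ``direction``."""
        d = _as_vec(direction)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        if not isinstance(anchor, Point3):
            anchor = Point3.from_array(anchor)
        return cls(anchor, tuple(d / n))

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction)

    @property
    def a(self) -> np.ndarray:
        return self.anchor.array

    def point_at(self, t: float) -> np.ndarray:
        return self.a + t * self.d

    def distance_to(self, p) -> float:
        """Perpendicular distance from point ``p`` to the line."""
        r = _as_vec(p) - self.a
        return float(np.linalg.norm(r - (r @ self.d) * self.d))


@dataclass(frozen=True)
class Vertex:
    """Reconstructed PCA point with its miss distance.

    ``miss_distance`` is the distance from the solution point to each of the
    two lines; for the two-line PCA these are equal (half the common
    perpendicular), so a single value is reported.
    """

    position: Point3
    miss_distance: float
    event_id: int = -1

    def __post_init__(self):
        if self.miss_distance < 0:
            raise ValueError("miss_distance must be >= 0")


@dataclass(frozen=True)
class DetectorPlane:
    """A rectangular pixelated sensor plane.

    ``axis_u``/``axis_v`` span the active area; both are orthonormal and
    perpendicular to ``normal``.  Defaults follow a 5x5 cm^2 silicon tracker
    with 55 um pitch and 50 um thickness.
    """

    center: Point3
    normal: tuple[float, float, float]
    axis_u: tuple[float, float, float]
    axis_v: tuple[float, float, float]
    half_width: float = 25.0
    half_height: float = 25.0
    pixel_pitch: float = 0.055
    thickness: float = 0.050

    def __post_init__(self):
        n, u, v = _as_vec(self.normal), _as_vec(self.axis_u), _as_vec(self.axis_v)
        for name, w in (("normal", n), ("axis_u", u), ("axis_v", v)):
            if abs(np.linalg.norm(w) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be unit-norm")
        if max(abs(u @ n), abs(v @ n), abs(u @ v)) > 1e-9:
            raise ValueError("plane axes must be mutually orthogonal")
        if min(self.half_width, self.half_height, self.pixel_pitch) <= 0:
            raise ValueError("plane dimensions must be positive")

    @property
    def n_u(self) -> int:
        return int(np.ceil(2 * self.half_width / self.pixel_pitch))

    @property
    def n_v(self) -> int:
        return int(np.ceil(2 * self.half_height / self.pixel_pitch))

    def to_lab(self, u, v) -> np.ndarray:
        """Map in-plane (u, v) mm to lab coordinates (vectorized)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        c = self.center.array
        return (
            c
            + np.multiply.outer(u, _as_vec(self.axis_u))
            + np.multiply.outer(v, _as_vec(self.axis_v))
        )


@dataclass(frozen=True)
class StackGeometry:
    """Two parallel sensor planes forming one tracker stack.

    The back plane is the front plane translated along the stack normal by
    ``plane_spacing``.  The stack axis makes ``angle_to_beam`` degrees with
    the +Z beam axis, tilted in the Z-Y plane, with the front-plane center
    ``distance_from_isocenter`` mm from the origin.
    """

    front: DetectorPlane
    back: DetectorPlane
    plane_spacing: float = 50.0
    angle_to_beam: float = 30.0
    distance_from_isocenter: float = 140.0

    def __post_init__(self):
        expected = self.front.center.array + self.plane_spacing * _as_vec(self.front.normal)
        if np.max(np.abs(expected - self.back.center.array)) > 1e-6:
            raise ValueError("back plane must be front plane shifted by plane_spacing")

    @property
    def axis(self) -> np.ndarray:
        return _as_vec(self.front.normal)


def make_stack(
    angle_to_beam: float = 30.0,
    distance_from_isocenter: float = 140.0,
    plane_spacing: float = 50.0,
    half_width: float = 25.0,
    half_height: float = 25.0,
    pixel_pitch: float = 0.055,
    side: int = +1,
) -> StackGeometry:
    """Construct a stack tilted by ``angle_to_beam`` degrees in the Z-Y plane.

    ``side=+1`` places the stack on the +Y side of the beam axis, ``-1``
    mirrors it (the dual-stack configuration uses one of each).
    """
    th = math.radians(angle_to_beam)
    axis = np.array([0.0, side * math.sin(th), math.cos(th)])
    # u along lab X, v completes the right-handed in-plane basis
    u = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, u)
    planes = []
    for dist in (distance_from_isocenter, distance_from_isocenter + plane_spacing):
        planes.append(
            DetectorPlane(
                center=Point3.from_array(dist * axis),
                normal=tuple(axis),
                axis_u=tuple(u),
                axis_v=tuple(v),
                half_width=half_width,
                half_height=half_height,
                pixel_pitch=pixel_pitch,
            )
        )
    return StackGeometry(
        front=planes[0],
        back=planes[1],
        plane_spacing=plane_spacing,
        angle_to_beam=angle_to_beam,
        distance_from_isocenter=distance_from_isocenter,
    )


def geometry_hash(stack: StackGeometry) -> str:
    """Short content hash of a stack geometry, for file provenance."""
    items = (
        stack.front.center.array.tolist(),
        list(stack.front.normal),
        stack.plane_spacing,
        stack.angle_to_beam,
        stack.front.half_width,
        stack.front.half_height,
        stack.front.pixel_pitch,
    )
    return hashlib.sha256(repr(items).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# PCA vertex solver


def point_of_closest_approach(
    frag: Line3, beam: Line3, parallel_tol: float = 1e-6, event_id: int = -1
) -> tuple[Vertex | None, str]:
    """Solve the two-line PCA by unregularized least squares.

    Returns ``(vertex, "ok")`` or ``(None, "degenerate")`` when the lines are
    parallel within ``parallel_tol`` (|d_frag . d_beam| > 1 - parallel_tol):
    the normal matrix is then singular and no unique PCA exists.
    """
    d1, d2 = frag.d, beam.d
    if abs(float(d1 @ d2)) > 1.0 - parallel_tol:
        return None, "degenerate"
    eye = np.eye(3)
    m1 = eye - np.outer(d1, d1)
    m2 = eye - np.outer(d2, d2)
    p = np.linalg.solve(m1 + m2, m1 @ frag.a + m2 @ beam.a)
    miss = 0.5 * (frag.distance_to(p) + beam.distance_to(p))  # equal by construction
    return Vertex(Point3.from_array(p), float(miss), event_id), "ok"


def pca_batch(
    a1: np.ndarray,
    d1: np.ndarray,
    a2: np.ndarray,
    d2: np.ndarray,
    parallel_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized PCA for N line pairs.

    Parameters are (N,3) arrays of anchors and unit directions.  Returns
    ``(points, miss, ok)`` where ``points`` is (N,3), ``miss`` the per-pair
    miss distance and ``ok`` a boolean mask (False for near-parallel pairs,
    whose point/miss entries are NaN).
    """
    a1, d1, a2, d2 = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (a1, d1, a2, d2))
    n = a1.shape[0]
    ok = np.abs(np.einsum("ij,ij->i", d1, d2)) <= 1.0 - parallel_tol
    eye = np.eye(3)
    m1 = eye - np.einsum("ni,nj->nij", d1, d1)
    m2 = eye - np.einsum("ni,nj->nij", d2, d2)
    rhs = np.einsum("nij,nj->ni", m1, a1) + np.einsum("nij,nj->ni", m2, a2)
    pts = np.full((n, 3), np.nan)
    if ok.any():
        pts[ok] = np.linalg.solve((m1 + m2)[ok], rhs[ok][..., None])[..., 0]
    r1 = pts - a1
    perp1 = r1 - np.einsum("ni,ni->n", r1, d1)[:, None] * d1
    miss = np.linalg.norm(perp1, axis=1)
    miss[~ok] = np.nan
    return pts, miss, ok


# ---------------------------------------------------------------------------
# Plane intersection and pixelation


def project_to_plane(line: Line3, plane: DetectorPlane) -> tuple[float, float, bool]:
    """Intersect a line with a sensor plane; return in-plane (u, v) and a hit flag.

    Raises ``ValueError`` when the line is parallel to the plane
    (|direction . normal| <= 1e-9; no intersection exists).
    """
    nvec = _as_vec(plane.normal)
    denom = float(line.d @ nvec)
    if abs(denom) <= 1e-9:
        raise ValueError("line is parallel to the detector plane")
    t = float((plane.center.array - line.a) @ nvec) / denom
    p = line.point_at(t)
    rel = p - plane.center.array
    u = float(rel @ _as_vec(plane.axis_u))
    v = float(rel @ _as_vec(plane.axis_v))
    hit = abs(u) <= plane.half_width and abs(v) <= plane.half_height
    return u, v, hit


def intersect_plane_batch(
    anchors: np.ndarray, dirs: np.ndarray, plane: DetectorPlane, forward_only: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized plane intersection: (u, v, hit) arrays for N rays."""
    nvec = _as_vec(plane.normal)
    denom = dirs @ nvec
    safe = np.abs(denom) > 1e-9
    t = np.where(safe, ((plane.center.array - anchors) @ nvec) / np.where(safe, denom, 1.0), np.nan)
    p = anchors + t[:, None] * dirs
    rel = p - plane.center.array
    u = rel @ _as_vec(plane.axis_u)
    v = rel @ _as_vec(plane.axis_v)
    hit = (
        safe
        & (np.abs(u) <= plane.half_width)
        & (np.abs(v) <= plane.half_height)
    )
    if forward_only:
        hit &= t > 0
    return u, v, hit


def pixelate(u, v, plane: DetectorPlane):
    """Quantize in-plane (u, v) mm onto the pixel grid.

    The grid is 0-based with half-open bins: index 0 covers
    [-half_width, -half_width + pitch).  Returns ``(iu, iv, uc, vc)`` with the
    pixel-center coordinates ``(uc, vc)``.  Out-of-area input raises.
    Vectorized over array input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(u) > plane.half_width) or np.any(np.abs(v) > plane.half_height):
        raise ValueError("(u, v) outside the active area")
    pitch = plane.pixel_pitch
    iu = np.clip(np.floor((u + plane.half_width) / pitch).astype(np.int64), 0, plane.n_u - 1)
    iv = np.clip(np.floor((v + plane.half_height) / pitch).astype(np.int64), 0, plane.n_v - 1)
    uc, vc = pixel_center(iu, iv, plane)
    if u.ndim == 0:
        return int(iu), int(iv), float(uc), float(vc)
    return iu, iv, uc, vc


def pixel_center(iu, iv, plane: DetectorPlane):
    """In-plane coordinates of pixel centers (exact inverse of ``pixelate``)."""
    pitch = plane.pixel_pitch
    uc = -plane.half_width + (np.asarray(iu) + 0.5) * pitch
    vc = -plane.half_height + (np.asarray(iv) + 0.5) * pitch
    return uc, vc
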