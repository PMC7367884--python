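"""Section-plane frames and plane–box intersection geometry.

A virtual section is a plane ``A·x + B·y + C·z + D = 0`` (μm coordinates in
the specimen frame).  Two orthonormal in-plane frames are attached to it:

* ``(ξ, η)`` with the constraint ``ξ_y = 0``:
  ``ξ = {C, 0, −A} / √(A²+C²)``, ``η = (ξ × n)/|ξ × n|``.
* ``(p, q)`` with the constraint ``p_z = 0`` — the rendering frame, chosen
  so that scanning the section row by row walks the image stack layer by
  layer, which keeps disk access sequential:
  ``p = {−B, A, 0} / √(A²+B²)``,
  ``q = {−AC, −BC, A²+B²} / √(A²C² + B²C² + (A²+B²)²)  ≡ (n × p)/|n × p|``.

``(p, q, n̂)`` is right-handed.  Degenerate orientations fall back to fixed
axes: planes with normal along y use ``ξ = e_x``; horizontal planes (normal
along z) use ``p = e_x`` and ``q = n̂ × p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SectionPlane",
    "SectionBasis",
    "section_basis",
    "plane_box_polygon",
    "polygon_area",
    "world_to_section",
    "section_to_world",
]

#: relative tolerance below which √(A²+C²) or √(A²+B²) counts as degenerate
DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class SectionPlane:
    """Plane coefficients ``(A, B, C, D)`` with a nonzero normal."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        coeffs = (self.a, self.b, self.c, self.d)
        if not all(math.isfinite(v) for v in coeffs):
            raise ValueError(f"plane coefficients must be finite, got {coeffs}")
        if self.a == 0.0 and self.b == 0.0 and self.c == 0.0:
            raise ValueError("invalid plane: normal vector (A, B, C) is zero")

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def unit_normal(self) -> np.ndarray:
        n = self.normal
        return n / np.linalg.norm(n)

    @classmethod
    def from_point_normal(cls, point, normal) -> "SectionPlane":
        point = np.asarray(point, dtype=float)
        normal = np.asarray(normal, dtype=float)
        return cls(normal[0], normal[1], normal[2], -float(normal @ point))

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        val = (pts @ self.normal + self.d) / np.linalg.norm(self.normal)
        return val[0] if np.ndim(points) == 1 else val


@dataclass(frozen=True)
class SectionBasis:
    """Unit normal, the (ξ, η) frame, the rendering frame (p, q) and an
    on-plane origin anchoring (u, v) section coordinates."""

    n_hat: np.ndarray
    xi: np.ndarray
    eta: np.ndarray
    p: np.ndarray
    q: np.ndarray
    origin: np.ndarray

    def with_origin(self, origin) -> "SectionBasis":
        return replace(self, origin=np.asarray(origin, dtype=float))

    def world_to_section(self, points) -> np.ndarray:
        """Project world points into (u, v) = ((x−o)·p, (x−o)·q) μm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        uv = np.stack([pts @ self.p, pts @ self.q], axis=-1)
        return uv[0] if np.ndim(points) == 1 else uv

    def section_to_world(self, u, v) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        pts = (self.origin[None, :]
               + np.atleast_1d(u)[:, None] * self.p
               + np.atleast_1d(v)[:, None] * self.q)
        return pts[0] if u.ndim == 0 else pts


def section_basis(plane: SectionPlane, origin=None) -> SectionBasis:
    """Construct the orthonormal section frames from plane coefficients.

    Closed forms as documented in the module docstring; both frames are
    invariant under positive rescaling of ``(A, B, C, D)``.  The default
    origin is the plane point closest to the world origin.
    """
    n = plane.normal
    nn = np.linalg.norm(n)
    n_hat = n / nn
    a, b, c = n

    # (xi, eta): xi_y = 0, xi ⟂ n  =>  A·xi_x + C·xi_z = 0
    ac = math.hypot(a, c)
    if ac <= DEGENERACY_RTOL * nn:
        xi = np.array([1.0, 0.0, 0.0])
    else:
        xi = np.array([c, 0.0, -a]) / ac
    eta = np.cross(xi, n)
    eta = eta / np.linalg.norm(eta)

    # (p, q): p_z = 0, p ⟂ n  =>  A·p_x + B·p_y = 0;  q = (n × p)/|n × p|
    ab = math.hypot(a, b)
    if ab <= DEGENERACY_RTOL * nn:
        p = np.array([1.0, 0.0, 0.0])
        q = np.cross(n_hat, p)
        q = q / np.linalg.norm(q)
    else:
        p = np.array([-b, a, 0.0]) / ab
        m_q = math.sqrt(a * a * c * c + b * b * c * c + (a * a + b * b) ** 2)
        q = np.array([-a * c, -b * c, a * a + b * b]) / m_q

    if origin is None:
        origin = -plane.d * n / (nn * nn)
    return SectionBasis(n_hat=n_hat, xi=xi, eta=eta, p=p, q=q,
                        origin=np.asarray(origin, dtype=float))


def world_to_section(basis: SectionBasis, points) -> np.ndarray:
    return basis.world_to_section(points)


def section_to_world(basis: SectionBasis, u, v) -> np.ndarray:
    return basis.section_to_world(u, v)


_BOX_EDGES = (
    (0, 1), (0, 2), (0, 4), (1, 3), (1, 5), (2, 3),
    (2, 6), (3, 7), (4, 5), (4, 6), (5, 7), (6, 7),
)


def _box_corners(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # corner index bit i selects hi along axis i
    corners = np.empty((8, 3))
    for idx in range(8):
        for ax in range(3):
            corners[idx, ax] = hi[ax] if (idx >> ax) & 1 else lo[ax]
    return corners


def plane_box_polygon(plane: SectionPlane, box_max, box_min=(0.0, 0.0, 0.0)
                      ) -> np.ndarray:
    """Intersection polygon of a plane with an axis-aligned box.

    ``box_min``/``box_max`` are the box corners in μm.  Returns a ``(V, 3)``
    vertex array (3–6 vertices for a proper intersection) ordered
    counter-clockwise when viewed from the +n̂ side, or an empty ``(0, 3)``
    array when the plane misses the box (or only grazes a corner/edge).
    """
    lo = np.asarray(box_min, dtype=float)
    hi = np.asarray(box_max, dtype=float)
    if np.any(hi <= lo):
        raise ValueError(f"box extents must be positive, got {lo} .. {hi}")
    corners = _box_corners(lo, hi)
    n = plane.normal
    f = corners @ n + plane.d
    scale = float(np.max(hi - lo))
    ftol = 1e-12 * np.linalg.norm(n) * max(scale, 1.0)

    pts = []
    for i0, i1 in _BOX_EDGES:
        f0, f1 = f[i0], f[i1]
        if abs(f1 - f0) <= ftol:
            if abs(f0) <= ftol:  # edge lies in the plane
                pts.append(corners[i0])
                pts.append(corners[i1])
            continue
        t = f0 / (f0 - f1)
        if -1e-12 <= t <= 1 + 1e-12:
            pts.append(corners[i0] + np.clip(t, 0.0, 1.0) * (corners[i1] - corners[i0]))
    if not pts:
        return np.empty((0, 3))

    # dedupe
    merged: list[np.ndarray] = []
    mtol = 1e-9 * max(scale, 1.0)
    for pt in pts:
        if not any(np.linalg.norm(pt - m) <= mtol for m in merged):
            merged.append(pt)
    if len(merged) < 3:
        return np.empty((0, 3))

    verts = np.array(merged)
    basis = section_basis(plane)
    n_hat = basis.n_hat
    u1 = basis.xi
    u2 = np.cross(n_hat, u1)
    center = verts.mean(axis=0)
    rel = verts - center
    ang = np.arctan2(rel @ u2, rel @ u1)
    verts = verts[np.argsort(ang)]
    if polygon_area(verts) <= mtol * mtol:
        return np.empty((0, 3))
    return verts


def polygon_area(vertices) -> float:
    """Area of a planar 3D polygon (vertices in order)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    acc = np.zeros(3)
    for i in range(1, len(v) - 1):
        acc += np.cross(v[i] - v[0], v[i + 1] - v[0])
    return 0.5 * float(np.linalg.norm(acc))
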