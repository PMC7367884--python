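"""Rasterize arbitrary plane sections of a color volume (multiplanar
reconstruction).

A section image is laid out in the plane's rendering frame ``(p, q)``:
columns run along ``p`` (coordinate ``u``), rows along ``q`` (coordinate
``v``, increasing downward in the saved image).  Pixel ``(r, c)`` has its
center at ``(u, v) = ((c + 0.5)·pitch, (r + 0.5)·pitch)`` measured from the
section origin, which is placed at the minimum corner of the (u, v)
bounding rectangle of the plane–box intersection polygon so all section
coordinates are non-negative.

When the requested plane coincides with a source layer plane (axis-aligned,
|z − Z_k| < 1e-9) and the section pitch equals the volume pitch, sampling
snaps to the source grid nodes, so such sections reproduce the stored layer
bit-exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import SectionBasis, SectionPlane, plane_box_polygon, section_basis
from .volume import RasterVolume

__all__ = ["SliceImage", "render_section", "slice_series", "save_slice"]

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class SliceImage:
    """A rendered plane section with its world georeferencing.

    ``mask`` marks pixels inside both the section polygon and the volume
    box; ``in_polygon`` additionally distinguishes pixels that are inside
    the polygon but outside the volume.
    """

    pixels: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray            # (H, W) bool: in polygon and in volume
    in_polygon: np.ndarray      # (H, W) bool
    basis: SectionBasis
    plane: SectionPlane
    pitch_um: float

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.pixels.size == 0

    def pixel_centers_world(self) -> np.ndarray:
        """World coordinates of every pixel center, shape (H, W, 3)."""
        h, w = self.pixels.shape[:2]
        u = (np.arange(w) + 0.5) * self.pitch_um
        v = (np.arange(h) + 0.5) * self.pitch_um
        uu, vv = np.meshgrid(u, v)
        return (self.basis.origin
                + uu[..., None] * self.basis.p
                + vv[..., None] * self.basis.q)

    def pixel_to_world(self, r: int, c: int) -> np.ndarray:
        return self.basis.section_to_world((c + 0.5) * self.pitch_um,
                                           (r + 0.5) * self.pitch_um)


def _layer_plane_index(volume: RasterVolume, plane: SectionPlane) -> int | None:
    """1-based k if the plane is an axis-aligned layer plane z = Z_k with
    positive orientation, else None."""
    a, b, c = plane.a, plane.b, plane.c
    nn = math.sqrt(a * a + b * b + c * c)
    if abs(a) > 1e-12 * nn or abs(b) > 1e-12 * nn or c <= 0:
        return None
    z_off = -plane.d / c
    k = round(z_off / volume.step_um) + 1
    if 1 <= k <= volume.n_layers and abs(z_off - (k - 1) * volume.step_um) < 1e-9:
        return k
    return None


def render_section(volume: RasterVolume, plane: SectionPlane,
                   pitch_um: float | None = None,
                   mode: str = "trilinear") -> SliceImage:
    """Render the cross-section of ``volume`` along ``plane``.

    ``pitch_um`` defaults to the volume's in-plane pitch (no resolution is
    invented beyond the data).  Pixels outside the section polygon or the
    volume box get the volume's ``fill_color`` and a False mask.  A plane
    that misses the volume yields an empty (0×0) image with a warning, not
    an exception.
    """
    if pitch_um is None:
        pitch_um = volume.pitch_um
    if not pitch_um > 0:
        raise ValueError(f"pitch_um must be > 0, got {pitch_um}")
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown sampling mode {mode!r}")

    # exactness fast path: layer planes reproduce stored layers bit-exactly
    k = _layer_plane_index(volume, plane)
    if k is not None and math.isclose(pitch_um, volume.pitch_um, rel_tol=1e-12):
        img = np.array(volume.layer(k), copy=True)
        h, w = img.shape[:2]
        basis = section_basis(plane, origin=(0.0, 0.0, volume.layer_z(k)))
        ones = np.ones((h, w), dtype=bool)
        return SliceImage(pixels=img, mask=ones, in_polygon=ones.copy(),
                          basis=basis, plane=plane, pitch_um=volume.pitch_um)

    poly = plane_box_polygon(plane, volume.extent_um)
    if len(poly) == 0:
        warnings.warn("section plane misses the volume; returning an empty slice")
        basis = section_basis(plane)
        return SliceImage(
            pixels=np.empty((0, 0, 3), dtype=np.uint8),
            mask=np.empty((0, 0), dtype=bool),
            in_polygon=np.empty((0, 0), dtype=bool),
            basis=basis, plane=plane, pitch_um=float(pitch_um),
        )

    basis0 = section_basis(plane)
    uv = basis0.world_to_section(poly)
    umin, vmin = uv.min(axis=0)
    umax, vmax = uv.max(axis=0)
    origin = basis0.section_to_world(umin, vmin)
    basis = basis0.with_origin(origin)
    w = max(1, math.ceil((umax - umin) / pitch_um - 1e-9))
    h = max(1, math.ceil((vmax - vmin) / pitch_um - 1e-9))

    u = (np.arange(w) + 0.5) * pitch_um
    v = (np.arange(h) + 0.5) * pitch_um
    uu, vv = np.meshgrid(u, v)

    poly_uv = basis.world_to_section(poly)
    in_poly = np.ones((h, w), dtype=bool)
    tol = 1e-9 * max(umax - umin, vmax - vmin, 1.0)
    nv = len(poly_uv)
    for e in range(nv):
        a0 = poly_uv[e]
        a1 = poly_uv[(e + 1) % nv]
        cross = (a1[0] - a0[0]) * (vv - a0[1]) - (a1[1] - a0[1]) * (uu - a0[0])
        in_poly &= cross >= -tol

    world = (basis.origin
             + uu[..., None] * basis.p
             + vv[..., None] * basis.q).reshape(-1, 3)
    in_vol = volume.contains(world).reshape(h, w)
    mask = in_poly & in_vol

    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:] = np.asarray(volume.fill_color, dtype=np.uint8)
    flat = mask.ravel()
    if flat.any():
        pixels.reshape(-1, 3)[flat] = volume.sample_color(world[flat], mode=mode)
    return SliceImage(pixels=pixels, mask=mask, in_polygon=in_poly,
                      basis=basis, plane=plane, pitch_um=float(pitch_um))


def slice_series(volume: RasterVolume, normal="z", count: int = 1,
                 pitch_um: float | None = None,
                 mode: str = "trilinear") -> list[SliceImage]:
    """Render ``count`` evenly spaced parallel sections spanning the volume.

    ``normal`` is an axis name (``"x"``, ``"y"``, ``"z"``) or a 3-vector;
    sections are ordered by increasing signed offset along the unit normal.
    ``count=1`` yields the single mid-volume section.  With ``normal="z"``
    and ``count`` equal to the layer count, the sections are exactly the
    source layer planes.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if isinstance(normal, str):
        try:
            n = _AXES[normal]
        except KeyError:
            raise ValueError(f"unknown axis {normal!r}") from None
    else:
        n = np.asarray(normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("normal vector must be nonzero")
        n = n / nn
    lo_c = np.zeros(3)
    hi_c = np.asarray(volume.extent_um)
    corners = np.array([[hi_c[0] * ((i >> 0) & 1), hi_c[1] * ((i >> 1) & 1),
                         hi_c[2] * ((i >> 2) & 1)] for i in range(8)])
    proj = corners @ n
    lo, hi = proj.min(), proj.max()
    if count == 1:
        offsets = np.array([(lo + hi) / 2.0])
    else:
        offsets = np.linspace(lo, hi, count)
    out = []
    for off in offsets:
        plane = SectionPlane(n[0], n[1], n[2], -float(off))
        out.append(render_section(volume, plane, pitch_um=pitch_um, mode=mode))
    return out


def save_slice(slc: SliceImage, path, with_sidecar: bool = True) -> Path:
    """Save a section as PNG/TIFF plus a JSON sidecar carrying the plane,
    frame vectors, origin and pitch — enough to re-derive the world
    coordinates of any pixel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = slc.pixels if not slc.is_empty else np.zeros((1, 1, 3), np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img, photometric="rgb")
    else:
        from PIL import Image

        Image.fromarray(img, mode="RGB").save(path)
    if with_sidecar:
        sidecar = {
            "plane": [slc.plane.a, slc.plane.b, slc.plane.c, slc.plane.d],
            "n_hat": slc.basis.n_hat.tolist(),
            "xi": slc.basis.xi.tolist(),
            "eta": slc.basis.eta.tolist(),
            "p": slc.basis.p.tolist(),
            "q": slc.basis.q.tolist(),
            "origin_um": slc.basis.origin.tolist(),
            "pitch_um": slc.pitch_um,
            "height": slc.height,
            "width": slc.width,
            "empty": bool(slc.is_empty),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path
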