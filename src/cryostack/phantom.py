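"""Synthetic image stacks with known ground truth.

The phantoms emulate what the milling camera sees: an opaque specimen
embedded in a uniform-color cryo-medium, photographed layer by layer.  Each
layer is the analytic cross-section of a solid at ``z = (k − 1)·Δz``,
rasterized with a center-in-shape rule (a pixel is specimen iff its center
lies inside the shape — no partial coverage, so pixel counts are exactly
predictable), optionally translated by logged integer camera jitter and
corrupted by clipped additive Gaussian noise.  All randomness flows from a
single seeded NumPy ``default_rng`` (PCG64), so identical spec + seed give
bit-identical stacks.

Default acquisition parameters mirror the real rig scaled to test size:
Δz = 10 μm step, 8 μm pixel pitch, 256×256 canvas.

Shapes
------
``sphere(radius_um)``
    Ball centered on a grid node; closed surface (boundary pixels count as
    specimen), so a sphere of radius R spans exactly 2R/Δz + 1 non-empty
    layers when R is a multiple of Δz.
``slab`` / ``cartilage(thickness_um, roughness…)``
    An extruded plate: specimen where
    ``y_out(x) ≤ y < y_out(x) + thickness`` with
    ``y_out(x) = y0 + a·sin(2π x / λ)``.  The thickness interval is
    half-open, which makes the traced boundary pair recover the stated
    thickness without rasterization bias.
``two_shell(r_outer_um, r_inner_um)``
    Spherical shell; its equatorial section is an annulus of radial
    thickness ``r_outer − r_inner``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate, optimize

from .volume import ArrayLayerLoader, RasterVolume, _round_half_up

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_cartilage_phantom",
    "sinusoid_surface_factor",
]

_SHAPES = ("sphere", "slab", "cartilage", "two_shell")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic specimen stack."""

    shape: str = "sphere"
    shape_params: dict = field(default_factory=dict)
    specimen_color: tuple[int, int, int] = (150, 80, 60)
    medium_color: tuple[int, int, int] = (200, 200, 210)
    pitch_um: float = 8.0
    step_um: float = 10.0
    canvas: tuple[int, int] = (256, 256)   # (P_x, P_y) = (width, height) px
    n_layers: int | None = None            # default: shape z-span + 1 margin layer each side
    jitter_px: int = 0
    noise_sigma: float = 0.0
    texture_amplitude: int = 0
    texture_scale_px: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        if not (self.pitch_um > 0 and self.step_um > 0):
            raise ValueError("pitch_um and step_um must be > 0")
        if self.canvas[0] < 2 or self.canvas[1] < 2:
            raise ValueError(f"canvas too small: {self.canvas}")
        if self.jitter_px < 0 or self.noise_sigma < 0:
            raise ValueError("jitter_px and noise_sigma must be >= 0")
        for color in (self.specimen_color, self.medium_color):
            if not all(0 <= c <= 255 for c in color):
                raise ValueError(f"color out of range: {color}")


@dataclass
class PhantomTruth:
    """Everything injected into a phantom, for test oracles."""

    spec: PhantomSpec
    params: dict                      # resolved analytic geometry (μm)
    shifts_px: np.ndarray             # (M, 2) injected (dx, dy) per layer
    masks: np.ndarray                 # (M, H, W) bool, jitter included

    def to_json(self) -> str:
        payload = {
            "shape": self.spec.shape,
            "params": self.params,
            "shifts_px": self.shifts_px.tolist(),
            "pitch_um": self.spec.pitch_um,
            "step_um": self.spec.step_um,
            "seed": self.spec.seed,
        }
        return json.dumps(payload, indent=2)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _resolve_geometry(spec: PhantomSpec) -> tuple[dict, int]:
    """Fill in shape parameters (μm) and the layer count."""
    w, h = spec.canvas
    pitch, step = spec.pitch_um, spec.step_um
    params = dict(spec.shape_params)

    if spec.shape == "sphere":
        r = float(params.get("radius_um", 100.0))
        if 2 * r >= min(w - 1, h - 1) * pitch:
            raise ValueError(f"sphere radius {r} um exceeds the canvas")
        n_shape = int(math.floor(2 * r / step)) + 1
        m = spec.n_layers or n_shape + 2
        cx = (w // 2) * pitch
        cy = (h // 2) * pitch
        kc = min(1 + int(math.ceil(r / step)), m - 1)
        cz = kc * step
        params.update(radius_um=r, center_um=[cx, cy, cz])
    elif spec.shape in ("slab", "cartilage"):
        t = float(params.get("thickness_um", 232.0))
        amp = float(params.get("roughness_amplitude_um", 0.0))
        lam = float(params.get("roughness_wavelength_um", 400.0))
        y0 = float(params.get("y_outer_um", ((h * pitch) - t) / 2.0))
        x0 = float(params.get("x_min_um", 2 * pitch))
        x1 = float(params.get("x_max_um", (w - 3) * pitch))
        if t < 2 * pitch:
            raise ValueError(f"thickness {t} um must be >= 2 pixels ({2 * pitch} um)")
        if y0 - amp < 0 or y0 + t + amp > (h - 1) * pitch:
            raise ValueError("slab does not fit the canvas vertically")
        m = spec.n_layers or 4
        params.update(thickness_um=t, roughness_amplitude_um=amp,
                      roughness_wavelength_um=lam, y_outer_um=y0,
                      x_min_um=x0, x_max_um=x1)
    elif spec.shape == "two_shell":
        r_out = float(params.get("r_outer_um", 300.0))
        r_in = float(params.get("r_inner_um", 100.0))
        if not 0 < r_in < r_out:
            raise ValueError(f"need 0 < r_inner < r_outer, got {r_in}, {r_out}")
        if 2 * r_out >= min(w - 1, h - 1) * pitch:
            raise ValueError(f"shell radius {r_out} um exceeds the canvas")
        n_shape = int(math.floor(2 * r_out / step)) + 1
        m = spec.n_layers or n_shape + 2
        cx = (w // 2) * pitch
        cy = (h // 2) * pitch
        kc = min(1 + int(math.ceil(r_out / step)), m - 1)
        cz = kc * step
        params.update(r_outer_um=r_out, r_inner_um=r_in, center_um=[cx, cy, cz])
    else:  # pragma: no cover
        raise AssertionError(spec.shape)
    return params, int(m)


def _layer_mask(spec: PhantomSpec, params: dict, z: float) -> np.ndarray:
    """Analytic cross-section at height z, rasterized center-in-shape."""
    w, h = spec.canvas
    x = np.arange(w) * spec.pitch_um
    y = np.arange(h) * spec.pitch_um
    xx, yy = np.meshgrid(x, y)
    if spec.shape == "sphere":
        cx, cy, cz = params["center_um"]
        r2 = params["radius_um"] ** 2 - (z - cz) ** 2
        if r2 < 0:
            return np.zeros((h, w), dtype=bool)
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r2
    if spec.shape in ("slab", "cartilage"):
        amp = params["roughness_amplitude_um"]
        lam = params["roughness_wavelength_um"]
        y_out = params["y_outer_um"] + (
            amp * np.sin(2 * np.pi * xx / lam) if amp else 0.0
        )
        inside = (yy >= y_out) & (yy < y_out + params["thickness_um"])
        inside &= (xx >= params["x_min_um"]) & (xx <= params["x_max_um"])
        return inside
    if spec.shape == "two_shell":
        cx, cy, cz = params["center_um"]
        ro2 = params["r_outer_um"] ** 2 - (z - cz) ** 2
        ri2 = params["r_inner_um"] ** 2 - (z - cz) ** 2
        if ro2 < 0:
            return np.zeros((h, w), dtype=bool)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        inside = d2 <= ro2
        if ri2 > 0:
            inside &= d2 > ri2
        return inside
    raise AssertionError(spec.shape)  # pragma: no cover


def _texture_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth integer brightness modulation shared by all layers (an
    extruded scene texture, so adjacent layers correlate for registration)."""
    w, h = spec.canvas
    amp = spec.texture_amplitude
    if amp <= 0:
        return np.zeros((h, w), dtype=np.int16)
    scale = max(2, spec.texture_scale_px)
    gh = h // scale + 2
    gw = w // scale + 2
    coarse = rng.integers(-amp, amp + 1, size=(gh, gw)).astype(float)
    yi = np.arange(h) / scale
    xi = np.arange(w) / scale
    y0 = yi.astype(int)
    x0 = xi.astype(int)
    ty = (yi - y0)[:, None]
    tx = (xi - x0)[None, :]
    f = ((1 - ty) * (1 - tx) * coarse[np.ix_(y0, x0)]
         + (1 - ty) * tx * coarse[np.ix_(y0, x0 + 1)]
         + ty * (1 - tx) * coarse[np.ix_(y0 + 1, x0)]
         + ty * tx * coarse[np.ix_(y0 + 1, x0 + 1)])
    return _round_half_up(f).astype(np.int16)


def _shift2d(arr: np.ndarray, dx: int, dy: int, fill) -> np.ndarray:
    out = np.empty_like(arr)
    out[...] = fill
    h, w = arr.shape[:2]
    ys0, ys1 = max(dy, 0), h + min(dy, 0)
    xs0, xs1 = max(dx, 0), w + min(dx, 0)
    if ys1 > ys0 and xs1 > xs0:
        out[ys0:ys1, xs0:xs1] = arr[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def make_phantom(spec: PhantomSpec) -> tuple[RasterVolume, PhantomTruth]:
    """Generate the stack and its ground truth.

    Draw order from the seeded generator: texture field, per-layer jitter
    (layer 1 pinned to (0, 0)), then per-layer noise — fixed so outputs are
    reproducible bit-for-bit.  Compositing is integer-valued before noise.
    """
    params, m = _resolve_geometry(spec)
    w, h = spec.canvas
    rng = np.random.default_rng(spec.seed)
    texture = _texture_field(spec, rng)
    if spec.jitter_px > 0:
        shifts = rng.integers(-spec.jitter_px, spec.jitter_px + 1, size=(m, 2))
        shifts[0] = 0
    else:
        shifts = np.zeros((m, 2), dtype=int)

    medium = np.asarray(spec.medium_color, dtype=np.int16)
    color = np.asarray(spec.specimen_color, dtype=np.int16)
    layers = np.empty((m, h, w, 3), dtype=np.uint8)
    masks = np.empty((m, h, w), dtype=bool)
    for k0 in range(m):
        z = k0 * spec.step_um
        inside = _layer_mask(spec, params, z)
        img = np.empty((h, w, 3), dtype=np.int16)
        img[...] = medium
        if inside.any():
            tex = np.clip(color[None, :] + texture[inside][:, None], 0, 255)
            img[inside] = tex
        dx, dy = int(shifts[k0, 0]), int(shifts[k0, 1])
        if dx or dy:
            img = _shift2d(img, dx, dy, medium)
            inside = _shift2d(inside, dx, dy, False)
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, size=img.shape)
            img = _round_half_up(img + noise).astype(np.int64)
        layers[k0] = np.clip(img, 0, 255).astype(np.uint8)
        masks[k0] = inside
    volume = RasterVolume(ArrayLayerLoader(layers), spec.step_um, spec.pitch_um,
                          fill_color=spec.medium_color)
    truth = PhantomTruth(spec=spec, params=params, shifts_px=shifts.astype(int),
                         masks=masks)
    return volume, truth


def make_cartilage_phantom(thickness_um: float = 232.0,
                           roughness_amplitude_um: float = 0.0,
                           roughness_wavelength_um: float = 800.0,
                           spec: PhantomSpec | None = None
                           ) -> tuple[RasterVolume, PhantomTruth]:
    """Curved-slab phantom for the cartilage measurements.

    A plate of the stated normal thickness (default 232 μm) with a
    sinusoidally rough outer border ``y = y0 + a·sin(2πx/λ)``.  The truth
    object's params retain (a, λ), so the analytic surface factor of the
    border is available via :func:`sinusoid_surface_factor`.
    """
    base = spec or PhantomSpec()
    merged = dict(base.shape_params)
    merged.update(
        thickness_um=float(thickness_um),
        roughness_amplitude_um=float(roughness_amplitude_um),
        roughness_wavelength_um=float(roughness_wavelength_um),
    )
    cart = PhantomSpec(
        shape="cartilage", shape_params=merged,
        specimen_color=base.specimen_color, medium_color=base.medium_color,
        pitch_um=base.pitch_um, step_um=base.step_um, canvas=base.canvas,
        n_layers=base.n_layers, jitter_px=base.jitter_px,
        noise_sigma=base.noise_sigma, texture_amplitude=base.texture_amplitude,
        texture_scale_px=base.texture_scale_px, seed=base.seed,
    )
    return make_phantom(cart)


def sinusoid_surface_factor(amplitude_um: float, wavelength_um: float,
                            spacing_um: float = 100.0,
                            x_range_um: tuple[float, float] = (0.0, 2000.0)
                            ) -> float:
    """Mean arc/chord factor of ``y = a·sin(2πx/λ)`` by numerical
    quadrature, for chord-spaced reference points.

    Independent of the polyline-walking measurement: reference points are
    found by root-solving the chord-distance equation on the continuous
    curve and arcs by adaptive quadrature of ``√(1 + y'²)``.
    """
    a = float(amplitude_um)
    k = 2.0 * math.pi / float(wavelength_um)

    def arc(x0: float, x1: float) -> float:
        val, _ = integrate.quad(lambda x: math.sqrt(1 + (a * k * math.cos(k * x)) ** 2),
                                x0, x1, limit=200)
        return val

    def chord(x0: float, x1: float) -> float:
        return math.hypot(x1 - x0, a * math.sin(k * x1) - a * math.sin(k * x0))

    factors = []
    x = x_range_um[0]
    while True:
        f = lambda x1: chord(x, x1) - spacing_um  # noqa: E731
        lo, hi = x + spacing_um / 4.0, x + 2.0 * spacing_um
        if hi > x_range_um[1]:
            break
        while f(hi) < 0:
            hi += spacing_um
            if hi > x_range_um[1]:
                return float(np.mean(factors))
        x1 = optimize.brentq(f, lo, hi)
        factors.append(arc(x, x1) / spacing_um)
        x = x1
    if not factors:
        raise ValueError("x_range too short for the requested spacing")
    return float(np.mean(factors))
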