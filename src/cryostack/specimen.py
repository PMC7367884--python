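"""Embedding-medium removal and inter-layer alignment.

The specimen sits in a near-uniform cryo-embedding compound; segmentation
thresholds the Euclidean RGB distance to a reference medium color, followed
by optional morphological cleanup.  Accidental camera motion between
milling passes shows up as small per-layer translations; alignment
estimates them by maximizing normalized cross-correlation over an integer
shift window (pure 2D translation — the camera is fixed, so rotation and
scale are excluded) and chains each layer to its already-aligned
predecessor.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, morphology

from .volume import ArrayLayerLoader, RasterVolume, _round_half_up

__all__ = [
    "SpecimenMask",
    "ShiftLog",
    "estimate_medium_color",
    "specimen_mask",
    "remove_medium",
    "estimate_shift",
    "align_stack",
]

DEFAULT_THRESHOLD = 30.0  # 8-bit RGB Euclidean distance


@dataclass
class SpecimenMask:
    """Per-layer binary masks separating specimen from medium, together
    with the parameters they were produced from (reproducible)."""

    masks: np.ndarray                # (M, H, W) bool
    medium_color: tuple[int, int, int]
    threshold: float
    min_area: int = 0
    keep_largest: bool = False

    @property
    def n_layers(self) -> int:
        return self.masks.shape[0]

    def layer(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_layers:
            raise IndexError(f"layer index k={k} out of range 1..{self.n_layers}")
        return self.masks[k - 1]


@dataclass
class ShiftLog:
    """Per-layer (dx, dy) translations (px) applied during alignment.

    The reference (first) layer's shift is (0, 0).  ``clamped[k]`` flags
    layers whose estimated shift exceeded the allowed maximum.
    """

    shifts: list[tuple[float, float]] = field(default_factory=list)
    clamped: list[bool] = field(default_factory=list)

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["k", "dx_px", "dy_px", "clamped"])
            for k0, ((dx, dy), cl) in enumerate(zip(self.shifts, self.clamped)):
                writer.writerow([k0 + 1, dx, dy, int(cl)])
        return path


def _luminance(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        return 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]
    return a


def estimate_medium_color(volume: RasterVolume, patch_px: int = 8
                          ) -> tuple[int, int, int]:
    """Robust medium-color estimate: per-channel median over the four
    corner patches of every layer.

    The specimen rarely reaches the image corners; taking the median across
    all 4·M patches tolerates a specimen touching some of them.
    """
    h, w = volume.layer_shape
    if h < patch_px or w < patch_px:
        raise ValueError(
            f"layers ({h}x{w}) smaller than the {patch_px}x{patch_px} corner patch"
        )
    samples = []
    for img in volume.layers():
        samples.append(img[:patch_px, :patch_px].reshape(-1, 3))
        samples.append(img[:patch_px, -patch_px:].reshape(-1, 3))
        samples.append(img[-patch_px:, :patch_px].reshape(-1, 3))
        samples.append(img[-patch_px:, -patch_px:].reshape(-1, 3))
    med = np.median(np.concatenate(samples, axis=0), axis=0)
    return tuple(int(v) for v in _round_half_up(med))


def specimen_mask(volume: RasterVolume, medium_color=None,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_area: int = 0, keep_largest: bool = False
                  ) -> SpecimenMask:
    """Mask the specimen: a pixel belongs to it iff its Euclidean RGB
    distance to ``medium_color`` exceeds ``threshold`` (strict), then
    per-layer cleanup removes components below ``min_area`` px and,
    optionally, everything but the largest component.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if medium_color is None:
        medium_color = estimate_medium_color(volume)
    ref = np.asarray(medium_color, dtype=float)
    masks = np.empty((volume.n_layers, *volume.layer_shape), dtype=bool)
    for k0, img in enumerate(volume.layers()):
        dist = np.sqrt(((img.astype(float) - ref) ** 2).sum(axis=-1))
        m = dist > threshold
        if min_area > 0:
            try:
                # removes components <= max_size (skimage >= 0.26 naming)
                m = morphology.remove_small_objects(m, max_size=min_area - 1)
            except TypeError:  # older scikit-image
                m = morphology.remove_small_objects(m, min_size=min_area)
        if keep_largest and m.any():
            labels = measure.label(m, connectivity=2)
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            m = labels == int(np.argmax(counts))
        masks[k0] = m
    return SpecimenMask(masks=masks, medium_color=tuple(int(v) for v in ref),
                        threshold=float(threshold), min_area=int(min_area),
                        keep_largest=bool(keep_largest))


def remove_medium(volume: RasterVolume, mask: SpecimenMask | np.ndarray,
                  fill_color=None) -> RasterVolume:
    """Replace out-of-mask (medium) pixels with ``fill_color``; in-mask
    pixels are untouched.

    The default fill is the mask's reference medium color (else the
    volume's fill_color), which keeps re-masking the cleaned volume with
    the same parameters idempotent.
    """
    masks = mask.masks if isinstance(mask, SpecimenMask) else np.asarray(mask)
    if masks.shape != (volume.n_layers, *volume.layer_shape):
        raise ValueError(
            f"mask shape {masks.shape} does not match volume "
            f"{(volume.n_layers, *volume.layer_shape)}"
        )
    if fill_color is None:
        fill_color = (mask.medium_color if isinstance(mask, SpecimenMask)
                      else volume.fill_color)
    fill = np.asarray(fill_color, dtype=np.uint8)
    out = np.empty((volume.n_layers, *volume.layer_shape, 3), dtype=np.uint8)
    for k0, img in enumerate(volume.layers()):
        layer = np.array(img, copy=True)
        layer[~masks[k0]] = fill
        out[k0] = layer
    return RasterVolume(ArrayLayerLoader(out), volume.step_um, volume.pitch_um,
                        volume.fill_color)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_shift(reference: np.ndarray, moving: np.ndarray,
                   max_shift_px: int = 8, subpixel: bool = False
                   ) -> tuple[float, float]:
    """Translation ``(dx, dy)`` of ``moving`` relative to ``reference``.

    Exhaustive search over integer shifts in ``[-max_shift_px, max_shift_px]²``
    maximizing normalized cross-correlation on the valid overlap; ties break
    toward the smallest displacement.  ``moving ≈ reference translated by
    (dx, dy)``, so applying ``(-dx, -dy)`` to ``moving`` aligns it.  With
    ``subpixel=True`` a parabolic fit around the integer peak refines each
    component.  Constant (featureless) images return (0, 0) with a warning.
    """
    ref = _luminance(reference)
    mov = _luminance(moving)
    if ref.shape != mov.shape:
        raise ValueError(f"image sizes differ: {ref.shape} vs {mov.shape}")
    if ref.std() == 0 or mov.std() == 0:
        warnings.warn("constant image in shift estimation; returning (0, 0)")
        return (0.0, 0.0)
    h, w = ref.shape
    s = int(max_shift_px)
    scores = np.full((2 * s + 1, 2 * s + 1), -np.inf)
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            # moving(x, y) = reference(x - dx, y - dy) on the overlap
            m = mov[max(dy, 0):h + min(dy, 0), max(dx, 0):w + min(dx, 0)]
            r = ref[max(-dy, 0):h + min(-dy, 0), max(-dx, 0):w + min(-dx, 0)]
            if m.size == 0:
                continue
            scores[dy + s, dx + s] = _ncc(r, m)
    flat = scores.ravel()
    best = flat.max()
    # deterministic tie-break: smallest |shift|, then lexicographic (dy, dx)
    cand = np.argwhere(scores >= best - 1e-15)
    cand = sorted(
        (float(np.hypot(dy - s, dx - s)), dy, dx) for dy, dx in cand
    )
    _, by, bx = cand[0]
    dy0, dx0 = by - s, bx - s

    if not subpixel:
        return (float(dx0), float(dy0))

    def refine(axis_scores, center):
        if center <= 0 or center >= len(axis_scores) - 1:
            return 0.0
        y0, y1, y2 = axis_scores[center - 1:center + 2]
        denom = y0 - 2 * y1 + y2
        if denom >= 0 or not np.isfinite([y0, y1, y2]).all():
            return 0.0
        return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))

    ddx = refine(scores[by, :], bx)
    ddy = refine(scores[:, bx], by)
    return (dx0 + ddx, dy0 + ddy)


def _shift_image(img: np.ndarray, dx: int, dy: int, fill) -> np.ndarray:
    """Integer-translate image content by (+dx, +dy); vacated pixels get
    ``fill`` (a color for RGB images, a scalar/False for masks)."""
    out = np.empty_like(img)
    out[...] = fill
    h, w = img.shape[:2]
    ys0, ys1 = max(dy, 0), h + min(dy, 0)
    xs0, xs1 = max(dx, 0), w + min(dx, 0)
    if ys1 > ys0 and xs1 > xs0:
        out[ys0:ys1, xs0:xs1] = img[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def align_stack(volume: RasterVolume, max_shift_px: int = 8,
                fill_color=None) -> tuple[RasterVolume, ShiftLog]:
    """Chain-align a stack: each layer k > 1 is registered against layer
    k−1's aligned result, translated, and logged.

    Estimated shifts are clamped per component to ``±max_shift_px`` (with a
    warning).  Vacated border pixels are filled with ``fill_color``
    (default: the estimated medium color, so the background stays uniform).
    Returns the aligned volume and the :class:`ShiftLog` of applied shifts.
    """
    if volume.n_layers < 2:
        raise ValueError("alignment needs at least 2 layers")
    if fill_color is None:
        fill_color = estimate_medium_color(volume)
    fill = np.asarray(fill_color, dtype=np.uint8)
    s = int(max_shift_px)
    out = np.empty((volume.n_layers, *volume.layer_shape, 3), dtype=np.uint8)
    out[0] = volume.layer(1)
    log = ShiftLog(shifts=[(0.0, 0.0)], clamped=[False])
    # search a slightly wider window than the clamp so over-limit jitter is
    # detected (and then clamped with a warning) instead of silently capped
    search = s + 4
    for k0 in range(1, volume.n_layers):
        moving = volume.layer(k0 + 1)
        dx, dy = estimate_shift(out[k0 - 1], moving, max_shift_px=search)
        adx, ady = -dx, -dy  # undo the detected displacement
        clamped = abs(adx) > s or abs(ady) > s
        if clamped:
            warnings.warn(
                f"layer {k0 + 1}: shift ({adx}, {ady}) clamped to ±{s} px"
            )
            adx = float(np.clip(adx, -s, s))
            ady = float(np.clip(ady, -s, s))
        out[k0] = _shift_image(moving, int(round(adx)), int(round(ady)), fill)
        log.shifts.append((adx, ady))
        log.clamped.append(clamped)
    aligned = RasterVolume(ArrayLayerLoader(out), volume.step_um,
                           volume.pitch_um, volume.fill_color)
    return aligned, log
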