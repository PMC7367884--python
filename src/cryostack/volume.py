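"""Color voxel volume built from an ordered stack of surface images.

A cryo-milled specimen is photographed after each milling pass, yielding an
ordered sequence of same-sized RGB images.  Stacked, these define a discrete
color field on an anisotropic grid: square in-plane pixels of size
``pitch_um`` (μm/px) and an inter-layer step ``step_um`` (Δz, μm).  The grid
is node-centered: pixel ``(i, j)`` of layer ``k`` (1-based, ``k = 1..M``)
sits at world coordinates

    (x, y, z) = (j * pitch_um, i * pitch_um, (k - 1) * step_um)

so every layer image lies exactly on its plane ``z = Z_k = (k - 1) * Δz``.
World coordinates are in μm throughout; ``x`` runs along image columns,
``y`` along image rows, ``z`` along the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RasterVolume",
    "StackManifest",
    "ArrayLayerLoader",
    "FileLayerLoader",
    "layer_z",
    "world_to_index",
    "index_to_world",
    "sample_color",
    "read_stack",
    "write_stack",
]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half-up (0.5 -> 1), the quantization rule used throughout."""
    return np.floor(np.asarray(x) + 0.5)


def _as_rgb_uint8(arr: np.ndarray, name: str = "image") -> np.ndarray:
    """Coerce a decoded image to (H, W, 3) uint8."""
    a = np.asarray(arr)
    if a.ndim == 2:  # grayscale -> replicate
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError(f"{name}: expected an RGB image, got shape {a.shape}")
    a = a[:, :, :3]
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.floating):
            a = np.clip(_round_half_up(a * 255.0), 0, 255)
        a = np.clip(a, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(a)


class ArrayLayerLoader:
    """In-memory loader over a ``(M, H, W, 3)`` uint8 array."""

    def __init__(self, stack: np.ndarray):
        stack = np.asarray(stack)
        if stack.ndim != 4 or stack.shape[3] != 3:
            raise ValueError(f"expected a (M, H, W, 3) stack, got {stack.shape}")
        if stack.dtype != np.uint8:
            stack = np.clip(stack, 0, 255).astype(np.uint8)
        self._stack = stack

    @property
    def n_layers(self) -> int:
        return self._stack.shape[0]

    @property
    def layer_shape(self) -> tuple[int, int]:
        return self._stack.shape[1], self._stack.shape[2]

    def __getitem__(self, k0: int) -> np.ndarray:
        return self._stack[k0]

    def as_array(self) -> np.ndarray:
        return self._stack


class FileLayerLoader:
    """Lazy loader that decodes each layer image on access.

    Behaviour is identical to :class:`ArrayLayerLoader`; only residency
    differs.  A one-layer cache makes scanline access patterns cheap.
    """

    def __init__(self, paths: Sequence[Path]):
        self._paths = [Path(p) for p in paths]
        if not self._paths:
            raise ValueError("empty layer list")
        first = _read_image(self._paths[0])
        self._shape = first.shape[:2]
        self._cache: tuple[int, np.ndarray] = (0, first)

    @property
    def n_layers(self) -> int:
        return len(self._paths)

    @property
    def layer_shape(self) -> tuple[int, int]:
        return self._shape

    def __getitem__(self, k0: int) -> np.ndarray:
        if self._cache[0] == k0:
            return self._cache[1]
        img = _read_image(self._paths[k0])
        if img.shape[:2] != self._shape:
            raise ValueError(
                f"layer {k0 + 1} size {img.shape[1]}x{img.shape[0]} differs from "
                f"layer 1 size {self._shape[1]}x{self._shape[0]}"
            )
        self._cache = (k0, img)
        return img


@dataclass(frozen=True)
class StackManifest:
    """Ordered description of an on-disk image stack.

    The order of ``files`` is authoritative and defines ``k = 1..M``.
    """

    files: tuple[str, ...]
    step_um: float
    pitch_um: float
    fill_color: tuple[int, int, int] = (0, 0, 0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.files:
            raise ValueError("manifest lists no files")
        if not self.step_um > 0:
            raise ValueError(f"step_um must be > 0, got {self.step_um}")
        if not self.pitch_um > 0:
            raise ValueError(f"pitch_um must be > 0, got {self.pitch_um}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "files": list(self.files),
                "step_um": self.step_um,
                "pitch_um": self.pitch_um,
                "fill_color": list(self.fill_color),
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StackManifest":
        obj = json.loads(text)
        return cls(
            files=tuple(obj["files"]),
            step_um=float(obj["step_um"]),
            pitch_um=float(obj["pitch_um"]),
            fill_color=tuple(obj.get("fill_color", (0, 0, 0))),
            metadata=obj.get("metadata", {}),
        )


class RasterVolume:
    """The discretized RGB field of an image stack (Ω in color space).

    Parameters
    ----------
    loader : ArrayLayerLoader or FileLayerLoader
        Access to the M ordered layers, each (H, W, 3) uint8.
    step_um : float
        Inter-layer step Δz in μm (> 0).
    pitch_um : float
        In-plane pixel size in μm/px (> 0, square pixels).
    fill_color : RGB triple
        Color returned for sample points outside the volume box.
    """

    def __init__(self, loader, step_um: float, pitch_um: float,
                 fill_color: tuple[int, int, int] = (0, 0, 0)):
        if not step_um > 0:
            raise ValueError(f"step_um must be > 0, got {step_um}")
        if not pitch_um > 0:
            raise ValueError(f"pitch_um must be > 0, got {pitch_um}")
        if loader.n_layers < 1:
            raise ValueError("volume needs at least one layer")
        self._loader = loader
        self.step_um = float(step_um)
        self.pitch_um = float(pitch_um)
        self.fill_color = tuple(int(c) for c in fill_color)

    @classmethod
    def from_array(cls, stack: np.ndarray, step_um: float, pitch_um: float,
                   fill_color: tuple[int, int, int] = (0, 0, 0)) -> "RasterVolume":
        return cls(ArrayLayerLoader(stack), step_um, pitch_um, fill_color)

    # -- geometry ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        """M, the number of layer images."""
        return self._loader.n_layers

    @property
    def layer_shape(self) -> tuple[int, int]:
        """(H, W) = (P_y, P_x) pixels per layer."""
        return self._loader.layer_shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """World extents (x, y, z) of the node-centered volume box."""
        h, w = self.layer_shape
        return (
            (w - 1) * self.pitch_um,
            (h - 1) * self.pitch_um,
            (self.n_layers - 1) * self.step_um,
        )

    def layer(self, k: int) -> np.ndarray:
        """Layer image for 1-based index ``k``."""
        if not 1 <= k <= self.n_layers:
            raise IndexError(f"layer index k={k} out of range 1..{self.n_layers}")
        return self._loader[k - 1]

    def layers(self) -> Iterable[np.ndarray]:
        for k0 in range(self.n_layers):
            yield self._loader[k0]

    def layer_z(self, k: int) -> float:
        """World z of layer ``k``: Z_k = (k − 1)·Δz."""
        if not 1 <= k <= self.n_layers:
            raise IndexError(f"layer index k={k} out of range 1..{self.n_layers}")
        return (k - 1) * self.step_um

    def world_to_index(self, points) -> np.ndarray:
        """Map world μm points to fractional grid indices (i, j, k).

        ``i`` and ``j`` are 0-based row/column, ``k`` is the 1-based layer
        coordinate; all fractional and unrestricted (out-of-volume points map
        to out-of-range indices, see :meth:`contains`).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.empty_like(pts)
        ijk[:, 0] = pts[:, 1] / self.pitch_um
        ijk[:, 1] = pts[:, 0] / self.pitch_um
        ijk[:, 2] = pts[:, 2] / self.step_um + 1.0
        return ijk[0] if np.ndim(points) == 1 else ijk

    def index_to_world(self, indices) -> np.ndarray:
        """Inverse of :meth:`world_to_index` ((i, j, k) -> (x, y, z) μm)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = np.empty_like(idx)
        pts[:, 0] = idx[:, 1] * self.pitch_um
        pts[:, 1] = idx[:, 0] * self.pitch_um
        pts[:, 2] = (idx[:, 2] - 1.0) * self.step_um
        return pts[0] if np.ndim(indices) == 1 else pts

    def contains(self, points) -> np.ndarray:
        """True for points inside the node-centered volume box (tiny slack
        keeps exact boundary points inside despite rounding)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ex, ey, ez = self.extent_um
        eps = 1e-9 * max(ex, ey, ez, 1.0)
        ok = (
            (pts[:, 0] >= -eps) & (pts[:, 0] <= ex + eps)
            & (pts[:, 1] >= -eps) & (pts[:, 1] <= ey + eps)
            & (pts[:, 2] >= -eps) & (pts[:, 2] <= ez + eps)
        )
        return ok[0] if np.ndim(points) == 1 else ok

    # -- sampling ---------------------------------------------------------

    def _gather(self, kk: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
        """Fetch colors at integer grid indices, batched by layer so a lazy
        loader touches each layer file once."""
        out = np.empty((len(kk), 3), dtype=np.uint8)
        for k0 in np.unique(kk):
            sel = kk == k0
            layer = self._loader[int(k0)]
            out[sel] = layer[ii[sel], jj[sel]]
        return out

    def sample_color(self, points, mode: str = "trilinear") -> np.ndarray:
        """Sample the color field at world points.

        ``nearest`` returns the stored color of the closest voxel (half-up
        rounding of fractional indices); ``trilinear`` interpolates
        bilinearly in-plane and linearly between the bracketing layers,
        quantized half-up to 8 bits.  Points outside the volume box return
        ``fill_color``.
        """
        if mode not in ("nearest", "trilinear"):
            raise ValueError(f"unknown sampling mode {mode!r}")
        single = np.ndim(points) == 1
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        out = np.empty((n, 3), dtype=np.uint8)
        out[:] = np.asarray(self.fill_color, dtype=np.uint8)
        inside = self.contains(pts)
        if np.any(inside):
            h, w = self.layer_shape
            m = self.n_layers
            p = pts[inside]
            i = p[:, 1] / self.pitch_um
            j = p[:, 0] / self.pitch_um
            k = p[:, 2] / self.step_um  # 0-based layer coordinate
            if mode == "nearest":
                ii = np.clip(_round_half_up(i).astype(int), 0, h - 1)
                jj = np.clip(_round_half_up(j).astype(int), 0, w - 1)
                kk = np.clip(_round_half_up(k).astype(int), 0, m - 1)
                out[inside] = self._gather(kk, ii, jj)
            else:
                i0 = np.clip(np.floor(i).astype(int), 0, max(h - 2, 0))
                j0 = np.clip(np.floor(j).astype(int), 0, max(w - 2, 0))
                k0 = np.clip(np.floor(k).astype(int), 0, max(m - 2, 0))
                ti = np.clip(i - i0, 0.0, 1.0)[:, None]
                tj = np.clip(j - j0, 0.0, 1.0)[:, None]
                tk = np.clip(k - k0, 0.0, 1.0)[:, None]
                i1 = np.minimum(i0 + 1, h - 1)
                j1 = np.minimum(j0 + 1, w - 1)
                k1 = np.minimum(k0 + 1, m - 1)
                acc = np.zeros((len(p), 3), dtype=float)
                for ka, wk in ((k0, 1.0 - tk), (k1, tk)):
                    for ia, wi in ((i0, 1.0 - ti), (i1, ti)):
                        for ja, wj in ((j0, 1.0 - tj), (j1, tj)):
                            wgt = wk * wi * wj
                            if np.all(wgt == 0.0):
                                continue
                            c = self._gather(ka, ia, ja).astype(float)
                            acc += wgt * c
                out[inside] = np.clip(_round_half_up(acc), 0, 255).astype(np.uint8)
        return out[0] if single else out

    def as_array(self) -> np.ndarray:
        """Materialize the full (M, H, W, 3) stack."""
        if isinstance(self._loader, ArrayLayerLoader):
            return self._loader.as_array()
        return np.stack([self._loader[k0] for k0 in range(self.n_layers)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, RasterVolume):
            return NotImplemented
        return (
            self.step_um == other.step_um
            and self.pitch_um == other.pitch_um
            and self.fill_color == other.fill_color
            and self.n_layers == other.n_layers
            and self.layer_shape == other.layer_shape
            and all(
                np.array_equal(a, b)
                for a, b in zip(self.layers(), other.layers())
            )
        )


# -- module-level conveniences matching the functional surface -------------

def layer_z(volume: RasterVolume, k: int) -> float:
    return volume.layer_z(k)


def world_to_index(volume: RasterVolume, points) -> np.ndarray:
    return volume.world_to_index(points)


def index_to_world(volume: RasterVolume, indices) -> np.ndarray:
    return volume.index_to_world(indices)


def sample_color(volume: RasterVolume, points, mode: str = "trilinear") -> np.ndarray:
    return volume.sample_color(points, mode=mode)


# -- stack I/O -------------------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"layer image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return _as_rgb_uint8(arr, name=str(path))


def read_stack(manifest_path, lazy: bool = False) -> RasterVolume:
    """Build a :class:`RasterVolume` from a JSON stack manifest.

    The manifest schema is ``{"files": [...], "step_um": float,
    "pitch_um": float, "fill_color": [r, g, b], "metadata": {...}}``; file
    paths are relative to the manifest's directory and their order defines
    the layer index ``k``.  With ``lazy=True`` layers are decoded on access
    instead of up front (identical sampling behaviour).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = StackManifest.from_json(manifest_path.read_text())
    paths = [manifest_path.parent / f for f in manifest.files]
    if lazy:
        loader = FileLayerLoader(paths)
    else:
        imgs = []
        shape = None
        for idx, p in enumerate(paths):
            img = _read_image(p)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"layer {idx + 1} ({p.name}) size {img.shape[1]}x{img.shape[0]} "
                    f"differs from layer 1 size {shape[1]}x{shape[0]}"
                )
            imgs.append(img)
        loader = ArrayLayerLoader(np.stack(imgs))
    return RasterVolume(loader, manifest.step_um, manifest.pitch_um,
                        manifest.fill_color)


def write_stack(volume: RasterVolume, directory, fmt: str = "tiff",
                prefix: str = "layer") -> Path:
    """Write a volume as numbered images + ``manifest.json``.

    ``fmt`` is ``tiff`` or ``png`` (both lossless, so a read/write round
    trip is bit-exact).  Returns the manifest path.
    """
    if fmt not in ("tiff", "png"):
        raise ValueError(f"unsupported output format {fmt!r} (use tiff or png)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for k0, img in enumerate(volume.layers()):
        name = f"{prefix}_{k0 + 1:04d}.{ 'tiff' if fmt == 'tiff' else 'png'}"
        out = directory / name
        if fmt == "tiff":
            import tifffile

            tifffile.imwrite(out, img, photometric="rgb")
        else:
            from PIL import Image

            Image.fromarray(img, mode="RGB").save(out)
        names.append(name)
    manifest = StackManifest(
        files=tuple(names),
        step_um=volume.step_um,
        pitch_um=volume.pitch_um,
        fill_color=volume.fill_color,
    )
    path = directory / "manifest.json"
    path.write_text(manifest.to_json())
    return path
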