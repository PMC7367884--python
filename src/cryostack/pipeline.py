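"""End-to-end pipeline: stack -> align -> mask/remove -> slice -> morphometrics.

A run is driven by a validated :class:`RunConfig` (strict schema, unknown
keys rejected) and emits every stage artifact plus ``report.json`` with
parameters, stage timings, warnings and SHA-256 hashes of all outputs —
identical config + inputs reproduce identical artifact bytes.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .geometry import SectionPlane
from .morphometrics import (
    optical_density,
    radial_thickness,
    rgb_profile,
    surface_factor,
    trace_boundary,
)
from .slicer import render_section, save_slice
from .specimen import align_stack, remove_medium, specimen_mask
from .volume import read_stack, write_stack

__all__ = ["RunConfig", "run_pipeline"]


class AlignParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    max_shift_px: int = Field(default=8, ge=0)


class MaskParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    threshold: float = Field(default=30.0, ge=0)
    min_area: int = Field(default=0, ge=0)
    keep_largest: bool = False
    medium_color: Optional[tuple[int, int, int]] = None
    fill_color: Optional[tuple[int, int, int]] = None


class SliceParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    plane: Optional[tuple[float, float, float, float]] = None  # (A, B, C, D), μm
    point: Optional[tuple[float, float, float]] = None          # alternative:
    normal: Optional[tuple[float, float, float]] = None         # point + normal
    pitch_um: Optional[float] = Field(default=None, gt=0)
    mode: Literal["nearest", "trilinear"] = "trilinear"

    def to_plane(self) -> SectionPlane:
        if self.plane is not None:
            return SectionPlane(*self.plane)
        if self.point is not None and self.normal is not None:
            return SectionPlane.from_point_normal(self.point, self.normal)
        raise ValueError("slice stage needs either 'plane' or 'point'+'normal'")


class MorphParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    spacing_um: float = Field(default=100.0, gt=0)
    n_rays: int = Field(default=90, ge=1)
    layer: Optional[int] = Field(default=None, ge=1)  # 1-based; default: slice


class RunConfig(BaseModel):
    """Validated pipeline configuration; all lengths in μm, shifts in px."""

    model_config = ConfigDict(extra="forbid")
    input_manifest: str
    output_dir: str
    seed: int = 0
    align: AlignParams = AlignParams()
    mask: MaskParams = MaskParams()
    slice: SliceParams = SliceParams()
    morph: MorphParams = MorphParams()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _save_mask_png(mask: np.ndarray, path: Path) -> None:
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in fixed order and return the report.

    Stage order: align -> mask/remove -> slice -> morphometrics.  A slice
    plane that misses the volume produces an empty artifact and a recorded
    warning, not a failure.  The report (also written to ``report.json``)
    carries enough to replay the run.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.model_dump(),
        "stages": [],
        "warnings": [],
    }
    outputs: dict[str, str] = {}

    def finish_stage(name: str, t0: float, info: dict, files: list[Path]):
        for f in files:
            outputs[str(f.relative_to(out_dir))] = _sha256(f)
        report["stages"].append(
            {"name": name, "elapsed_s": round(time.perf_counter() - t0, 4),
             **info}
        )

    volume = read_stack(config.input_manifest)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.align.enabled:
            t0 = time.perf_counter()
            volume, shift_log = align_stack(
                volume, max_shift_px=config.align.max_shift_px,
                fill_color=config.mask.medium_color,
            )
            align_dir = out_dir / "aligned"
            manifest = write_stack(volume, align_dir, fmt="png")
            csv_path = shift_log.to_csv(out_dir / "shifts.csv")
            finish_stage("align", t0,
                         {"n_layers": volume.n_layers,
                          "max_abs_shift_px": float(np.max(np.abs(shift_log.shifts)))},
                         [manifest, csv_path]
                         + sorted(align_dir.glob("layer_*.png")))

        mask_obj = None
        if config.mask.enabled:
            t0 = time.perf_counter()
            mask_obj = specimen_mask(
                volume, medium_color=config.mask.medium_color,
                threshold=config.mask.threshold,
                min_area=config.mask.min_area,
                keep_largest=config.mask.keep_largest,
            )
            volume = remove_medium(volume, mask_obj,
                                   fill_color=config.mask.fill_color)
            mask_dir = out_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
            files = []
            for k0 in range(mask_obj.n_layers):
                p = mask_dir / f"mask_{k0 + 1:04d}.png"
                _save_mask_png(mask_obj.masks[k0], p)
                files.append(p)
            params_path = mask_dir / "mask_params.json"
            params_path.write_text(json.dumps({
                "medium_color": list(mask_obj.medium_color),
                "threshold": mask_obj.threshold,
                "min_area": mask_obj.min_area,
                "keep_largest": mask_obj.keep_largest,
            }, indent=2))
            files.append(params_path)
            finish_stage("mask", t0,
                         {"specimen_px": int(mask_obj.masks.sum())}, files)

        slc = None
        if config.slice.enabled:
            t0 = time.perf_counter()
            plane = config.slice.to_plane()
            slc = render_section(volume, plane,
                                 pitch_um=config.slice.pitch_um,
                                 mode=config.slice.mode)
            slice_path = save_slice(slc, out_dir / "slice.png")
            files = [slice_path, slice_path.with_suffix(".json")]
            if not slc.is_empty:
                mpath = out_dir / "slice_mask.png"
                _save_mask_png(slc.mask, mpath)
                files.append(mpath)
            finish_stage("slice", t0,
                         {"empty": bool(slc.is_empty),
                          "size_px": [slc.height, slc.width]}, files)

        if config.morph.enabled:
            t0 = time.perf_counter()
            morph_report = _morph_stage(config, volume, mask_obj, slc)
            morph_path = out_dir / "morphometrics.json"
            morph_path.write_text(json.dumps(morph_report, indent=2,
                                             sort_keys=True))
            finish_stage("morph", t0, {}, [morph_path])

        report["warnings"] = [str(w.message) for w in caught]

    report["outputs"] = outputs
    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
    return report


def _morph_stage(config: RunConfig, volume, mask_obj, slc) -> dict:
    """Morphometrics on the rendered section when available, otherwise on
    the configured (or middle) layer."""
    pitch = volume.pitch_um
    if slc is not None and not slc.is_empty and slc.mask.any():
        image = slc.pixels
        fill = np.asarray(volume.fill_color, dtype=np.uint8)
        specimen = slc.mask & ~np.all(slc.pixels == fill, axis=-1)
        pitch = slc.pitch_um
        source = "slice"
    else:
        k = config.morph.layer or (volume.n_layers + 1) // 2
        image = volume.layer(k)
        if mask_obj is not None:
            specimen = mask_obj.layer(k)
        else:
            fill = np.asarray(volume.fill_color, dtype=np.uint8)
            specimen = ~np.all(image == fill, axis=-1)
        source = f"layer {k}"

    out: dict = {"source": source}
    if not specimen.any():
        out["note"] = "no specimen pixels; morphometrics skipped"
        return out

    rgb = rgb_profile(image, specimen)
    out["rgb_mean"] = [round(v, 4) for v in rgb]
    out["optical_density"] = round(optical_density(rgb), 4)

    boundaries = trace_boundary(specimen, pitch_um=pitch)
    boundaries.sort(key=lambda b: b.arc_length, reverse=True)
    if boundaries:
        try:
            sf = surface_factor(boundaries[0], spacing_um=config.morph.spacing_um)
            out["surface_factor"] = {
                "mean": round(sf.mean, 6),
                "n_segments": sf.n_segments,
                "spacing_um": sf.spacing_um,
            }
        except ValueError as exc:
            out["surface_factor"] = {"note": str(exc)}
    if len(boundaries) >= 2:
        try:
            thick = radial_thickness(boundaries[0], boundaries[1],
                                     n_rays=config.morph.n_rays)
            out["radial_thickness_um"] = {
                "median": round(thick.median, 3),
                "q1": round(thick.q1, 3),
                "q3": round(thick.q3, 3),
                "mean": round(thick.mean, 3),
                "n": len(thick.values_um),
                "n_missed": thick.n_missed,
            }
        except ValueError as exc:
            out["radial_thickness_um"] = {"note": str(exc)}
    return out
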