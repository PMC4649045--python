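"""File formats: ray tables (CSV + JSON sidecar), section label maps
(16-bit PNG + JSON sidecar), outline / ring-metrics / accuracy tables (CSV).

All schemas are plain text and documented here so externally produced
files (e.g. exports from other image-analysis tools) can be ingested by
following the same conventions.  Round trips are lossless to the declared
precision: coordinates 1e-4 mm, areas 1 µm².
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .config import WoodModelConfig
from .metrics import OUTLINE_COLUMNS
from .microtome import SectionImage, SectionSpec
from .wood import WoodModel

__all__ = [
    "SchemaError",
    "write_model",
    "read_model",
    "write_section",
    "read_section",
    "write_outlines",
    "read_outlines",
    "write_ring_metrics",
    "read_ring_metrics",
    "write_accuracy",
    "read_accuracy",
    "file_sha256",
]

RAY_COLUMNS = ["ray_id", "t_center", "z_center", "r_init", "r_term", "height_um", "width_um", "lens_p"]
RING_COLUMNS_REQUIRED = ["ring", "ring_width_mm", "perpar", "perpar_early", "perpar_late", "newray_per_mm"]
OUTLINE_REQUIRED = ["ray_id", "area_um2"]
ACCURACY_COLUMNS = ["size", "mean", "cv"]


class SchemaError(ValueError):
    """A file does not follow the declared schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# wood model
# ---------------------------------------------------------------------------


def write_model(model: WoodModel, out_dir: Union[str, Path]) -> list[Path]:
    """Write ``rays.csv`` (one row per ray) and ``model.json`` (config echo,
    ring borders, latewood onsets, year factors)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rays = model.rays[RAY_COLUMNS].copy()
    for c in ("t_center", "z_center", "r_init", "r_term"):
        rays[c] = rays[c].round(6)
    for c in ("height_um", "width_um"):
        rays[c] = rays[c].round(3)
    csv_path = out / "rays.csv"
    rays.to_csv(csv_path, index=False)
    meta = {
        "config": model.config.to_dict(),
        "ring_borders": [round(float(x), 6) for x in model.ring_borders],
        "latewood_onsets": [round(float(x), 6) for x in model.latewood_onsets],
        "year_factors": [float(x) for x in model.year_factors],
        "placement_area_mm2": model.placement_area_mm2,
    }
    json_path = out / "model.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return [csv_path, json_path]


def read_model(in_dir: Union[str, Path]) -> WoodModel:
    src = Path(in_dir)
    csv_path, json_path = src / "rays.csv", src / "model.json"
    if not json_path.exists():
        raise SchemaError(f"{json_path} not found")
    meta = json.loads(json_path.read_text())
    try:
        config = WoodModelConfig.from_dict(meta["config"])
    except KeyError as exc:
        raise SchemaError(f"{json_path}: missing key {exc}") from exc
    rays = pd.read_csv(csv_path)
    _require_columns(rays, RAY_COLUMNS, csv_path)
    return WoodModel(
        config=config,
        ring_borders=meta["ring_borders"],
        latewood_onsets=meta["latewood_onsets"],
        year_factors=meta["year_factors"],
        rays=rays,
        placement_area_mm2=meta.get("placement_area_mm2"),
    )


# ---------------------------------------------------------------------------
# section images
# ---------------------------------------------------------------------------


def write_section(image: SectionImage, out_dir: Union[str, Path], name: str = "section") -> list[Path]:
    """Write ``<name>.png`` (16-bit label map, id 0 = background) and
    ``<name>.json`` (spec, pixel size, origin, ring borders, zones)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if image.labels.max(initial=0) > 0xFFFF:
        raise SchemaError("more than 65535 ray labels: cannot store as 16-bit PNG")
    png_path = out / f"{name}.png"
    Image.fromarray(image.labels.astype(np.uint16)).save(png_path, format="PNG")
    spec = image.spec
    meta = {
        "plane": spec.plane,
        "offset_mm": spec.offset,
        "thickness_um": spec.thickness,
        "misalignment_deg": spec.misalignment_deg,
        "resolution_um": spec.resolution,
        "extent_mm": spec.extent,
        "pixel_size_um": image.pixel_size_um,
        "origin_mm": list(image.origin),
        "ring_borders": None if image.ring_borders is None else [float(x) for x in image.ring_borders],
        "latewood_onsets": None if image.latewood_onsets is None else [float(x) for x in image.latewood_onsets],
    }
    json_path = out / f"{name}.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return [png_path, json_path]


def read_section(png_path: Union[str, Path], json_path: Optional[Union[str, Path]] = None) -> SectionImage:
    png_path = Path(png_path)
    if json_path is None:
        json_path = png_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    for key in ("plane", "pixel_size_um", "origin_mm"):
        if key not in meta:
            raise SchemaError(f"{json_path}: missing key {key!r}")
    labels = np.asarray(Image.open(png_path), dtype=np.int32)
    extent = meta.get("extent_mm")
    spec = SectionSpec(
        plane=meta["plane"],
        offset=meta.get("offset_mm"),
        thickness=meta.get("thickness_um", 15.0),
        misalignment_deg=meta.get("misalignment_deg", 0.0),
        resolution=meta["pixel_size_um"],
        extent=None if extent is None else tuple(tuple(pair) for pair in extent),
    )
    return SectionImage(
        labels=labels,
        counts=None,
        spec=spec,
        pixel_size_um=meta["pixel_size_um"],
        origin=tuple(meta["origin_mm"]),
        ring_borders=meta.get("ring_borders"),
        latewood_onsets=meta.get("latewood_onsets"),
    )


# ---------------------------------------------------------------------------
# tabular schemas
# ---------------------------------------------------------------------------


def write_outlines(outlines: pd.DataFrame, path: Union[str, Path], section_id: str = "", plane: str = "") -> Path:
    """Outline table: one row per outline, with section/plane provenance."""
    path = Path(path)
    df = outlines[[c for c in OUTLINE_COLUMNS if c in outlines.columns]].copy()
    df.insert(0, "section_id", section_id)
    df.insert(1, "plane", plane)
    if len(df):
        for c in ("centroid_0_mm", "centroid_1_mm", "inner_end_mm", "outer_end_mm"):
            if c in df.columns:
                df[c] = df[c].round(6)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_outlines(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, OUTLINE_REQUIRED, path)
    return df


def write_ring_metrics(metrics: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(path, index=False)
    return path


def read_ring_metrics(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RING_COLUMNS_REQUIRED, path)
    return df


def write_accuracy(curve_frame: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve_frame.to_csv(path, index=False)
    return path


def read_accuracy(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ACCURACY_COLUMNS, path)
    return df
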