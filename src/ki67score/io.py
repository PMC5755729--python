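"""Readers and writers for the package's external formats.

Images arrive as 8-bit RGB TIFF or PNG; annotations as GeoJSON
FeatureCollections of Polygon/MultiPolygon in 0-based pixel coordinates
(y-down, CRS ignored); tables as comma-separated UTF-8 CSV with a header row
and empty fields for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .errors import InvalidInputError
from .imaging import NucleusDetection, SlideImage
from .tiling import SlideScore, Tile

__all__ = [
    "load_image",
    "load_annotation",
    "save_annotation",
    "detections_to_frame",
    "tiles_to_frame",
    "score_to_dict",
]


def _mpp_from_tiff(path: Path) -> float | None:
    """Read an isotropic mpp from TIFF resolution tags, if present."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or yres is None or unit is None:
                return None
            to_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch / cm
            if to_um is None:
                return None
            mx = to_um * xres.value[1] / xres.value[0]
            my = to_um * yres.value[1] / yres.value[0]
            if not np.isclose(mx, my, rtol=1e-3):
                raise InvalidInputError(
                    f"anisotropic pixel size ({mx:.4f} x {my:.4f} um) is not supported"
                )
            return float(mx)
    except tifffile.TiffFileError:
        return None


def load_image(path: str | Path, mpp: float | None = None) -> SlideImage:
    """Load an RGB TIFF/PNG slide image.

    TIFF resolution tags supply the mpp when present; an explicitly passed
    ``mpp`` always wins. A missing scale is an error — scores are defined in
    physical units.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        tag_mpp = _mpp_from_tiff(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
        tag_mpp = None
    resolved = mpp if mpp is not None else tag_mpp
    if resolved is None:
        raise InvalidInputError(
            f"no microns-per-pixel available for {path.name}: pass --mpp "
            "(no resolution tags found in the file)"
        )
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[..., :3]
    if pixels.dtype != np.uint8:
        raise InvalidInputError(f"expected 8-bit image, got {pixels.dtype}")
    return SlideImage(pixels=pixels, mpp=float(resolved))


def load_annotation(path: str | Path):
    """Read a GeoJSON FeatureCollection into a single (Multi)Polygon."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"cannot parse annotation {path}: {exc}") from exc
    if payload.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in payload.get("features", [])]
    elif payload.get("type") == "Feature":
        geoms = [shape(payload["geometry"])]
    else:
        geoms = [shape(payload)]
    geoms = [g for g in geoms if not g.is_empty]
    if not geoms:
        raise InvalidInputError(f"annotation {path} contains no geometry")
    bad = [g.geom_type for g in geoms if g.geom_type not in ("Polygon", "MultiPolygon")]
    if bad:
        raise InvalidInputError(f"annotation must contain polygons, found {bad}")
    region = unary_union(geoms)
    if region.area <= 0:
        raise InvalidInputError("annotation region has zero area")
    return region


def save_annotation(region, path: str | Path, name: str = "tumor") -> None:
    feature = {
        "type": "Feature",
        "properties": {"name": name},
        "geometry": mapping(region),
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": [feature]}, indent=1)
    )


def detections_to_frame(detections: list[NucleusDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_px": d.centroid_x,
                "y_px": d.centroid_y,
                "area_px2": d.area_px2,
                "mean_dab_od": d.mean_dab_od,
                "mean_hema_od": d.mean_hema_od,
                "label": d.label,
            }
            for d in detections
        ],
        columns=["x_px", "y_px", "area_px2", "mean_dab_od", "mean_hema_od", "label"],
    )


def tiles_to_frame(tiles: list[Tile]) -> pd.DataFrame:
    """Per-tile table; percent_positive left empty where undefined."""
    rows = []
    for t in tiles:
        pct = t.percent_positive
        rows.append({
            "row": t.row, "col": t.col,
            "x0_px": t.x0, "y0_px": t.y0, "x1_px": t.x1, "y1_px": t.y1,
            "total_cells": t.total_cells, "positive_cells": t.positive_cells,
            "percent_positive": round(pct, 2) if pct is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=[
        "row", "col", "x0_px", "y0_px", "x1_px", "y1_px",
        "total_cells", "positive_cells", "percent_positive",
    ])


def score_to_dict(score: SlideScore, slide_id: str, params: dict) -> dict:
    """Summary payload with the resolved parameters echoed for auditability."""
    def _round(v):
        return round(v, 2) if v is not None else None

    return {
        "slide_id": slide_id,
        "hot_spot_index": _round(score.hot_spot_index),
        "whole_slide_index": _round(score.whole_slide_index),
        "n_tiles": score.n_tiles,
        "n_qualifying_tiles": score.n_qualifying_tiles,
        "n_hotspot_tiles_used": score.n_hotspot_tiles_used,
        "hotspot_fallback": score.hotspot_fallback,
        "params": params,
    }
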