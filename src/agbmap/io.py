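"""Readers and writers for the pipeline's file formats.

Rasters travel as single- or multi-band GeoTIFFs (float32 with an explicit
nodata value); georeferencing is carried in the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GDAL nodata) written through tifffile.
Plot tables are CSV with the header ``plot_id,x,y,agb_t_ha`` (extra columns
preserved), written as float64 text at 12 significant digits. Run
configuration and manifests are YAML.

Coordinates are planar metric (a projected CRS is assumed); no reprojection
is performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import GridGeometry, RasterStack

__all__ = [
    "write_raster",
    "read_raster",
    "write_stack",
    "read_stack",
    "write_plots",
    "read_plots",
    "read_config",
    "write_manifest",
]

_NODATA = -9999.0
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

PLOT_COLUMNS = ["plot_id", "x", "y", "agb_t_ha"]


def write_raster(path, band: np.ndarray, grid: GridGeometry,
                 band_names: list[str] | None = None, nodata: float = _NODATA) -> None:
    """Write one band (2D) or a band stack (3D, band-major) as GeoTIFF."""
    arr = np.asarray(band, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[-2:] != grid.shape:
        raise ValueError("raster shape does not match the grid")
    data = np.where(np.isfinite(arr), arr, np.float32(nodata))
    desc = json.dumps({"band_names": band_names or [f"band{i+1}" for i in range(len(arr))]})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    if data.shape[0] == 1:
        data = data[0]  # single band as one 2D page
    tifffile.imwrite(path, data, extratags=extratags, description=desc,
                     metadata=None, photometric="minisblack")


def read_raster(path) -> tuple[np.ndarray, GridGeometry, list[str]]:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible).

    Returns (bands, grid, band_names); nodata becomes NaN. ``bands`` is 3D
    band-major even for a single band.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = tf.asarray().astype(np.float32)
        tags = {t.code: t.value for t in page.tags.values()}
    if arr.ndim == 2:
        arr = arr[None]
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if abs(sx - sy) > 1e-9:
        raise ValueError("non-square cells are not supported")
    tie = tags[_TAG_TIEPOINT]
    origin_x = tie[3] - tie[0] * sx
    origin_y = tie[4] + tie[1] * sy
    grid = GridGeometry(arr.shape[-2], arr.shape[-1], float(sx),
                        float(origin_x), float(origin_y))
    nodata = float(tags.get(_TAG_GDAL_NODATA, _NODATA))
    out = np.where(arr == np.float32(nodata), np.nan, arr).astype(float)
    names = [f"band{i+1}" for i in range(len(arr))]
    desc = tags.get(270)
    if desc:
        try:
            names = json.loads(desc)["band_names"]
        except (ValueError, KeyError, TypeError):
            pass
    return out, grid, names


def write_stack(path, stack: RasterStack, nodata: float = _NODATA) -> None:
    """Write a whole stack as one multiband GeoTIFF."""
    bands = np.stack(list(stack.bands.values()))
    write_raster(path, bands, stack.grid, band_names=stack.names, nodata=nodata)


def read_stack(path) -> RasterStack:
    bands, grid, names = read_raster(path)
    return RasterStack(grid, dict(zip(names, bands)))


def write_plots(path, plots: pd.DataFrame) -> None:
    """Plot CSV with the canonical header; float64 at 12 significant digits."""
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing column(s): {', '.join(missing)}")
    ordered = plots[PLOT_COLUMNS + [c for c in plots.columns if c not in PLOT_COLUMNS]]
    ordered.to_csv(path, index=False, float_format="%.12g")


def read_plots(path) -> pd.DataFrame:
    """Read and validate a plot CSV; malformed rows are reported by line."""
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)} "
                         f"(header must start with {','.join(PLOT_COLUMNS)})")
    for col in ("x", "y", "agb_t_ha"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric or missing {col!r} at line(s) {lines}")
        df[col] = vals.astype(float)
    return df


def read_config(path, defaults: dict, name: str = "config") -> dict:
    """Load a YAML mapping, rejecting keys absent from ``defaults``.

    Returns ``defaults`` updated with the file's values, so the merged dict
    (echoed into the run manifest) records every effective setting.
    """
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: {name} must be a YAML mapping")
    merged = dict(defaults)
    unknown = []
    for key, value in loaded.items():
        if key not in defaults:
            unknown.append(key)
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"{path}: {key!r} must be a mapping")
            sub_unknown = set(value) - set(defaults[key])
            if sub_unknown:
                unknown.extend(f"{key}.{u}" for u in sorted(sub_unknown))
                continue
            merged[key] = {**defaults[key], **value}
        else:
            merged[key] = value
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {', '.join(sorted(unknown))}")
    return merged


def write_manifest(path, config: dict, seed: int, outputs: list[str]) -> None:
    """Persist the fully-resolved configuration, master seed and artifact list."""
    manifest = {"seed": int(seed), "config": config, "outputs": sorted(map(str, outputs))}
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))
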