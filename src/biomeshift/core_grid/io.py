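"""Raster and table I/O.

Biome grids are read and written as CF-style netCDF (``lat``/``lon``
coordinates plus an integer ``biome`` variable; series add a
``slice_start`` coordinate) or as single-band integer GeoTIFF with
ModelPixelScale/ModelTiepoint geo-tags.  Longitudes spanning 0-360 are
normalized to [-180, 180) on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from ..errors import FormatError
from .geometry import GridGeometry, normalize_lon
from .grid import BiomeGrid, parse_slice_label, slice_label_for

_GEOTIFF_SUFFIXES = {".tif", ".tiff"}
_NETCDF_SUFFIXES = {".nc", ".nc4", ".cdf"}

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


# ---------------------------------------------------------------------------
# geometry <-> coordinate arrays


def _geometry_from_coords(lats: np.ndarray, lons: np.ndarray) -> tuple[GridGeometry, bool, int]:
    """Infer a GridGeometry from 1-D coordinate arrays.

    Returns (geometry, flip_lat, lon_roll): flip_lat is True when the file
    stores latitudes ascending (south first); lon_roll is the column shift
    needed after normalizing 0-360 longitudes to -180..180.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.ndim != 1 or lons.ndim != 1 or lats.size < 1 or lons.size < 1:
        raise FormatError("lat/lon coordinates must be non-empty 1-D arrays")

    def _step(vals: np.ndarray, what: str) -> float:
        if vals.size == 1:
            raise FormatError(f"cannot infer {what} step from a single coordinate")
        diffs = np.diff(vals)
        if not np.allclose(diffs, diffs[0], atol=1e-6):
            raise FormatError(f"{what} coordinate is not regularly spaced")
        return float(diffs[0])

    flip_lat = False
    if lats.size > 1:
        lat_step = _step(lats, "latitude")
        if lat_step > 0:
            flip_lat = True
            lats = lats[::-1]
            lat_step = -lat_step
        lat_step = -lat_step
    else:
        raise FormatError("grid must have at least two latitude rows")

    lon_roll = 0
    norm = normalize_lon(lons)
    if lons.size > 1:
        lon_step = _step(lons, "longitude")
        if lon_step <= 0:
            raise FormatError("longitudes must be ascending")
        if not np.all(np.diff(norm) > 0):
            # 0-360 (or antimeridian-crossing) convention: roll so the
            # column whose normalized longitude is westernmost comes first
            lon_roll = int(np.argmin(norm))
            norm = np.roll(norm, -lon_roll)
            if not np.all(np.diff(norm) > 0):
                raise FormatError(
                    "longitudes do not map to a monotone -180..180 range"
                )
    else:
        lon_step = 360.0

    geometry = GridGeometry(
        n_lat=lats.size,
        n_lon=lons.size,
        lat_step=lat_step,
        lon_step=lon_step,
        origin=(float(lats[0]), float(norm[0])),
    )
    return geometry, flip_lat, lon_roll


def _orient(values: np.ndarray, flip_lat: bool, lon_roll: int) -> np.ndarray:
    if flip_lat:
        values = values[::-1, :]
    if lon_roll:
        values = np.roll(values, -lon_roll, axis=1)
    return values


def _require_int(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.integer):
        return arr
    if np.issubdtype(arr.dtype, np.floating) and np.all(
        np.isfinite(arr) & (arr == np.round(arr))
    ):
        return arr.astype(np.int64)
    raise FormatError(f"{what} must hold integer codes")


# ---------------------------------------------------------------------------
# netCDF


def _grid_to_dataset(grids: list[BiomeGrid]) -> xr.Dataset:
    geom = grids[0].geometry
    starts = [parse_slice_label(g.slice_label) for g in grids]
    data = np.stack([g.codes for g in grids]).astype(np.int32)
    ds = xr.Dataset(
        {"biome": (("slice_start", "lat", "lon"), data)},
        coords={
            "slice_start": np.asarray(starts, dtype=np.int32),
            "lat": geom.lat_centers,
            "lon": geom.lon_centers,
        },
        attrs={"level": grids[0].level, "sentinel": -1},
    )
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds["slice_start"].attrs.update(units="year", long_name="20-year slice start")
    ds["biome"].attrs.update(long_name="categorical biome code")
    return ds


def write_biome_series(grids: list[BiomeGrid], path: str | Path) -> None:
    """Write one or more slices (shared geometry/level) to a netCDF file."""
    if not grids:
        raise FormatError("no grids to write")
    for g in grids[1:]:
        grids[0].require_compatible(g)
    _grid_to_dataset(grids).to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_biome_series(path: str | Path) -> list[BiomeGrid]:
    """Read all slices from a netCDF biome file, sorted by slice start."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if "biome" not in ds:
            raise FormatError(f"{path}: no 'biome' variable")
        if "lat" not in ds.coords or "lon" not in ds.coords:
            raise FormatError(f"{path}: missing lat/lon coordinates")
        geometry, flip_lat, lon_roll = _geometry_from_coords(
            ds["lat"].values, ds["lon"].values
        )
        level = str(ds.attrs.get("level", "biome"))
        var = ds["biome"]
        if "slice_start" in var.dims:
            starts = [int(s) for s in ds["slice_start"].values]
            raw = _require_int(var.values, "biome variable")
        elif var.ndim == 2:
            starts = [int(ds.attrs.get("slice_start", 2000))]
            raw = _require_int(var.values, "biome variable")[None, :, :]
        else:
            raise FormatError(f"{path}: unexpected biome variable dimensions {var.dims}")
    order = np.argsort(starts)
    grids = []
    for k in order:
        codes = _orient(raw[k], flip_lat, lon_roll)
        grids.append(
            BiomeGrid(
                geometry=geometry,
                codes=codes,
                slice_label=slice_label_for(starts[k]),
                level=level,
            )
        )
    return grids


def write_biome_grid(grid: BiomeGrid, path: str | Path) -> None:
    """Write a single slice as netCDF or GeoTIFF depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in _GEOTIFF_SUFFIXES:
        _write_geotiff(grid.codes, grid.geometry, path,
                       meta={"slice_label": grid.slice_label, "level": grid.level})
    elif path.suffix.lower() in _NETCDF_SUFFIXES:
        write_biome_series([grid], path)
    else:
        raise FormatError(f"unsupported raster suffix: {path.suffix!r}")


def read_biome_grid(path: str | Path, slice_label: str | None = None) -> BiomeGrid:
    """Read one slice; ``slice_label`` selects within a multi-slice file."""
    path = Path(path)
    if path.suffix.lower() in _GEOTIFF_SUFFIXES:
        codes, geometry, meta = _read_geotiff(path)
        label = slice_label or meta.get("slice_label")
        if label is None:
            raise FormatError(f"{path}: GeoTIFF lacks a slice label; pass slice_label")
        return BiomeGrid(
            geometry=geometry,
            codes=_require_int(codes, "GeoTIFF band"),
            slice_label=label,
            level=meta.get("level", "biome"),
        )
    grids = read_biome_series(path)
    if slice_label is None:
        if len(grids) != 1:
            raise FormatError(f"{path} holds {len(grids)} slices; pass slice_label")
        return grids[0]
    for g in grids:
        if parse_slice_label(g.slice_label) == parse_slice_label(slice_label):
            return g
    raise FormatError(f"{path}: no slice labelled {slice_label!r}")


# ---------------------------------------------------------------------------
# GeoTIFF (single integer band + ModelPixelScale / ModelTiepoint tags)


def _write_geotiff(values: np.ndarray, geometry: GridGeometry,
                   path: Path, meta: dict | None = None) -> None:
    lat0, lon0 = geometry.origin
    west_edge = lon0 - geometry.lon_step / 2.0
    north_edge = lat0 + geometry.lat_step / 2.0
    scale = (geometry.lon_step, geometry.lat_step, 0.0)
    tiepoint = (0.0, 0.0, 0.0, west_edge, north_edge, 0.0)
    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.int32),
        description=json.dumps(meta or {}),
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale, True),
            (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        ],
    )


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridGeometry, dict]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
        lon_step, lat_step = float(scale_tag.value[0]), float(scale_tag.value[1])
        west_edge, north_edge = float(tie_tag.value[3]), float(tie_tag.value[4])
        values = page.asarray()
        meta = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single band")
    geometry = GridGeometry(
        n_lat=values.shape[0],
        n_lon=values.shape[1],
        lat_step=lat_step,
        lon_step=lon_step,
        origin=(
            north_edge - lat_step / 2.0,
            float(normalize_lon(west_edge + lon_step / 2.0)),
        ),
    )
    return values, geometry, meta


def write_categorical_geotiff(values: np.ndarray, geometry: GridGeometry,
                              path: str | Path, meta: dict | None = None) -> None:
    """Write any integer categorical raster (e.g. an anthrome mask)."""
    _write_geotiff(values, geometry, Path(path), meta)


def read_categorical_geotiff(path: str | Path) -> tuple[np.ndarray, GridGeometry, dict]:
    values, geometry, meta = _read_geotiff(Path(path))
    return _require_int(values, "GeoTIFF band"), geometry, meta


# ---------------------------------------------------------------------------
# metrics tables


def write_metrics(table, path: str | Path) -> None:
    """Write a MetricsTable (or DataFrame) as deterministic tidy CSV."""
    frame = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
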