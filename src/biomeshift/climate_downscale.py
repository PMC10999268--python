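"""Anomaly (delta) downscaling of coarse monthly climate fields.

The change between a future and a pre-industrial coarse field is
bilinearly interpolated onto a fine reference grid and applied to the
reference climatology: additively for temperature and cloud fraction,
multiplicatively (capped ratio) for precipitation.  The coarse grid is
treated as globally periodic in longitude; latitudes outside the coarse
cell-center range are clamped (nearest row).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .core_grid import GridGeometry
from .core_grid.io import _geometry_from_coords  # shared coordinate parsing
from .errors import FormatError

VARIABLES = ("temperature", "precipitation", "cloud")

#: Ratio anomalies are capped here and set to 1 where the pre-industrial
#: value falls below RATIO_MIN_REFERENCE (mm/month).
RATIO_CAP = 5.0
RATIO_MIN_REFERENCE = 0.1


@dataclass(frozen=True)
class ClimateField:
    """Twelve monthly layers of one climate variable on a regular grid."""

    variable: str
    values: np.ndarray  # (12, n_lat, n_lon)
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise FormatError(
                f"variable must be one of {VARIABLES}, got {self.variable!r}"
            )
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (12, self.geometry.n_lat, self.geometry.n_lon):
            raise FormatError(
                f"expected 12 monthly layers of shape {self.geometry.shape}, "
                f"got {arr.shape}"
            )
        if self.variable == "precipitation" and np.nanmin(arr) < 0:
            raise FormatError("precipitation must be non-negative")
        if self.variable == "cloud" and (
            np.nanmin(arr) < 0 or np.nanmax(arr) > 1
        ):
            raise FormatError("cloud fraction must be within [0, 1]")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)


def _interp_monthly(values: np.ndarray, coarse: GridGeometry,
                    fine: GridGeometry) -> np.ndarray:
    """Bilinear interpolation of (12, nlat, nlon) onto the fine grid with
    longitudinal wrap and latitudinal clamping."""
    lat_src = coarse.lat_centers[::-1]  # ascending for the interpolator
    lon_src = coarse.lon_centers
    order = np.argsort(lon_src)
    lon_sorted = lon_src[order]
    # periodic extension: repeat the first column 360 degrees east
    lon_ext = np.concatenate([lon_sorted, [lon_sorted[0] + 360.0]])

    lat_q = np.clip(fine.lat_centers, lat_src[0], lat_src[-1])
    lon_q = fine.lon_centers.copy()
    lon_q = lon_sorted[0] + ((lon_q - lon_sorted[0]) % 360.0)
    pts_lat, pts_lon = np.meshgrid(lat_q, lon_q, indexing="ij")
    query = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])

    out = np.empty((12, fine.n_lat, fine.n_lon))
    for m in range(12):
        layer = values[m][::-1, :][:, order]
        layer_ext = np.concatenate([layer, layer[:, :1]], axis=1)
        interp = RegularGridInterpolator(
            (lat_src, lon_ext), layer_ext, method="linear", bounds_error=True
        )
        out[m] = interp(query).reshape(fine.n_lat, fine.n_lon)
    return out


def downscale_anomaly(
    future_coarse: ClimateField,
    preindustrial_coarse: ClimateField,
    reference_fine: ClimateField,
    *,
    precipitation_mode: str = "ratio",
    ratio_cap: float = RATIO_CAP,
    ratio_min_reference: float = RATIO_MIN_REFERENCE,
) -> ClimateField:
    """Apply a coarse anomaly to a fine reference climatology.

    Temperature and cloud use additive anomalies; precipitation defaults
    to ratio anomalies (``precipitation_mode='additive'`` switches).
    Cloud output is clipped to [0, 1], precipitation floored at 0.
    """
    if not (future_coarse.variable == preindustrial_coarse.variable
            == reference_fine.variable):
        raise FormatError("all three fields must carry the same variable")
    if not future_coarse.geometry.approx_equal(preindustrial_coarse.geometry):
        raise FormatError("future and pre-industrial fields must share geometry")
    if precipitation_mode not in ("ratio", "additive"):
        raise FormatError(f"unknown precipitation mode {precipitation_mode!r}")

    variable = future_coarse.variable
    fine = reference_fine.geometry

    if variable == "precipitation" and precipitation_mode == "ratio":
        pre = preindustrial_coarse.values
        ratio = np.where(
            pre < ratio_min_reference,
            1.0,
            future_coarse.values / np.maximum(pre, ratio_min_reference),
        )
        ratio = np.clip(ratio, 0.0, ratio_cap)
        ratio_fine = _interp_monthly(ratio, future_coarse.geometry, fine)
        out = np.maximum(reference_fine.values * ratio_fine, 0.0)
    else:
        anomaly = future_coarse.values - preindustrial_coarse.values
        anomaly_fine = _interp_monthly(anomaly, future_coarse.geometry, fine)
        out = reference_fine.values + anomaly_fine
        if variable == "cloud":
            out = np.clip(out, 0.0, 1.0)
        elif variable == "precipitation":
            out = np.maximum(out, 0.0)
    return ClimateField(variable=variable, values=out, geometry=fine)


# ---------------------------------------------------------------------------
# netCDF I/O


def write_climate_field(field: ClimateField, path: str | Path) -> None:
    ds = xr.Dataset(
        {field.variable: (("month", "lat", "lon"), field.values)},
        coords={
            "month": np.arange(1, 13, dtype=np.int32),
            "lat": field.geometry.lat_centers,
            "lon": field.geometry.lon_centers,
        },
    )
    ds["lat"].attrs.update(units="degrees_north")
    ds["lon"].attrs.update(units="degrees_east")
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_climate_field(path: str | Path, variable: str) -> ClimateField:
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"{path}: no {variable!r} variable")
        geometry, flip_lat, lon_roll = _geometry_from_coords(
            ds["lat"].values, ds["lon"].values
        )
        vals = np.asarray(ds[variable].values, dtype=float)
    if vals.ndim != 3 or vals.shape[0] != 12:
        raise FormatError(f"{path}: expected 12 monthly layers")
    if flip_lat:
        vals = vals[:, ::-1, :]
    if lon_roll:
        vals = np.roll(vals, -lon_roll, axis=2)
    return ClimateField(variable=variable, values=vals, geometry=geometry)
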