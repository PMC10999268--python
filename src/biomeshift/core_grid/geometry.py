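"""Grid geometry and spherical cell areas.

The package works on regular latitude-longitude grids with cell-center
registration.  Row 0 is the northernmost row and longitudes are kept in
[-180, 180).  Cell areas follow the spherical-zone formula

    A = R^2 * dlambda * (sin(phi_north) - sin(phi_south))

which is exact for a spherical Earth and longitude-invariant along a row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidGeometryError

#: Default Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0

#: Reserved code for non-terrestrial cells (ocean, ice, barren, masked out).
SENTINEL = -1

_EPS = 1e-9


def normalize_lon(lon):
    """Map longitudes (scalar or array) into [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class GridGeometry:
    """Regular lat-lon grid, cell-center registered, row 0 northernmost.

    Parameters
    ----------
    n_lat, n_lon : int
        Number of rows / columns.
    lat_step, lon_step : float
        Cell size in degrees (positive).
    origin : tuple of float
        (lat, lon) of the center of cell (0, 0), i.e. the north-west cell.
    radius_km : float
        Sphere radius used for all areas and distances.
    """

    n_lat: int
    n_lon: int
    lat_step: float
    lon_step: float
    origin: tuple[float, float]
    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise InvalidGeometryError("grid must have at least one row and column")
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise InvalidGeometryError("cell steps must be positive")
        if self.radius_km <= 0:
            raise InvalidGeometryError("radius must be positive")
        if self.n_lat * self.lat_step > 180.0 + _EPS:
            raise InvalidGeometryError("latitudinal extent exceeds 180 degrees")
        if self.n_lon * self.lon_step > 360.0 + _EPS:
            raise InvalidGeometryError("longitudinal extent exceeds 360 degrees")
        lat0, _ = self.origin
        north_edge = lat0 + self.lat_step / 2.0
        south_edge = lat0 - (self.n_lat - 1) * self.lat_step - self.lat_step / 2.0
        if north_edge > 90.0 + _EPS or south_edge < -90.0 - _EPS:
            raise InvalidGeometryError("grid rows extend beyond the poles")
        centers = self.lat_centers
        if np.any(np.abs(centers) >= 90.0):
            raise InvalidGeometryError("cell centers must satisfy |lat| < 90")

    @property
    def lat_centers(self) -> np.ndarray:
        """Row-center latitudes, northernmost first (descending)."""
        lat0, _ = self.origin
        return lat0 - self.lat_step * np.arange(self.n_lat)

    @property
    def lon_centers(self) -> np.ndarray:
        """Column-center longitudes, ascending; the first lies in [-180, 180).

        Kept continuous (values may reach up to first + 360) so coordinate
        arrays stay monotone for grids crossing the antimeridian.
        """
        _, lon0 = self.origin
        start = float(normalize_lon(lon0))
        return start + self.lon_step * np.arange(self.n_lon)

    def lat_bounds(self, row: int) -> tuple[float, float]:
        """(south, north) edge latitudes of a row, clipped to the poles."""
        center = self.origin[0] - self.lat_step * row
        south = max(center - self.lat_step / 2.0, -90.0)
        north = min(center + self.lat_step / 2.0, 90.0)
        return south, north

    @property
    def is_global_lon(self) -> bool:
        """True if the grid closes in longitude (covers the full 360 degrees)."""
        return abs(self.n_lon * self.lon_step - 360.0) < 1e-6

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def refine(self, factor: int) -> "GridGeometry":
        """Geometry of this grid split into factor x factor children per cell."""
        if factor < 1:
            raise InvalidGeometryError("refinement factor must be >= 1")
        child_lat = self.lat_step / factor
        child_lon = self.lon_step / factor
        lat0, lon0 = self.origin
        new_lat0 = lat0 + self.lat_step / 2.0 - child_lat / 2.0
        new_lon0 = lon0 - self.lon_step / 2.0 + child_lon / 2.0
        return GridGeometry(
            n_lat=self.n_lat * factor,
            n_lon=self.n_lon * factor,
            lat_step=child_lat,
            lon_step=child_lon,
            origin=(new_lat0, float(normalize_lon(new_lon0))),
            radius_km=self.radius_km,
        )

    def approx_equal(self, other: "GridGeometry", tol_deg: float = 1e-6) -> bool:
        """Same shape and cell centers within ``tol_deg`` degrees."""
        if self.shape != other.shape:
            return False
        if abs(self.lat_step - other.lat_step) > tol_deg:
            return False
        if abs(self.lon_step - other.lon_step) > tol_deg:
            return False
        dlat = abs(self.origin[0] - other.origin[0])
        dlon = abs(normalize_lon(self.origin[1] - other.origin[1]))
        return dlat <= tol_deg and dlon <= tol_deg


def global_half_degree(radius_km: float = EARTH_RADIUS_KM) -> GridGeometry:
    """The standard 0.5-degree global grid (360 x 720, NW cell at 89.75N, 179.75W)."""
    return GridGeometry(
        n_lat=360,
        n_lon=720,
        lat_step=0.5,
        lon_step=0.5,
        origin=(89.75, -179.75),
        radius_km=radius_km,
    )


def cell_area(
    lat_south: float,
    lat_north: float,
    lon_step: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Surface area (km^2) of a lat-lon cell on a sphere.

    Uses the exact spherical-zone expression
    ``R^2 * radians(lon_step) * (sin(lat_north) - sin(lat_south))``.

    Raises
    ------
    InvalidGeometryError
        If the latitudes are reversed, equal, or outside [-90, 90], or the
        longitude step is non-positive.
    """
    if not (-90.0 <= lat_south < lat_north <= 90.0):
        raise InvalidGeometryError(
            f"invalid latitude bounds: south={lat_south}, north={lat_north}"
        )
    if lon_step <= 0:
        raise InvalidGeometryError(f"longitude step must be positive, got {lon_step}")
    dlam = math.radians(lon_step)
    return (
        radius_km * radius_km * dlam
        * (math.sin(math.radians(lat_north)) - math.sin(math.radians(lat_south)))
    )


@dataclass(frozen=True)
class CellAreaVector:
    """Per-latitude-row cell areas in km^2 (length n_lat, row 0 northernmost)."""

    areas_km2: np.ndarray
    geometry: GridGeometry = field(compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.areas_km2, dtype=float)
        if arr.ndim != 1 or arr.shape[0] != self.geometry.n_lat:
            raise InvalidGeometryError("area vector length must equal n_lat")
        if np.any(arr <= 0):
            raise InvalidGeometryError("cell areas must be strictly positive")
        object.__setattr__(self, "areas_km2", arr)

    def as_grid(self) -> np.ndarray:
        """Broadcast to the full (n_lat, n_lon) weight matrix."""
        return np.broadcast_to(
            self.areas_km2[:, None], (self.geometry.n_lat, self.geometry.n_lon)
        )

    @property
    def total_km2(self) -> float:
        return float(self.areas_km2.sum() * self.geometry.n_lon)


def build_area_vector(geometry: GridGeometry) -> CellAreaVector:
    """Vectorized :func:`cell_area` over every latitude row of a geometry."""
    areas = np.empty(geometry.n_lat, dtype=float)
    for i in range(geometry.n_lat):
        south, north = geometry.lat_bounds(i)
        areas[i] = cell_area(south, north, geometry.lon_step, geometry.radius_km)
    return CellAreaVector(areas_km2=areas, geometry=geometry)
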