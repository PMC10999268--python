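"""Migration-feasibility statistics.

For each biome and slice: the proportion of its suitable area overlapping
its previous-slice area (one minus this is area requiring colonization);
the fraction lying in cells not even adjacent to previous-slice area
(long-distance migration); connected-patch counts; and area-weighted
centroid tracks with great-circle step distance and initial bearing.

Connectivity (4 or 8 neighbours) and longitudinal wrap are configurable;
both default to the common landscape-metrics convention (8, wrap on) and
should be reported alongside results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_grid import EARTH_RADIUS_KM, BiomeGrid, CellAreaVector
from .errors import BiomeAbsentError, DegenerateCentroidError

#: Steps shorter than this are flagged as having a numerically unstable bearing.
LOW_CONFIDENCE_STEP_KM = 1.0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _dilate_wrapped(mask: np.ndarray, connectivity: int, wrap: bool) -> np.ndarray:
    """Binary dilation (including the original cells), optionally wrapping
    across the first/last longitude columns."""
    structure = _structure(connectivity)
    if wrap and mask.shape[1] > 1:
        padded = np.pad(mask, ((0, 0), (1, 1)), mode="wrap")
        return ndimage.binary_dilation(padded, structure=structure)[:, 1:-1]
    return ndimage.binary_dilation(mask, structure=structure)


# ---------------------------------------------------------------------------
# overlap and adjacency


def overlap_proportion(
    grid_t: BiomeGrid,
    grid_prev: BiomeGrid,
    areas: CellAreaVector,
) -> dict[int, float]:
    """Per biome present at t: area suitable in the same cells as at prev,
    divided by the biome's area at t.  Biomes absent at prev score 0."""
    grid_t.require_compatible(grid_prev)
    weights = areas.as_grid()
    out: dict[int, float] = {}
    for code in grid_t.present_codes():
        now = grid_t.codes == code
        denom = float(weights[now].sum())
        inter = float(weights[now & (grid_prev.codes == code)].sum())
        out[code] = inter / denom if denom > 0 else 0.0
    return out


def non_adjacent_fraction(
    grid_t: BiomeGrid,
    grid_prev: BiomeGrid,
    areas: CellAreaVector,
    connectivity: int = 8,
    wrap: bool = True,
) -> dict[int, float]:
    """Per biome present at t: fraction of its area in cells that neither
    carried the biome at prev nor touch any cell that did."""
    grid_t.require_compatible(grid_prev)
    weights = areas.as_grid()
    out: dict[int, float] = {}
    for code in grid_t.present_codes():
        now = grid_t.codes == code
        reachable = _dilate_wrapped(grid_prev.codes == code, connectivity, wrap)
        denom = float(weights[now].sum())
        far = float(weights[now & ~reachable].sum())
        out[code] = far / denom if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# patches


@dataclass(frozen=True)
class PatchLabeling:
    """Connected-component labelling of every biome in one slice."""

    counts: dict[int, int]
    labels: dict[int, np.ndarray]
    connectivity: int
    wrap: bool

    def patch_cells(self, code: int) -> list[set[tuple[int, int]]]:
        """Cell sets of each patch of a biome (testing helper)."""
        lab = self.labels[code]
        return [
            {(int(i), int(j)) for i, j in zip(*np.nonzero(lab == k))}
            for k in range(1, self.counts[code] + 1)
        ]


def _label_wrapped(mask: np.ndarray, connectivity: int, wrap: bool) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    n_cols = mask.shape[1]
    if not wrap or n <= 1 or n_cols <= 1:
        return labels, n
    # merge components touching across the first/last column seam
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    left, right = labels[:, 0], labels[:, -1]
    n_rows = mask.shape[0]
    offsets = (0,) if connectivity == 4 else (-1, 0, 1)
    for i in range(n_rows):
        if left[i] == 0:
            continue
        for di in offsets:
            k = i + di
            if 0 <= k < n_rows and right[k] != 0:
                union(int(left[i]), int(right[k]))
    roots = sorted({find(x) for x in range(1, n + 1)})
    remap = np.zeros(n + 1, dtype=labels.dtype)
    for new, root in enumerate(roots, start=1):
        remap[root] = new
    for x in range(1, n + 1):
        remap[x] = remap[find(x)]
    return remap[labels], len(roots)


def label_patches(
    grid: BiomeGrid,
    connectivity: int = 8,
    wrap: bool = True,
) -> PatchLabeling:
    """Count and label the connected patches of every biome in a slice."""
    counts: dict[int, int] = {}
    labels: dict[int, np.ndarray] = {}
    for code in grid.present_codes():
        lab, n = _label_wrapped(grid.codes == code, connectivity, wrap)
        counts[code] = int(n)
        labels[code] = lab
    return PatchLabeling(counts=counts, labels=labels,
                         connectivity=connectivity, wrap=wrap)


# ---------------------------------------------------------------------------
# centroids and geodesy


def biome_centroid(
    grid: BiomeGrid,
    biome: int,
    areas: CellAreaVector,
) -> tuple[float, float]:
    """Area-weighted centroid (lat, lon) of a biome's suitable cells.

    Cell centers are averaged as 3-D unit vectors and the mean is projected
    back to the sphere, which keeps the estimate well defined across the
    antimeridian.  Raises :class:`BiomeAbsentError` when the biome is not
    present and :class:`DegenerateCentroidError` when the mean vector is
    numerically zero (antipodally balanced distribution).
    """
    mask = grid.codes == biome
    if not mask.any():
        raise BiomeAbsentError(
            f"biome {biome} absent from slice {grid.slice_label}"
        )
    geom = grid.geometry
    lat = np.radians(np.broadcast_to(geom.lat_centers[:, None], geom.shape))
    lon = np.radians(np.broadcast_to(geom.lon_centers[None, :], geom.shape))
    w = areas.as_grid()[mask]
    clat = np.cos(lat[mask])
    x = float((w * clat * np.cos(lon[mask])).sum())
    y = float((w * clat * np.sin(lon[mask])).sum())
    z = float((w * np.sin(lat[mask])).sum())
    total = float(w.sum())
    x, y, z = x / total, y / total, z / total
    norm = math.sqrt(x * x + y * y + z * z)
    if norm < 1e-9:
        raise DegenerateCentroidError(
            f"biome {biome} is antipodally balanced in slice {grid.slice_label}"
        )
    lat_c = math.degrees(math.asin(max(-1.0, min(1.0, z / norm))))
    lon_c = math.degrees(math.atan2(y, x))
    if lon_c >= 180.0:
        lon_c -= 360.0
    return lat_c, lon_c


def centroid_step(
    c_prev: tuple[float, float],
    c_t: tuple[float, float],
    radius_km: float = EARTH_RADIUS_KM,
) -> tuple[float, float]:
    """Great-circle (haversine) distance and initial bearing between two
    points.  Bearing is degrees clockwise from north in [0, 360); identical
    points return (0, 0) by convention."""
    lat1, lon1 = math.radians(c_prev[0]), math.radians(c_prev[1])
    lat2, lon2 = math.radians(c_t[0]), math.radians(c_t[1])
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = (math.sin(dlat / 2.0) ** 2
         + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2)
    distance = 2.0 * radius_km * math.asin(min(1.0, math.sqrt(a)))
    if distance == 0.0:
        return 0.0, 0.0
    theta = math.atan2(
        math.sin(dlon) * math.cos(lat2),
        math.cos(lat1) * math.sin(lat2)
        - math.sin(lat1) * math.cos(lat2) * math.cos(dlon),
    )
    bearing = math.degrees(theta) % 360.0
    return distance, bearing


@dataclass(frozen=True)
class CentroidRecord:
    """One slice of a biome's centroid track (NaN fields mark gaps)."""

    slice_label: str
    lat: float
    lon: float
    step_distance_km: float
    step_bearing_deg: float
    low_confidence_bearing: bool


def centroid_track(
    grids: list[BiomeGrid],
    biome: int,
    areas: CellAreaVector,
) -> list[CentroidRecord]:
    """Centroid per slice plus step distance/bearing from the previous slice.

    Slices where the biome is absent produce NaN coordinates (a gap); the
    step after a gap is also NaN.  Steps shorter than
    :data:`LOW_CONFIDENCE_STEP_KM` carry a low-confidence bearing flag.
    """
    records: list[CentroidRecord] = []
    prev: tuple[float, float] | None = None
    for grid in grids:
        try:
            cen = biome_centroid(grid, biome, areas)
        except BiomeAbsentError:
            records.append(CentroidRecord(grid.slice_label, math.nan, math.nan,
                                          math.nan, math.nan, False))
            prev = None
            continue
        if prev is None:
            dist, bearing = math.nan, math.nan
            low = False
        else:
            dist, bearing = centroid_step(prev, cen, grid.geometry.radius_km)
            low = dist < LOW_CONFIDENCE_STEP_KM
        records.append(CentroidRecord(grid.slice_label, cen[0], cen[1],
                                      dist, bearing, low))
        prev = cen
    return records
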