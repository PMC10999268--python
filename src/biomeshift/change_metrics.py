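"""Area-weighted change statistics.

Two families of statistics: the fraction of terrestrial area whose code
differs between a slice and a reference slice (the previous slice or the
2000-2020 baseline), globally and in low/mid/high latitude bands; and the
total area climatically suitable for each biome per slice.

Cells that are sentinel in either grid of a comparison are excluded from
both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_grid import BiomeGrid, CellAreaVector
from .errors import AlignmentError

SCOPES = ("global", "low", "mid", "high")


@dataclass(frozen=True)
class LatBandScheme:
    """Latitude bands by cell-center latitude.

    low: |lat| < 30; mid: 30 <= |lat| < 60; high: 60 <= |lat| <= 90.
    Boundary cells go to the more poleward band (half-open toward the
    equator), so the bands partition all cells.
    """

    low_limit: float = 30.0
    mid_limit: float = 60.0

    def band_of(self, lat: float | np.ndarray) -> np.ndarray:
        a = np.abs(np.asarray(lat, dtype=float))
        out = np.where(a >= self.mid_limit, "high",
                       np.where(a >= self.low_limit, "mid", "low"))
        return out

    def masks_for(self, grid: BiomeGrid) -> dict[str, np.ndarray]:
        """Boolean cell masks per scope (including the all-true 'global')."""
        lat = np.broadcast_to(
            grid.geometry.lat_centers[:, None], grid.geometry.shape
        )
        bands = self.band_of(lat)
        return {
            "global": np.ones(grid.geometry.shape, dtype=bool),
            "low": bands == "low",
            "mid": bands == "mid",
            "high": bands == "high",
        }


class ChangeStat(NamedTuple):
    """Changed area, reference terrestrial area, and their ratio for one scope."""

    changed_km2: float
    total_km2: float
    fraction: float


def change_fraction(
    grid_t: BiomeGrid,
    grid_ref: BiomeGrid,
    areas: CellAreaVector,
    bands: LatBandScheme | None = None,
) -> dict[str, ChangeStat]:
    """Fraction of terrestrial area coded differently than in the reference.

    Returns one :class:`ChangeStat` per scope; the fraction is 0 for an
    empty scope.  Band fractions are normalized by the band's own
    terrestrial area (numerator and denominator are both reported so the
    global-normalized convention is recoverable).
    """
    grid_t.require_compatible(grid_ref)
    if bands is None:
        bands = LatBandScheme()
    weights = areas.as_grid()
    both = grid_t.terrestrial & grid_ref.terrestrial
    changed = both & (grid_t.codes != grid_ref.codes)
    out: dict[str, ChangeStat] = {}
    for scope, mask in bands.masks_for(grid_t).items():
        total = float(weights[both & mask].sum())
        num = float(weights[changed & mask].sum())
        frac = num / total if total > 0 else 0.0
        out[scope] = ChangeStat(changed_km2=num, total_km2=total, fraction=frac)
    return out


def area_by_biome(grid: BiomeGrid, areas: CellAreaVector) -> dict[int, float]:
    """Total suitable area (km^2) per non-sentinel code present in the grid."""
    weights = areas.as_grid()
    out: dict[int, float] = {}
    for code in grid.present_codes():
        out[code] = float(weights[grid.codes == code].sum())
    return out


_COLUMNS = [
    "scenario", "slice_label", "reference", "scope",
    "level", "tier", "statistic", "biome", "value",
]

_FRACTION_STATS = {
    "change_fraction", "overlap_proportion", "non_adjacent_fraction",
}


@dataclass
class MetricsTable:
    """Long-format statistic records, written as tidy CSV.

    One row per (scenario, slice, reference, scope, level, tier,
    statistic, biome).  Empty string marks a field that does not apply
    (e.g. ``biome`` for global change fractions).
    """

    records: list[dict] = field(default_factory=list)

    def add(self, *, statistic: str, value: float, scenario: str = "",
            slice_label: str = "", reference: str = "", scope: str = "",
            level: str = "", tier: str = "", biome: str = "") -> None:
        if statistic in _FRACTION_STATS and np.isfinite(value):
            if not -1e-12 <= value <= 1.0 + 1e-12:
                raise ValueError(f"{statistic}={value} outside [0, 1]")
            value = min(max(value, 0.0), 1.0)
        if statistic.endswith("_km2") and np.isfinite(value) and value < 0:
            raise ValueError(f"{statistic}={value} is negative")
        self.records.append({
            "scenario": scenario, "slice_label": slice_label,
            "reference": reference, "scope": scope, "level": level,
            "tier": tier, "statistic": statistic, "biome": biome,
            "value": value,
        })

    def extend(self, other: "MetricsTable") -> None:
        self.records.extend(other.records)

    def to_frame(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=_COLUMNS)
        return pd.DataFrame.from_records(self.records, columns=_COLUMNS)

    def __len__(self) -> int:
        return len(self.records)


def change_records(
    grid_t: BiomeGrid,
    grid_ref: BiomeGrid,
    areas: CellAreaVector,
    *,
    reference: str,
    bands: LatBandScheme | None = None,
    scenario: str = "",
    tier: str = "",
) -> MetricsTable:
    """change_fraction plus its numerator/denominator as table rows."""
    table = MetricsTable()
    stats = change_fraction(grid_t, grid_ref, areas, bands)
    for scope, stat in stats.items():
        common = dict(scenario=scenario, slice_label=grid_t.slice_label,
                      reference=reference, scope=scope, level=grid_t.level,
                      tier=tier)
        table.add(statistic="change_fraction", value=stat.fraction, **common)
        table.add(statistic="changed_area_km2", value=stat.changed_km2, **common)
        table.add(statistic="scope_area_km2", value=stat.total_km2, **common)
    return table


def area_records(
    grid: BiomeGrid,
    areas: CellAreaVector,
    *,
    scenario: str = "",
    tier: str = "",
    biome_labels: dict[int, str] | None = None,
) -> MetricsTable:
    table = MetricsTable()
    for code, km2 in sorted(area_by_biome(grid, areas).items()):
        label = biome_labels.get(code, str(code)) if biome_labels else str(code)
        table.add(statistic="suitable_area_km2", value=km2, scenario=scenario,
                  slice_label=grid.slice_label, scope="global",
                  level=grid.level, tier=tier, biome=label)
    return table
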