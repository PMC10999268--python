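"""Synthetic biome time series and anthrome masks.

Downstream statistics are exercised without the real model outputs by
generating zonally banded biome maps whose per-slice transition
probability, poleward boundary drift and patchiness are controlled
parameters.  All randomness flows through ``numpy.random.default_rng``
seeded from the spec, so identical specs give bit-identical outputs on
any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_grid import SENTINEL, BiomeGrid, GridGeometry, slice_label_for
from .errors import SpecError
from .masking import ANTHROME_CLASSES, AnthromeMask

_MAX_SLICES = 25  # 2000-2020 .. 2480-2500


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic biome scenario.

    ``zonal_layout`` lists the biome code of each latitude band from north
    to south; bands divide [-90, 90] equally.  Between adjacent slices each
    terrestrial cell independently switches biome with probability
    ``per_slice_change_rate`` (always to a *different* code, drawn from a
    neighbouring band so the change resembles climatic forcing), and zone
    boundaries move poleward by ``drift_deg_per_slice`` degrees.
    """

    geometry: GridGeometry
    zonal_layout: tuple[int, ...]
    n_slices: int = _MAX_SLICES
    per_slice_change_rate: float = 0.0
    drift_deg_per_slice: float = 0.0
    patchiness: float = 0.0
    ocean_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        layout = tuple(int(c) for c in self.zonal_layout)
        if not layout:
            raise SpecError("zonal_layout must list at least one biome code")
        if any(c < 0 for c in layout):
            raise SpecError("zonal_layout codes must be non-negative")
        if len(set(layout)) > 26:
            raise SpecError("zonal_layout uses more than 26 distinct biomes")
        if not 2 <= self.n_slices <= _MAX_SLICES:
            raise SpecError(f"n_slices must be in [2, {_MAX_SLICES}]")
        if not 0.0 <= self.per_slice_change_rate <= 1.0:
            raise SpecError("per_slice_change_rate must be in [0, 1]")
        if not 0.0 <= self.ocean_fraction <= 1.0:
            raise SpecError("ocean_fraction must be in [0, 1]")
        if self.drift_deg_per_slice < 0 or self.patchiness < 0:
            raise SpecError("drift and patchiness must be non-negative")
        object.__setattr__(self, "zonal_layout", layout)

    @property
    def n_biomes(self) -> int:
        return len(set(self.zonal_layout))


@dataclass(frozen=True)
class AnthromeSpec:
    """Parameters of a synthetic anthrome mask."""

    geometry: GridGeometry
    class_fractions: dict[str, float] = field(default_factory=lambda: {"wild": 1.0})
    clustering: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = dict(self.class_fractions)
        unknown = set(fractions) - set(ANTHROME_CLASSES)
        if unknown:
            raise SpecError(f"unknown anthrome classes: {sorted(unknown)}")
        if any(v < 0 for v in fractions.values()):
            raise SpecError("class fractions must be non-negative")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"class fractions must sum to 1, got {total}")
        if self.clustering < 0:
            raise SpecError("clustering must be non-negative")
        object.__setattr__(self, "class_fractions", fractions)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Correlated noise: white noise passed through a moving-average kernel
    of the given correlation length (cells), wrapping in longitude."""
    noise = rng.standard_normal(shape)
    size = int(round(length))
    if size > 1:
        noise = ndimage.uniform_filter(
            noise, size=size, mode=("nearest", "wrap")
        )
    return noise


def _band_index(lat_eff: np.ndarray, n_bands: int) -> np.ndarray:
    """Band of each effective latitude; bands split [-90, 90] equally, north first."""
    idx = np.floor((90.0 - lat_eff) / 180.0 * n_bands).astype(np.int64)
    return np.clip(idx, 0, n_bands - 1)


def make_scenario(spec: ScenarioSpec) -> list[BiomeGrid]:
    """Generate ``spec.n_slices`` biome grids (labels 2000-2020 onwards)."""
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    n_bands = len(spec.zonal_layout)
    layout = np.asarray(spec.zonal_layout, dtype=np.int16)

    lat = np.broadcast_to(geom.lat_centers[:, None], geom.shape).astype(float)

    # static fields: ocean mask and boundary jitter (fixed over time so that
    # inter-slice change comes only from drift and switches)
    ocean = np.zeros(geom.shape, dtype=bool)
    if spec.ocean_fraction > 0:
        f = _smooth_field(rng, geom.shape, spec.patchiness)
        ocean = f < np.quantile(f, spec.ocean_fraction)
    jitter = np.zeros(geom.shape)
    if spec.patchiness > 0:
        raw = _smooth_field(rng, geom.shape, spec.patchiness)
        std = raw.std()
        if std > 0:
            jitter = raw / std * (spec.patchiness * geom.lat_step)

    def band_at(t: int) -> np.ndarray:
        # poleward boundary drift: each cell sees the zone that sat
        # drift*t degrees closer to the equator at slice 0
        shift = np.sign(lat) * spec.drift_deg_per_slice * t
        return _band_index(lat - shift + jitter, n_bands)

    grids: list[BiomeGrid] = []
    band_prev = band_at(0)
    codes = layout[band_prev].copy()
    codes[ocean] = SENTINEL
    grids.append(BiomeGrid(geometry=geom, codes=codes,
                           slice_label=slice_label_for(2000), level="biome"))

    all_codes = np.asarray(sorted(set(spec.zonal_layout)), dtype=np.int16)
    for t in range(1, spec.n_slices):
        band_t = band_at(t)
        codes = grids[-1].codes.copy()
        moved = (band_t != band_prev) & ~ocean
        codes[moved] = layout[band_t[moved]]
        if spec.per_slice_change_rate > 0:
            switch = (rng.random(geom.shape) < spec.per_slice_change_rate) & ~ocean
            rows, cols = np.nonzero(switch)
            pick = rng.random(rows.size)
            for k in range(rows.size):
                i, j = rows[k], cols[k]
                b = band_t[i, j]
                current = codes[i, j]
                neighbours = [layout[b - 1]] if b > 0 else []
                if b < n_bands - 1:
                    neighbours.append(layout[b + 1])
                candidates = [c for c in neighbours if c != current]
                if not candidates:
                    candidates = [c for c in all_codes if c != current]
                if candidates:
                    codes[i, j] = candidates[int(pick[k] * len(candidates))]
        grids.append(BiomeGrid(geometry=geom, codes=codes,
                               slice_label=slice_label_for(2000 + 20 * t),
                               level="biome"))
        band_prev = band_t
    return grids


def make_anthromes(spec: AnthromeSpec) -> AnthromeMask:
    """Generate a clustered anthrome mask with the requested class fractions.

    Cells are ranked by a correlated noise field and classes are assigned
    by cumulative quantile in catalogue order, so realized fractions match
    the request up to rounding while classes form spatial clusters.
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    n_cells = geom.n_lat * geom.n_lon
    fields = _smooth_field(rng, geom.shape, spec.clustering).ravel()
    order = np.argsort(fields, kind="stable")

    classes = np.full(n_cells, SENTINEL, dtype=np.int16)
    counts = []
    for name in ANTHROME_CLASSES:
        counts.append(spec.class_fractions.get(name, 0.0) * n_cells)
    # largest-remainder rounding so counts total exactly n_cells
    floors = [int(np.floor(c)) for c in counts]
    remainder = n_cells - sum(floors)
    by_frac = sorted(range(len(counts)),
                     key=lambda i: (counts[i] - floors[i], -i), reverse=True)
    for i in by_frac[:remainder]:
        floors[i] += 1
    start = 0
    for idx, count in enumerate(floors):
        classes[order[start:start + count]] = idx
        start += count
    return AnthromeMask(geometry=geom,
                        classes=classes.reshape(geom.shape),
                        class_names=ANTHROME_CLASSES)
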