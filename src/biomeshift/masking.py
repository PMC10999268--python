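"""Human-land-use masking.

Biome grids are disaggregated to the resolution of a static anthrome
raster (1/12 degree for the standard inputs, factor 6 from 0.5 degree)
and cells with a human presence are removed at one of two severities:

* ``urban``    — remove only 'urban' and 'dense settlement' cells;
* ``non_wild`` — keep only 'wild' and 'semi-natural' cells.

Masked cells become sentinel cells and drop out of every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pathlib import Path

import pandas as pd

from .core_grid import SENTINEL, BiomeGrid, GridGeometry
from .core_grid.io import read_categorical_geotiff, write_categorical_geotiff
from .errors import AlignmentError, FormatError, SpecError

logger = logging.getLogger(__name__)

#: Recognized anthrome class vocabulary (HYDE-style labels).
ANTHROME_CLASSES = (
    "urban",
    "dense settlement",
    "cropland",
    "rangeland",
    "semi-natural",
    "wild",
)

TIER1_REMOVED = frozenset({"urban", "dense settlement"})
TIER2_KEPT = frozenset({"wild", "semi-natural"})

TIERS = ("none", "urban", "non_wild")


@dataclass(frozen=True)
class AnthromeMask:
    """Static categorical human-land-use raster.

    ``classes`` holds indices into ``class_names``; :data:`SENTINEL` (-1)
    marks non-terrestrial (ocean) cells of the anthrome product itself.
    """

    geometry: GridGeometry
    classes: np.ndarray
    class_names: tuple[str, ...] = ANTHROME_CLASSES

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("anthrome classes must be integer indices")
        if arr.shape != self.geometry.shape:
            raise FormatError(
                f"anthrome shape {arr.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        valid = (arr == SENTINEL) | ((arr >= 0) & (arr < len(self.class_names)))
        if not valid.all():
            raise FormatError("anthrome class index out of range")
        arr = arr.astype(np.int16, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "classes", arr)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def terrestrial(self) -> np.ndarray:
        return self.classes != SENTINEL

    def removed_at(self, tier: str) -> np.ndarray:
        """Boolean mask of cells removed by a tier (among the mask's cells).

        Classes outside the recognized vocabulary are retained at tier
        ``urban`` and removed at tier ``non_wild`` (conservative); their
        occurrence is logged.
        """
        if tier not in TIERS:
            raise SpecError(f"tier must be one of {TIERS}, got {tier!r}")
        if tier == "none":
            return np.zeros(self.classes.shape, dtype=bool)
        known = set(ANTHROME_CLASSES)
        unknown_idx = [
            i for i, name in enumerate(self.class_names) if name not in known
        ]
        if unknown_idx:
            n_unknown = int(np.isin(self.classes, unknown_idx).sum())
            if n_unknown:
                logger.warning(
                    "anthrome mask has %d cells in unrecognized classes %s "
                    "(retained at tier 'urban', removed at tier 'non_wild')",
                    n_unknown,
                    [self.class_names[i] for i in unknown_idx],
                )
        if tier == "urban":
            removed_names = TIER1_REMOVED
            removed_idx = [
                i for i, name in enumerate(self.class_names) if name in removed_names
            ]
            return np.isin(self.classes, removed_idx)
        # non_wild: everything except the explicitly kept classes
        kept_idx = [
            i for i, name in enumerate(self.class_names) if name in TIER2_KEPT
        ]
        return self.terrestrial & ~np.isin(self.classes, kept_idx)

    def class_fraction(self, name: str) -> float:
        """Fraction of mask cells (terrestrial only) in a named class."""
        terr = self.terrestrial
        if not terr.any():
            return 0.0
        idx = self.class_names.index(name)
        return float((self.classes == idx).sum() / terr.sum())


def disaggregate(grid: BiomeGrid, factor: int) -> BiomeGrid:
    """Split every cell into ``factor`` x ``factor`` children with the same code.

    Per-biome area is conserved by construction: the children of a parent
    cell tile exactly the parent's spherical zone.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise SpecError(f"disaggregation factor must be a positive integer, got {factor}")
    if factor == 1:
        return grid.with_codes(grid.codes)
    codes = np.repeat(np.repeat(grid.codes, factor, axis=0), factor, axis=1)
    return grid.with_codes(codes, geometry=grid.geometry.refine(int(factor)))


def apply_mask(grid: BiomeGrid, mask: AnthromeMask | None, tier: str) -> BiomeGrid:
    """Remove human-occupied cells from a biome grid at the given tier.

    ``tier='none'`` is the identity.  Otherwise the grid and mask must be
    cell-aligned (disaggregate the grid first); cells terrestrial in only
    one of the two rasters become sentinel — the intersection defines the
    terrestrial area.
    """
    if tier not in TIERS:
        raise SpecError(f"tier must be one of {TIERS}, got {tier!r}")
    if tier == "none":
        return grid.with_codes(grid.codes)
    if mask is None:
        raise SpecError(f"tier {tier!r} requires an anthrome mask")
    tol = min(grid.geometry.lat_step, grid.geometry.lon_step) / 2.0
    if not grid.geometry.approx_equal(mask.geometry, tol_deg=tol):
        raise AlignmentError(
            "biome grid and anthrome mask are not cell-aligned; "
            "disaggregate the grid to the mask resolution first"
        )
    keep = grid.terrestrial & mask.terrestrial & ~mask.removed_at(tier)
    codes = np.where(keep, grid.codes, np.int16(SENTINEL)).astype(np.int16)
    return grid.with_codes(codes)


def save_anthromes(mask: AnthromeMask, path: str | Path) -> None:
    """Write an anthrome mask as a categorical GeoTIFF (class names embedded)."""
    write_categorical_geotiff(
        mask.classes, mask.geometry, path,
        meta={"class_names": list(mask.class_names)},
    )


def load_anthromes(path: str | Path, class_csv: str | Path | None = None) -> AnthromeMask:
    """Read an anthrome GeoTIFF; class names come from the embedded metadata
    or from a sidecar CSV with columns ``index,name``."""
    values, geometry, meta = read_categorical_geotiff(path)
    if class_csv is not None:
        table = pd.read_csv(class_csv)
        if not {"index", "name"} <= set(table.columns):
            raise FormatError(f"{class_csv}: sidecar needs 'index' and 'name' columns")
        table = table.sort_values("index")
        if list(table["index"]) != list(range(len(table))):
            raise FormatError(f"{class_csv}: class indices must be 0..n-1")
        names = tuple(str(n) for n in table["name"])
    elif "class_names" in meta:
        names = tuple(str(n) for n in meta["class_names"])
    else:
        names = ANTHROME_CLASSES
    return AnthromeMask(geometry=geometry, classes=values, class_names=names)
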