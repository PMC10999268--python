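"""Categorical biome rasters and megabiome aggregation."""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from ..errors import AlignmentError, FormatError, UnknownCodeError
from .geometry import SENTINEL, GridGeometry
from .scheme import BiomeScheme

LEVELS = ("biome", "megabiome")

# labels like "2000-2020"; both hyphen-minus and en dash are accepted
_SLICE_RE = re.compile(r"^(\d{4})[–-](\d{4})$")


def parse_slice_label(label: str) -> int:
    """Validate a 20-year slice label and return the interval start year.

    Valid starts are 2000, 2020, ..., 2480 and the end must be start + 20.
    """
    m = _SLICE_RE.match(label)
    if not m:
        raise FormatError(f"slice label {label!r} is not of the form 'YYYY-YYYY'")
    start, end = int(m.group(1)), int(m.group(2))
    if end != start + 20:
        raise FormatError(f"slice label {label!r} does not span 20 years")
    if start < 2000 or start > 2480 or (start - 2000) % 20 != 0:
        raise FormatError(f"slice label {label!r} start not in 2000..2480 step 20")
    return start


def slice_label_for(start_year: int) -> str:
    return f"{start_year}-{start_year + 20}"


@dataclass(frozen=True)
class BiomeGrid:
    """One time slice of categorical codes on a regular lat-lon grid.

    ``codes`` is an (n_lat, n_lon) integer matrix; :data:`SENTINEL` (-1)
    marks non-terrestrial cells (ocean, ice, barren, or masked out), which
    every statistic in the package excludes.
    """

    geometry: GridGeometry
    codes: np.ndarray
    slice_label: str
    level: str = "biome"

    def __post_init__(self) -> None:
        arr = np.asarray(self.codes)
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"biome codes must be integers, got dtype {arr.dtype}")
        if arr.shape != self.geometry.shape:
            raise FormatError(
                f"code matrix shape {arr.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if self.level not in LEVELS:
            raise FormatError(f"level must be one of {LEVELS}, got {self.level!r}")
        parse_slice_label(self.slice_label)
        arr = arr.astype(np.int16, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "codes", arr)

    @property
    def terrestrial(self) -> np.ndarray:
        """Boolean mask of non-sentinel cells."""
        return self.codes != SENTINEL

    def present_codes(self) -> list[int]:
        """Sorted distinct non-sentinel codes in the grid."""
        vals = np.unique(self.codes)
        return [int(v) for v in vals if v != SENTINEL]

    def with_codes(self, codes: np.ndarray, **changes) -> "BiomeGrid":
        return replace(self, codes=codes, **changes)

    def require_compatible(self, other: "BiomeGrid") -> None:
        """Raise AlignmentError unless grids share geometry and level."""
        if not self.geometry.approx_equal(other.geometry):
            raise AlignmentError("grids do not share geometry")
        if self.level != other.level:
            raise AlignmentError(
                f"grids are at different levels: {self.level} vs {other.level}"
            )


def aggregate_megabiomes(grid: BiomeGrid, scheme: BiomeScheme | None = None) -> BiomeGrid:
    """Collapse a biome-level grid onto the 9 megabiome classes.

    Sentinel cells pass through unchanged.  Aggregation is idempotent:
    a grid already at megabiome level is returned as-is (a copy).
    """
    if scheme is None:
        scheme = BiomeScheme.default()
    if grid.level == "megabiome":
        return grid.with_codes(grid.codes)
    lookup = scheme.megabiome_lookup()
    max_code = max(lookup) if lookup else 0
    # index 0 reserved for sentinel via +1 offset
    table = np.full(max_code + 2, -999, dtype=np.int16)
    table[0] = SENTINEL
    for biome_code, mega_code in lookup.items():
        table[biome_code + 1] = mega_code
    shifted = grid.codes.astype(np.int64) + 1
    bad = (shifted < 0) | (shifted > max_code + 1)
    if not bad.any():
        out = table[shifted]
        bad = out == -999
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise UnknownCodeError(
            f"code {int(grid.codes[i, j])} at cell ({int(i)}, {int(j)}) "
            "is not in the biome scheme"
        )
    return grid.with_codes(out, level="megabiome")
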