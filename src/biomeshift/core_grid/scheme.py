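"""The 26-biome catalogue and its 9-megabiome grouping.

The mapping ships as a CSV (``data/biome_scheme.csv``) with columns
``code,name,abbreviation,megabiome``.  Megabiomes receive integer codes
1..9 in order of first appearance in the catalogue, so that aggregated
grids remain plain integer rasters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import FormatError

_REQUIRED_COLUMNS = ["code", "name", "abbreviation", "megabiome"]


@dataclass(frozen=True)
class BiomeScheme:
    """Immutable biome -> megabiome classification table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"scheme table missing columns: {missing}")
        if df["code"].duplicated().any():
            raise FormatError("scheme table has duplicate biome codes")
        if df["abbreviation"].duplicated().any():
            raise FormatError("scheme table has duplicate abbreviations")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    # -- catalogue views -------------------------------------------------

    @property
    def biome_codes(self) -> list[int]:
        return [int(c) for c in self.table["code"]]

    @property
    def megabiome_names(self) -> list[str]:
        """Megabiome names, ordered by first appearance (defines their codes)."""
        seen: list[str] = []
        for name in self.table["megabiome"]:
            if name not in seen:
                seen.append(name)
        return seen

    @property
    def n_biomes(self) -> int:
        return len(self.table)

    @property
    def n_megabiomes(self) -> int:
        return len(self.megabiome_names)

    # -- lookups ---------------------------------------------------------

    def code_of(self, abbreviation: str) -> int:
        row = self.table.loc[self.table["abbreviation"] == abbreviation]
        if row.empty:
            raise KeyError(f"unknown biome abbreviation: {abbreviation!r}")
        return int(row["code"].iloc[0])

    def name_of(self, code: int) -> str:
        row = self.table.loc[self.table["code"] == code]
        if row.empty:
            raise KeyError(f"unknown biome code: {code}")
        return str(row["name"].iloc[0])

    def megabiome_of(self, biome_code: int) -> str:
        row = self.table.loc[self.table["code"] == biome_code]
        if row.empty:
            raise KeyError(f"unknown biome code: {biome_code}")
        return str(row["megabiome"].iloc[0])

    def megabiome_code(self, megabiome_name: str) -> int:
        names = self.megabiome_names
        try:
            return names.index(megabiome_name) + 1
        except ValueError:
            raise KeyError(f"unknown megabiome: {megabiome_name!r}") from None

    def megabiome_name_of_code(self, megabiome_code: int) -> str:
        names = self.megabiome_names
        if not 1 <= megabiome_code <= len(names):
            raise KeyError(f"unknown megabiome code: {megabiome_code}")
        return names[megabiome_code - 1]

    def megabiome_lookup(self) -> dict[int, int]:
        """biome code -> megabiome code mapping (total over the catalogue)."""
        return {
            int(code): self.megabiome_code(mega)
            for code, mega in zip(self.table["code"], self.table["megabiome"])
        }

    def codes_at_level(self, level: str) -> list[int]:
        if level == "biome":
            return self.biome_codes
        if level == "megabiome":
            return list(range(1, self.n_megabiomes + 1))
        raise ValueError(f"unknown level: {level!r}")

    def label_at_level(self, code: int, level: str) -> str:
        """Human-readable label for a code at either classification level."""
        if level == "biome":
            return self.name_of(code)
        return self.megabiome_name_of_code(code)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiomeScheme":
        df = pd.read_csv(path)
        return cls(table=df)

    @classmethod
    def default(cls) -> "BiomeScheme":
        return _load_default()


@lru_cache(maxsize=1)
def _load_default() -> BiomeScheme:
    ref = resources.files("biomeshift.core_grid").joinpath("data/biome_scheme.csv")
    with resources.as_file(ref) as path:
        return BiomeScheme.from_csv(path)
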