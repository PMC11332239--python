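"""Named colour categories over the Lab grid.

Every cell of the grid maps to exactly one of ten named plumage colour
categories (blue, purple, red, yellow, green, rufous, brown, grey, white,
black).  Seven of those — blue, brown, green, grey, purple, red, rufous —
additionally carry a light/dark tone tag depending on the lightness bin;
white, black and yellow are defined by their lightness to begin with, so a
light/dark split is not meaningful for them.

The default map is rule-based on the cell centroid's lightness L, chroma
C = sqrt(a^2 + b^2) and hue angle h = atan2(b, a).  It is exported/imported
as a plain CSV of (L_bin, a_bin, b_bin, category, tone) rows so it can be
audited and edited.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ColorHistogram, LabGridSpec

__all__ = [
    "CATEGORIES",
    "SPLITTABLE",
    "CategoryMap",
    "default_category_map",
]

CATEGORIES = (
    "blue", "purple", "red", "yellow", "green",
    "rufous", "brown", "grey", "white", "black",
)
#: colours with a meaningful light/dark distinction
SPLITTABLE = ("blue", "brown", "green", "grey", "purple", "red", "rufous")

# rule thresholds (Lab units / degrees); see docs for rationale.
# The achromatic cutoff must exceed the centroid chroma of the four central
# chromatic cells (~13 on the default grid) so grey/white/black exist.
_ACHROMATIC_CHROMA = 15.0
_BLACK_L_MAX = 25.0
_WHITE_L_MIN = 75.0
_RUFOUS_CHROMA_MIN = 45.0
_YELLOW_L_MIN = 50.0


def _rule_category(L: float, a: float, b: float) -> str:
    chroma = float(np.hypot(a, b))
    hue = float(np.degrees(np.arctan2(b, a))) % 360.0
    if chroma < _ACHROMATIC_CHROMA:
        if L < _BLACK_L_MAX:
            return "black"
        if L >= _WHITE_L_MIN:
            return "white"
        return "grey"
    if hue >= 330.0 or hue < 25.0:
        return "red"
    if hue < 70.0:  # warm orange hues: saturated -> rufous, muted -> brown
        return "rufous" if chroma >= _RUFOUS_CHROMA_MIN else "brown"
    if hue < 110.0:  # yellow hues: dark yellows read as brown
        return "yellow" if L >= _YELLOW_L_MIN else "brown"
    if hue < 180.0:
        return "green"
    if hue < 280.0:
        return "blue"
    return "purple"


@dataclass
class CategoryMap:
    """Total mapping from grid cells to named categories and tones.

    ``table`` has one row per grid cell with columns
    (L_bin, a_bin, b_bin, category, tone); tone is 'light'/'dark' for the
    seven splittable colours and empty otherwise.
    """

    table: pd.DataFrame
    grid: LabGridSpec

    def __post_init__(self) -> None:
        required = {"L_bin", "a_bin", "b_bin", "category", "tone"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"category map missing columns: {sorted(missing)}")
        if len(self.table) != self.grid.total_cells:
            raise ValueError(
                f"category map covers {len(self.table)} cells, grid has {self.grid.total_cells}"
            )
        key = self.table[["L_bin", "a_bin", "b_bin"]].to_numpy()
        if len(np.unique(key, axis=0)) != self.grid.total_cells:
            raise ValueError("category map must list every grid cell exactly once")
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories in map: {sorted(bad)}")
        self._lookup = {
            (int(r.L_bin), int(r.a_bin), int(r.b_bin)): (r.category, r.tone or None)
            for r in self.table.itertuples()
        }

    def category_of(self, cell: tuple[int, int, int]) -> str:
        try:
            return self._lookup[tuple(int(c) for c in cell)][0]
        except KeyError:
            raise KeyError(f"grid cell {tuple(cell)} is not covered by the category map") from None

    def tone_of(self, cell: tuple[int, int, int]) -> str | None:
        try:
            return self._lookup[tuple(int(c) for c in cell)][1]
        except KeyError:
            raise KeyError(f"grid cell {tuple(cell)} is not covered by the category map") from None

    def cells_of(self, category: str) -> np.ndarray:
        sub = self.table[self.table["category"] == category]
        return sub[["L_bin", "a_bin", "b_bin"]].to_numpy(dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, grid: LabGridSpec | None = None) -> "CategoryMap":
        table = pd.read_csv(path, keep_default_na=False)
        return cls(table=table, grid=grid or LabGridSpec())


@lru_cache(maxsize=8)
def _default_map_cached(grid: LabGridSpec) -> CategoryMap:
    cells = grid.all_cells()
    cents = grid.cell_centroid(cells)
    L_mid = 0.5 * (grid.L_range[0] + grid.L_range[1])
    rows = []
    for (iL, ia, ib), (L, a, b) in zip(cells, cents):
        cat = _rule_category(L, a, b)
        # dark = lower half of the lightness bins, light = upper half
        tone = ("dark" if L < L_mid else "light") if cat in SPLITTABLE else ""
        rows.append((int(iL), int(ia), int(ib), cat, tone))
    table = pd.DataFrame(rows, columns=["L_bin", "a_bin", "b_bin", "category", "tone"])
    return CategoryMap(table=table, grid=grid)


def default_category_map(grid: LabGridSpec | None = None) -> CategoryMap:
    """The package's rule-based default category map for a given grid."""
    return _default_map_cached(grid or LabGridSpec())


def categorize(hist: ColorHistogram, cmap: CategoryMap | None = None) -> dict[str, float]:
    """Aggregate an occupied-cell histogram to named-category proportions.

    Returns all ten categories (zeros included); the values sum to 1.
    """
    cmap = cmap or default_category_map(hist.grid)
    out = {c: 0.0 for c in CATEGORIES}
    for cell, p in zip(hist.cells, hist.proportions):
        out[cmap.category_of(tuple(cell))] += float(p)
    return out


def split_light_dark(hist: ColorHistogram, cmap: CategoryMap | None = None) -> dict[str, float]:
    """Light/dark sub-proportions for the seven splittable colours.

    Keys are e.g. ``blue_light`` / ``blue_dark``; for each splittable colour
    light + dark equals the category total from :func:`categorize`.
    """
    cmap = cmap or default_category_map(hist.grid)
    out = {f"{c}_{t}": 0.0 for c in SPLITTABLE for t in ("light", "dark")}
    for cell, p in zip(hist.cells, hist.proportions):
        cell = tuple(cell)
        cat = cmap.category_of(cell)
        tone = cmap.tone_of(cell)
        if tone:
            out[f"{cat}_{tone}"] += float(p)
    return out
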