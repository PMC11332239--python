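"""CIELAB colour grid: bin specification, pixel binning and histograms.

The colour space is divided into a regular 3-D grid: the two chromatic axes
(a: green-red, b: blue-yellow) into ``a_bins`` x ``b_bins`` cells and the
achromatic axis (L: lightness, 0-100) into ``L_bins`` slabs.  Each occupied
cell of the grid is a "colour locus"; the histogram of foreground-pixel
proportions over loci is the basic colour description of a plumage image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["LabGridSpec", "ColorHistogram", "build_histogram"]


@dataclass(frozen=True)
class LabGridSpec:
    """Regular binning of CIELAB space.

    Defaults give 12 x 12 chromatic bins and 4 lightness bins, i.e. 576
    cells.  Bins are half-open ``[lo, hi)`` except the last bin on each
    axis, which is closed so the axis maximum is representable.  Pixels
    outside the chromatic ranges are clamped to the edge bins (and counted,
    see :func:`build_histogram`); the default ``[-110, 110]`` ranges cover
    the whole sRGB gamut.
    """

    a_bins: int = 12
    b_bins: int = 12
    L_bins: int = 4
    a_range: tuple[float, float] = (-110.0, 110.0)
    b_range: tuple[float, float] = (-110.0, 110.0)
    L_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if min(self.a_bins, self.b_bins, self.L_bins) < 1:
            raise ValueError("all bin counts must be >= 1")
        for lo, hi in (self.a_range, self.b_range, self.L_range):
            if not hi > lo:
                raise ValueError("each range must satisfy hi > lo")

    @property
    def total_cells(self) -> int:
        return self.a_bins * self.b_bins * self.L_bins

    def axis_edges(self, axis: str) -> np.ndarray:
        n, (lo, hi) = {
            "L": (self.L_bins, self.L_range),
            "a": (self.a_bins, self.a_range),
            "b": (self.b_bins, self.b_range),
        }[axis]
        return np.linspace(lo, hi, n + 1)

    def _axis_index(self, x: np.ndarray, axis: str) -> tuple[np.ndarray, int]:
        n, (lo, hi) = {
            "L": (self.L_bins, self.L_range),
            "a": (self.a_bins, self.a_range),
            "b": (self.b_bins, self.b_range),
        }[axis]
        width = (hi - lo) / n
        idx = np.floor((np.asarray(x, dtype=float) - lo) / width).astype(np.int64)
        n_out = int(np.count_nonzero((idx < 0) | (idx > n - 1)))
        # x == hi lands in index n and is folded into the closed last bin,
        # which is not an out-of-range event
        n_out -= int(np.count_nonzero(np.asarray(x) == hi))
        return np.clip(idx, 0, n - 1), max(n_out, 0)

    def cell_index(self, lab: np.ndarray) -> tuple[np.ndarray, int]:
        """Map Lab triples (n, 3) to integer cell triples (n, 3) = (iL, ia, ib).

        Returns the index array and the number of out-of-range pixels that
        were clamped to edge bins.
        """
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        iL, oL = self._axis_index(lab[:, 0], "L")
        ia, oa = self._axis_index(lab[:, 1], "a")
        ib, ob = self._axis_index(lab[:, 2], "b")
        return np.column_stack([iL, ia, ib]), oL + oa + ob

    def cell_centroid(self, cells: np.ndarray) -> np.ndarray:
        """Lab coordinates of cell centres for (n, 3) index triples."""
        cells = np.atleast_2d(np.asarray(cells, dtype=np.int64))
        out = np.empty((len(cells), 3), dtype=float)
        for j, axis in enumerate(("L", "a", "b")):
            edges = self.axis_edges(axis)
            out[:, j] = 0.5 * (edges[cells[:, j]] + edges[cells[:, j] + 1])
        return out

    def all_cells(self) -> np.ndarray:
        """All (iL, ia, ib) triples in lexicographic order."""
        iL, ia, ib = np.meshgrid(
            np.arange(self.L_bins), np.arange(self.a_bins), np.arange(self.b_bins),
            indexing="ij",
        )
        return np.column_stack([iL.ravel(), ia.ravel(), ib.ravel()])


@dataclass
class ColorHistogram:
    """Occupied-cell histogram of one image's foreground pixels.

    ``cells`` holds the occupied (iL, ia, ib) triples sorted lexicographically,
    ``counts`` the pixel counts per occupied cell.  Proportions are counts
    normalised by the foreground total.
    """

    cells: np.ndarray
    counts: np.ndarray
    grid: LabGridSpec = field(default_factory=LabGridSpec)

    def __post_init__(self) -> None:
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=np.int64))
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.cells) != len(self.counts):
            raise ValueError("cells and counts must have equal length")
        if np.any(self.counts <= 0):
            raise ValueError("occupied cells must have positive counts")
        order = np.lexsort((self.cells[:, 2], self.cells[:, 1], self.cells[:, 0]))
        self.cells = self.cells[order]
        self.counts = self.counts[order]

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def n_occupied(self) -> int:
        return len(self.counts)

    def centroids(self) -> np.ndarray:
        return self.grid.cell_centroid(self.cells)

    def mean_color(self) -> np.ndarray:
        """Proportion-weighted mean Lab colour over occupied cell centroids."""
        return self.proportions @ self.centroids()

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        p = self.proportions
        return {tuple(c): float(p[i]) for i, c in enumerate(self.cells)}


def build_histogram(lab_pixels: np.ndarray, grid: LabGridSpec | None = None) -> ColorHistogram:
    """Bin foreground Lab pixels into the grid.

    Out-of-range pixels are clamped to edge bins, still counted, and the
    clamp count is logged at WARNING level.
    """
    grid = grid or LabGridSpec()
    lab_pixels = np.atleast_2d(np.asarray(lab_pixels, dtype=float))
    if lab_pixels.size == 0:
        raise ValueError("cannot build a histogram from zero pixels")
    idx, n_clamped = grid.cell_index(lab_pixels)
    if n_clamped:
        logger.warning("%d pixel coordinate(s) outside grid ranges clamped to edge bins", n_clamped)
    flat = (idx[:, 0] * grid.a_bins + idx[:, 1]) * grid.b_bins + idx[:, 2]
    uniq, counts = np.unique(flat, return_counts=True)
    cells = np.column_stack([
        uniq // (grid.a_bins * grid.b_bins),
        (uniq // grid.b_bins) % grid.a_bins,
        uniq % grid.b_bins,
    ])
    return ColorHistogram(cells=cells, counts=counts, grid=grid)
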