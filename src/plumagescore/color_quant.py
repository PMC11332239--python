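"""Plumage image quantification: sRGB -> CIELAB -> colour loci -> metrics.

The pipeline per image is: convert the masked foreground pixels to CIELAB
(sRGB -> XYZ under D65 -> Lab), bin them into the 3-D colour grid, aggregate
occupied cells ("colour loci") into named categories with light/dark
variants, and compute two scalar summaries:

* colour diversity — the number of occupied loci;
* colour elaboration — the proportion-weighted mean Euclidean Lab distance
  (Delta-E*ab) between the species' loci and the global average colour of
  the whole panel, which for real birds is a brown-grey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2lab

from .categories import CATEGORIES, SPLITTABLE, CategoryMap, categorize, default_category_map, split_light_dark
from .grid import ColorHistogram, LabGridSpec, build_histogram

__all__ = [
    "PlumageImage",
    "ColorProfile",
    "rgb_to_lab",
    "quantify_image",
    "colour_diversity",
    "colour_elaboration",
    "panel_mean_color",
    "profile_panel",
    "profiles_to_frame",
]


@dataclass
class PlumageImage:
    """One illustrated bird: 8-bit RGB raster plus boolean foreground mask."""

    rgb: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = bird
    species_id: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.dtype != np.uint8:
            raise ValueError("rgb must be an (H, W, 3) uint8 array")
        if self.mask.shape != self.rgb.shape[:2]:
            raise ValueError("mask shape must match image shape")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def foreground_rgb(self) -> np.ndarray:
        return self.rgb[self.mask]

    def save_png(self, path: str | Path) -> None:
        """Write as RGBA PNG; the alpha channel encodes the mask."""
        alpha = np.where(self.mask, 255, 0).astype(np.uint8)
        rgba = np.dstack([self.rgb, alpha])
        Image.fromarray(rgba, mode="RGBA").save(path, format="PNG")

    @classmethod
    def load(cls, path: str | Path, mask_path: str | Path | None = None,
             species_id: str | None = None, sex: str | None = None) -> "PlumageImage":
        """Read PNG/TIFF; the mask comes from the alpha channel or a
        separate single-channel image (non-zero = foreground)."""
        im = Image.open(path)
        arr = np.asarray(im.convert("RGBA"))
        rgb = arr[..., :3].copy()
        if mask_path is not None:
            mask = np.asarray(Image.open(mask_path).convert("L")) > 0
        elif im.mode in ("RGBA", "LA", "PA") or "transparency" in im.info:
            mask = arr[..., 3] > 0
        else:
            mask = np.ones(rgb.shape[:2], dtype=bool)
        return cls(rgb=rgb, mask=mask, species_id=species_id, sex=sex)


def rgb_to_lab(image: PlumageImage | np.ndarray) -> np.ndarray:
    """CIELAB triples of the foreground pixels of an image.

    Accepts a :class:`PlumageImage` or a bare (n, 3) uint8 pixel array.
    The conversion is sRGB -> XYZ (D65 white point) -> CIELAB, so white
    (255,255,255) maps to L=100, a=b~0 and black to L=0.
    """
    if isinstance(image, PlumageImage):
        pixels = image.foreground_rgb()
        if pixels.size == 0:
            raise ValueError("image has no foreground pixels")
    else:
        pixels = np.asarray(image)
    if pixels.dtype != np.uint8:
        raise ValueError("expected 8-bit sRGB input")
    return rgb2lab(pixels.reshape(-1, 1, 3) / 255.0).reshape(-1, 3)


def colour_diversity(hist: ColorHistogram, min_proportion: float = 0.0) -> int:
    """Number of occupied colour loci.

    ``min_proportion`` optionally suppresses near-empty cells (e.g.
    anti-aliasing speckle); the default of 0 counts every occupied cell.
    """
    if min_proportion <= 0.0:
        return hist.n_occupied
    return int(np.count_nonzero(hist.proportions > min_proportion))


def colour_elaboration(hist: ColorHistogram, global_mean: np.ndarray,
                       weighted: bool = True) -> float:
    """Mean Euclidean Lab distance from the histogram's loci to ``global_mean``.

    With ``weighted=True`` (default) each locus contributes in proportion to
    its pixel share; otherwise all occupied loci count equally.  Zero iff
    all colour mass sits exactly at the global mean.
    """
    global_mean = np.asarray(global_mean, dtype=float)
    if global_mean.shape != (3,):
        raise ValueError("global_mean must be a Lab triple")
    d = np.linalg.norm(hist.centroids() - global_mean, axis=1)
    if weighted:
        return float(hist.proportions @ d)
    return float(d.mean())


@dataclass
class ColorProfile:
    """Full colour description of one species x sex image."""

    species_id: str | None
    sex: str | None
    categories: dict[str, float]
    tones: dict[str, float]
    colour_diversity: int
    colour_elaboration: float
    mean_color: np.ndarray
    histogram: ColorHistogram = field(repr=False)

    def as_row(self) -> dict[str, float | int | str | None]:
        row: dict = {"species_id": self.species_id, "sex": self.sex}
        row.update(self.categories)
        row.update(self.tones)
        row["colour_diversity"] = self.colour_diversity
        row["colour_elaboration"] = self.colour_elaboration
        return row


def quantify_image(image: PlumageImage, grid: LabGridSpec | None = None,
                   cmap: CategoryMap | None = None) -> ColorHistogram:
    """Histogram of one image's foreground over the Lab grid."""
    grid = grid or LabGridSpec()
    return build_histogram(rgb_to_lab(image), grid)


def panel_mean_color(hists: Sequence[ColorHistogram]) -> np.ndarray:
    """Global average colour of a panel: the unweighted mean over images of
    each image's proportion-weighted mean Lab colour."""
    if not hists:
        raise ValueError("panel is empty")
    return np.mean([h.mean_color() for h in hists], axis=0)


def profile_panel(images: Iterable[PlumageImage], grid: LabGridSpec | None = None,
                  cmap: CategoryMap | None = None, weighted_elaboration: bool = True,
                  global_mean: np.ndarray | None = None) -> list[ColorProfile]:
    """Quantify a whole panel of images.

    Elaboration needs the panel-wide average colour, so the panel is
    processed in two passes: histograms first, then per-image metrics
    against the shared global mean (which may also be supplied explicitly).
    """
    grid = grid or LabGridSpec()
    cmap = cmap or default_category_map(grid)
    images = list(images)
    hists = [quantify_image(im, grid, cmap) for im in images]
    if global_mean is None:
        global_mean = panel_mean_color(hists)
    profiles = []
    for im, h in zip(images, hists):
        profiles.append(ColorProfile(
            species_id=im.species_id,
            sex=im.sex,
            categories=categorize(h, cmap),
            tones=split_light_dark(h, cmap),
            colour_diversity=colour_diversity(h),
            colour_elaboration=colour_elaboration(h, global_mean, weighted=weighted_elaboration),
            mean_color=h.mean_color(),
            histogram=h,
        ))
    return profiles


def profiles_to_frame(profiles: Sequence[ColorProfile]) -> pd.DataFrame:
    """Tabulate profiles as one row per species x sex."""
    return pd.DataFrame([p.as_row() for p in profiles])
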