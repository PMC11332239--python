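"""Synthetic taxonomies, plumage images, traits and crowd ratings.

Everything downstream of this module (colour quantification, consensus
scoring, the beta mixed models) is tested against data generated here with
known ground truth: known per-image colour composition, known rater/photo
effects, and attractiveness drawn from the same beta mixed-model structure
the fitting code assumes.

Random streams are split per sub-generator with ``SeedSequence.spawn`` so
that, e.g., adding photos never perturbs the taxonomy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import lab2rgb

from .categories import CATEGORIES, CategoryMap, default_category_map
from .color_quant import PlumageImage, quantify_image, rgb_to_lab
from .grid import ColorHistogram, LabGridSpec, build_histogram

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomySpec",
    "generate_taxonomy",
    "representative_colors",
    "generate_plumage_image",
    "simulate_species_traits",
    "simulate_colour_mixes",
    "simulate_attractiveness",
    "simulate_ratings",
    "AttractivenessTruth",
    "SimulatedRatings",
]

TAXONOMIC_LEVELS = ("order", "family", "genus", "species_id")


# ---------------------------------------------------------------------------
# taxonomy

@dataclass(frozen=True)
class TaxonomySpec:
    """Shape of a synthetic taxonomy.

    Counts may be fixed integers or inclusive ``(lo, hi)`` ranges sampled
    per parent.  ``dichromatic_fraction`` of species get separate male and
    female records; the rest get a single 'undefined' record, mirroring how
    sex-specific plumage scores exist only for dichromatic species.
    """

    n_orders: int = 3
    families_per_order: int | tuple[int, int] = 2
    genera_per_family: int | tuple[int, int] = 2
    species_per_genus: int | tuple[int, int] = 3
    dichromatic_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_orders", "families_per_order", "genera_per_family", "species_per_genus"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, tuple) else v
            hi = v[1] if isinstance(v, tuple) else v
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if not 0.0 <= self.dichromatic_fraction <= 1.0:
            raise ValueError("dichromatic_fraction must lie in [0, 1]")


def _resolve(v: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(v, tuple):
        return int(rng.integers(v[0], v[1] + 1))
    return int(v)


def generate_taxonomy(spec: TaxonomySpec) -> pd.DataFrame:
    """One row per species x sex with a full Order/Family/Genus path.

    Genus, family and order labels are globally unique, so nesting is
    implicit in the coding.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []
    i_fam = i_gen = i_sp = 0
    for i_ord in range(spec.n_orders):
        order = f"ord{i_ord + 1:02d}"
        for _ in range(_resolve(spec.families_per_order, rng)):
            family = f"fam{(i_fam := i_fam + 1):03d}"
            for _ in range(_resolve(spec.genera_per_family, rng)):
                genus = f"gen{(i_gen := i_gen + 1):04d}"
                for _ in range(_resolve(spec.species_per_genus, rng)):
                    species = f"sp{(i_sp := i_sp + 1):05d}"
                    dichromatic = bool(rng.random() < spec.dichromatic_fraction)
                    sexes = ("male", "female") if dichromatic else ("undefined",)
                    for sex in sexes:
                        rows.append((order, family, genus, species, sex, dichromatic))
    return pd.DataFrame(rows, columns=["order", "family", "genus", "species_id", "sex", "dichromatic"])


# ---------------------------------------------------------------------------
# plumage images

@lru_cache(maxsize=8)
def _representative_cells(grid: LabGridSpec) -> dict[tuple[str, str], list[tuple[int, int, int]]]:
    """Verified sRGB colours per (category, tone).

    A candidate is a grid-cell centroid converted to 8-bit sRGB; it is kept
    only if converting that sRGB value back to Lab bins into a cell of the
    same category (and tone, where applicable), so painted pixels are
    guaranteed to land where intended despite gamut clipping.  Candidates
    are ordered by chroma then centrality in L, so the most gamut-safe,
    most typical colours come first.
    """
    cmap = default_category_map(grid)
    cents = grid.cell_centroid(cmap.table[["L_bin", "a_bin", "b_bin"]].to_numpy())
    chroma = np.hypot(cents[:, 1], cents[:, 2])
    order = np.lexsort((np.abs(cents[:, 0] - 50.0), chroma))
    out: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for i in order:
        row = cmap.table.iloc[int(i)]
        cell = (int(row.L_bin), int(row.a_bin), int(row.b_bin))
        cat, tone = row.category, (row.tone or None)
        rgb = _lab_cell_to_srgb(grid, cell)
        if rgb is None:
            continue
        lab_back = rgb_to_lab(np.array([rgb], dtype=np.uint8))
        cell_back, _ = grid.cell_index(lab_back)
        cell_back = tuple(int(c) for c in cell_back[0])
        if cmap.category_of(cell_back) != cat or cmap.tone_of(cell_back) != tone:
            continue
        for key in ((cat, tone or ""), (cat, "any")):
            lst = out.setdefault(key, [])
            if rgb not in lst:
                lst.append(rgb)
    return out


def _lab_cell_to_srgb(grid: LabGridSpec, cell: tuple[int, int, int]) -> tuple[int, int, int] | None:
    lab = grid.cell_centroid(np.array([cell]))[0]
    # out-of-gamut clipping is expected here; validity is enforced by the
    # round-trip check in _representative_cells
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rgb = lab2rgb(lab.reshape(1, 1, 3)).reshape(3)
    if np.any(~np.isfinite(rgb)):
        return None
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return (int(rgb8[0]), int(rgb8[1]), int(rgb8[2]))


def representative_colors(grid: LabGridSpec | None = None, tone: str = "any",
                          n_per_category: int = 1) -> dict[str, list[tuple[int, int, int]]]:
    """Up to ``n_per_category`` round-trip-verified sRGB colours per category.

    ``tone`` may be 'any', 'light' or 'dark' (tone-restricted lists exist
    only for the splittable colours).
    """
    grid = grid or LabGridSpec()
    if tone not in ("any", "light", "dark", ""):
        raise ValueError("tone must be 'any', 'light' or 'dark'")
    table = _representative_cells(grid)
    out: dict[str, list[tuple[int, int, int]]] = {}
    for cat in CATEGORIES:
        colors = table.get((cat, tone), [])
        if colors:
            out[cat] = list(colors[:n_per_category])
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``weights``."""
    ideal = weights / weights.sum() * total
    counts = np.floor(ideal).astype(int)
    frac = ideal - counts
    short = total - counts.sum()
    for i in np.argsort(-frac, kind="stable")[:short]:
        counts[i] += 1
    return counts


def generate_plumage_image(
    category_mix: Mapping[str, float],
    layout: str = "stripe",
    size: int | tuple[int, int] = 32,
    seed: int = 0,
    grid: LabGridSpec | None = None,
    colors_per_category: int = 1,
    species_id: str | None = None,
    sex: str | None = None,
) -> tuple[PlumageImage, ColorHistogram]:
    """Emit an image whose foreground realises a requested category mix.

    Foreground is everything inside a 1-pixel transparent border.  Each
    category is painted with up to ``colors_per_category`` representative
    sRGB colours chosen at Lab cell centroids and verified by round-trip
    conversion, so pixel counts per category match the mix to within one
    pixel of rounding.  Returns the image together with its expected
    histogram (the exact binning of the emitted foreground).
    """
    grid = grid or LabGridSpec()
    if not category_mix:
        raise ValueError("category_mix is empty")
    unknown = set(category_mix) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown colour categories: {sorted(unknown)}")
    weights = np.array([category_mix[c] for c in category_mix], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("category_mix must be a simplex (non-negative, summing to 1)")
    if layout not in ("stripe", "blob"):
        raise ValueError("layout must be 'stripe' or 'blob'")

    H, W = (size, size) if isinstance(size, int) else size
    if H < 3 or W < 3:
        raise ValueError("image must be at least 3x3 to hold a foreground")
    mask = np.zeros((H, W), dtype=bool)
    mask[1:-1, 1:-1] = True
    n_fg = int(mask.sum())

    reps = representative_colors(grid, n_per_category=colors_per_category)
    cats = [c for c in category_mix if category_mix[c] > 0]
    missing = [c for c in cats if c not in reps]
    if missing:
        raise ValueError(f"no in-gamut representative colour for: {missing}")
    # split each category's pixel share over its representative colours
    cat_counts = _largest_remainder(np.array([category_mix[c] for c in cats]), n_fg)
    colors: list[tuple[int, int, int]] = []
    counts: list[int] = []
    for c, n_c in zip(cats, cat_counts):
        cols = reps[c]
        for col, n_col in zip(cols, _largest_remainder(np.ones(len(cols)), n_c)):
            if n_col > 0:
                colors.append(col)
                counts.append(int(n_col))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    fg_idx = np.flatnonzero(mask.ravel())
    if layout == "blob":
        # grow each colour patch outward from a random seed pixel
        rows, cols_ = np.unravel_index(fg_idx, (H, W))
        assigned = np.full(n_fg, -1, dtype=int)
        seeds = rng.integers(0, n_fg, size=len(colors))
        for k in np.argsort(-np.asarray(counts), kind="stable"):
            d = np.hypot(rows - rows[seeds[k]], cols_ - cols_[seeds[k]])
            free = np.flatnonzero(assigned < 0)
            take = free[np.argsort(d[free], kind="stable")[: counts[k]]]
            assigned[take] = k
    else:
        assigned = np.repeat(np.arange(len(colors)), counts)

    flat = np.zeros((H * W, 3), dtype=np.uint8)
    palette = np.array(colors, dtype=np.uint8)
    flat[fg_idx] = palette[assigned]
    image = PlumageImage(rgb=flat.reshape(H, W, 3), mask=mask, species_id=species_id, sex=sex)
    expected = build_histogram(rgb_to_lab(image), grid)
    return image, expected


# ---------------------------------------------------------------------------
# species traits and colour mixes

def simulate_species_traits(taxonomy: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Species-level morphology/ecology table emulating a trait database.

    Body mass is log-normal; beak and tail lengths follow allometric power
    laws of mass with log-normal noise; crest is an ordinal 0-3 score;
    range size is log-normal, the range-centroid latitude uniform, and the
    conservation/trophic/migration labels use raw vocabularies that the
    trait-preparation step must reclassify.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    species = taxonomy.drop_duplicates("species_id")[["order", "family", "genus", "species_id"]]
    n = len(species)
    mass = np.exp(rng.normal(np.log(50.0), 1.0, n))
    beak = 2.2 * mass ** 0.35 * np.exp(rng.normal(0.0, 0.15, n))
    tail = 7.5 * mass ** 0.33 * np.exp(rng.normal(0.0, 0.20, n))
    crest = rng.choice([0, 1, 2, 3], size=n, p=[0.70, 0.15, 0.10, 0.05])
    range_size = np.exp(rng.normal(np.log(3e5), 1.5, n))
    latitude = rng.uniform(-60.0, 70.0, n)
    iucn = rng.choice(
        ["Least Concern", "Near Threatened", "Vulnerable", "Endangered",
         "Critically Endangered", "Data Deficient", "Not Evaluated"],
        size=n, p=[0.60, 0.12, 0.10, 0.07, 0.04, 0.04, 0.03])
    trophic = rng.choice(
        ["predator", "scavenger", "invertivore", "omnivore", "herbivore",
         "frugivore", "granivore", "nectarivore"],
        size=n, p=[0.10, 0.03, 0.30, 0.22, 0.10, 0.10, 0.10, 0.05])
    migration = rng.choice(["resident", "partial migrant", "full migrant"],
                           size=n, p=[0.55, 0.25, 0.20])
    out = species.copy().reset_index(drop=True)
    out["body_mass"] = mass
    out["beak_length"] = beak
    out["tail_length"] = tail
    out["crest"] = crest
    out["range_size"] = range_size
    out["latitude"] = latitude
    out["iucn_raw"] = iucn
    out["trophic_raw"] = trophic
    out["migration_raw"] = migration
    return out


#: Dirichlet concentration of the plumage mix; dull colours dominate, as in
#: real birds where grey/black/white/brown are the most common categories.
_BASE_ALPHA = {
    "brown": 4.0, "grey": 4.0, "black": 3.0, "white": 3.0, "rufous": 1.0,
    "yellow": 0.4, "red": 0.3, "blue": 0.3, "green": 0.4, "purple": 0.2,
}
#: extra weight on showy colours for males of dichromatic species
_MALE_BONUS = {"blue": 1.0, "red": 1.0, "yellow": 0.6, "green": 0.5, "purple": 0.3}


def simulate_colour_mixes(taxonomy: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """True colour-category proportions per species x sex (a simplex row)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    rows = []
    for r in taxonomy.itertuples():
        alpha = np.array([_BASE_ALPHA[c] for c in CATEGORIES])
        if r.sex == "male":
            alpha = alpha + np.array([_MALE_BONUS.get(c, 0.0) for c in CATEGORIES])
        mix = rng.dirichlet(alpha)
        rows.append({"species_id": r.species_id, "sex": r.sex,
                     **{c: float(p) for c, p in zip(CATEGORIES, mix)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# attractiveness (the beta mixed-model data-generating process)

@dataclass
class AttractivenessTruth:
    """Simulated response plus every latent quantity needed for recovery tests."""

    frame: pd.DataFrame  # input rows + eta, mu, response
    random_effects: dict[str, pd.Series]
    coefficients: dict[str, float]
    intercept: float
    sigmas: dict[str, float]
    phi: float


def simulate_attractiveness(
    traits: pd.DataFrame,
    coefficients: Mapping[str, float],
    sigmas: Mapping[str, float] | None = None,
    phi: float = 30.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> AttractivenessTruth:
    """Draw attractiveness responses from the beta mixed model.

    ``logit(mu) = intercept + X beta + b_order + b_family + b_genus + b_species``
    with ``y ~ Beta(mu * phi, (1 - mu) * phi)``.  ``coefficients`` maps
    column names of ``traits`` (assumed already standardized) to betas;
    ``sigmas`` maps taxonomic level names to random-intercept SDs.  Draw
    order is fixed (one normal vector per level in taxonomic order, levels
    sorted, then one beta vector) so an independent script can reproduce
    the exact draws from the same seed.
    """
    sigmas = dict(sigmas or {})
    if any(s < 0 for s in sigmas.values()):
        raise ValueError("random-intercept SDs must be >= 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    eta = np.full(len(traits), float(intercept))
    for name, beta in coefficients.items():
        eta = eta + beta * traits[name].to_numpy(dtype=float)
    random_effects: dict[str, pd.Series] = {}
    for level in TAXONOMIC_LEVELS:
        sd = sigmas.get(level, 0.0)
        if level not in traits.columns:
            if sd > 0:
                raise ValueError(f"sigma given for '{level}' but column is missing")
            continue
        labels = np.unique(traits[level].to_numpy())
        b = rng.normal(0.0, sd, len(labels)) if sd > 0 else np.zeros(len(labels))
        eff = pd.Series(b, index=labels)
        random_effects[level] = eff
        eta = eta + eff.loc[traits[level]].to_numpy()
    mu = 1.0 / (1.0 + np.exp(-eta))
    n_clamped = int(np.count_nonzero((mu < 1e-6) | (mu > 1 - 1e-6)))
    if n_clamped:
        logger.warning("%d simulated mean(s) clamped away from the (0,1) boundary", n_clamped)
    mu = np.clip(mu, 1e-6, 1 - 1e-6)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-10, 1 - 1e-10)
    frame = traits.copy()
    frame["eta_true"] = eta
    frame["mu_true"] = mu
    frame["response"] = y
    return AttractivenessTruth(frame=frame, random_effects=random_effects,
                               coefficients=dict(coefficients), intercept=float(intercept),
                               sigmas=sigmas, phi=float(phi))


# ---------------------------------------------------------------------------
# crowd ratings

@dataclass
class SimulatedRatings:
    """Ratings table plus the latent photo and rater effects behind it."""

    ratings: pd.DataFrame
    photos: pd.DataFrame
    raters: pd.DataFrame


def _truncated_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int, size: int) -> np.ndarray:
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = rng.poisson(lam, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def simulate_ratings(
    truth: pd.DataFrame,
    n_raters: int = 100,
    mean_photos: float = 5.0,
    photo_range: tuple[int, int] = (1, 15),
    ratings_per_photo: int = 6,
    quality_effect: float = 0.0,
    language_effects: Mapping[str, float] | None = None,
    photo_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SimulatedRatings:
    """Emit integer 1-10 crowd ratings for each species x sex.

    ``truth`` must carry species_id, sex and a ``response`` column in (0,1);
    the latent mean rating of a species x sex is ``1 + 9 * response``.  Each
    species x sex gets a truncated-Poisson number of photos (default mean 5,
    range 1-15, emulating a crowd-rating photo pool), each photo a quality
    score 1-5 (skewed high, since real pools prioritise good photos) and a
    Gaussian photo effect; each rating adds a rater-language effect, a
    photo-quality effect proportional to (quality - 5), and Gaussian noise,
    then rounds and clips to the 1-10 scale.
    """
    if n_raters < 1 or ratings_per_photo < 1:
        raise ValueError("n_raters and ratings_per_photo must be >= 1")
    if photo_range[0] < 1 or photo_range[1] < photo_range[0]:
        raise ValueError("photo_range must satisfy 1 <= lo <= hi")
    language_effects = dict(language_effects or {"en": 0.0})
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])

    langs = sorted(language_effects)
    rater_lang = rng.choice(langs, size=n_raters)
    raters = pd.DataFrame({
        "rater_id": [f"r{i + 1:05d}" for i in range(n_raters)],
        "language": rater_lang,
        "effect": [language_effects[l] for l in rater_lang],
    })

    n_photos = _truncated_poisson(rng, mean_photos, *photo_range, size=len(truth))
    photo_rows = []
    for (row, k) in zip(truth.itertuples(), n_photos):
        for _ in range(k):
            photo_rows.append((f"p{len(photo_rows) + 1:06d}", row.species_id, row.sex,
                               1.0 + 9.0 * row.response))
    photos = pd.DataFrame(photo_rows, columns=["photo_id", "species_id", "sex", "true_mean"])
    photos["quality"] = rng.choice([1, 2, 3, 4, 5], size=len(photos),
                                   p=[0.05, 0.10, 0.20, 0.30, 0.35])
    photos["photo_effect"] = rng.normal(0.0, photo_sd, len(photos)) if photo_sd > 0 else 0.0

    idx = rng.integers(0, n_raters, size=(len(photos), ratings_per_photo))
    noise = rng.normal(0.0, noise_sd, size=idx.shape) if noise_sd > 0 else np.zeros(idx.shape)
    rec = []
    rater_ids = raters["rater_id"].to_numpy()
    rater_eff = raters["effect"].to_numpy()
    languages = raters["language"].to_numpy()
    for j, photo in enumerate(photos.itertuples()):
        base = photo.true_mean + quality_effect * (photo.quality - 5) + photo.photo_effect
        for t in range(ratings_per_photo):
            r = idx[j, t]
            value = base + rater_eff[r] + noise[j, t]
            rec.append((rater_ids[r], languages[r], photo.photo_id, photo.quality,
                        photo.species_id, photo.sex, int(np.clip(np.round(value), 1, 10))))
    ratings = pd.DataFrame(rec, columns=[
        "rater_id", "rater_language", "photo_id", "photo_quality",
        "species_id", "sex", "rating"])
    return SimulatedRatings(ratings=ratings, photos=photos, raters=raters)
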