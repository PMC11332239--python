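"""End-to-end orchestration: scenario -> images -> consensus -> models.

A single YAML config drives the whole chain.  In simulation mode the
pipeline generates a taxonomy, species traits and true colour mixes, paints
one plumage image per species x sex, quantifies the images, simulates crowd
ratings from attractiveness drawn under the beta mixed model, estimates
consensus scores, prepares the predictor table and fits the model battery.
Every output is written under the configured directory together with a
manifest (seed, versions, row counts, SHA-256 checksums) so reruns are
verifiably deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta_glmm import MODEL_NAMES, run_model_battery, validate
from .categories import CATEGORIES, default_category_map
from .color_quant import PlumageImage, profile_panel, profiles_to_frame
from .consensus import fit_consensus
from .grid import LabGridSpec
from .synthetic import (TaxonomySpec, generate_plumage_image, generate_taxonomy,
                        simulate_attractiveness, simulate_colour_mixes,
                        simulate_ratings, simulate_species_traits)
from .trait_prep import (collinearity_screen, reclassify_iucn, reclassify_migration,
                         reclassify_trophic, relative_ornament, transform_and_scale)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "grouped_summary"]

_DEFAULT_COEFFICIENTS = {
    "colour_elaboration": 0.5, "blue": 0.3, "red": 0.3, "black": -0.2,
    "white": -0.1, "body_mass": -0.3, "crest": 0.2, "rel_tail": 0.2,
}
_DEFAULT_SIGMAS = {"order": 0.3, "family": 0.2, "genus": 0.2, "species_id": 0.1}


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (one YAML file)."""

    seed: int = 0
    output_dir: str = "plumagescore_out"
    scenario: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None  # real data: images_dir, ratings, traits
    grid: dict[str, int] = field(default_factory=dict)
    models: tuple[str, ...] = ("main",)
    collinearity_threshold: float = 0.6
    squeeze_n: int | None = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("exactly one of 'scenario' and 'inputs' must be set")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def make_grid(self) -> LabGridSpec:
        return LabGridSpec(**self.grid) if self.grid else LabGridSpec()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def grouped_summary(estimates: pd.DataFrame, taxonomy: pd.DataFrame, level: str,
                    value: str = "raw_score") -> pd.DataFrame:
    """Per-family or per-order mean/SD/n of a score or residual column."""
    if level not in ("family", "order"):
        raise ValueError("level must be 'family' or 'order'")
    taxo = taxonomy.drop_duplicates("species_id")[["species_id", "family", "order"]]
    joined = estimates.merge(taxo, on="species_id", how="left")
    out = (joined.groupby(level)[value].agg(["mean", "std", "count"])
           .reset_index().rename(columns={"count": "n"}))
    return out


def _scalable(table: pd.DataFrame) -> tuple[str, ...]:
    """Continuous predictors present with non-zero variance; constant
    columns (e.g. a tone nobody wears in a small panel) are logged and
    left unscaled rather than aborting the run."""
    from .trait_prep import CONTINUOUS_PREDICTORS
    out = []
    for c in CONTINUOUS_PREDICTORS:
        if c not in table.columns:
            continue
        if table[c].nunique(dropna=True) < 2:
            logger.warning("column '%s' is constant in this panel; left unscaled", c)
            continue
        out.append(c)
    return tuple(out)


def prepare_trait_table(traits: pd.DataFrame, profiles: pd.DataFrame,
                        taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Join species traits with colour profiles and derive model predictors."""
    table = taxonomy.merge(traits.drop(columns=["order", "family", "genus"]),
                           on="species_id", how="left")
    table = table.merge(profiles, on=["species_id", "sex"], how="left")
    table["rel_beak"] = relative_ornament(table["beak_length"], table["body_mass"])
    table["rel_tail"] = relative_ornament(table["tail_length"], table["body_mass"])
    table["iucn"] = reclassify_iucn(table["iucn_raw"])
    table["trophic"] = reclassify_trophic(table["trophic_raw"])
    table["migration"] = reclassify_migration(table["migration_raw"])
    return table


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full chain and return the in-memory output bundle.

    Stages run in order (simulate ->) quantify -> consensus -> prepare ->
    fit -> validate; a failure aborts with the stage name while earlier
    outputs remain on disk.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = config.make_grid()
    cmap = default_category_map(grid)
    written: list[Path] = []
    bundle: dict[str, Any] = {}
    stage = "configure"
    try:
        if config.scenario is not None:
            stage = "simulate"
            sim = _simulate_stage(config, grid, out_dir, written)
            images, taxonomy, traits = sim["images"], sim["taxonomy"], sim["traits"]
            ratings = sim["ratings"]
            bundle.update(sim)
        else:
            stage = "load"
            images, taxonomy, traits, ratings = _load_inputs(config)
            bundle.update({"taxonomy": taxonomy, "traits": traits, "ratings": ratings})

        stage = "quantify"
        profiles = profiles_to_frame(profile_panel(images, grid, cmap))
        _write_csv(profiles, p := out_dir / "color_profiles.csv"); written.append(p)
        bundle["profiles"] = profiles

        stage = "consensus"
        cons = fit_consensus(ratings, squeeze_n=config.squeeze_n)
        _write_csv(cons.estimates, p := out_dir / "consensus_estimates.csv"); written.append(p)
        bundle["consensus"] = cons

        stage = "prepare"
        table = prepare_trait_table(traits, profiles, taxonomy)
        table = table.merge(cons.estimates[["species_id", "sex", "response"]],
                            on=["species_id", "sex"], how="inner")
        model_ready, scaler = transform_and_scale(table, continuous=_scalable(table))
        screen = collinearity_screen(model_ready, threshold=config.collinearity_threshold,
                                     drop=("colour_diversity",))
        _write_csv(model_ready, p := out_dir / "model_ready.csv"); written.append(p)
        _write_csv(screen.to_frame(), p := out_dir / "collinearity_report.csv"); written.append(p)
        bundle.update({"model_ready": model_ready, "scaler": scaler, "screen": screen})

        stage = "fit"
        fits = run_model_battery(model_ready, models=tuple(config.models))
        for name, res in fits.items():
            _write_csv(res.summary_frame(), p := out_dir / f"fit_{name}.csv"); written.append(p)
            (out_dir / f"fit_{name}.json").write_text(
                json.dumps(res.to_json_dict(), indent=2, sort_keys=True))
            written.append(out_dir / f"fit_{name}.json")
        bundle["fits"] = fits

        stage = "validate"
        diags = {name: validate(res) for name, res in fits.items()}
        diag_rows = [{"model": d.model, "n": d.n_residuals, "ks_statistic": d.ks_statistic,
                      "ks_p_value": d.ks_p_value, "resid_fitted_corr": d.resid_fitted_corr}
                     for d in diags.values()]
        _write_csv(pd.DataFrame(diag_rows), p := out_dir / "diagnostics.csv"); written.append(p)
        bundle["diagnostics"] = diags

        stage = "report"
        fam = grouped_summary(cons.estimates, taxonomy, "family")
        _write_csv(fam, p := out_dir / "family_summary.csv"); written.append(p)
        bundle["family_summary"] = fam
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "models": list(config.models),
        "grid_cells": grid.total_cells,
        "row_counts": {
            "taxonomy": int(len(taxonomy)),
            "ratings": int(len(ratings)),
            "model_ready": int(len(bundle["model_ready"])),
        },
        "checksums": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def _simulate_stage(config: PipelineConfig, grid: LabGridSpec, out_dir: Path,
                    written: list[Path]) -> dict[str, Any]:
    sc = dict(config.scenario or {})
    tax_cfg = dict(sc.get("taxonomy", {}))
    for key in ("families_per_order", "genera_per_family", "species_per_genus"):
        if isinstance(tax_cfg.get(key), list):
            tax_cfg[key] = tuple(tax_cfg[key])
    taxonomy = generate_taxonomy(TaxonomySpec(seed=config.seed, **tax_cfg))
    traits = simulate_species_traits(taxonomy, seed=config.seed)
    mixes = simulate_colour_mixes(taxonomy, seed=config.seed)

    img_cfg = dict(sc.get("image", {}))
    size = img_cfg.get("size", 24)
    layout = img_cfg.get("layout", "stripe")
    n_colors = img_cfg.get("colors_per_category", 2)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    img_dir = out_dir / "images"
    img_dir.mkdir(exist_ok=True)
    images = []
    for row in mixes.itertuples():
        mix = {c: getattr(row, c) for c in CATEGORIES if getattr(row, c) > 0}
        total = sum(mix.values())
        mix = {c: v / total for c, v in mix.items()}
        image, _ = generate_plumage_image(
            mix, layout=layout, size=size, seed=int(rng.integers(2 ** 31)),
            grid=grid, colors_per_category=n_colors,
            species_id=row.species_id, sex=row.sex)
        image.save_png(img_dir / f"{row.species_id}_{row.sex}.png")
        images.append(image)

    # attractiveness is simulated on the standardized predictor table so the
    # configured coefficients are on the same scale the models estimate
    base_profiles = profiles_to_frame(profile_panel(images, grid))
    base = prepare_trait_table(traits, base_profiles, taxonomy)
    model_ready, _ = transform_and_scale(base, continuous=_scalable(base))
    att_cfg = dict(sc.get("attractiveness", {}))
    truth = simulate_attractiveness(
        model_ready,
        coefficients=att_cfg.get("coefficients", _DEFAULT_COEFFICIENTS),
        sigmas=att_cfg.get("sigmas", _DEFAULT_SIGMAS),
        phi=att_cfg.get("phi", 30.0),
        intercept=att_cfg.get("intercept", 0.0),
        seed=config.seed)

    rat_cfg = dict(sc.get("ratings", {}))
    sim = simulate_ratings(
        truth.frame,
        n_raters=rat_cfg.get("n_raters", 80),
        mean_photos=rat_cfg.get("mean_photos", 5.0),
        ratings_per_photo=rat_cfg.get("ratings_per_photo", 6),
        quality_effect=rat_cfg.get("quality_effect", 0.15),
        language_effects=rat_cfg.get("language_effects", {"en": 0.0, "fi": 0.2, "es": -0.2}),
        photo_sd=rat_cfg.get("photo_sd", 0.3),
        noise_sd=rat_cfg.get("noise_sd", 1.0),
        seed=config.seed)
    ratings = sim.ratings.merge(
        taxonomy[["species_id", "sex", "genus", "family", "order"]],
        on=["species_id", "sex"], how="left")

    _write_csv(taxonomy, p := out_dir / "taxonomy.csv"); written.append(p)
    _write_csv(traits, p := out_dir / "traits.csv"); written.append(p)
    _write_csv(truth.frame[["species_id", "sex", "eta_true", "mu_true", "response"]],
               p := out_dir / "truth.csv"); written.append(p)
    _write_csv(ratings, p := out_dir / "ratings.csv"); written.append(p)
    return {"taxonomy": taxonomy, "traits": traits, "mixes": mixes,
            "images": images, "truth": truth, "ratings": ratings}


def _load_inputs(config: PipelineConfig):
    inputs = config.inputs or {}
    for key in ("images_dir", "ratings", "traits", "taxonomy"):
        if key not in inputs:
            raise ValueError(f"real-data mode requires input path '{key}'")
    taxonomy = pd.read_csv(inputs["taxonomy"])
    traits = pd.read_csv(inputs["traits"])
    ratings = pd.read_csv(inputs["ratings"])
    images = []
    for png in sorted(Path(inputs["images_dir"]).glob("*.png")):
        species_id, _, sex = png.stem.rpartition("_")
        images.append(PlumageImage.load(png, species_id=species_id, sex=sex))
    if not images:
        raise ValueError(f"no PNG images found in {inputs['images_dir']}")
    return images, taxonomy, traits, ratings
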