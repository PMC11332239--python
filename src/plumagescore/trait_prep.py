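"""Predictor preparation: allometric residuals, reclassification, scaling,
and the collinearity screen.

Ornament sizes (beak, tail) are expressed relative to body size as the
residuals of an ordinary least-squares allometric regression of log length
on log mass across the species panel.  Raw conservation/trophic/migration
vocabularies collapse to balanced category sets.  Body mass and range size
are log-transformed, latitude enters as its absolute value, and all
continuous predictors are z-scaled (mean 0, SD 1) with the scaling
parameters retained for exact inversion.  A Pearson correlation screen
reports pairs above a threshold; variables are only ever dropped through an
explicit, documented drop list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "relative_ornament",
    "reclassify_iucn",
    "reclassify_trophic",
    "reclassify_migration",
    "Scaler",
    "transform_and_scale",
    "collinearity_screen",
    "CollinearityReport",
    "CONTINUOUS_PREDICTORS",
]

#: continuous predictors that are z-scaled by default (when present)
CONTINUOUS_PREDICTORS = (
    "body_mass", "crest", "rel_beak", "rel_tail", "colour_elaboration",
    "colour_diversity", "range_size", "abs_latitude",
    "black", "white", "yellow", "blue", "red", "green",
    "purple", "brown", "grey", "rufous",
    "blue_light", "blue_dark", "red_light", "red_dark", "green_light", "green_dark",
)

#: columns log-transformed before scaling
LOG_COLUMNS = ("body_mass", "range_size")


def relative_ornament(length: pd.Series | np.ndarray, body_mass: pd.Series | np.ndarray,
                      log_scale: bool = True) -> np.ndarray:
    """Ornament size relative to body size: OLS residuals of length on mass.

    With ``log_scale=True`` (the standard allometric form) the fit is
    log(length) ~ log(mass); rows with non-positive length or mass are
    excluded from the fit, logged, and returned as NaN.
    """
    length = np.asarray(length, dtype=float)
    mass = np.asarray(body_mass, dtype=float)
    if len(length) != len(mass):
        raise ValueError("length and body_mass must align")
    valid = np.isfinite(length) & np.isfinite(mass)
    if log_scale:
        valid &= (length > 0) & (mass > 0)
    n_bad = int(np.count_nonzero(~valid))
    if n_bad:
        logger.warning("relative_ornament: excluding %d row(s) with non-positive or missing values", n_bad)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid species for the allometric fit")
    x = np.log(mass[valid]) if log_scale else mass[valid]
    yv = np.log(length[valid]) if log_scale else length[valid]
    slope, intercept = np.polyfit(x, yv, 1)
    out = np.full(len(length), np.nan)
    out[valid] = yv - (intercept + slope * x)
    return out


_IUCN_MAP = {
    "Vulnerable": "Threatened", "Endangered": "Threatened",
    "Critically Endangered": "Threatened",
    "Least Concern": "Non-threatened", "Near Threatened": "Non-threatened",
    "Data Deficient": "Unknown", "Not Evaluated": "Unknown",
}

_TROPHIC_MAP = {
    # all predators, scavengers and invertivores count as carnivores
    "predator": "carnivore", "carnivore": "carnivore", "scavenger": "carnivore",
    "invertivore": "carnivore", "vertivore": "carnivore", "aquatic predator": "carnivore",
    "omnivore": "omnivore",
    "herbivore": "herbivore", "frugivore": "herbivore", "granivore": "herbivore",
    "nectarivore": "herbivore",
}

_MIGRATION_MAP = {
    "full migrant": "migratory", "partial migrant": "migratory", "migratory": "migratory",
    "resident": "non-migratory", "sedentary": "non-migratory",
}


def _apply_map(values, mapping: dict[str, str], what: str):
    arr = pd.Series(values, dtype=object)
    unknown = sorted(set(arr.dropna()) - set(mapping))
    if unknown:
        raise ValueError(f"unknown {what} label(s): {unknown}")
    out = arr.map(mapping)
    return out.iloc[0] if np.isscalar(values) or isinstance(values, str) else out.to_numpy()


def reclassify_iucn(values):
    """Collapse Red-List categories to Threatened / Non-threatened / Unknown."""
    return _apply_map(values, _IUCN_MAP, "IUCN")


def reclassify_trophic(values):
    """Collapse trophic labels to carnivore / omnivore / herbivore."""
    return _apply_map(values, _TROPHIC_MAP, "trophic")


def reclassify_migration(values):
    """Collapse migratory status to migratory / non-migratory."""
    return _apply_map(values, _MIGRATION_MAP, "migration")


@dataclass
class Scaler:
    """Stored per-column means/SDs (post any log transform) for inversion."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    logged: tuple[str, ...] = ()

    def inverse(self, column: str, values) -> np.ndarray:
        x = np.asarray(values, dtype=float) * self.sds[column] + self.means[column]
        if column in self.logged:
            x = np.exp(x)
        return x


def transform_and_scale(
    table: pd.DataFrame,
    continuous: tuple[str, ...] | None = None,
    log_columns: tuple[str, ...] = LOG_COLUMNS,
    latitude_column: str = "latitude",
) -> tuple[pd.DataFrame, Scaler]:
    """Produce the model-ready predictor table.

    Body mass and range size are log-transformed then z-scaled; the range
    latitude enters as ``abs_latitude = |latitude|`` before scaling; every
    other listed continuous column is z-scaled in place.  A zero-variance
    column is an error naming the column.  Pure: the input is not modified.
    """
    out = table.copy()
    if latitude_column in out.columns and "abs_latitude" not in out.columns:
        out["abs_latitude"] = out[latitude_column].abs()
    cols = [c for c in (continuous or CONTINUOUS_PREDICTORS) if c in out.columns]
    scaler = Scaler(logged=tuple(c for c in log_columns if c in cols))
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        if c in scaler.logged:
            if np.any(x <= 0):
                raise ValueError(f"column '{c}' must be positive for the log transform")
            x = np.log(x)
        m, s = float(np.nanmean(x)), float(np.nanstd(x, ddof=0))
        if s == 0.0 or not np.isfinite(s):
            raise ValueError(f"column '{c}' has zero variance and cannot be scaled")
        scaler.means[c] = m
        scaler.sds[c] = s
        out[c] = (x - m) / s
    return out, scaler


@dataclass
class CollinearityReport:
    """All pairwise Pearson correlations plus the flagged pairs."""

    correlations: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    threshold: float
    dropped: tuple[str, ...]
    retained: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"var1": a, "var2": b, "pearson_r": r, "flagged": abs(r) > self.threshold}
                for i, a in enumerate(self.correlations.columns)
                for b in self.correlations.columns[i + 1:]
                for r in [float(self.correlations.loc[a, b])]]
        return pd.DataFrame(rows)


def collinearity_screen(table: pd.DataFrame, columns: tuple[str, ...] | None = None,
                        threshold: float = 0.6, drop: tuple[str, ...] = ()) -> CollinearityReport:
    """Pairwise Pearson screen of continuous predictors.

    Pairs with ``|r| > threshold`` are flagged.  Nothing is dropped
    automatically: ``drop`` is an explicit, documented drop list (e.g.
    colour diversity, which co-varies with several colour proportions)
    applied to form the retained set.
    """
    cols = [c for c in (columns or CONTINUOUS_PREDICTORS) if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least two continuous predictors to screen")
    corr = table[cols].corr(method="pearson")
    flagged = [(a, b, float(corr.loc[a, b]))
               for i, a in enumerate(cols) for b in cols[i + 1:]
               if abs(corr.loc[a, b]) > threshold]
    for a, b, r in flagged:
        logger.info("collinearity: |r(%s, %s)| = %.3f exceeds %.2f", a, b, abs(r), threshold)
    retained = tuple(c for c in cols if c not in drop)
    return CollinearityReport(correlations=corr, flagged=flagged, threshold=threshold,
                              dropped=tuple(drop), retained=retained)
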