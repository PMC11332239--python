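"""Beta mixed models for attractiveness: model specs, battery, diagnostics.

The headline model regresses the (0,1) attractiveness score on sex, body
mass, crest, relative beak and tail length, colour elaboration and six
colour proportions, with random intercepts for Order, Family, Genus and
Species — a beta GLMM with logit link.  An extended model adds the
non-aesthetic predictors (trophic level, threat status, range size,
absolute latitude, migration).  A battery of sensitivity variants re-fits
the model on sex subsets, with dark/light colour versions, with the number
of colour loci, or with the dull colours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstest

from ._mixed import MixedFit, MixedModel

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "DiagnosticsReport",
    "build_design",
    "fit",
    "run_model_battery",
    "validate",
    "MODEL_NAMES",
]

TAXONOMIC_GROUPS = ("order", "family", "genus", "species_id")

#: reference class per categorical predictor ('undefined' sex is the
#: reference so male/female effects are read against monomorphic species)
REFERENCE_LEVELS = {
    "sex": "undefined",
    "trophic": "omnivore",
    "iucn": "Non-threatened",
    "migration": "non-migratory",
}

MAIN_COLOURS = ("black", "white", "yellow", "blue", "red", "green")
_ORNAMENT_TERMS = ("body_mass", "crest", "rel_beak", "rel_tail", "colour_elaboration")
MAIN_TERMS = ("sex",) + _ORNAMENT_TERMS + MAIN_COLOURS
EXTENDED_TERMS = ("sex", "trophic", "iucn", "range_size", "abs_latitude",
                  "migration") + _ORNAMENT_TERMS + MAIN_COLOURS
DULL_COLOURS = ("purple", "brown", "grey", "rufous")

MODEL_NAMES = ("main", "extended", "males", "females", "undefined",
               "dark", "light", "loci", "dull")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one beta GLMM."""

    name: str
    fixed: tuple[str, ...]
    groups: tuple[str, ...] = TAXONOMIC_GROUPS
    family: str = "beta"
    response: str = "response"
    subset_sex: str | None = None  # restrict rows to one sex label

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) + "".join(f" + (1|{g})" for g in self.groups)
        return f"{self.response} ~ {rhs}"


def model_spec(name: str) -> ModelSpec:
    """Build one of the named battery specs."""
    subset_terms = tuple(t for t in MAIN_TERMS if t != "sex")
    subset_groups = ("order", "family", "genus")  # sex subsets drop Species ID
    tone = lambda t: tuple(f"{c}_{t}" if c in ("blue", "red", "green") else c
                           for c in MAIN_COLOURS)
    specs = {
        "main": ModelSpec("main", MAIN_TERMS),
        "extended": ModelSpec("extended", EXTENDED_TERMS),
        "males": ModelSpec("males", subset_terms, subset_groups, subset_sex="male"),
        "females": ModelSpec("females", subset_terms, subset_groups, subset_sex="female"),
        "undefined": ModelSpec("undefined", subset_terms, subset_groups, subset_sex="undefined"),
        "dark": ModelSpec("dark", ("sex",) + _ORNAMENT_TERMS + tone("dark")),
        "light": ModelSpec("light", ("sex",) + _ORNAMENT_TERMS + tone("light")),
        "loci": ModelSpec("loci", ("sex",) + _ORNAMENT_TERMS + ("colour_diversity",)),
        "dull": ModelSpec("dull", ("sex",) + _ORNAMENT_TERMS + DULL_COLOURS),
    }
    try:
        return specs[name]
    except KeyError:
        raise ValueError(f"unknown model name '{name}'; choose from {MODEL_NAMES}") from None


def build_design(data: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Dense design matrix with intercept; categoricals expand to dummies
    against the documented reference levels."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["(Intercept)"]
    for term in fixed:
        if term not in data.columns:
            raise ValueError(f"fixed term '{term}' not found in the data")
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = REFERENCE_LEVELS.get(term, levels[0])
            if ref not in levels:
                ref = levels[0]
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((col.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{term}[{lv}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


@dataclass
class FitResult:
    """A fitted model: spec, engine result, and quantile residuals."""

    spec: ModelSpec
    fit: MixedFit
    residuals: np.ndarray
    data_index: pd.Index
    order_labels: np.ndarray | None = None

    @property
    def name(self) -> str:
        return self.spec.name

    def summary_frame(self) -> pd.DataFrame:
        return self.fit.summary_frame()

    def to_json_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "formula": self.spec.formula(),
            "n_obs": self.fit.n_obs,
            "family": self.fit.family,
            "loglik": self.fit.loglik,
            "converged": self.fit.converged,
            "precision_phi": self.fit.dispersion,
            "variance_components": self.fit.variance_components,
            "coefficients": self.summary_frame().to_dict(orient="records"),
        }


def fit(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one beta GLMM by Laplace-approximate maximum likelihood."""
    if spec.subset_sex is not None:
        data = data[data["sex"] == spec.subset_sex]
        if data.empty:
            raise ValueError(f"sex subset '{spec.subset_sex}' is empty")
    y = data[spec.response].to_numpy(dtype=float)
    X, names = build_design(data, spec.fixed)
    groups = {g: data[g].to_numpy() for g in spec.groups}
    model = MixedModel(X, y, groups=groups, family=spec.family, terms=names)
    mfit = model.fit()
    if not mfit.converged:
        logger.warning("model '%s' flagged as not converged: %s", spec.name, mfit.message)
    resid = model.quantile_residuals(mfit)
    return FitResult(spec=spec, fit=mfit, residuals=resid, data_index=data.index,
                     order_labels=data["order"].to_numpy() if "order" in data else None)


def run_model_battery(data: pd.DataFrame, models: tuple[str, ...] = MODEL_NAMES) -> dict[str, FitResult]:
    """Fit the requested battery; empty subsets are skipped with a log entry."""
    results: dict[str, FitResult] = {}
    for name in models:
        spec = model_spec(name)
        missing = [t for t in spec.fixed if t not in data.columns]
        if missing:
            logger.warning("skipping model '%s': missing columns %s", name, missing)
            continue
        if spec.subset_sex is not None and not (data["sex"] == spec.subset_sex).any():
            logger.warning("skipping model '%s': no rows with sex == %s", name, spec.subset_sex)
            continue
        results[name] = fit(spec, data)
    return results


@dataclass
class DiagnosticsReport:
    """Residual-based validation of a converged fit."""

    model: str
    n_residuals: int
    ks_statistic: float
    ks_p_value: float
    resid_fitted_corr: float
    by_order: pd.DataFrame | None

    @property
    def ok(self) -> bool:
        return self.ks_p_value > 0.05


def validate(result: FitResult) -> DiagnosticsReport:
    """Inspect randomized quantile residuals of a fit.

    Under a correctly specified model the residuals are standard normal;
    the report carries a Kolmogorov-Smirnov test against N(0,1), the
    residual-vs-fitted correlation, and per-Order residual summaries.
    """
    z = result.residuals
    ks = kstest(z, "norm")
    eta = result.fit.fitted_eta
    corr = float(np.corrcoef(eta, z)[0, 1]) if np.std(eta) > 0 else 0.0
    by_order = None
    if result.order_labels is not None:
        by_order = (pd.DataFrame({"order": result.order_labels, "residual": z})
                    .groupby("order")["residual"].agg(["mean", "std", "count"])
                    .reset_index())
    return DiagnosticsReport(
        model=result.spec.name,
        n_residuals=len(z),
        ks_statistic=float(ks.statistic),
        ks_p_value=float(ks.pvalue),
        resid_fitted_corr=corr,
        by_order=by_order,
    )
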