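"""Consensus attractiveness scores from raw 1-10 crowd ratings.

Raw ratings confound the bird's appeal with photo quality, rater language
and repeated scoring of the same photo.  A Gaussian linear mixed model on
the ratings — fixed effects for photo quality, rater language and sex;
random intercepts for photo, species, genus, family and order — separates
these, and the consensus score of a species x sex is the model prediction
at reference conditions (best photo quality, majority language) plus its
taxonomic random intercepts.  The 1-10 prediction is shifted to a 0-9 raw
score and divided by 10 to give a (0,1) response ready for beta regression,
with exact-boundary values squeezed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mixed import MixedFit, MixedModel

logger = logging.getLogger(__name__)

__all__ = ["AttractivenessEstimate", "ConsensusResult", "fit_consensus", "transform_response"]

_CONSENSUS_GROUPS = ("photo_id", "species_id", "genus", "family", "order")
_REQUIRED = ("rater_language", "photo_id", "photo_quality", "species_id", "sex",
             "rating", "genus", "family", "order")


@dataclass
class AttractivenessEstimate:
    species_id: str
    sex: str
    raw_score: float  # 0-9 scale
    response: float  # (0,1), boundary-squeezed
    n_ratings: int
    se: float


@dataclass
class ConsensusResult:
    estimates: pd.DataFrame  # species_id, sex, raw_score, response, se, n_ratings
    fit: MixedFit | None

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False)


def transform_response(raw_score, n: int | None = None, squeeze: str = "boundary"):
    """Map a 0-9 raw consensus score to the (0,1) beta-regression scale.

    The score is divided by 10; values landing exactly on 0 or 1 are then
    squeezed with the standard compression ``(y * (n - 1) + 0.5) / n``
    (``squeeze='boundary'``, the default, touches only exact-boundary
    values; ``squeeze='all'`` compresses every value, ``squeeze='none'``
    leaves them untouched).  ``n`` is the number of scores in the panel.
    """
    raw = np.asarray(raw_score, dtype=float)
    scalar = raw.ndim == 0
    raw = np.atleast_1d(raw)
    if np.any((raw < 0.0) | (raw > 9.0)):
        raise ValueError("raw scores must lie in [0, 9]")
    y = raw / 10.0
    if squeeze not in ("boundary", "all", "none"):
        raise ValueError("squeeze must be 'boundary', 'all' or 'none'")
    if squeeze != "none":
        if n is None or n < 2:
            raise ValueError("the squeeze needs the panel size n >= 2")
        sq = (y * (n - 1) + 0.5) / n
        y = sq if squeeze == "all" else np.where((y <= 0.0) | (y >= 1.0), sq, y)
    return float(y[0]) if scalar else y


def fit_consensus(ratings: pd.DataFrame, squeeze_n: int | None = None) -> ConsensusResult:
    """Estimate one consensus score per species x sex from raw ratings.

    ``ratings`` must carry the taxonomy columns (genus/family/order) joined
    in.  Photo quality and rater language enter as categorical fixed
    effects with reference levels quality 5 and the majority language, so
    predictions correspond to the best-photo, typical-viewer condition.
    With no rating variation at all the model is degenerate and the scores
    reduce to the common value.
    """
    missing = [c for c in _REQUIRED if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    if ratings.empty:
        raise ValueError("ratings table is empty")

    keys = ratings.groupby(["species_id", "sex"], sort=True)
    counts = keys.size().rename("n_ratings")
    sds = keys["rating"].std(ddof=1).fillna(0.0)
    taxo = ratings.drop_duplicates(["species_id", "sex"]).set_index(["species_id", "sex"])

    y = ratings["rating"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        logger.warning("all ratings identical; consensus model is degenerate, "
                       "returning the common value with all variances pinned at 0")
        pred = pd.Series(y[0], index=counts.index)
        mfit = None
    else:
        X, names = _consensus_design(ratings)
        groups = {g: ratings[g].to_numpy() for g in _CONSENSUS_GROUPS}
        model = MixedModel(X, y, groups=groups, family="gaussian", terms=names)
        mfit = model.fit()
        # prediction at reference quality/language: intercept + sex effect
        # + species-level taxonomic BLUPs
        sex_eff = {}
        for term, est in zip(mfit.terms, mfit.coefficients):
            if term.startswith("sex["):
                sex_eff[term[4:-1]] = est
        intercept = mfit.coefficients[0]
        rows = {}
        for (sp, sex) in counts.index:
            t = taxo.loc[(sp, sex)]
            val = intercept + sex_eff.get(sex, 0.0)
            for level, col in (("species_id", sp), ("genus", t["genus"]),
                               ("family", t["family"]), ("order", t["order"])):
                b = mfit.blups.get(level)
                if b is not None and col in b.index:
                    val += float(b.loc[col])
            rows[(sp, sex)] = val
        pred = pd.Series(rows)
        pred.index.names = ["species_id", "sex"]

    raw = np.clip(pred.to_numpy() - 1.0, 0.0, 9.0)
    n_panel = squeeze_n if squeeze_n is not None else max(len(counts), 2)
    response = transform_response(raw, n=n_panel, squeeze="boundary")
    estimates = pd.DataFrame({
        "species_id": [k[0] for k in counts.index],
        "sex": [k[1] for k in counts.index],
        "raw_score": raw,
        "response": response,
        "se": (sds / np.sqrt(counts.clip(lower=1))).to_numpy(),
        "n_ratings": counts.to_numpy(),
    })
    return ConsensusResult(estimates=estimates, fit=mfit)


def _consensus_design(ratings: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(ratings))]
    names = ["(Intercept)"]
    # photo quality: categorical, reference = 5 (best photos)
    for q in sorted(ratings["photo_quality"].unique()):
        if q == 5:
            continue
        cols.append((ratings["photo_quality"] == q).to_numpy(dtype=float))
        names.append(f"quality[{q}]")
    # language: reference = majority language
    lang_counts = ratings["rater_language"].value_counts()
    ref_lang = lang_counts.index[0]
    for lang in sorted(ratings["rater_language"].unique()):
        if lang == ref_lang:
            continue
        cols.append((ratings["rater_language"] == lang).to_numpy(dtype=float))
        names.append(f"language[{lang}]")
    # sex: reference = undefined
    for sx in sorted(ratings["sex"].unique()):
        if sx == "undefined":
            continue
        cols.append((ratings["sex"] == sx).to_numpy(dtype=float))
        names.append(f"sex[{sx}]")
    X = np.column_stack(cols)
    # drop constant dummies (single-level factors) to keep full rank
    keep = [0] + [j for j in range(1, X.shape[1]) if X[:, j].std() > 0]
    return X[:, keep], [names[j] for j in keep]
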