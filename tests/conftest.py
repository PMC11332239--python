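import numpy as np
import pandas as pd
import pytest

from plumagescore import LabGridSpec, default_category_map
from plumagescore.synthetic import TaxonomySpec, generate_taxonomy, simulate_attractiveness

#: ground truth used by every parameter-recovery exercise, keyed by the
#: term names the fitted models report
GLMM_TRUTH = {
    "(Intercept)": 0.1,
    "sex[female]": 0.05,
    "sex[male]": 0.1,
    "body_mass": -0.3,
    "crest": 0.2,
    "rel_beak": 0.0,
    "rel_tail": 0.2,
    "colour_elaboration": 0.5,
    "black": -0.2,
    "white": -0.1,
    "yellow": 0.1,
    "blue": 0.3,
    "red": 0.3,
    "green": 0.1,
}
GLMM_SIGMAS = {"order": 0.3, "family": 0.2, "genus": 0.2, "species_id": 0.1}
GLMM_PHI = 30.0

_CONTINUOUS_TERMS = [k for k in GLMM_TRUTH if "[" not in k and k != "(Intercept)"]


def make_glmm_panel(seed, n_orders=10, families_per_order=3, genera_per_family=5,
                    species_per_genus=(8, 10), dichromatic_fraction=0.35,
                    sigmas=GLMM_SIGMAS, phi=GLMM_PHI):
    """Simulate one attractiveness panel under the exact model the beta
    GLMM assumes: iid standard-normal predictors, known coefficients,
    nested taxonomic random intercepts, beta noise."""
    tax = generate_taxonomy(TaxonomySpec(
        n_orders=n_orders, families_per_order=families_per_order,
        genera_per_family=genera_per_family, species_per_genus=species_per_genus,
        dichromatic_fraction=dichromatic_fraction, seed=seed))
    rng = np.random.default_rng(seed + 100_000)
    df = tax.copy()
    for t in _CONTINUOUS_TERMS:
        df[t] = rng.normal(size=len(df))
    df["sex_is_male"] = (df["sex"] == "male").astype(float)
    df["sex_is_female"] = (df["sex"] == "female").astype(float)
    coefs = {t: GLMM_TRUTH[t] for t in _CONTINUOUS_TERMS}
    coefs["sex_is_male"] = GLMM_TRUTH["sex[male]"]
    coefs["sex_is_female"] = GLMM_TRUTH["sex[female]"]
    truth = simulate_attractiveness(df, coefs, sigmas=sigmas, phi=phi,
                                    seed=seed, intercept=GLMM_TRUTH["(Intercept)"])
    return truth.frame


@pytest.fixture(scope="session")
def grid():
    return LabGridSpec()


@pytest.fixture(scope="session")
def cmap(grid):
    return default_category_map(grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_bin(lab_pixels, grid):
    """Independent nested-loop binning oracle: per-pixel edge scan.

    Deliberately avoids the vectorised arithmetic of the implementation.
    """
    counts: dict[tuple[int, int, int], int] = {}
    axes = [("L", grid.L_bins), ("a", grid.a_bins), ("b", grid.b_bins)]
    edges = {name: grid.axis_edges(name) for name, _ in axes}
    for pix in np.atleast_2d(lab_pixels):
        idx = []
        for (name, nbins), x in zip(axes, pix):
            e = edges[name]
            j = None
            for k in range(nbins):
                last = k == nbins - 1
                if (e[k] <= x < e[k + 1]) or (last and x == e[k + 1]):
                    j = k
                    break
            if j is None:  # out of range: clamp to edge bin
                j = 0 if x < e[0] else nbins - 1
            idx.append(j)
        key = tuple(idx)
        counts[key] = counts.get(key, 0) + 1
    return counts
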