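import numpy as np
import pandas as pd
import pytest
from statsmodels.othermod.betareg import BetaModel

from plumagescore._mixed import MixedModel
from plumagescore.beta_glmm import fit, model_spec, run_model_battery, validate

from conftest import GLMM_PHI, GLMM_SIGMAS, GLMM_TRUTH, make_glmm_panel


def _plain_beta_data(seed, n=400):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta = np.array([0.2, 0.5, -0.3])
    mu = 1 / (1 + np.exp(-(X @ beta)))
    y = rng.beta(mu * 25.0, (1 - mu) * 25.0)
    return X, y


def test_reduction_to_plain_beta_regression_matches_statsmodels():
    """With no random effects the engine is exactly a beta regression and
    must agree with an independent ML fit."""
    X, y = _plain_beta_data(21)
    ours = MixedModel(X, y, groups=None, family="beta").fit()
    ref = BetaModel(y, X, exog_precision=np.ones((len(y), 1))).fit(disp=0)
    assert np.max(np.abs(ours.coefficients - ref.params[:3])) < 1e-4
    assert ours.dispersion == pytest.approx(np.exp(ref.params[3]), rel=1e-3)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)


def test_single_factor_with_null_variance_converges_to_fixed_fit():
    X, y = _plain_beta_data(22)
    groups = {"g": np.repeat(np.arange(20), len(y) // 20)}
    mixed = MixedModel(X, y, groups=groups, family="beta").fit()
    plain = MixedModel(X, y, groups=None, family="beta").fit()
    # data were simulated with no group structure: the variance collapses
    # and the coefficients agree with the fixed-effects-only fit
    assert mixed.variance_components["g"] < 1e-2
    assert np.allclose(mixed.coefficients, plain.coefficients, atol=2e-3)


def test_response_on_boundary_instructs_squeeze():
    X = np.ones((10, 1))
    y = np.linspace(0.0, 0.9, 10)
    with pytest.raises(ValueError, match="squeeze"):
        MixedModel(X, y, family="beta")


def test_rank_deficient_design_rejected():
    X = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(ValueError, match="rank"):
        MixedModel(X, np.full(10, 0.5), family="beta")


def test_intercept_only_symmetric_data_gives_zero_logit(rng):
    y = rng.beta(0.5 * 40, 0.5 * 40, size=4000)
    fit_ = MixedModel(np.ones((4000, 1)), y, family="beta").fit()
    # logit(0.5) = 0 up to MC error ~ 3 SE
    assert abs(fit_.coefficients[0]) < 3.5 * fit_.se[0] + 1e-3
    assert abs(fit_.coefficients[0]) < 0.02


def test_equivariance_under_predictor_scaling():
    data = make_glmm_panel(seed=31, n_orders=4, families_per_order=2,
                           genera_per_family=3, species_per_genus=5)
    res1 = fit(model_spec("main"), data)
    scaled = data.copy()
    scaled["blue"] = scaled["blue"] * 2.0
    res2 = fit(model_spec("main"), scaled)
    i = res1.fit.terms.index("blue")
    assert res2.fit.coefficients[i] == pytest.approx(res1.fit.coefficients[i] / 2.0, rel=1e-4)


def test_optimum_likelihood_dominates_truth():
    data = make_glmm_panel(seed=32, n_orders=5, families_per_order=2,
                           genera_per_family=3, species_per_genus=5)
    res = fit(model_spec("main"), data)
    model = _rebuild_model(data)
    x_true = np.concatenate([
        np.log([GLMM_SIGMAS["order"] ** 2, GLMM_SIGMAS["family"] ** 2,
                GLMM_SIGMAS["genus"] ** 2, GLMM_SIGMAS["species_id"] ** 2]),
        [np.log(GLMM_PHI)],
    ])
    ll_true = -model._laplace_negloglik(x_true)
    assert res.fit.loglik >= ll_true - 1e-4


def _rebuild_model(data):
    from plumagescore.beta_glmm import build_design
    spec = model_spec("main")
    X, names = build_design(data, spec.fixed)
    groups = {g: data[g].to_numpy() for g in spec.groups}
    return MixedModel(X, data["response"].to_numpy(), groups=groups, family="beta", terms=names)


def test_nested_models_never_lose_likelihood():
    data = make_glmm_panel(seed=33, n_orders=4, families_per_order=2,
                           genera_per_family=3, species_per_genus=4)
    rng = np.random.default_rng(5)
    for extra in ("trophic", "iucn", "migration"):
        levels = {"trophic": ["carnivore", "omnivore", "herbivore"],
                  "iucn": ["Threatened", "Non-threatened", "Unknown"],
                  "migration": ["migratory", "non-migratory"]}[extra]
        data[extra] = rng.choice(levels, size=len(data))
    data["range_size"] = rng.normal(size=len(data))
    data["abs_latitude"] = rng.normal(size=len(data))
    main = fit(model_spec("main"), data)
    extended = fit(model_spec("extended"), data)
    assert extended.fit.loglik >= main.fit.loglik - 1e-3


def test_recovery_on_one_panel_is_well_inside_cis():
    data = make_glmm_panel(seed=34)
    res = fit(model_spec("main"), data)
    frame = res.summary_frame().set_index("term")
    n_covered = sum(
        float(frame.loc[t, "ci_low"]) <= GLMM_TRUTH[t] <= float(frame.loc[t, "ci_high"])
        for t in GLMM_TRUTH)
    assert n_covered >= len(GLMM_TRUTH) - 1
    assert res.fit.dispersion == pytest.approx(GLMM_PHI, rel=0.15)


def test_battery_handles_monomorphic_data_and_subsets():
    data = make_glmm_panel(seed=35, n_orders=4, families_per_order=2,
                           genera_per_family=3, species_per_genus=5,
                           dichromatic_fraction=0.0)
    data["colour_diversity"] = np.random.default_rng(1).normal(size=len(data))
    results = run_model_battery(data, models=("main", "males", "females", "undefined", "loci"))
    assert "males" not in results and "females" not in results
    assert results["undefined"].fit.n_obs == len(data)
    # sex subsets drop the sex term and the species random factor
    assert "sex" not in results["undefined"].spec.fixed
    assert "species_id" not in results["undefined"].spec.groups


def test_loci_model_recovers_positive_diversity_effect():
    data = make_glmm_panel(seed=36, n_orders=5, families_per_order=2,
                           genera_per_family=3, species_per_genus=6)
    rng = np.random.default_rng(9)
    data["colour_diversity"] = rng.normal(size=len(data))
    # rebuild the response with a +0.5 diversity effect added on the link scale
    from plumagescore.synthetic import simulate_attractiveness
    truth = simulate_attractiveness(
        data, {"colour_diversity": 0.5, "body_mass": -0.3}, sigmas=GLMM_SIGMAS,
        phi=GLMM_PHI, seed=36)
    data["response"] = truth.frame["response"]
    res = fit(model_spec("loci"), data)
    i = res.fit.terms.index("colour_diversity")
    assert res.fit.coefficients[i] > 0.3
    assert res.fit.ci_low[i] > 0


def test_diagnostics_on_well_specified_and_mis_specified_fits():
    data = make_glmm_panel(seed=37, n_orders=4, families_per_order=2,
                           genera_per_family=3, species_per_genus=6)
    res = fit(model_spec("main"), data)
    report = validate(res)
    assert report.n_residuals == res.fit.n_obs
    assert report.ks_p_value > 0.05
    assert report.by_order is not None and report.by_order["count"].sum() == res.fit.n_obs

    # deliberately mis-simulated response: an interior bimodal mixture,
    # which no single beta density can accommodate
    rng = np.random.default_rng(2)
    bad = data.copy()
    comp = rng.integers(0, 2, len(bad))
    bad["response"] = np.clip(np.where(comp, 0.8, 0.2) + rng.normal(0, 0.02, len(bad)),
                              1e-6, 1 - 1e-6)
    res_bad = fit(model_spec("main"), bad)
    report_bad = validate(res_bad)
    assert report_bad.ks_p_value < 0.01
    assert report_bad.ks_statistic > report.ks_statistic
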