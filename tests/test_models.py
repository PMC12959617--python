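"""Phylogenetic correlation, designs, PGLS and mixed-model fits."""

import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

import thermoscope as ts
from thermoscope.models import (
    Design,
    MissingTipError,
    ModelId,
    ModelSpec,
    PhyloFit,
    build_design,
    fit_mixed,
    fit_pgls,
    fit_species_intercept_model,
    phylo_correlation,
    r_squared,
    tree_tip_labels,
)
from thermoscope.simulate import simulate_tree

from conftest import fit_model, model_table


# ---------------------------------------------------------------------------
# Correlation structure


def test_lambda_zero_is_identity(cherry_tree):
    C = phylo_correlation(cherry_tree, ["A", "B", "C"], lam=0.0)
    np.testing.assert_array_equal(C, np.eye(3))


def test_cherry_shares_half_path(cherry_tree):
    C = phylo_correlation(cherry_tree, ["A", "B", "C"], lam=1.0)
    assert C[0, 1] == pytest.approx(0.5)
    assert C[0, 2] == pytest.approx(0.0)
    np.testing.assert_array_equal(np.diag(C), np.ones(3))


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
def test_correlation_symmetric_psd_on_random_trees(seed, lam):
    tree = simulate_tree(10, seed=seed)
    species = tree_tip_labels(tree)
    C = phylo_correlation(tree, species, lam=lam)
    np.testing.assert_allclose(C, C.T, atol=1e-14)
    assert np.linalg.eigvalsh(C).min() >= -1e-8


def test_missing_tip_error_lists_names(cherry_tree):
    with pytest.raises(MissingTipError) as err:
        phylo_correlation(cherry_tree, ["A", "Nemo", "Dory"])
    assert "Nemo" in str(err.value) and "Dory" in str(err.value)


# ---------------------------------------------------------------------------
# Design construction


def species_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(n)],
            "heat_tolerance_std": rng.normal(35, 3, n),
            "acclimation_std": rng.choice([-5.0, 0.0, 5.0], n),
            "latitude": rng.uniform(-50, 50, n),
            "max_habitat_temp": rng.uniform(5, 30, n),
            "thermal_variability": rng.uniform(0.005, 0.04, n),
            "realm": rng.choice(["marine", "freshwater", "brackish"], n),
        }
    )


def test_quadratic_column_orthogonal_to_linear_and_intercept():
    table = species_table()
    y, X, design = build_design(table, ModelSpec(ModelId.MODEL2))
    q2 = X[:, design.names.index("acct_q2")]
    acct = table["acclimation_std"].to_numpy()
    assert abs(q2.sum()) < 1e-9
    assert abs(q2 @ acct) < 1e-9
    assert np.linalg.norm(q2) == pytest.approx(1.0)


def test_model2_design_has_six_columns():
    y, X, design = build_design(species_table(), ModelSpec(ModelId.MODEL2))
    assert X.shape[1] == 6
    assert design.names[0] == "intercept"


def test_model3_realm_contrasts_use_marine_reference():
    table = species_table()
    y, X, design = build_design(table, ModelSpec(ModelId.MODEL3))
    assert X.shape[1] == 10
    fresh = X[:, design.names.index("realm[freshwater]")]
    np.testing.assert_array_equal(fresh, (table["realm"] == "freshwater").astype(float))
    marine_rows = table["realm"] == "marine"
    assert X[marine_rows.values][:, 6:].sum() == 0


def test_unknown_realm_level_rejected():
    table = species_table()
    table.loc[0, "realm"] = "estuarine"
    with pytest.raises(ValueError, match="realm"):
        build_design(table, ModelSpec(ModelId.MODEL3))


def test_constant_acclimation_is_degenerate():
    table = species_table()
    table["acclimation_std"] = 0.0
    with pytest.raises(ValueError, match="degenerate|collinear"):
        build_design(table, ModelSpec(ModelId.MODEL2))


# ---------------------------------------------------------------------------
# PGLS


def pgls_xy(tree, beta=(1.0, 0.5), lam=0.9, sigma=1.0, seed=0):
    species = tree_tip_labels(tree)
    n = len(species)
    rng = np.random.default_rng(seed)
    C = phylo_correlation(tree, species, 1.0)
    L = np.linalg.cholesky(lam * C + (1 - lam) * np.eye(n) + 1e-10 * np.eye(n))
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = X @ np.asarray(beta) + sigma * (L @ rng.normal(size=n))
    return y, X, species


def test_pgls_at_lambda_zero_equals_ols():
    tree = simulate_tree(30, seed=5)
    y, X, species = pgls_xy(tree, seed=5)
    fit = fit_pgls(y, X, tree, species, lambda_fixed=0.0)
    import statsmodels.api as sm

    ols = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coef["estimate"].to_numpy(), ols.params, atol=1e-10)
    np.testing.assert_allclose(fit.coef["se"].to_numpy(), ols.bse, atol=1e-10)


def test_pgls_matches_dense_gls_oracle_on_five_tips():
    # compare at a fixed lambda so V is safely non-singular; the profiled
    # optimum is covered separately by the grid and recovery checks
    tree = simulate_tree(5, seed=3)
    y, X, species = pgls_xy(tree, seed=3)
    fit = fit_pgls(y, X, tree, species, lambda_fixed=0.6)
    C = phylo_correlation(tree, species, 1.0)
    V = 0.6 * C + 0.4 * np.eye(5)
    Vi = np.linalg.inv(V)
    beta_oracle = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    np.testing.assert_allclose(
        fit.coef["estimate"].to_numpy(), beta_oracle, atol=1e-8
    )
    # and the oracle covariance / t machinery agrees too
    resid = y - X @ beta_oracle
    sigma2 = resid @ Vi @ resid / (5 - 2)
    se_oracle = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ Vi @ X)))
    np.testing.assert_allclose(fit.coef["se"].to_numpy(), se_oracle, atol=1e-8)


def test_pgls_profile_optimum_beats_lambda_grid():
    tree = simulate_tree(40, seed=11)
    y, X, species = pgls_xy(tree, lam=0.7, seed=11)
    fit = fit_pgls(y, X, tree, species)
    for lam in np.linspace(0, 1, 21):
        fixed = fit_pgls(y, X, tree, species, lambda_fixed=float(lam))
        assert fit.log_likelihood >= fixed.log_likelihood - 1e-6


def test_pgls_rejects_rank_deficient_design():
    tree = simulate_tree(10, seed=1)
    y, X, species = pgls_xy(tree, seed=1)
    X = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match="rank"):
        fit_pgls(y, X, tree, species)


# ---------------------------------------------------------------------------
# Mixed models


def mixed_toy(n_species=25, reps=4, sigma_sp=1.5, sigma_e=0.5, seed=0,
              slope=0.4):
    rng = np.random.default_rng(seed)
    species = np.repeat([f"sp{i:03d}" for i in range(n_species)], reps)
    u = np.repeat(rng.normal(0, sigma_sp, n_species), reps)
    x = rng.normal(size=species.size)
    y = 2.0 + slope * x + u + rng.normal(0, sigma_e, species.size)
    X = np.column_stack([np.ones_like(x), x])
    return y, X, species


def test_zero_variance_limit_matches_ols():
    rng = np.random.default_rng(2)
    n = 120
    species = np.array([f"sp{i % 30}" for i in range(n)])
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = 1.0 + 0.7 * x + rng.normal(0, 0.3, n)  # no species structure
    spec = ModelSpec(ModelId.DURATION, random_terms=("species",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_mixed(y, X, None, species, spec)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.coef["estimate"].to_numpy(), beta_ols, atol=0.01)
    assert fit.varcomp["species"] < 0.05


def test_species_intercept_slope_matches_statsmodels_mixedlm():
    y, X, species = mixed_toy(seed=4)
    ours = fit_species_intercept_model(y, X[:, 1], species)
    import statsmodels.formula.api as smf

    frame = pd.DataFrame({"y": y, "x": X[:, 1], "species": species})
    res = smf.mixedlm("y ~ x", frame, groups="species").fit(reml=True)
    assert ours == pytest.approx(res.params["x"], abs=1e-4)


def test_general_reml_matches_statsmodels_mixedlm():
    y, X, species = mixed_toy(seed=9)
    spec = ModelSpec(ModelId.DURATION, random_terms=("species",))
    fit = fit_mixed(y, X, None, species, spec)
    import statsmodels.formula.api as smf

    frame = pd.DataFrame({"y": y, "x": X[:, 1], "species": species})
    res = smf.mixedlm("y ~ x", frame, groups="species").fit(reml=True)
    np.testing.assert_allclose(
        fit.coef["estimate"].to_numpy(),
        [res.params["Intercept"], res.params["x"]], atol=1e-4,
    )
    assert fit.varcomp["species"] == pytest.approx(
        float(res.cov_re.iloc[0, 0]), rel=1e-2
    )
    assert fit.varcomp["residual"] == pytest.approx(res.scale, rel=1e-2)


def test_star_tree_phylogeny_equals_duplicated_species_effect():
    n = 20
    taxa = dendropy.TaxonNamespace([f"sp{i:03d}" for i in range(n)])
    star = dendropy.Tree(taxon_namespace=taxa)
    for taxon in taxa:
        child = dendropy.Node(taxon=taxon)
        child.edge.length = 1.0
        star.seed_node.add_child(child)
    y, X, species = mixed_toy(n_species=n, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with_phylo = fit_mixed(
            y, X, star, species,
            ModelSpec(ModelId.DURATION, random_terms=("phylogeny", "species")),
        )
        species_only = fit_mixed(
            y, X, None, species,
            ModelSpec(ModelId.DURATION, random_terms=("species",)),
        )
    np.testing.assert_allclose(
        with_phylo.coef["estimate"].to_numpy(),
        species_only.coef["estimate"].to_numpy(), atol=1e-6,
    )
    # the two structures coincide, so only the summed variance is identified
    assert (
        with_phylo.varcomp["phylogeny"] + with_phylo.varcomp["species"]
        == pytest.approx(species_only.varcomp["species"], rel=1e-2)
    )


def test_reml_trace_is_monotone_decreasing(model3_fit):
    trace = np.asarray(model3_fit.trace)
    assert len(trace) > 3
    assert np.all(np.diff(trace) <= 0)


def test_predictions_invariant_to_row_order(medium_bundle):
    table = model_table(medium_bundle)
    spec = ModelSpec(ModelId.MODEL2)
    y, X, design = build_design(table, spec)
    shuffled = table.sample(frac=1.0, random_state=1)
    y2, X2, design2 = build_design(shuffled, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = fit_mixed(y, X, medium_bundle.tree, table["species"].to_numpy(str),
                       spec, design)
        f2 = fit_mixed(y2, X2, medium_bundle.tree,
                       shuffled["species"].to_numpy(str), spec, design2)
    # identical up to optimiser-termination noise
    np.testing.assert_allclose(
        f1.coef["estimate"].to_numpy(), f2.coef["estimate"].to_numpy(), atol=2e-4
    )
    data = {
        "max_habitat_temp": [20.0], "thermal_variability": [0.02],
        "acclimation_std": [2.0], "realm": ["marine"],
    }
    assert f1.predict(data)[0] == pytest.approx(f2.predict(data)[0], abs=2e-4)


def test_population_sensitivity_refit_barely_moves_arr(medium_bundle):
    """Adding population-in-species intercepts when the generator has no
    local adaptation leaves the acclimation slope essentially unchanged."""
    table = model_table(medium_bundle)
    table["population"] = table["species"] + "@" + table["latitude"].round(1).astype(str)
    spec = ModelSpec(ModelId.MODEL2)
    y, X, design = build_design(table, spec)
    sp = table["species"].to_numpy(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = fit_mixed(y, X, medium_bundle.tree, sp, spec, design)
        spec_pop = ModelSpec(
            ModelId.MODEL2,
            random_terms=("phylogeny", "species", "population_in_species"),
        )
        nested = fit_mixed(
            y, X, medium_bundle.tree, sp, spec_pop, design,
            population_ids=table["population"].to_numpy(str),
        )
    assert abs(
        base.coef.loc["acct", "estimate"] - nested.coef.loc["acct", "estimate"]
    ) < 0.05
    assert "population_in_species" in nested.varcomp


# ---------------------------------------------------------------------------
# R² and serialisation


def test_r_squared_worked_example_matches_variance_ratio():
    rng = np.random.default_rng(8)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    beta = np.array([1.0, 2.0])
    coef = pd.DataFrame(
        {"estimate": beta, "se": 0.1, "ci_low": 0, "ci_high": 0, "p": 0.5},
        index=["intercept", "x"],
    )
    fit = PhyloFit(
        model_id=ModelId.DURATION, backend="reml", coef=coef,
        varcomp={"phylogeny": 0.5, "species": 0.25, "residual": 0.75},
        lambda_=None, r2_marginal=0.0, r2_conditional=0.0,
        log_likelihood=0.0, n_obs=30, n_species=30,
        design=Design(ModelId.DURATION, ["intercept", "x"]),
    )
    marginal, conditional = r_squared(fit, X)
    var_f = np.var(X @ beta)
    assert marginal == pytest.approx(var_f / (var_f + 1.5), abs=1e-10)
    assert conditional == pytest.approx((var_f + 0.75) / (var_f + 1.5), abs=1e-10)
    # degenerate limits
    fit.varcomp = {"phylogeny": 0.0, "species": 0.0, "residual": 0.75}
    m2, c2 = r_squared(fit, X)
    assert m2 == pytest.approx(c2)
    fit.coef["estimate"] = [1.0, 0.0]  # intercept only: no fixed variance
    m3, _ = r_squared(fit, X)
    assert m3 == pytest.approx(0.0, abs=1e-12)


def test_fit_r2_ordering(model3_fit):
    assert 0.0 <= model3_fit.r2_marginal <= model3_fit.r2_conditional <= 1.0


def test_fit_json_round_trip(model3_fit, tmp_path):
    path = tmp_path / "fit.json"
    model3_fit.to_json(path)
    back = PhyloFit.from_json(path)
    pd.testing.assert_frame_equal(back.coef, model3_fit.coef)
    assert back.varcomp == model3_fit.varcomp
    assert back.r2_marginal == model3_fit.r2_marginal
    data = {
        "max_habitat_temp": [22.0], "thermal_variability": [0.015],
        "acclimation_std": [1.5], "realm": ["freshwater"],
    }
    assert back.predict(data)[0] == model3_fit.predict(data)[0]
    assert back.predict_se(data)[0] == pytest.approx(
        model3_fit.predict_se(data)[0], abs=1e-12
    )


def test_mcmc_backend_agrees_with_reml(small_bundle):
    table = model_table(small_bundle)
    spec = ModelSpec(ModelId.MODEL2, backend="mcmc")
    y, X, design = build_design(table, spec)
    sp = table["species"].to_numpy(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcmc = fit_mixed(y, X, small_bundle.tree, sp, spec, design,
                         seed=3, mcmc_steps=250, mcmc_burn=100)
        reml = fit_mixed(y, X, small_bundle.tree, sp,
                         ModelSpec(ModelId.MODEL2), design)
    assert mcmc.backend == "mcmc"
    assert list(mcmc.coef.columns) == list(reml.coef.columns)
    # point estimates agree within the posterior spread
    diff = np.abs(mcmc.coef["estimate"] - reml.coef["estimate"])
    assert (diff < 4 * mcmc.coef["se"] + 1e-3).all()
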