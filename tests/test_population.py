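"""Synthetic population generator: link models, propensities, oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from panelbench.population import (Covariate, JointBlock, LogisticModel,
                                   OutcomeModel, PopulationConfig, Term,
                                   cell_grid, draw_probability_sample,
                                   generate_population, outcome_prevalences,
                                   recruit_panel, true_benchmarks)

from _scenarios import zero_bias_config


def _cfg(outcomes, covariates=None, **kw):
    return PopulationConfig(
        n_population=kw.pop("n", 100_000),
        covariates=covariates or (Covariate("sex", ("M", "F"), (0.5, 0.5)),),
        outcomes=outcomes, **kw)


@pytest.mark.parametrize("intercept,expected", [
    (0.0, 0.5),                      # logit 0 -> prevalence 1/2
    (-3.476, float(expit(-3.476))),  # rare behavior, ~3.0%
])
def test_binary_prevalence_matches_link(intercept, expected):
    cfg = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", intercept),),
               seed=11)
    pop = generate_population(cfg)
    emp = pop.data["y"].mean()
    mc_se = np.sqrt(expected * (1 - expected) / cfg.n_population)
    assert abs(emp - expected) < 4 * mc_se
    if intercept == -3.476:
        assert round(100 * expected, 1) == 3.0  # prints as 3.0%


def test_covariate_dependent_prevalence_equals_mixture():
    # exact enumeration over the covariate grid is the oracle
    cov = (Covariate("x", ("a", "b"), (0.3, 0.7)),)
    out = OutcomeModel("y", "binary", "CASI", "behavior", -1.0,
                       terms=(Term("x", 1.0, "a"),))
    cfg = _cfg((out,), covariates=cov, seed=7)
    expected = 0.3 * expit(0.0) + 0.7 * expit(-1.0)
    assert outcome_prevalences(cfg)["y"] == pytest.approx(expected, abs=1e-12)
    pop = generate_population(cfg)
    mc_se = np.sqrt(expected * (1 - expected) / cfg.n_population)
    assert abs(pop.data["y"].mean() - expected) < 4 * mc_se


def test_generation_reproducible_and_digest_stable(tmp_path):
    cfg = zero_bias_config(5000, seed=42, n_outcomes=5)
    p1, p2 = generate_population(cfg), generate_population(cfg)
    pd.testing.assert_frame_equal(p1.data, p2.data)
    assert p1.digest == p2.digest
    p1.to_csv(tmp_path / "a.csv")
    p2.to_csv(tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_ordinal_generator_coherent_and_enumerable():
    out = OutcomeModel("op", "ordinal", "CAPI", "opinion",
                       thresholds=(-1.0, 0.0, 0.8, 1.7),
                       terms=(Term("sex", 0.5, "M"),))
    cfg = _cfg((out,), seed=3, n=50_000)
    cat_probs = outcome_prevalences(cfg)["op"]
    assert cat_probs.shape == (5,)
    assert cat_probs.sum() == pytest.approx(1.0, abs=1e-12)
    # cumulative probabilities nondecreasing within every covariate cell
    grid = cell_grid(cfg)
    for _, row in grid.iterrows():
        eta = 0.5 * (row["sex"] == "M")
        cum = expit(np.asarray(out.thresholds) - eta)
        assert np.all(np.diff(cum) >= 0)
    pop = generate_population(cfg)
    emp = pop.data["op"].value_counts(normalize=True).sort_index().to_numpy()
    assert np.allclose(emp, cat_probs, atol=0.01)


def test_planted_effects_recovered_by_logistic_regression():
    cov = (Covariate("x1", ("a", "b"), (0.5, 0.5)),
           Covariate("x2", ("u", "v"), (0.4, 0.6)))
    out = OutcomeModel("y", "binary", "CASI", "behavior", -1.0,
                       terms=(Term("x1", 0.5, "b"), Term("x2", -0.3, "v")))
    cfg = _cfg((out,), covariates=cov, seed=9)
    pop = generate_population(cfg)
    X = sm.add_constant(np.column_stack([
        (pop.data["x1"] == "b").to_numpy(float),
        (pop.data["x2"] == "v").to_numpy(float)]))
    fit = sm.Logit(pop.data["y"].to_numpy(float), X).fit(disp=0)
    for est, se, truth in zip(fit.params, fit.bse, (-1.0, 0.5, -0.3)):
        assert abs(est - truth) < 3 * se


def test_joint_block_dependence_and_grid_probabilities():
    rows = ((("a", "u"), 0.4), (("a", "v"), 0.1),
            (("b", "u"), 0.1), (("b", "v"), 0.4))
    cov = (Covariate("x", ("a", "b"), (0.5, 0.5)),
           Covariate("z", ("u", "v"), (0.5, 0.5)))
    cfg = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
               covariates=cov, joint_blocks=(JointBlock(("x", "z"), rows),),
               seed=5, n=50_000)
    grid = cell_grid(cfg)
    assert grid["p_cell"].sum() == pytest.approx(1.0, abs=1e-12)
    pop = generate_population(cfg)
    share_au = ((pop.data["x"] == "a") & (pop.data["z"] == "u")).mean()
    assert abs(share_au - 0.4) < 0.01


def test_probability_sample_identity_and_gradient():
    cfg = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
               covariates=(Covariate("age", ("young", "old"), (0.5, 0.5)),),
               response_model=LogisticModel(10.0),  # p_respond ~ 1
               seed=2, n=2000)
    pop = generate_population(cfg)
    full = draw_probability_sample(pop, len(pop), seed=1)
    assert len(full) == len(pop)

    # propensity gradient shifts the realized age distribution as computed
    # in closed form: share(young) = p_y r_y / (p_y r_y + p_o r_o)
    cfg2 = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
                covariates=(Covariate("age", ("young", "old"), (0.5, 0.5)),),
                response_model=LogisticModel(-1.0, (Term("age", 1.0, "young"),)),
                seed=2, n=100_000)
    pop2 = generate_population(cfg2)
    samp = draw_probability_sample(pop2, 20_000, seed=3)
    r_y, r_o = expit(0.0), expit(-1.0)
    expected_young = 0.5 * r_y / (0.5 * r_y + 0.5 * r_o)
    emp = (samp.data["age"] == "young").mean()
    assert abs(emp - expected_young) < 0.01
    with pytest.raises(ValueError):
        draw_probability_sample(pop, len(pop) + 1)


def test_panel_recruitment_bias_matches_joining_model():
    cfg = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", -1.0),),
               covariates=(Covariate("x", ("a", "b"), (0.5, 0.5)),),
               joining_model=LogisticModel(-1.0, (Term("x", 0.7, "b"),)),
               seed=4)
    pop = generate_population(cfg)
    panel = recruit_panel(pop, seed=5)
    joined = pop.data["person_id"].isin(panel.data["person_id"])
    tab = pd.crosstab(pop.data["x"], joined)
    log_or = np.log(tab.loc["b", True] * tab.loc["a", False]
                    / (tab.loc["b", False] * tab.loc["a", True]))
    assert abs(log_or - 0.7) < 0.05

    # p_join == 1 returns the whole population
    cfg_all = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
                   joining_model=LogisticModel(50.0), seed=1, n=1000)
    pop_all = generate_population(cfg_all)
    assert len(recruit_panel(pop_all, seed=0)) == len(pop_all)


def test_outcome_dependent_joining_plants_nonignorable_bias():
    # enumeration oracle: P(y=1 | joined) for a single covariate cell
    i, a, b = -1.0, -2.0, 1.5
    cfg = _cfg((OutcomeModel("y", "binary", "CASI", "behavior", i),),
               joining_model=LogisticModel(a, (Term("y", b, None),)),
               seed=8)
    p1 = expit(i)
    expected = p1 * expit(a + b) / (p1 * expit(a + b) + (1 - p1) * expit(a))
    pop = generate_population(cfg)
    panel = recruit_panel(pop, seed=9)
    assert panel.data["y"].mean() > pop.data["y"].mean()
    assert abs(panel.data["y"].mean() - expected) < 0.01


def test_true_benchmarks_exact_tabulation():
    cfg = zero_bias_config(4000, seed=13, n_outcomes=3)
    pop = generate_population(cfg)
    bench = true_benchmarks(pop, ["sex", ("sex", "y00")])
    assert sum(bench["sex"].values()) == pytest.approx(1.0, abs=1e-12)
    assert bench.proportion("sex", "M") == (pop.data["sex"] == "M").mean()
    joint = bench[("sex", "y00")]
    assert sum(joint.values()) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(KeyError):
        true_benchmarks(pop, ["nonexistent"])


@pytest.mark.parametrize("bad", [
    dict(covariates=(Covariate("x", ("a",), (0.9,)),)),          # probs != 1
    dict(outcomes=(OutcomeModel("y", "ordinal", "CAPI", "opinion",
                                thresholds=(1.0, 0.5, 2.0, 3.0)),)),  # not increasing
    dict(outcomes=(OutcomeModel("y", "binary", "CASI", "behavior", 0.0,
                                terms=(Term("ghost", 1.0, "a"),)),)),  # undeclared var
])
def test_invalid_configs_rejected(bad):
    base = dict(n_population=100,
                covariates=(Covariate("x", ("a", "b"), (0.5, 0.5)),),
                outcomes=(OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
                seed=0)
    base.update(bad)
    with pytest.raises(ValueError):
        PopulationConfig(**base).validate()
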