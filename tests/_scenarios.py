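"""Shared synthetic study conditions used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from panelbench import OutcomeMeta, outcome_prevalences
from panelbench.benchmarks import BenchmarkSet
from panelbench.population import (Covariate, LogisticModel, OutcomeModel,
                                   PopulationConfig, Term)
from panelbench.samples import SurveySample


def zero_bias_config(n: int, seed: int, n_outcomes: int = 20) -> PopulationConfig:
    """Outcome battery with prevalences 10%-50%, no covariate effects and a
    representative (constant-propensity) panel: every survey is an i.i.d.
    draw from the superpopulation."""
    outs = tuple(OutcomeModel(
        name=f"y{j:02d}", kind="binary", mode="CASI", qtype="behavior",
        intercept=float(logit(0.10 + 0.40 * j / (n_outcomes - 1))))
        for j in range(n_outcomes))
    return PopulationConfig(
        n_population=n,
        covariates=(Covariate("sex", ("M", "F"), (0.5, 0.5)),),
        outcomes=outs, seed=seed)


def biased_panel_config(n: int, join_beta: float, seed: int,
                        n_outcomes: int = 20,
                        driver_beta: float = 1.0) -> PopulationConfig:
    """Panel-joining bias planted on a covariate that drives half the
    outcomes: joining log-OR ``join_beta`` for x=b, outcome log-OR
    ``driver_beta`` per driven outcome.  Intercepts are solved so marginal
    prevalences still run 10%-50%."""
    outs = []
    for j in range(n_outcomes):
        p = 0.10 + 0.40 * j / (n_outcomes - 1)
        if j < n_outcomes // 2:
            a = brentq(lambda a: 0.5 * expit(a) + 0.5 * expit(a + driver_beta) - p,
                       -10, 10)
            terms = (Term("x", driver_beta, "b"),)
        else:
            a, terms = float(logit(p)), ()
        outs.append(OutcomeModel(f"y{j:02d}", "binary", "CASI", "behavior",
                                 float(a), (), terms))
    return PopulationConfig(
        n_population=n,
        covariates=(Covariate("x", ("a", "b"), (0.5, 0.5)),),
        outcomes=tuple(outs),
        joining_model=LogisticModel(-1.0, (Term("x", join_beta, "b"),)),
        seed=seed)


def exact_benchmarks(config: PopulationConfig) -> BenchmarkSet:
    """Superpopulation outcome prevalences as an aggregate benchmark set."""
    prev = outcome_prevalences(config)
    return BenchmarkSet({k: {"0": 1 - v, "1": v} for k, v in prev.items()
                         if np.isscalar(v) or np.ndim(v) == 0})


def binary_metas(config: PopulationConfig) -> list[OutcomeMeta]:
    return [OutcomeMeta(o.name, "binary", o.mode, o.qtype)
            for o in config.outcomes if o.kind == "binary"]


def panel_subsample(panel, n: int, seed: int) -> SurveySample:
    """First-come volunteer recruitment: a random n panel members."""
    rng = np.random.default_rng(seed)
    take = rng.choice(len(panel), size=n, replace=False)
    return SurveySample(panel.data.iloc[take].reset_index(drop=True).copy(),
                        provenance="panel-quota", label="web")


def gee_battery_config(n: int, seed: int, n_questions: int = 4,
                       latent_sd: float = 1.0,
                       shift: dict | None = None) -> PopulationConfig:
    """Small question battery with within-person correlation via a shared
    latent logit offset; ``shift`` maps question index -> extra intercept
    (a planted survey difference)."""
    shift = shift or {}
    outs = tuple(OutcomeModel(f"q{j}", "binary", "CASI", "behavior",
                              -0.4 + 0.2 * j + shift.get(j, 0.0))
                 for j in range(n_questions))
    return PopulationConfig(
        n_population=n,
        covariates=(Covariate("sex", ("M", "F"), (0.5, 0.5)),),
        outcomes=outs, latent_sd=latent_sd, seed=seed)
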