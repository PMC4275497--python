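"""Quota construction, streaming recruitment, relaxation, fill rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelbench.benchmarks import BenchmarkSet
from panelbench.population import Covariate, OutcomeModel, PopulationConfig, \
    generate_population, true_benchmarks
from panelbench.quotas import (QuotaCell, QuotaSpec, build_quota_spec,
                               fill_rate, largest_remainder, omnibus_prescreen,
                               run_quota_survey)


def _panel(n=4000, seed=0, p_young=0.3):
    cfg = PopulationConfig(
        n_population=n,
        covariates=(Covariate("sex", ("M", "F"), (0.5, 0.5)),
                    Covariate("agegrp", ("18-24", "25-34"), (p_young, 1 - p_young))),
        outcomes=(OutcomeModel("y", "binary", "CASI", "behavior", 0.0),),
        seed=seed)
    return generate_population(cfg)


def _spec(panel, total, groupings=(("sex", "agegrp"),)):
    bench = true_benchmarks(panel, list(groupings))
    return build_quota_spec(bench, groupings, total)


# ---- largest remainder ----------------------------------------------------

@pytest.mark.parametrize("props,total,expected", [
    ([0.5, 0.5], 2000, [1000, 1000]),
    ([0.335, 0.333, 0.332], 1000, [335, 333, 332]),
])
def test_largest_remainder_known_cases(props, total, expected):
    assert largest_remainder(props, total) == expected


@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
       st.integers(1, 5000))
def test_largest_remainder_sums_exactly(raw, total):
    p = np.asarray(raw) / np.sum(raw)
    targets = largest_remainder(p, total)
    assert sum(targets) == total
    assert all(t >= 0 for t in targets)
    # each target within 1 of the exact share
    assert all(abs(t - pi * total) < 1 for t, pi in zip(targets, p))


def test_build_quota_spec_targets_sum_per_grouping():
    panel = _panel()
    spec = _spec(panel, 777, groupings=(("sex", "agegrp"), ("sex",)))
    for g in spec.groupings:
        assert sum(c.target for c in spec.cells_for(g)) == 777


# ---- fill rates ------------------------------------------------------------

@pytest.mark.parametrize("achieved,target,pct", [
    (211, 267, 79.0),   # undertarget young men
    (228, 267, 85.4),
    (267, 267, 100.0),
])
def test_fill_rate_percent_to_one_decimal(achieved, target, pct):
    spec = QuotaSpec((("agegrp",),),
                     [QuotaCell(("agegrp",), ("18-24",), target, achieved)],
                     target)
    assert fill_rate(spec)["percent"].iloc[0] == pct


def test_fill_rate_zero_target_undefined():
    spec = QuotaSpec((("agegrp",),), [QuotaCell(("agegrp",), ("18-24",), 0, 0)], 0)
    assert np.isnan(fill_rate(spec)["percent"].iloc[0])


# ---- quota streaming -------------------------------------------------------

def test_ample_panel_fills_without_relaxation():
    panel = _panel(6000)
    spec = _spec(panel, 1000)
    sample, log = run_quota_survey(panel, spec, seed=3)
    assert len(sample) == 1000
    assert not log.any_relaxed
    fr = fill_rate(sample.meta["quota_spec"])
    assert (fr["percent"] == 100.0).all()


def test_caps_respected_without_relaxation_across_seeds():
    panel = _panel(6000)
    spec = _spec(panel, 1000)
    for seed in range(5):
        sample, log = run_quota_survey(panel, spec, seed=seed)
        run_spec = sample.meta["quota_spec"]
        assert not log.any_relaxed
        assert all(c.achieved <= c.target for c in run_spec.cells)


def test_deficient_panel_relaxes_and_meets_target():
    # young people nearly absent from the panel; target wants 30%
    panel = _panel(4000, p_young=0.02)
    bench = BenchmarkSet({"sex*agegrp": {
        "M|18-24": 0.15, "M|25-34": 0.35, "F|18-24": 0.15, "F|25-34": 0.35}})
    spec = build_quota_spec(bench, (("sex", "agegrp"),), 1000)
    sample, log = run_quota_survey(panel, spec, seed=1)
    assert len(sample) == 1000
    assert log.any_relaxed
    fr = fill_rate(sample.meta["quota_spec"]).set_index("cell")
    assert fr.loc["M|18-24", "percent"] < 100.0   # the unfillable cell
    assert fr.loc["M|25-34", "achieved"] > fr.loc["M|25-34", "target"]  # overfilled


def test_category_absent_entirely_logs_its_shortfall():
    panel = _panel(800, p_young=0.3)
    panel.data = panel.data[panel.data["agegrp"] != "18-24"].reset_index(drop=True)
    bench = BenchmarkSet({"agegrp": {"18-24": 0.3, "25-34": 0.7}})
    spec = build_quota_spec(bench, (("agegrp",),), 500)
    sample, log = run_quota_survey(panel, spec, seed=2)
    run_spec = sample.meta["quota_spec"]
    young = [c for c in run_spec.cells if c.categories == ("18-24",)][0]
    assert young.achieved == 0
    assert log.any_relaxed
    assert len(sample) == 500  # others absorb the released shortfall


def test_unreachable_target_returns_partial_with_shortfall():
    panel = _panel(300)
    spec = _spec(panel, 1000)
    with pytest.warns(UserWarning, match="shortfall"):
        sample, log = run_quota_survey(panel, spec, seed=0)
    assert len(sample) + log.shortfall == 1000
    assert log.events[-1]["action"] == "shortfall"


def test_conservation_and_determinism():
    panel = _panel(3000, p_young=0.1)
    spec = _spec(panel, 800)
    s1, log = run_quota_survey(panel, spec, seed=9)
    never = len(panel) - (log.accepted + log.rejected)
    assert log.accepted + log.rejected + never == len(panel)
    assert never >= 0
    s2, _ = run_quota_survey(panel, spec, seed=9)
    pd.testing.assert_frame_equal(s1.data, s2.data)
    s3, _ = run_quota_survey(panel, spec, seed=10)
    assert not s1.data["person_id"].equals(s3.data["person_id"])


def test_accepted_composition_stable_in_expectation_over_seeds():
    # deficient panel => composition varies per seed but not its mean
    panel = _panel(1400, p_young=0.22)
    spec = _spec(panel, 900)
    shares = []
    for seed in range(50):
        s, _ = run_quota_survey(panel, spec, seed=seed)
        shares.append((s.data["agegrp"] == "18-24").mean())
    a, b = np.mean(shares[:25]), np.mean(shares[25:])
    assert abs(a - b) < 0.02


# ---- omnibus pre-screen ----------------------------------------------------

def test_omnibus_prescreen_sizes_and_warning():
    panel = _panel(1000)
    full = omnibus_prescreen(panel, ["sex"], 1000, seed=0)
    assert full.data["omnibus_flagged"].all()
    none = omnibus_prescreen(panel, ["sex"], 0, seed=0)
    assert not none.data["omnibus_flagged"].any()
    part = omnibus_prescreen(panel, ["sex"], 300, seed=0)
    assert part.data["omnibus_flagged"].sum() == 300
    with pytest.warns(UserWarning, match="exceeds panel size"):
        omnibus_prescreen(panel, ["sex"], 2000, seed=0)
    with pytest.raises(KeyError):
        omnibus_prescreen(panel, ["ghost"], 10, seed=0)
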