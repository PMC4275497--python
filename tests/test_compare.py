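"""Odds-ratio machinery, summaries, bootstrap and difference tests."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.miscmodels.ordinal_model import OrderedModel

from panelbench.benchmarks import BenchmarkSet
from panelbench.compare import (OutcomeMeta, abs_or, bootstrap_avg_abs_or,
                                combined_basic_avg, compare_avg_abs_or,
                                kish_neff, neutral_share,
                                or_vs_aggregate_benchmark,
                                or_vs_microdata_benchmark, reduce_categorical,
                                summarize, survey_or_results)
from panelbench.population import generate_population
from panelbench.samples import SurveySample

from _scenarios import binary_metas, exact_benchmarks, zero_bias_config


# ---- absolute OR -----------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(0.5, 2.0), (1.0, 1.0), (3.45, 3.45),
                                        (0.25, 4.0)])
def test_abs_or_folds_at_one(x, expected):
    assert abs_or(x) == expected


@pytest.mark.parametrize("bad", [0.0, -1.0, np.inf, np.nan])
def test_abs_or_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        abs_or(bad)


# ---- aggregate-benchmark ORs ----------------------------------------------

def test_aggregate_or_identity_and_known_values():
    r = or_vs_aggregate_benchmark(0.2, 1000, 0.2)
    assert r.or_value == pytest.approx(1.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0, abs=1e-12)
    # 12.9% vs 3.0% benchmark: cross-product by hand
    r2 = or_vs_aggregate_benchmark(0.129, 2000, 0.03)
    assert r2.or_value == pytest.approx((0.129 / 0.871) / (0.03 / 0.97), rel=1e-12)
    assert r2.or_value == pytest.approx(4.7888, abs=5e-4)
    # complementary proportions: (0.8/0.2)/(0.2/0.8) = 16
    r3 = or_vs_aggregate_benchmark(0.8, 500, 0.2)
    assert r3.or_value == pytest.approx(16.0, rel=1e-12)
    assert r.ci_low <= r.or_value <= r.ci_high


def test_aggregate_or_boundary_needs_continuity_flag():
    with pytest.raises(ValueError):
        or_vs_aggregate_benchmark(0.0, 100, 0.3)
    r = or_vs_aggregate_benchmark(0.0, 100, 0.3, continuity=True)
    assert 0 < r.or_value < 1


# ---- microdata ORs ---------------------------------------------------------

def _two_group_sample(y, w=None):
    df = pd.DataFrame({"out": y})
    if w is not None:
        df["weight"] = w
    return SurveySample(df)


def test_identical_samples_give_or_one():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 500)
    r = or_vs_microdata_benchmark(_two_group_sample(y), _two_group_sample(y),
                                  OutcomeMeta("out"))
    assert r.or_value == pytest.approx(1.0, abs=1e-10)


def test_weighted_or_equals_weighted_crossproduct():
    rng = np.random.default_rng(1)
    ys, yb = rng.integers(0, 2, 300), rng.integers(0, 2, 400)
    ws, wb = rng.uniform(0.5, 2.0, 300), rng.uniform(0.5, 2.0, 400)
    r = or_vs_microdata_benchmark(_two_group_sample(ys, ws),
                                  _two_group_sample(yb, wb),
                                  OutcomeMeta("out"))
    a, b = ws[ys == 1].sum(), ws[ys == 0].sum()
    c, d = wb[yb == 1].sum(), wb[yb == 0].sum()
    assert r.or_value == pytest.approx((a * d) / (b * c), rel=1e-6)


def test_constant_outcome_is_error():
    with pytest.raises(ValueError):
        or_vs_microdata_benchmark(_two_group_sample(np.ones(50, int)),
                                  _two_group_sample(np.r_[np.zeros(25, int),
                                                          np.ones(25, int)]),
                                  OutcomeMeta("out"))


def test_flip_invariance_of_binary_outcome():
    rng = np.random.default_rng(2)
    ys, yb = rng.integers(0, 2, 400), rng.integers(0, 2, 400)
    meta = OutcomeMeta("out")
    r1 = or_vs_microdata_benchmark(_two_group_sample(ys), _two_group_sample(yb), meta)
    r2 = or_vs_microdata_benchmark(_two_group_sample(1 - ys),
                                   _two_group_sample(1 - yb), meta)
    assert r2.or_value == pytest.approx(1.0 / r1.or_value, abs=1e-10)
    assert r2.abs_or == pytest.approx(r1.abs_or, abs=1e-10)
    assert r2.p_value == pytest.approx(r1.p_value, abs=1e-10)


def test_ordinal_or_matches_statsmodels_ordered_model():
    rng = np.random.default_rng(3)
    from scipy.special import expit
    n = 700
    th = np.array([-1.0, 0.0, 0.8, 1.7])
    x = np.r_[np.zeros(n), np.ones(n)]
    cum = expit(th[:, None] - 0.6 * x[None, :])
    y = 1 + (rng.random(2 * n)[None, :] > cum).sum(axis=0)
    meta = OutcomeMeta("out", scale="ordinal")
    r = or_vs_microdata_benchmark(_two_group_sample(y[n:]),
                                  _two_group_sample(y[:n]), meta)
    om = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
    assert np.log(r.or_value) == pytest.approx(om.params[0], abs=1e-4)
    assert r.method == "microdata-ordinal"


# ---- categorical reduction -------------------------------------------------

def test_reduce_categorical_mapping_and_errors():
    red = {"white": 0, "black": 1, "asian": 1}
    out = reduce_categorical(pd.Series(["white", "asian", "black"]), red)
    assert list(out) == [0, 1, 1]
    with pytest.raises(ValueError, match="not covered"):
        reduce_categorical(pd.Series(["white", "mixed"]), red)
    with pytest.raises(ValueError):
        OutcomeMeta("eth", scale="categorical")  # reduction required


def test_reduced_or_equals_prereduced_binary_or():
    rng = np.random.default_rng(4)
    cats = rng.choice(["w", "b", "a"], 600)
    cats_b = rng.choice(["w", "b", "a"], 600, p=[0.5, 0.3, 0.2])
    red = {"w": 0, "b": 1, "a": 1}
    meta_cat = OutcomeMeta("out", scale="categorical", binary_reduction=red)
    r_cat = or_vs_microdata_benchmark(_two_group_sample(cats),
                                      _two_group_sample(cats_b), meta_cat)
    r_bin = or_vs_microdata_benchmark(
        _two_group_sample(reduce_categorical(pd.Series(cats), red)),
        _two_group_sample(reduce_categorical(pd.Series(cats_b), red)),
        OutcomeMeta("out"))
    assert r_cat.or_value == pytest.approx(r_bin.or_value, abs=1e-12)


# ---- summaries -------------------------------------------------------------

def _fake_result(or_value, p=0.5, qtype="behavior", mode="CAPI"):
    from panelbench.compare import ORResult
    return ORResult(OutcomeMeta(f"o{or_value}", qtype=qtype, mode=mode),
                    or_value, or_value * 0.8, or_value * 1.2, p, "test")


def test_summarize_folds_and_counts():
    blocks = summarize([_fake_result(2.0), _fake_result(0.5)],
                       groups=(("All", None, None),))
    assert blocks[0].avg_abs_or == 2.0
    assert blocks[0].largest_abs_or == 2.0
    blocks = summarize([_fake_result(1.0, p=0.8), _fake_result(1.0, p=0.9)],
                       groups=(("All", None, None),))
    assert blocks[0].avg_abs_or == 1.0
    assert blocks[0].n_sig == 0


def test_summary_blocks_respect_bounds():
    rng = np.random.default_rng(5)
    results = [_fake_result(float(np.exp(rng.normal(0, 0.5))),
                            p=float(rng.random()),
                            qtype=rng.choice(["behavior", "opinion"]),
                            mode=rng.choice(["CAPI", "CASI"]))
               for _ in range(40)]
    for b in summarize(results):
        assert 1.0 <= b.avg_abs_or <= b.largest_abs_or
        assert 0 <= b.n_sig <= b.n_total


def test_neutral_share_weighted():
    df = pd.DataFrame({"op": [1, 2, 3, 3, 5], "weight": [1, 1, 2, 1, 1]})
    s = SurveySample(df)
    meta = OutcomeMeta("op", scale="ordinal", qtype="opinion")
    assert neutral_share(s, meta) == pytest.approx(3 / 6)
    assert neutral_share(s, meta, neutral_categories={1, 2, 3, 5}) == 1.0
    assert neutral_share(s, meta, neutral_categories={4}) == 0.0
    with pytest.raises(ValueError):
        neutral_share(s, meta, neutral_categories=set())


# ---- difference test -------------------------------------------------------

def test_compare_avg_abs_or_known_quantiles():
    z, p = compare_avg_abs_or((1.5, 0.1), (1.5, 0.1))
    assert (z, p) == (0.0, 1.0)
    se = 0.1
    diff = 1.959963984540054 * np.sqrt(2) * se
    z, p = compare_avg_abs_or((1.5 + diff, se), (1.5, se))
    assert p == pytest.approx(0.05, abs=1e-6)
    z, p = compare_avg_abs_or((1.5, 0.0), (1.5, 0.0))
    assert p == 1.0
    with pytest.warns(UserWarning):
        z, p = compare_avg_abs_or((1.6, 0.0), (1.5, 0.0))
    assert p == 0.0


# ---- bootstrap -------------------------------------------------------------

def test_bootstrap_deterministic_and_scales_with_n():
    cfg_s = zero_bias_config(1000, seed=21, n_outcomes=10)
    cfg_l = zero_bias_config(4000, seed=22, n_outcomes=10)
    bench = exact_benchmarks(cfg_s)
    metas = binary_metas(cfg_s)
    small = SurveySample(generate_population(cfg_s).data)
    large = SurveySample(generate_population(cfg_l).data)

    b1 = bootstrap_avg_abs_or([small], bench, metas, B=100, seed=5)
    b2 = bootstrap_avg_abs_or([small], bench, metas, B=100, seed=5)
    assert b1.se == b2.se
    assert len(b1.replicate_values) == 100

    b_large = bootstrap_avg_abs_or([large], bench, metas, B=100, seed=6)
    ratio = b_large.se / b1.se
    assert abs(ratio - 0.5) < 0.3 * 0.5  # root-n scaling within 30%


def test_bootstrap_repoststratifies_each_replicate():
    cfg = zero_bias_config(2000, seed=23, n_outcomes=6)
    bench = exact_benchmarks(cfg)
    metas = binary_metas(cfg)
    s = SurveySample(generate_population(cfg).data)
    margins = BenchmarkSet({"sex": {"M": 0.5, "F": 0.5}})
    b = bootstrap_avg_abs_or([s], bench, metas, B=20, margins=margins,
                             cells="sex", seed=7)
    assert b.se > 0
    assert b.n_failed_replicates == 0


def test_combined_basic_pooling():
    cfg = zero_bias_config(1500, seed=24, n_outcomes=8)
    bench = exact_benchmarks(cfg)
    metas = binary_metas(cfg)
    a = SurveySample(generate_population(cfg).data)
    block_single = summarize(survey_or_results(a, bench, metas),
                             groups=(("All", None, None),))[0]
    block_pooled = combined_basic_avg(a, a, bench, metas)
    assert block_pooled.avg_abs_or == pytest.approx(block_single.avg_abs_or,
                                                    abs=1e-10)
    b = SurveySample(generate_population(
        zero_bias_config(1500, seed=25, n_outcomes=8)).data)
    block_b = summarize(survey_or_results(b, bench, metas),
                        groups=(("All", None, None),))[0]
    pooled = combined_basic_avg(a, b, bench, metas)
    lo = min(block_single.avg_abs_or, block_b.avg_abs_or)
    hi = max(block_single.avg_abs_or, block_b.avg_abs_or)
    # pooling shrinks noise; typically between the two (not a theorem)
    assert pooled.avg_abs_or <= hi + 0.05


def test_kish_neff():
    assert kish_neff(np.ones(100)) == pytest.approx(100.0)
    assert kish_neff([2.0, 2.0]) == pytest.approx(2.0)
    assert kish_neff([3.0, 1.0]) < 2.0
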