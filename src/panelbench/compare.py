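"""Odds-ratio benchmark comparison and the absolute-OR summary battery.

Each survey estimate is compared with a benchmark through an odds ratio:

* against an *aggregate* benchmark (census / large-survey margin), the OR is
  the cross-product of the survey's weighted proportion against the fixed
  benchmark proportion, with survey-side-only variance via the delta method
  and a Kish effective sample size;
* against a *microdata* benchmark (the probability survey), the OR comes
  from a weighted logistic (binary) or proportional-odds (ordinal)
  regression of the outcome on a survey-membership indicator, with a
  probability-weight sandwich variance.

Bias summaries fold every OR to the absolute OR max(OR, 1/OR), average it
over outcome groups (all, behavior/opinion by CAPI/CASI), count outcomes
significantly different at the 5% level (no multiplicity adjustment), and
attach bootstrap standard errors by resampling participants within each
survey (benchmark held fixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .benchmarks import BenchmarkSet
from .ordinal import ProportionalOddsError, fit_proportional_odds
from .samples import SurveySample

Z95 = stats.norm.ppf(0.975)


# --------------------------------------------------------------------------
# outcome metadata and result types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeMeta:
    """How one outcome enters the comparison battery."""

    name: str
    scale: str = "binary"  # binary | ordinal | categorical
    mode: str = "CAPI"
    qtype: str = "behavior"
    binary_reduction: dict | None = None  # category -> 0/1
    n_categories: int = 5
    neutral_categories: frozenset = frozenset({3})

    def __post_init__(self):
        if self.scale == "categorical" and not self.binary_reduction:
            raise ValueError(
                f"categorical outcome {self.name!r} must declare a binary_reduction")

    def reduction(self) -> dict:
        if self.binary_reduction:
            return self.binary_reduction
        if self.scale == "ordinal":
            # default split: top-two box of a 5-point scale
            cut = self.n_categories - 1
            return {k: int(k >= cut) for k in range(1, self.n_categories + 1)}
        return {0: 0, 1: 1}


@dataclass
class ORResult:
    outcome: OutcomeMeta
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # aggregate-benchmark | microdata-logistic | microdata-ordinal

    @property
    def abs_or(self) -> float:
        return abs_or(self.or_value)


@dataclass
class SummaryBlock:
    label: str
    avg_abs_or: float
    largest_abs_or: float
    n_sig: int
    n_total: int


@dataclass
class BootstrapResult:
    B: int
    replicate_values: np.ndarray
    se: float
    seed: int
    avg_abs_or: float = np.nan           # point estimate on the original sample
    n_dropped_ors: int = 0               # ORs uncomputable within replicates
    n_failed_replicates: int = 0
    unreliable: bool = False


# --------------------------------------------------------------------------
# elementary pieces
# --------------------------------------------------------------------------

def abs_or(or_value: float) -> float:
    """Direction-free distance of an OR from 1: max(OR, 1/OR).

    An OR of 0.5 is treated as 2.0.
    """
    if not np.isfinite(or_value) or or_value <= 0:
        raise ValueError(f"odds ratio must be positive and finite, got {or_value}")
    return float(max(or_value, 1.0 / or_value))


def kish_neff(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w ** 2).sum())


def weighted_proportion(values, weights) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float((w * v).sum() / w.sum())


def reduce_categorical(values, reduction: dict):
    """Deterministically map a categorical/ordinal column to {0, 1}."""
    v = pd.Series(values)
    out = v.map(reduction)
    if out.isna().any():
        unseen = sorted(v[out.isna()].unique().tolist())
        raise ValueError(f"categories not covered by reduction: {unseen}")
    vals = set(out.unique()) - {0, 1}
    if vals:
        raise ValueError(f"reduction maps to non-binary values: {sorted(vals)}")
    return out.to_numpy(dtype=np.int64)


def _bench_reduced_prop(table: dict, reduction: dict) -> float:
    """Benchmark proportion of the '1' side of a declared binary split.

    Benchmark categories arrive as strings from serialisation; reduction
    keys may be ints (ordinal codes) or strings.
    """
    p = 0.0
    for cat, prop in table.items():
        key = cat
        if key not in reduction:
            try:
                key = int(cat)
            except (TypeError, ValueError):
                pass
        if key not in reduction:
            raise ValueError(f"benchmark category {cat!r} not covered by reduction")
        if reduction[key] == 1:
            p += prop
    return p


def _wald(log_or: float, se: float) -> tuple[float, float, float]:
    lo = np.exp(log_or - Z95 * se)
    hi = np.exp(log_or + Z95 * se)
    p = 2 * stats.norm.sf(abs(log_or) / se) if se > 0 else (1.0 if log_or == 0 else 0.0)
    return float(lo), float(hi), float(p)


# --------------------------------------------------------------------------
# odds ratios vs benchmarks
# --------------------------------------------------------------------------

def or_vs_aggregate_benchmark(weighted_prop: float, n_eff: float,
                              bench_prop: float, outcome: OutcomeMeta | None = None,
                              continuity: bool = False) -> ORResult:
    """OR of a weighted survey proportion against a fixed benchmark proportion.

    The benchmark is treated as a known constant; the variance of the log
    odds is survey-side only, 1 / (n_eff p (1-p)) by the delta method.
    """
    if not 0 < bench_prop < 1:
        raise ValueError(f"benchmark proportion must be in (0,1), got {bench_prop}")
    p = weighted_prop
    if not 0 < p < 1:
        if not continuity:
            raise ValueError(
                f"survey proportion {p} on the boundary; set continuity=True "
                f"to apply a 0.5-cell correction")
        x = p * n_eff
        p = (x + 0.5) / (n_eff + 1.0)
    log_or = np.log(p / (1 - p)) - np.log(bench_prop / (1 - bench_prop))
    se = np.sqrt(1.0 / (n_eff * p * (1 - p)))
    lo, hi, pval = _wald(log_or, se)
    return ORResult(outcome or OutcomeMeta("unnamed"), float(np.exp(log_or)),
                    lo, hi, pval, "aggregate-benchmark")


def _weighted_group_logit(values, weights) -> tuple[float, float]:
    """(logit p, sandwich variance of logit p) for one survey group."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = (w * y).sum() / w.sum()
    if p <= 0 or p >= 1:
        raise ValueError("outcome constant within a sample")
    var_p = ((w ** 2) * (y - p) ** 2).sum() / w.sum() ** 2
    return float(np.log(p / (1 - p))), float(var_p / (p * (1 - p)) ** 2)


def or_vs_microdata_benchmark(sample: SurveySample, benchmark_sample: SurveySample,
                              outcome: OutcomeMeta) -> ORResult:
    """OR for survey membership from weighted regression on stacked microdata.

    Binary (or reduced categorical) outcomes use weighted logistic
    regression with the benchmark as the reference level — for the
    saturated membership model the MLE equals the weighted 2x2
    cross-product ratio, computed in closed form, with a probability-weight
    sandwich variance.  Ordinal outcomes use a weighted proportional-odds
    model; on fit failure the declared binary split is used instead.
    """
    for s in (sample, benchmark_sample):
        if outcome.name not in s.data.columns:
            raise KeyError(f"outcome {outcome.name!r} missing from sample")

    if outcome.scale == "ordinal":
        y = np.concatenate([benchmark_sample.data[outcome.name].to_numpy(),
                            sample.data[outcome.name].to_numpy()])
        x = np.concatenate([np.zeros(len(benchmark_sample)), np.ones(len(sample))])
        w = np.concatenate([benchmark_sample.weights, sample.weights])
        if len(np.unique(sample.data[outcome.name])) < 2 or \
           len(np.unique(benchmark_sample.data[outcome.name])) < 2:
            raise ValueError(f"outcome {outcome.name!r} constant in a sample")
        try:
            fit = fit_proportional_odds(y, x[:, None], w)
            log_or = float(fit.beta[0])
            se = float(fit.beta_se()[0])
            lo, hi, pval = _wald(log_or, se)
            return ORResult(outcome, float(np.exp(log_or)), lo, hi, pval,
                            "microdata-ordinal")
        except ProportionalOddsError as exc:
            warnings.warn(f"proportional-odds fit failed for {outcome.name!r} "
                          f"({exc}); falling back to binary split")
            red = outcome.reduction()
            return _binary_micro_or(
                reduce_categorical(sample.data[outcome.name], red), sample.weights,
                reduce_categorical(benchmark_sample.data[outcome.name], red),
                benchmark_sample.weights, outcome)

    red = outcome.reduction()
    ys = reduce_categorical(sample.data[outcome.name], red) \
        if outcome.scale != "binary" else sample.data[outcome.name].to_numpy()
    yb = reduce_categorical(benchmark_sample.data[outcome.name], red) \
        if outcome.scale != "binary" else benchmark_sample.data[outcome.name].to_numpy()
    return _binary_micro_or(ys, sample.weights, yb, benchmark_sample.weights, outcome)


def _binary_micro_or(ys, ws, yb, wb, outcome: OutcomeMeta) -> ORResult:
    ls, vs = _weighted_group_logit(ys, ws)
    lb, vb = _weighted_group_logit(yb, wb)
    log_or = ls - lb
    se = np.sqrt(vs + vb)
    lo, hi, pval = _wald(log_or, se)
    return ORResult(outcome, float(np.exp(log_or)), lo, hi, pval,
                    "microdata-logistic")


# --------------------------------------------------------------------------
# batteries and summaries
# --------------------------------------------------------------------------

def survey_or_results(sample: SurveySample, benchmark, outcomes,
                      continuity: bool = False) -> list[ORResult]:
    """One ORResult per outcome, dispatching on the benchmark type.

    ``benchmark`` is a :class:`BenchmarkSet` (aggregate margins; binary and
    reduced outcomes only) or a :class:`SurveySample` (microdata).
    """
    results = []
    for meta in outcomes:
        if isinstance(benchmark, BenchmarkSet):
            red = meta.reduction()
            vals = sample.data[meta.name]
            y = vals.to_numpy() if meta.scale == "binary" else \
                reduce_categorical(vals, red)
            table = benchmark[meta.name]
            p_b = _bench_reduced_prop(table, red)
            p_s = weighted_proportion(y, sample.weights)
            results.append(or_vs_aggregate_benchmark(
                p_s, kish_neff(sample.weights), p_b, meta, continuity=continuity))
        else:
            results.append(or_vs_microdata_benchmark(sample, benchmark, meta))
    return results


GROUPS = (("All", None, None),
          ("Behavior CAPI", "behavior", "CAPI"),
          ("Behavior CASI", "behavior", "CASI"),
          ("Opinion CAPI", "opinion", "CAPI"),
          ("Opinion CASI", "opinion", "CASI"))


def summarize(results, alpha: float = 0.05, label_prefix: str = "",
              groups=GROUPS) -> list[SummaryBlock]:
    """Average/largest absolute OR and 5%-level significance counts,
    overall and by question type x interview mode."""
    if not results:
        raise ValueError("no OR results to summarize")
    blocks = []
    for label, qtype, mode in groups:
        sel = [r for r in results
               if (qtype is None or r.outcome.qtype == qtype)
               and (mode is None or r.outcome.mode == mode)]
        if not sel:
            if qtype is not None:
                warnings.warn(f"no outcomes in group {label!r}; block omitted")
            continue
        avals = [r.abs_or for r in sel]
        blocks.append(SummaryBlock(
            label=(label_prefix + label).strip(),
            avg_abs_or=float(np.mean(avals)),
            largest_abs_or=float(np.max(avals)),
            n_sig=int(sum(r.p_value < alpha for r in sel)),
            n_total=len(sel)))
    return blocks


def neutral_share(sample: SurveySample, outcome: OutcomeMeta,
                  neutral_categories=None) -> float:
    """Weighted share choosing a neutral category ('neither agree nor
    disagree' style midpoints) — the satisficing indicator."""
    cats = set(neutral_categories) if neutral_categories is not None \
        else set(outcome.neutral_categories)
    if not cats:
        raise ValueError("neutral category set is empty")
    vals = sample.data[outcome.name]
    return weighted_proportion(vals.isin(cats).to_numpy(), sample.weights)


# --------------------------------------------------------------------------
# bootstrap machinery
# --------------------------------------------------------------------------

class _FastSample:
    """Pre-extracted arrays for fast within-survey resampling."""

    def __init__(self, sample: SurveySample, outcomes, margins, cells):
        self.n = len(sample)
        self.base_weights = sample.weights
        self.values = {}
        for meta in outcomes:
            v = sample.data[meta.name]
            if meta.scale == "ordinal":
                # 0-based category codes for fast weighted tabulation
                self.values[meta.name] = v.to_numpy(dtype=np.int64) - 1
            elif meta.scale == "binary":
                self.values[meta.name] = v.to_numpy(dtype=np.int64)
            else:
                self.values[meta.name] = reduce_categorical(v, meta.reduction())
        self.cell_codes = None
        if margins is not None:
            names = [cells] if isinstance(cells, str) else list(cells)
            lab = sample.data[names[0]].astype(str)
            for v in names[1:]:
                lab = lab + "|" + sample.data[v].astype(str)
            from .benchmarks import cross_key
            table = margins[cross_key(names)]
            cats = list(table)
            code = {c: i for i, c in enumerate(cats)}
            self.cell_codes = lab.map(code).to_numpy(dtype=np.int64)
            self.cell_targets = np.array([table[c] for c in cats])

    def replicate_weights(self, idx) -> np.ndarray | None:
        """Poststratified weights for a resample (None if a cell emptied)."""
        if self.cell_codes is None:
            w = self.base_weights[idx]
            return w / w.mean()
        codes = self.cell_codes[idx]
        counts = np.bincount(codes, minlength=len(self.cell_targets))
        if np.any((counts == 0) & (self.cell_targets > 0)):
            return None
        with np.errstate(divide="ignore"):
            factor = np.where(counts > 0,
                              self.cell_targets / (counts / len(idx)), 0.0)
        w = factor[codes]
        return w / w.mean()


def _replicate_abs_ors(fasts, idxs, ws, benchmark_stats, outcomes) -> tuple[list, int]:
    """Per-outcome absolute ORs for one (possibly pooled) replicate.

    The proportional-odds likelihood with a single membership regressor
    depends on the data only through the weight totals per
    category x survey cell, so ordinal refits run on those sufficient
    statistics rather than the full stack.
    """
    out = []
    dropped = 0
    for meta in outcomes:
        y = np.concatenate([f.values[meta.name][i] for f, i in zip(fasts, idxs)])
        w = np.concatenate(ws)
        bstat = benchmark_stats[meta.name]
        try:
            if meta.scale == "ordinal" and bstat["kind"] == "micro-ordinal":
                K = meta.n_categories
                wsum = np.bincount(y, weights=w, minlength=K)
                if np.count_nonzero(wsum) < 2:
                    raise ValueError("degenerate ordinal distribution")
                cats = np.concatenate([np.arange(K), np.arange(K)])
                xx = np.concatenate([np.zeros(K), np.ones(K)])
                ww = np.concatenate([bstat["wsum"], wsum])
                keep = ww > 0
                fit = fit_proportional_odds(cats[keep], xx[keep, None], ww[keep])
                out.append(abs_or(float(np.exp(fit.beta[0]))))
            else:
                p_s = float((w * y).sum() / w.sum())
                if not 0 < p_s < 1:
                    raise ValueError("degenerate proportion")
                p_b = bstat["p"]
                out.append(abs_or((p_s / (1 - p_s)) / (p_b / (1 - p_b))))
        except (ValueError, ProportionalOddsError):
            dropped += 1
    return out, dropped


def _benchmark_stats(benchmark, outcomes) -> dict:
    stats_ = {}
    for meta in outcomes:
        if isinstance(benchmark, BenchmarkSet):
            p_b = _bench_reduced_prop(benchmark[meta.name], meta.reduction())
            stats_[meta.name] = {"kind": "aggregate", "p": p_b}
        elif meta.scale == "ordinal":
            yb = benchmark.data[meta.name].to_numpy(dtype=np.int64) - 1
            stats_[meta.name] = {"kind": "micro-ordinal",
                                 "wsum": np.bincount(yb, weights=benchmark.weights,
                                                     minlength=meta.n_categories)}
        else:
            red = meta.reduction()
            y = benchmark.data[meta.name].to_numpy() if meta.scale == "binary" \
                else reduce_categorical(benchmark.data[meta.name], red)
            stats_[meta.name] = {"kind": "micro-binary",
                                 "p": weighted_proportion(y, benchmark.weights)}
    return stats_


def bootstrap_avg_abs_or(samples, benchmark, outcomes, B: int = 100,
                         margins=None, cells=None, seed: int = 0) -> BootstrapResult:
    """Bootstrap SE of the average absolute OR, resampling participants
    with replacement independently within each input survey (sizes
    preserved), re-poststratifying each replicate, and holding the
    benchmark fixed.

    Multiple ``samples`` are pooled (the combined-basic-surveys case).  An
    OR that cannot be computed in a replicate is dropped from that
    replicate's average; if more than 10% of replicates are affected the SE
    is flagged unreliable.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if isinstance(samples, SurveySample):
        samples = [samples]
    outcomes = list(outcomes)
    fasts = [_FastSample(s, outcomes, margins, cells) for s in samples]
    bstats = _benchmark_stats(benchmark, outcomes)
    rng = np.random.default_rng(seed)

    # point estimate on the original samples (identity resample)
    idx0 = [np.arange(f.n) for f in fasts]
    w0 = [f.base_weights / f.base_weights.mean() for f in fasts]
    point_vals, _ = _replicate_abs_ors(fasts, idx0, w0, bstats, outcomes)
    point = float(np.mean(point_vals)) if point_vals else np.nan

    reps = []
    dropped_total = 0
    affected = 0
    failed = 0
    for _ in range(B):
        idxs = [rng.integers(0, f.n, f.n) for f in fasts]
        ws = []
        ok = True
        for f, i in zip(fasts, idxs):
            w = f.replicate_weights(i)
            if w is None:
                ok = False
                break
            ws.append(w)
        if not ok:
            failed += 1
            continue
        vals, dropped = _replicate_abs_ors(fasts, idxs, ws, bstats, outcomes)
        if not vals:
            failed += 1
            continue
        if dropped:
            affected += 1
            dropped_total += dropped
        reps.append(float(np.mean(vals)))

    reps = np.asarray(reps)
    if len(reps) < 2:
        raise RuntimeError("fewer than 2 usable bootstrap replicates")
    se = float(np.std(reps, ddof=1))
    unreliable = (affected + failed) > 0.1 * B
    if unreliable:
        warnings.warn(f"bootstrap SE flagged unreliable: {affected} replicates "
                      f"with dropped ORs, {failed} failed, of B={B}")
    return BootstrapResult(B=B, replicate_values=reps, se=se, seed=seed,
                           avg_abs_or=point, n_dropped_ors=dropped_total,
                           n_failed_replicates=failed, unreliable=unreliable)


def compare_avg_abs_or(a: tuple[float, float], b: tuple[float, float]) -> tuple[float, float]:
    """Normal-approximation test for a difference in average absolute ORs.

    ``a`` and ``b`` are (average, bootstrap SE) pairs from independent
    surveys.  Returns (z, two-sided p).
    """
    avg_a, se_a = a
    avg_b, se_b = b
    denom = np.sqrt(se_a ** 2 + se_b ** 2)
    if denom == 0:
        if avg_a == avg_b:
            return 0.0, 1.0
        warnings.warn("zero combined SE with unequal averages; p = 0")
        return np.inf if avg_a > avg_b else -np.inf, 0.0
    z = (avg_a - avg_b) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


def combined_basic_avg(sample_a: SurveySample, sample_b: SurveySample,
                       benchmark, outcomes, method: str = "pool") -> SummaryBlock:
    """Average absolute OR for two basic-quota surveys treated as one.

    ``method="pool"`` stacks the two samples (weights rescaled jointly to
    mean 1) and computes one OR per outcome on the pooled sample;
    ``method="average"`` averages the two surveys' per-outcome absolute ORs.
    """
    shared = []
    for meta in outcomes:
        if meta.name in sample_a.data.columns and meta.name in sample_b.data.columns:
            shared.append(meta)
        else:
            warnings.warn(f"outcome {meta.name!r} missing from one survey; excluded")
    if not shared:
        raise ValueError("no shared outcomes")

    if method == "average":
        ra = survey_or_results(sample_a, benchmark, shared)
        rb = survey_or_results(sample_b, benchmark, shared)
        avals = [(x.abs_or + y.abs_or) / 2 for x, y in zip(ra, rb)]
        return SummaryBlock("combined-basic (average)", float(np.mean(avals)),
                            float(np.max(avals)), -1, len(shared))
    if method != "pool":
        raise ValueError(f"unknown method {method!r}")

    pooled = pd.concat([sample_a.data, sample_b.data], ignore_index=True)
    pooled = pooled.copy()
    pooled["weight"] = pooled["weight"] / pooled["weight"].mean()
    pooled_sample = SurveySample(pooled, provenance="panel-quota",
                                 label="combined-basic")
    results = survey_or_results(pooled_sample, benchmark, shared)
    block = summarize(results)[0]
    block.label = "combined-basic (pooled)"
    return block
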