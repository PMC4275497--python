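"""Quota-modification variable selection.

Two procedures choose which extra variables should become quota controls:

* a forward-stepwise logistic regression of a survey-membership indicator
  (probability survey vs web survey, or probability survey vs panel
  omnibus) on candidate variables, entering by likelihood-ratio p-value
  below alpha, with a post-hoc collinearity rule that keeps the more
  significant member of any strongly associated pair;
* a bivariate screen ranking candidates by how many key outcomes they are
  associated with, both marginally and after adjusting for the basic quota
  variables (age group, partnership status, region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import association
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .samples import SurveySample

DEFAULT_ADJUSTERS = ("agegrp", "partnership", "region")


@dataclass
class SelectionResult:
    selected: list[tuple[str, float]]  # (variable, entry p-value), entry order
    dropped_for_collinearity: list[tuple[str, str, float]] = field(default_factory=list)
    candidate_pool: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def selected_names(self) -> list[str]:
        return [v for v, _ in self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": [{"variable": v, "entry_p": p} for v, p in self.selected],
            "dropped_for_collinearity": [
                {"dropped": d, "kept": k, "cramers_v": v}
                for d, k, v in self.dropped_for_collinearity],
            "candidate_pool": self.candidate_pool,
            "skipped": self.skipped,
        }


def _dummies(frame: pd.DataFrame, variables) -> np.ndarray:
    """Full dummy blocks (drop-first) for a list of categorical variables."""
    if not variables:
        return np.empty((len(frame), 0))
    blocks = [pd.get_dummies(frame[v].astype(str), prefix=v, drop_first=True)
              .to_numpy(dtype=float) for v in variables]
    return np.hstack(blocks)


def _logit_llf(y: np.ndarray, X: np.ndarray) -> float:
    X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 30:
        raise PerfectSeparationError("separation suspected")
    return float(res.llf)


def _lrt_p(y, frame, base_vars, candidate) -> float:
    """Likelihood-ratio p-value for adding ``candidate``'s dummy block."""
    X0 = _dummies(frame, base_vars)
    X1 = _dummies(frame, list(base_vars) + [candidate])
    df = X1.shape[1] - X0.shape[1]
    if df <= 0:
        return 1.0
    ll0 = _logit_llf(y, X0)
    ll1 = _logit_llf(y, X1)
    lr = max(0.0, 2 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, df))


def cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b).to_numpy()
    if min(tab.shape) < 2:
        return 0.0
    return float(association(tab, method="cramer"))


def _forward_stepwise(frame: pd.DataFrame, y: np.ndarray, candidates,
                      alpha: float, condition_on=()) -> SelectionResult:
    entered: list[tuple[str, float]] = []
    skipped: list[str] = []
    pool = list(candidates)
    remaining = list(pool)
    while remaining:
        pvals = {}
        for cand in list(remaining):
            base = list(condition_on) + [v for v, _ in entered]
            try:
                pvals[cand] = _lrt_p(y, frame, base, cand)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"candidate {cand!r} skipped: {exc}")
                remaining.remove(cand)
                skipped.append(cand)
        if not pvals:
            break
        best = min(pvals, key=pvals.get)
        if pvals[best] >= alpha:
            break
        entered.append((best, pvals[best]))
        remaining.remove(best)

    # collinearity rule: among entered variables, if a pair is strongly
    # associated (Cramér's V > 0.5) keep the one with the smaller entry p
    dropped: list[tuple[str, str, float]] = []
    keep = list(entered)
    changed = True
    while changed:
        changed = False
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                (vi, pi), (vj, pj) = keep[i], keep[j]
                v = cramers_v(frame[vi], frame[vj])
                if v > 0.5:
                    drop, keep_var = (keep[i], vj) if pi > pj else (keep[j], vi)
                    dropped.append((drop[0], keep_var, v))
                    keep.remove(drop)
                    changed = True
                    break
            if changed:
                break
    return SelectionResult(selected=keep, dropped_for_collinearity=dropped,
                           candidate_pool=pool, skipped=skipped)


def stepwise_membership_selection(prob_sample: SurveySample,
                                  web_sample: SurveySample, candidates,
                                  alpha: float = 0.05,
                                  condition_on=()) -> SelectionResult:
    """Forward stepwise logistic selection of membership predictors.

    Stacks the probability sample and the web survey with a binary
    indicator (web = 1) and enters, at each step, the candidate with the
    smallest likelihood-ratio p-value below ``alpha`` given the variables
    already entered; stops when none qualifies.
    """
    frame = pd.concat([prob_sample.data[list(set(candidates) | set(condition_on))],
                       web_sample.data[list(set(candidates) | set(condition_on))]],
                      ignore_index=True)
    y = np.concatenate([np.zeros(len(prob_sample)), np.ones(len(web_sample))])
    return _forward_stepwise(frame, y, candidates, alpha, condition_on)


def omnibus_membership_selection(prob_sample: SurveySample,
                                 omnibus_sample: SurveySample, candidates,
                                 alpha: float = 0.05,
                                 condition_on=()) -> SelectionResult:
    """Same contract as :func:`stepwise_membership_selection` with the
    panel-omnibus respondents as the second stratum."""
    return stepwise_membership_selection(prob_sample, omnibus_sample,
                                         candidates, alpha, condition_on)


def _ordinal_lrt_p(y, frame, base_vars, candidate) -> float:
    X0 = _dummies(frame, base_vars)
    X1 = _dummies(frame, list(base_vars) + [candidate])
    df = X1.shape[1] - X0.shape[1]
    if df <= 0:
        return 1.0

    def llf(X):
        if X.shape[1] == 0:
            # thresholds-only model: multinomial log-likelihood of margins
            _, counts = np.unique(y, return_counts=True)
            p = counts / counts.sum()
            return float((counts * np.log(p)).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        return float(res.llf)

    lr = max(0.0, 2 * (llf(X1) - llf(X0)))
    return float(stats.chi2.sf(lr, df))


def bivariate_screen(prob_sample: SurveySample, key_outcomes, candidates,
                     adjusters=DEFAULT_ADJUSTERS, alpha: float = 0.05) -> pd.DataFrame:
    """Rank candidates by their number of robust outcome associations.

    For each candidate, counts the key outcomes for which both the
    bivariate association and the association adjusted for the basic quota
    variables are significant at ``alpha`` (logistic for binary outcomes,
    proportional odds for ordinal).  Returns a DataFrame sorted by count.
    """
    if not key_outcomes:
        raise ValueError("key_outcomes is empty")
    frame = prob_sample.data
    rows = []
    for cand in candidates:
        count = 0
        detail = []
        for meta in key_outcomes:
            name, scale = (meta.name, meta.scale) if hasattr(meta, "name") \
                else (meta, "binary")
            y = frame[name].to_numpy()
            try:
                if scale == "ordinal":
                    p_biv = _ordinal_lrt_p(y, frame, [], cand)
                    p_adj = _ordinal_lrt_p(y, frame, list(adjusters), cand)
                else:
                    p_biv = _lrt_p(y, frame, [], cand)
                    p_adj = _lrt_p(y, frame, list(adjusters), cand)
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"association of {cand!r} with {name!r} skipped: {exc}")
                continue
            hit = (p_biv < alpha) and (p_adj < alpha)
            count += hit
            detail.append((name, p_biv, p_adj, hit))
        rows.append({"candidate": cand, "n_significant": count,
                     "n_outcomes": len(key_outcomes)})
    table = pd.DataFrame(rows).sort_values("n_significant", ascending=False,
                                           kind="stable").reset_index(drop=True)
    return table
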