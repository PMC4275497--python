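"""Cross-panel consistency test with within-person clustering.

Two web surveys asking the same battery of questions are compared by
stacking all (person, question, binary response) rows and fitting marginal
logit models with an independence working correlation and a sandwich
variance clustered on person — the generalized-estimating-equations
estimator, whose point estimates coincide with pooled logistic maximum
likelihood under the independence working structure.

Three things are reported: per-question survey effects, a single
common-effect test from the main-effect-only model, and a joint Wald test
that every survey term is zero (the primary consistency test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .samples import SurveySample


@dataclass
class GEEResult:
    per_question: pd.DataFrame     # question, log_or, se, z, p
    common_log_or: float
    common_se: float
    common_z: float
    common_p: float
    joint_stat: float
    joint_df: int
    joint_p: float
    dropped_questions: list

    def to_dict(self) -> dict:
        return {
            "per_question": self.per_question.to_dict(orient="records"),
            "common_effect": {"log_or": self.common_log_or, "se": self.common_se,
                              "z": self.common_z, "p": self.common_p},
            "joint_wald": {"stat": self.joint_stat, "df": self.joint_df,
                           "p": self.joint_p},
            "dropped_questions": self.dropped_questions,
        }


def stack_for_gee(sample_a: SurveySample, sample_b: SurveySample,
                  outcomes) -> pd.DataFrame:
    """Long-format stack of the two surveys' shared binary responses.

    Ordinal and categorical outcomes are reduced through their declared
    binary split.  Person ids are prefixed by survey so clusters never
    collide; absent responses are omitted, not imputed.
    """
    from .compare import reduce_categorical

    shared = [m for m in outcomes
              if m.name in sample_a.data.columns and m.name in sample_b.data.columns]
    if not shared:
        raise ValueError("no shared outcomes between the two surveys")
    frames = []
    for tag, s in (("A", sample_a), ("B", sample_b)):
        for meta in shared:
            vals = s.data[meta.name]
            y = vals.to_numpy(dtype=np.int64) if meta.scale == "binary" \
                else reduce_categorical(vals, meta.reduction())
            mask = pd.notna(vals).to_numpy()
            frames.append(pd.DataFrame({
                "person_id": tag + ":" + s.data["person_id"].astype(str)[mask],
                "survey": 0 if tag == "A" else 1,
                "question": meta.name,
                "response": y[mask],
                "weight": s.weights[mask],
            }))
    return pd.concat(frames, ignore_index=True)


def gee_consistency_test(stack: pd.DataFrame, use_weights: bool = False) -> GEEResult:
    """Do the two surveys give the same answers question by question?

    Fits a logit marginal model with question fixed effects and (a) one
    survey effect per question, (b) a single common survey effect, both
    with person-clustered sandwich variances; the joint Wald test that all
    per-question survey effects are zero is the primary output.
    """
    questions = sorted(stack["question"].unique())
    if len(questions) < 2:
        raise ValueError("need at least 2 questions")
    if stack["survey"].nunique() != 2:
        raise ValueError("both surveys must be represented")

    dropped = []
    for q in list(questions):
        sub = stack.loc[stack["question"] == q, "response"]
        if sub.nunique() < 2:
            warnings.warn(f"question {q!r} constant across both surveys; dropped")
            questions.remove(q)
            dropped.append(q)
    if len(questions) < 2:
        raise ValueError("fewer than 2 usable questions after dropping constants")
    data = stack[stack["question"].isin(questions)].reset_index(drop=True)

    qdum = pd.get_dummies(data["question"]).astype(float)  # all K columns, no intercept
    qcols = list(qdum.columns)
    surv = data["survey"].to_numpy(dtype=float)
    groups = data["person_id"].to_numpy()
    y = data["response"].to_numpy(dtype=float)
    fw = data["weight"].to_numpy(dtype=float) if use_weights else None

    def fit(X):
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=fw)
        try:
            return model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        except Exception as exc:  # noqa: BLE001 - surface with question context
            raise RuntimeError(
                f"consistency model failed to converge for questions {questions}"
            ) from exc

    # (a) per-question survey effects: question dummies + survey x question
    X_int = np.hstack([qdum.to_numpy(), qdum.to_numpy() * surv[:, None]])
    res_int = fit(X_int)
    k = len(qcols)
    eff = res_int.params[k:]
    se = res_int.bse[k:]
    z = eff / se
    per_q = pd.DataFrame({"question": qcols, "log_or": eff, "se": se, "z": z,
                          "p": 2 * stats.norm.sf(np.abs(z))})

    # joint Wald: all survey terms zero
    V = np.asarray(res_int.cov_params())[k:, k:]
    stat = float(eff @ np.linalg.solve(V, eff))
    joint_p = float(stats.chi2.sf(stat, k))

    # (b) common-effect model: question dummies + survey main effect
    X_main = np.hstack([qdum.to_numpy(), surv[:, None]])
    res_main = fit(X_main)
    c_eff = float(res_main.params[-1])
    c_se = float(res_main.bse[-1])
    c_z = c_eff / c_se
    return GEEResult(per_question=per_q, common_log_or=c_eff, common_se=c_se,
                     common_z=float(c_z), common_p=float(2 * stats.norm.sf(abs(c_z))),
                     joint_stat=stat, joint_df=k, joint_p=joint_p,
                     dropped_questions=dropped)
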