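"""Poststratification and raking to external margins.

Every survey in the comparison is poststratified to the census analog for
age group within sex; the probability survey can additionally be raked to a
region margin by iterative proportional fitting.  Web surveys are not
weighted by region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmarks import BenchmarkSet, cross_key, cross_label
from .samples import SurveySample, WeightedSample

IPF_TOL = 1e-10
IPF_MAX_ITER = 1000


def _cell_labels(data: pd.DataFrame, variables) -> pd.Series:
    names = [variables] if isinstance(variables, str) else list(variables)
    lab = data[names[0]].astype(str)
    for v in names[1:]:
        lab = lab + "|" + data[v].astype(str)
    return lab


def _target_series(margins: BenchmarkSet, variables) -> pd.Series:
    table = margins[cross_key(variables if not isinstance(variables, str) else variables)]
    return pd.Series(table, dtype=float)


def poststratify(sample: SurveySample, margins: BenchmarkSet,
                 cells) -> WeightedSample:
    """Weight so the sample's distribution over ``cells`` matches ``margins``.

    ``cells`` is a variable name or a tuple of names forming a full cross
    (e.g. ``("sex", "agegrp")``).  The new weight of a person in cell c is
    the old weight times target(c) / weighted-sample-share(c), rescaled to
    mean 1.  An empty sample cell with a nonzero target is a hard error.
    """
    names = [cells] if isinstance(cells, str) else list(cells)
    lab = _cell_labels(sample.data, names)
    target = _target_series(margins, names)

    unknown = set(lab.unique()) - set(target.index)
    if unknown:
        raise ValueError(f"sample cells not in margins: {sorted(unknown)}")

    w = sample.weights
    share = pd.Series(w, index=lab.values).groupby(level=0).sum() / w.sum()

    factors = {}
    for cell, t in target.items():
        s = share.get(cell, 0.0)
        if t > 0 and s == 0:
            raise ValueError(f"poststratification cell {cell!r} is empty but has "
                             f"target proportion {t}")
        if t == 0 and s > 0:
            raise ValueError(f"poststratification cell {cell!r} has zero target "
                             f"but contains sample members")
        factors[cell] = t / s if s > 0 else 0.0

    new_w = w * lab.map(factors).to_numpy()
    new_w = new_w / new_w.mean()
    data = sample.data.copy()
    data["weight"] = new_w
    return WeightedSample(data, provenance=sample.provenance, label=sample.label,
                          meta={**sample.meta, "poststratified_to": cross_key(names)},
                          margin_variables=tuple(names))


def rake(sample: SurveySample, margins: BenchmarkSet, groupings,
         tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER) -> WeightedSample:
    """Iterative proportional fitting over several margins.

    ``groupings`` is a list of variable names / crosses, each present in
    ``margins``.  Converged when the maximum relative weight change in a
    full cycle is below ``tol``.
    """
    groupings = [g if isinstance(g, str) else tuple(g) for g in groupings]
    labels = [_cell_labels(sample.data, g) for g in groupings]
    targets = [_target_series(margins, g) for g in groupings]

    w = sample.weights.copy()
    for _ in range(max_iter):
        w_prev = w.copy()
        for lab, target in zip(labels, targets):
            share = pd.Series(w, index=lab.values).groupby(level=0).sum() / w.sum()
            missing = [c for c, t in target.items() if t > 0 and share.get(c, 0) == 0]
            if missing:
                raise ValueError(f"raking cell(s) empty with nonzero target: {missing}")
            factor = {c: (t / share[c] if share.get(c, 0) > 0 else 0.0)
                      for c, t in target.items()}
            w = w * lab.map(factor).to_numpy()
        rel = np.max(np.abs(w - w_prev) / np.maximum(w_prev, 1e-300))
        if rel < tol:
            break
    else:
        raise RuntimeError(f"raking did not converge in {max_iter} iterations")

    w = w / w.mean()
    data = sample.data.copy()
    data["weight"] = w
    return WeightedSample(data, provenance=sample.provenance, label=sample.label,
                          meta={**sample.meta,
                                "raked_to": [cross_key(g) for g in groupings]},
                          margin_variables=tuple(groupings))


def weighted_tabulation(sample: SurveySample, variables) -> dict[str, float]:
    """Weighted category shares for a variable or cross (sums to 1)."""
    lab = _cell_labels(sample.data, [variables] if isinstance(variables, str)
                       else list(variables))
    w = sample.weights
    shares = pd.Series(w, index=lab.values).groupby(level=0).sum() / w.sum()
    return shares.to_dict()
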