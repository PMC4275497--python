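"""Quota-controlled recruitment from a volunteer panel.

Quota cells are defined on crosses of covariates (age group within sex,
partnership status within sex, region, plus any modification variables).
Panel members are streamed in seeded random order and accepted only while
every cell they fall into is still under target.  When the stream runs out
before the total target is met, quotas are relaxed one cell at a time —
the unfilled cell with the largest absolute shortfall loses its cap — and
streaming restarts over the remaining members, mimicking re-invitation
waves.  The relaxation log records every release and any final shortfall.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmarks import BenchmarkSet, cross_key, cross_label
from .population import Population
from .samples import SurveySample


@dataclass
class QuotaCell:
    grouping: tuple[str, ...]
    categories: tuple[str, ...]
    target: int
    achieved: int = 0
    relaxed: bool = False

    @property
    def label(self) -> str:
        return cross_label(self.categories)


@dataclass
class QuotaSpec:
    groupings: tuple[tuple[str, ...], ...]
    cells: list[QuotaCell]
    total_target: int

    def validate(self) -> None:
        for g in self.groupings:
            tot = sum(c.target for c in self.cells if c.grouping == g)
            if tot != self.total_target:
                raise ValueError(
                    f"targets for grouping {cross_key(g)} sum to {tot}, "
                    f"expected {self.total_target}")
        if any(c.target < 0 for c in self.cells):
            raise ValueError("negative cell target")

    def cells_for(self, grouping) -> list[QuotaCell]:
        g = tuple([grouping] if isinstance(grouping, str) else grouping)
        return [c for c in self.cells if c.grouping == g]

    def reset(self) -> "QuotaSpec":
        return QuotaSpec(self.groupings,
                         [QuotaCell(c.grouping, c.categories, c.target)
                          for c in self.cells],
                         self.total_target)

    # ---- serialisation -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "total_target": self.total_target,
            "groupings": [list(g) for g in self.groupings],
            "cells": [{"grouping": list(c.grouping), "categories": list(c.categories),
                       "target": c.target, "achieved": c.achieved,
                       "relaxed": c.relaxed} for c in self.cells],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuotaSpec":
        doc = yaml.safe_load(Path(path).read_text())
        cells = [QuotaCell(tuple(c["grouping"]), tuple(c["categories"]),
                           int(c["target"]), int(c.get("achieved", 0)),
                           bool(c.get("relaxed", False))) for c in doc["cells"]]
        return cls(tuple(tuple(g) for g in doc["groupings"]), cells,
                   int(doc["total_target"]))


@dataclass
class RelaxationLog:
    events: list[dict] = field(default_factory=list)
    shortfall: int = 0
    contacted: int = 0
    accepted: int = 0
    rejected: int = 0

    @property
    def any_relaxed(self) -> bool:
        return any(e["action"] == "relax" for e in self.events)

    def to_json_lines(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


def largest_remainder(proportions, total: int) -> list[int]:
    """Integer targets summing exactly to ``total`` (largest-remainder rule)."""
    p = np.asarray(proportions, dtype=float)
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    # distribute remaining units to the largest fractional parts (stable ties)
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base.tolist()


def build_quota_spec(benchmarks: BenchmarkSet, groupings, total_target: int) -> QuotaSpec:
    """Quota targets matching the benchmark distribution for each grouping."""
    norm_groupings = tuple(tuple([g] if isinstance(g, str) else g) for g in groupings)
    cells: list[QuotaCell] = []
    for g in norm_groupings:
        table = benchmarks[cross_key(g)]
        labels = list(table)
        targets = largest_remainder([table[c] for c in labels], total_target)
        for lab, t in zip(labels, targets):
            if table[lab] == 0 and t == 0:
                warnings.warn(f"quota cell {cross_key(g)}={lab} has zero "
                              f"benchmark proportion; target 0")
            cells.append(QuotaCell(g, tuple(lab.split("|")), t))
    spec = QuotaSpec(norm_groupings, cells, int(total_target))
    spec.validate()
    return spec


def _cell_index(panel: pd.DataFrame, spec: QuotaSpec):
    """Map each panel member to one cell id per grouping; -1 = no matching cell."""
    cell_ids = []
    lookup_tables = []
    for g in spec.groupings:
        cells_g = spec.cells_for(g)
        lookup = {c.label: i for i, c in enumerate(spec.cells) if c.grouping == g}
        lab = panel[list(g)].astype(str).agg("|".join, axis=1)
        cell_ids.append(lab.map(lambda s: lookup.get(s, -1)).to_numpy())
        lookup_tables.append(lookup)
    return np.column_stack(cell_ids)


def run_quota_survey(panel: Population, spec: QuotaSpec, questionnaire=None,
                     seed: int = 0) -> tuple[SurveySample, RelaxationLog]:
    """Stream the panel through the quota screen until the target is met.

    Members arrive in seeded random order; a member is accepted iff every
    cell they fall into is under target.  On stream exhaustion the
    unfilled cell with the largest absolute shortfall is relaxed: its
    unmet shortfall becomes transferable slack for its grouping, so full
    sibling cells may overfill by at most that amount (a cap released to
    an unfillable cell would not bind — the blockers are the full
    siblings).  Remaining members are then re-streamed in a fresh seeded
    order, mimicking re-invitation waves.  Returns the accepted sample
    (unit weights) and the relaxation log.
    """
    spec = spec.reset()
    spec.validate()
    if len(panel) == 0:
        raise ValueError("panel is empty")
    data = panel.data.reset_index(drop=True)
    member_cells = _cell_index(data, spec)
    grouping_of = {idx: spec.cells[idx].grouping for idx in range(len(spec.cells))}

    rng = np.random.default_rng(seed)
    log = RelaxationLog()
    accepted: list[int] = []
    remaining = rng.permutation(len(data))
    contacted_ever = np.zeros(len(data), dtype=bool)
    slack: dict[tuple, int] = {g: 0 for g in spec.groupings}

    while len(accepted) < spec.total_target:
        rejected_this_pass: list[int] = []
        for i in remaining:
            cells_i = member_cells[i]
            contacted_ever[i] = True
            log.contacted += 1
            # unknown category (-1) never blocks: no cap declared for it
            need_slack = []
            ok = True
            for c in cells_i:
                if c < 0:
                    continue
                cell = spec.cells[c]
                if cell.achieved < cell.target:
                    continue
                g = grouping_of[c]
                if slack[g] > 0 and g not in need_slack:
                    need_slack.append(g)
                else:
                    ok = False
                    break
            if ok:
                accepted.append(int(i))
                for g in need_slack:
                    slack[g] -= 1
                for c in cells_i:
                    if c >= 0:
                        spec.cells[c].achieved += 1
                        if spec.cells[c].achieved > spec.cells[c].target:
                            spec.cells[c].relaxed = True  # overfilled via slack
                if len(accepted) >= spec.total_target:
                    break
            else:
                rejected_this_pass.append(int(i))
        if len(accepted) >= spec.total_target:
            break
        # stream exhausted: release the unfilled cell with the largest
        # absolute shortfall (deterministic tie-break: declaration order)
        candidates = [(c.target - c.achieved, idx) for idx, c in enumerate(spec.cells)
                      if not c.relaxed and c.achieved < c.target]
        if not candidates or not rejected_this_pass:
            log.shortfall = spec.total_target - len(accepted)
            log.events.append({"action": "shortfall", "missing": log.shortfall})
            warnings.warn(f"quota target unreachable; shortfall {log.shortfall}")
            break
        shortfall, idx = max(candidates, key=lambda t: (t[0], -t[1]))
        spec.cells[idx].relaxed = True
        slack[grouping_of[idx]] += int(shortfall)
        log.events.append({
            "action": "relax",
            "grouping": cross_key(spec.cells[idx].grouping),
            "cell": spec.cells[idx].label,
            "shortfall_at_release": int(shortfall),
            "contacted_so_far": int(log.contacted),
        })
        remaining = rng.permutation(np.asarray(rejected_this_pass))

    log.accepted = len(accepted)
    log.rejected = int(contacted_ever.sum()) - len(accepted)

    keep_cols = [c for c in data.columns if c not in {"p_respond", "p_join"}]
    if questionnaire is not None:
        drop_outcomes = [o.name for o in panel.config.outcomes
                         if o.name not in set(questionnaire)]
        keep_cols = [c for c in keep_cols if c not in drop_outcomes]
    frame = data.loc[sorted(accepted), keep_cols].reset_index(drop=True)
    frame["weight"] = 1.0
    sample = SurveySample(frame, provenance="panel-quota",
                          meta={"config_digest": panel.digest, "seed": seed,
                                "total_target": spec.total_target,
                                "shortfall": log.shortfall})
    sample.meta["quota_spec"] = spec
    return sample, log


def omnibus_prescreen(panel: Population, extra_vars, screen_target: int,
                      seed: int = 0) -> Population:
    """Flag a random subset of the panel as having answered the omnibus
    survey, so the extra quota variables are observed for them up front.

    Unflagged members are only screened on those variables at survey entry.
    """
    for v in extra_vars:
        if v not in panel.data.columns:
            raise KeyError(f"extra variable {v!r} not in panel records")
    n = len(panel)
    rng = np.random.default_rng(seed)
    if screen_target >= n:
        if screen_target > n:
            warnings.warn(f"screen_target {screen_target} exceeds panel size {n}; "
                          f"flagging whole panel")
        flagged = np.ones(n, dtype=bool)
    else:
        flagged = np.zeros(n, dtype=bool)
        flagged[rng.choice(n, size=screen_target, replace=False)] = True
    data = panel.data.copy()
    data["omnibus_flagged"] = flagged
    return Population(data, panel.config, panel.digest)


def fill_rate(spec: QuotaSpec) -> pd.DataFrame:
    """Achieved counts vs targets, as percent to one decimal place."""
    rows = []
    for c in spec.cells:
        pct = round(100.0 * c.achieved / c.target, 1) if c.target > 0 else np.nan
        rows.append({"grouping": cross_key(c.grouping), "cell": c.label,
                     "achieved": c.achieved, "target": c.target,
                     "percent": pct, "relaxed": c.relaxed})
    return pd.DataFrame(rows)
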