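"""Synthetic finite population with known selection mechanisms.

The generator produces a finite population of individuals with categorical
covariates (the quota variables: age group within sex, partnership status,
region, plus candidate modification variables such as age finished
full-time education, under-18s in household, household size, drinking
frequency and attitude items), binary and 5-point ordinal outcomes tagged
by interview mode (CAPI/CASI) and question type (behavior/opinion), and two
latent propensities per person:

* ``p_respond`` — probability of taking part in the probability survey,
* ``p_join``   — probability of belonging to the volunteer web panel.

Outcomes follow logistic (binary) or proportional-odds (ordinal) link
models in the covariates, optionally sharing a person-level latent logit
offset to induce within-person correlation across outcomes.  The joining
model may reference outcomes directly, planting non-ignorable selection
bias whose magnitude is known exactly — every downstream comparison can
therefore be validated against enumerable truth.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .benchmarks import BenchmarkSet, cross_key, cross_label
from .samples import SurveySample


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Covariate:
    """A categorical covariate with marginal category probabilities."""

    name: str
    categories: tuple[str, ...]
    probs: tuple[float, ...]

    def validate(self) -> None:
        if not self.categories:
            raise ValueError(f"covariate {self.name!r}: empty category set")
        if len(self.categories) != len(self.probs):
            raise ValueError(f"covariate {self.name!r}: categories/probs mismatch")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ValueError(f"covariate {self.name!r}: probability outside [0,1]")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"covariate {self.name!r}: probabilities sum to {sum(self.probs)}")


@dataclass(frozen=True)
class JointBlock:
    """Explicit joint distribution over a subset of covariates.

    Overrides the independent marginal draw for ``variables``; rows list
    every category combination with nonzero probability.
    """

    variables: tuple[str, ...]
    rows: tuple[tuple[tuple[str, ...], float], ...]  # ((cat, ...), prob)

    def validate(self, config: "PopulationConfig") -> None:
        if len(self.variables) < 2:
            raise ValueError("joint block needs at least 2 variables")
        total = sum(p for _, p in self.rows)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint block {self.variables}: probabilities sum to {total}")
        for cats, p in self.rows:
            if len(cats) != len(self.variables):
                raise ValueError(f"joint block {self.variables}: bad row {cats}")
            if not 0 <= p <= 1:
                raise ValueError(f"joint block {self.variables}: probability {p}")
            for v, c in zip(self.variables, cats):
                if c not in config.covariate(v).categories:
                    raise ValueError(
                        f"joint block {self.variables}: unknown category {c!r} of {v!r}")


@dataclass(frozen=True)
class Term:
    """One linear-predictor term: beta times a covariate-category indicator,
    or beta times a (numeric-coded) outcome value when ``category`` is None."""

    var: str
    beta: float
    category: str | None = None


@dataclass(frozen=True)
class OutcomeModel:
    """Link model for one survey outcome.

    binary:  logit P(Y=1) = intercept + x'beta
    ordinal: logit P(Y<=k) = thresholds[k] - x'beta  (proportional odds,
             categories coded 1..n_categories)
    """

    name: str
    kind: str  # "binary" | "ordinal"
    mode: str  # "CAPI" | "CASI"
    qtype: str  # "behavior" | "opinion"
    intercept: float = 0.0
    thresholds: tuple[float, ...] = ()
    terms: tuple[Term, ...] = ()
    n_categories: int = 5
    neutral_category: int = 3

    def validate(self) -> None:
        if self.kind not in {"binary", "ordinal"}:
            raise ValueError(f"outcome {self.name!r}: unknown kind {self.kind!r}")
        if self.mode not in {"CAPI", "CASI"}:
            raise ValueError(f"outcome {self.name!r}: unknown mode {self.mode!r}")
        if self.qtype not in {"behavior", "opinion"}:
            raise ValueError(f"outcome {self.name!r}: unknown qtype {self.qtype!r}")
        if self.kind == "ordinal":
            if len(self.thresholds) != self.n_categories - 1:
                raise ValueError(
                    f"outcome {self.name!r}: need {self.n_categories - 1} thresholds"
                )
            diffs = np.diff(self.thresholds)
            if len(diffs) and not np.all(diffs > 0):
                raise ValueError(f"outcome {self.name!r}: thresholds not strictly increasing")


@dataclass(frozen=True)
class LogisticModel:
    """Participation / panel-joining propensity model on the logit scale."""

    intercept: float = 0.0
    terms: tuple[Term, ...] = ()


@dataclass(frozen=True)
class PopulationConfig:
    n_population: int
    covariates: tuple[Covariate, ...]
    outcomes: tuple[OutcomeModel, ...]
    response_model: LogisticModel = LogisticModel()
    joining_model: LogisticModel = LogisticModel()
    joint_blocks: tuple[JointBlock, ...] = ()
    latent_sd: float = 0.0  # SD of shared person-level logit offset on outcomes
    seed: int = 0

    def covariate(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def outcome(self, name: str) -> OutcomeModel:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)

    def validate(self) -> None:
        if self.n_population <= 0:
            raise ValueError("n_population must be positive")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        onames = [o.name for o in self.outcomes]
        if len(set(onames)) != len(onames):
            raise ValueError("duplicate outcome names")
        if set(names) & set(onames):
            raise ValueError("covariate and outcome names overlap")
        for c in self.covariates:
            c.validate()
        for o in self.outcomes:
            o.validate()
            for t in o.terms:
                self._check_term(t, allow_outcomes=False, owner=o.name)
        for m, label in ((self.response_model, "response_model"),
                         (self.joining_model, "joining_model")):
            for t in m.terms:
                self._check_term(t, allow_outcomes=True, owner=label)
        seen = set()
        for jb in self.joint_blocks:
            jb.validate(self)
            if seen & set(jb.variables):
                raise ValueError("joint blocks overlap")
            seen |= set(jb.variables)
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be nonnegative")

    def _check_term(self, t: Term, allow_outcomes: bool, owner: str) -> None:
        cov_names = {c.name for c in self.covariates}
        out_names = {o.name for o in self.outcomes}
        if t.var in cov_names:
            if t.category is None:
                raise ValueError(f"{owner}: term on covariate {t.var!r} needs a category")
            if t.category not in self.covariate(t.var).categories:
                raise ValueError(f"{owner}: unknown category {t.category!r} of {t.var!r}")
        elif t.var in out_names:
            if not allow_outcomes:
                raise ValueError(f"{owner}: outcome-valued term {t.var!r} not allowed here")
        else:
            raise ValueError(f"{owner}: term references undeclared variable {t.var!r}")

    def digest(self) -> str:
        payload = json.dumps(_config_to_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_to_jsonable(cfg: PopulationConfig) -> dict:
    def term(t):
        return [t.var, t.beta, t.category]

    return {
        "n_population": cfg.n_population,
        "covariates": [[c.name, list(c.categories), list(c.probs)] for c in cfg.covariates],
        "outcomes": [
            [o.name, o.kind, o.mode, o.qtype, o.intercept, list(o.thresholds),
             [term(t) for t in o.terms], o.n_categories, o.neutral_category]
            for o in cfg.outcomes
        ],
        "joint_blocks": [[list(jb.variables),
                          [[list(c), p] for c, p in jb.rows]]
                         for jb in cfg.joint_blocks],
        "response_model": [cfg.response_model.intercept,
                           [term(t) for t in cfg.response_model.terms]],
        "joining_model": [cfg.joining_model.intercept,
                          [term(t) for t in cfg.joining_model.terms]],
        "latent_sd": cfg.latent_sd,
        "seed": cfg.seed,
    }


# --------------------------------------------------------------------------
# population container
# --------------------------------------------------------------------------

@dataclass
class Population:
    """A finite synthetic population (or subpopulation, e.g. a web panel)."""

    data: pd.DataFrame
    config: PopulationConfig
    digest: str = ""

    def __post_init__(self):
        if not self.digest:
            self.digest = self.config.digest()
        if self.data["person_id"].duplicated().any():
            raise ValueError("person_id not unique")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        """CSV export with a JSON sidecar carrying config digest and seed."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"config_digest": self.digest, "seed": self.config.seed,
             "n": len(self.data)}, indent=2))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _linear_predictor(model_terms, intercept, frame: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(frame), float(intercept))
    for t in model_terms:
        col = frame[t.var]
        if t.category is not None:
            eta += t.beta * (col.to_numpy() == t.category)
        else:
            eta += t.beta * col.to_numpy(dtype=float)
    return eta


def _draw_ordinal(rng, thresholds, eta) -> np.ndarray:
    # P(Y<=k) = expit(threshold_k - eta); invert a uniform through the CDF
    cum = expit(np.subtract.outer(np.asarray(thresholds), eta))  # (K-1, n)
    u = rng.random(eta.shape[0])
    return 1 + (u > cum).sum(axis=0)


def generate_population(config: PopulationConfig) -> Population:
    """Draw a full population according to ``config`` (reproducible by seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_population

    cols: dict[str, np.ndarray] = {"person_id": np.arange(n)}
    joint_vars = {v for jb in config.joint_blocks for v in jb.variables}
    for cov in config.covariates:
        if cov.name in joint_vars:
            continue
        idx = rng.choice(len(cov.categories), size=n, p=np.asarray(cov.probs))
        cols[cov.name] = np.asarray(cov.categories, dtype=object)[idx]
    for jb in config.joint_blocks:
        probs = np.asarray([p for _, p in jb.rows])
        idx = rng.choice(len(jb.rows), size=n, p=probs)
        for j, v in enumerate(jb.variables):
            cats = np.asarray([c[j] for c, _ in jb.rows], dtype=object)
            cols[v] = cats[idx]
    frame = pd.DataFrame({k: cols[k] for k in
                          ["person_id"] + [c.name for c in config.covariates]})

    latent = rng.normal(0.0, config.latent_sd, n) if config.latent_sd > 0 else 0.0
    for out in config.outcomes:
        eta = _linear_predictor(out.terms, out.intercept if out.kind == "binary" else 0.0,
                                frame) + latent
        if out.kind == "binary":
            frame[out.name] = (rng.random(n) < expit(eta)).astype(np.int64)
        else:
            frame[out.name] = _draw_ordinal(rng, out.thresholds, eta)

    frame["p_respond"] = expit(_linear_predictor(
        config.response_model.terms, config.response_model.intercept, frame))
    frame["p_join"] = expit(_linear_predictor(
        config.joining_model.terms, config.joining_model.intercept, frame))
    return Population(frame, config)


# --------------------------------------------------------------------------
# sampling operations
# --------------------------------------------------------------------------

def draw_probability_sample(pop: Population, target_n: int,
                            seed: int | None = None) -> SurveySample:
    """Bernoulli (Poisson) sample with inclusion probability proportional to
    ``p_respond``, scaled so the expected size is ``target_n``.

    The benchmark survey's stratified clustered design is deliberately not
    simulated; design effects are orthogonal to the comparison machinery.
    """
    if target_n > len(pop):
        raise ValueError(f"target_n {target_n} exceeds population size {len(pop)}")
    rng = np.random.default_rng(pop.config.seed + 1 if seed is None else seed)
    p = pop.data["p_respond"].to_numpy(dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("all response propensities are zero")
    scaled = p * (target_n / total)
    if (scaled > 1).any():
        warnings.warn("inclusion probabilities capped at 1; expected size < target_n")
        scaled = np.minimum(scaled, 1.0)
    take = rng.random(len(pop)) < scaled
    frame = pop.data.loc[take].drop(columns=["p_respond", "p_join"]).reset_index(drop=True)
    frame["weight"] = 1.0
    return SurveySample(frame, provenance="probability", label="probability",
                        meta={"config_digest": pop.digest, "target_n": target_n})


def recruit_panel(pop: Population, seed: int | None = None) -> Population:
    """Volunteer web panel: each person joins independently with ``p_join``."""
    rng = np.random.default_rng(pop.config.seed + 2 if seed is None else seed)
    take = rng.random(len(pop)) < pop.data["p_join"].to_numpy(dtype=float)
    return Population(pop.data.loc[take].reset_index(drop=True), pop.config, pop.digest)


def true_benchmarks(pop: Population, variables) -> BenchmarkSet:
    """Exact finite-population category proportions (the census analog).

    ``variables`` is a list whose entries are either a variable name or a
    tuple of names (a cross, e.g. ``("sex", "agegrp")`` for age within sex).
    """
    tables: dict[str, dict[str, float]] = {}
    n = len(pop)
    for var in variables:
        names = [var] if isinstance(var, str) else list(var)
        for v in names:
            if v not in pop.data.columns:
                raise KeyError(f"unknown variable {v!r}")
        counts = pop.data.groupby(names, observed=True).size()
        tables[cross_key(names)] = {
            cross_label(k if isinstance(k, tuple) else (k,)): c / n
            for k, c in counts.items()
        }
    return BenchmarkSet(tables)


# --------------------------------------------------------------------------
# exact enumeration over the covariate cell grid (oracle machinery)
# --------------------------------------------------------------------------

def cell_grid(config: PopulationConfig) -> pd.DataFrame:
    """All covariate cells with their exact joint probability ``p_cell``.

    The joint distribution is a product over independent covariates and any
    declared joint blocks; the explicit finite grid enables exact
    enumeration oracles for every downstream quantity.
    """
    joint_vars = {v for jb in config.joint_blocks for v in jb.variables}
    # blocks: each independent covariate alone, plus each joint block
    blocks: list[tuple[list[str], list[tuple[tuple, float]]]] = []
    for c in config.covariates:
        if c.name not in joint_vars:
            blocks.append(([c.name], [((cat,), p)
                                      for cat, p in zip(c.categories, c.probs)]))
    for jb in config.joint_blocks:
        blocks.append((list(jb.variables), [(tuple(c), p) for c, p in jb.rows]))

    names = [n for blk, _ in blocks for n in blk]
    rows = []
    for combo in product(*[rows_ for _, rows_ in blocks]):
        cats = tuple(c for part, _ in combo for c in part)
        p = float(np.prod([pr for _, pr in combo]))
        rows.append(cats + (p,))
    grid = pd.DataFrame(rows, columns=names + ["p_cell"])
    # restore declared covariate order
    return grid[[c.name for c in config.covariates] + ["p_cell"]]


def _gauss_hermite_expit(eta: np.ndarray, sd: float, nodes: int = 41) -> np.ndarray:
    if sd == 0:
        return expit(eta)
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / w.sum()
    return expit(eta[:, None] + sd * x[None, :]) @ w


def outcome_prevalences(config: PopulationConfig) -> dict[str, object]:
    """Superpopulation outcome distributions by exact enumeration.

    Binary outcomes map to their marginal prevalence P(Y=1); ordinal
    outcomes map to the length-K vector of category probabilities.
    Integrates over the shared latent offset by Gauss-Hermite quadrature.
    """
    grid = cell_grid(config)
    p_cell = grid["p_cell"].to_numpy()
    out: dict[str, object] = {}
    for o in config.outcomes:
        eta = _linear_predictor(o.terms, o.intercept if o.kind == "binary" else 0.0, grid)
        if o.kind == "binary":
            out[o.name] = float(p_cell @ _gauss_hermite_expit(eta, config.latent_sd))
        else:
            cum = np.stack([
                _gauss_hermite_expit(t - eta, config.latent_sd) for t in o.thresholds
            ])  # (K-1, cells)
            cum = np.vstack([cum, np.ones(len(grid))])
            cat = np.diff(cum, axis=0, prepend=0.0)
            out[o.name] = cat @ p_cell
    return out
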