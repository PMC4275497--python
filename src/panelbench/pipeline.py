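"""End-to-end study replica.

Composes all stages in the study's order: generate a synthetic finite
population with known selection bias, draw a probability-sample benchmark
survey, recruit a volunteer web panel, run four quota surveys from it (two
with basic age/sex/partnership/region quotas, two with quotas modified by
the two variable-selection procedures), poststratify everything to the
census analog, and compare each survey against truth — emitting the
participant-characteristics summary, the behavior/opinion OR battery by
sex, mode and question type, the bootstrap comparison of basic vs modified
quotas, and the cross-panel GEE consistency test.

The default scenario mirrors the study's shape: a probability survey of
8969, four web surveys of 2099/2000/2000/2021 completed interviews, an
omnibus pre-screen reaching 9176 panel members, bootstrap B=100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmarks import BenchmarkSet, cross_key
from .compare import (OutcomeMeta, bootstrap_avg_abs_or, combined_basic_avg,
                      compare_avg_abs_or, neutral_share, summarize,
                      survey_or_results)
from .gee import gee_consistency_test, stack_for_gee
from .population import (Covariate, JointBlock, LogisticModel, OutcomeModel,
                         Population, PopulationConfig, Term,
                         draw_probability_sample, generate_population,
                         recruit_panel, true_benchmarks)
from .quotas import build_quota_spec, fill_rate, omnibus_prescreen, run_quota_survey
from .samples import SurveySample
from .selection import (bivariate_screen, omnibus_membership_selection,
                        stepwise_membership_selection)
from .weighting import poststratify, rake, weighted_tabulation

log = logging.getLogger("panelbench")

POSTSTRAT_CELLS = ("sex", "agegrp")
BASIC_GROUPINGS = (("sex", "agegrp"), ("sex", "partnership"), ("region",))
WSM1_CANDIDATES = ("educ_age", "econ_activity", "under18s", "hhsize")
WSM2_CANDIDATES = ("smoke", "drink", "educ_age", "tenure",
                   "att_samesex", "att_abortion")
TABLE2_VARIABLES = ("tenure", "econ_activity", "ethnicity",
                    "gen_health", "driving", "sexid")


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

def default_covariates() -> tuple[Covariate, ...]:
    """Covariate distributions loosely shaped on the British 18-44
    population (census-order magnitudes, not official figures)."""
    return (
        Covariate("sex", ("Male", "Female"), (0.494, 0.506)),
        Covariate("agegrp", ("18-24", "25-34", "35-44"), (0.267, 0.373, 0.360)),
        Covariate("region", ("London", "Rest"), (0.16, 0.84)),
        Covariate("partnership", ("MarrCohab", "Other"), (0.52, 0.48)),
        Covariate("educ_age", ("<=16", "17-18", ">=19"), (0.28, 0.33, 0.39)),
        Covariate("econ_activity", ("Working", "NotWorking"), (0.75, 0.25)),
        Covariate("under18s", ("Yes", "No"), (0.38, 0.62)),
        Covariate("hhsize", ("1", "2", "3", "4+"), (0.14, 0.30, 0.25, 0.31)),
        Covariate("drink", ("LessWeekly", "Weekly+"), (0.52, 0.48)),
        Covariate("smoke", ("Smoker", "NonSmoker"), (0.25, 0.75)),
        Covariate("tenure", ("OwnerOccupier", "Renting"), (0.55, 0.45)),
        Covariate("att_samesex", ("Tolerant", "Other"), (0.62, 0.38)),
        Covariate("att_abortion", ("Tolerant", "Other"), (0.56, 0.44)),
        Covariate("ethnicity", ("White", "Other"), (0.86, 0.14)),
        Covariate("gen_health", ("Good", "NotGood"), (0.81, 0.19)),
        Covariate("driving", ("Licence", "NoLicence"), (0.71, 0.29)),
        Covariate("sexid", ("Hetero", "Other"), (0.97, 0.03)),
    )


def _educ_econ_joint() -> JointBlock:
    # strong (but realistic) dependence between age finished education and
    # economic activity; marginals match the declared covariates
    rows = []
    p_work = {"<=16": 0.60, "17-18": 0.74, ">=19": 0.86}
    marg = {"<=16": 0.28, "17-18": 0.33, ">=19": 0.39}
    for e, pe in marg.items():
        rows.append(((e, "Working"), pe * p_work[e]))
        rows.append(((e, "NotWorking"), pe * (1 - p_work[e])))
    total = sum(p for _, p in rows)
    rows = tuple((c, p / total) for c, p in rows)
    return JointBlock(("educ_age", "econ_activity"), rows)


def default_outcomes(n_behavior_capi: int = 12, n_behavior_casi: int = 15,
                     n_opinion_capi: int = 4, n_opinion_casi: int = 4,
                     spec_seed: int = 20260101) -> tuple[OutcomeModel, ...]:
    """The ~35-outcome battery: binary behaviors (CAPI and CASI) and
    5-point opinion items, with covariate-dependent prevalences.

    Coefficients are assigned from a fixed internal seed so the battery is
    one frozen condition, not a per-run random draw.
    """
    rng = np.random.default_rng(spec_seed)
    drivers = (("sex", "Male"), ("agegrp", "18-24"), ("agegrp", "35-44"),
               ("partnership", "Other"), ("drink", "Weekly+"),
               ("educ_age", ">=19"), ("region", "London"), ("under18s", "Yes"),
               ("smoke", "Smoker"))
    outcomes: list[OutcomeModel] = []

    def terms():
        picks = rng.choice(len(drivers), size=3, replace=False)
        return tuple(Term(drivers[i][0], float(rng.uniform(-0.7, 0.7)),
                          drivers[i][1]) for i in picks)

    mk = 0
    for mode, count in (("CAPI", n_behavior_capi), ("CASI", n_behavior_casi)):
        for _ in range(count):
            mk += 1
            # prevalences from rare (~3%) to common (~50%)
            intercept = float(rng.uniform(-3.5, 0.0))
            outcomes.append(OutcomeModel(
                name=f"beh_{mode.lower()}_{mk:02d}", kind="binary", mode=mode,
                qtype="behavior", intercept=intercept, terms=terms()))
    for mode, count in (("CAPI", n_opinion_capi), ("CASI", n_opinion_casi)):
        for j in range(count):
            base = float(rng.uniform(-1.5, -0.5))
            thresholds = tuple(np.cumsum(
                [base] + list(rng.uniform(0.5, 1.0, 3))))
            outcomes.append(OutcomeModel(
                name=f"op_{mode.lower()}_{j + 1}", kind="ordinal", mode=mode,
                qtype="opinion", thresholds=thresholds, terms=terms()))
    return tuple(outcomes)


def default_population_config(n_population: int = 120_000,
                              join_bias: float = 1.0,
                              outcome_join_beta: float = 0.5,
                              latent_sd: float = 0.0,
                              seed: int = 0) -> PopulationConfig:
    """The default biased study condition.

    ``join_bias`` scales every covariate term of the panel-joining model
    (0 gives a representative panel); ``outcome_join_beta`` is the direct
    log-odds effect of one sensitive CASI behavior on joining the panel —
    the planted non-ignorable selection bias.
    """
    outcomes = default_outcomes()
    join_terms = [
        Term("agegrp", 0.35 * join_bias, "18-24"),
        Term("agegrp", -0.25 * join_bias, "35-44"),
        Term("educ_age", 0.30 * join_bias, ">=19"),
        Term("drink", 0.40 * join_bias, "Weekly+"),
        Term("region", 0.20 * join_bias, "London"),
        Term("under18s", -0.15 * join_bias, "Yes"),
        Term("partnership", 0.25 * join_bias, "Other"),
        # heavy-internet-user skews on the benchmark-only variables:
        # renters, non-workers, smokers and sexual minorities over-join
        Term("tenure", 0.35 * join_bias, "Renting"),
        Term("econ_activity", 0.25 * join_bias, "NotWorking"),
        Term("smoke", 0.20 * join_bias, "Smoker"),
        Term("gen_health", 0.15 * join_bias, "NotGood"),
        Term("driving", 0.20 * join_bias, "NoLicence"),
        Term("sexid", 0.90 * join_bias, "Other"),
    ]
    if outcome_join_beta:
        join_terms.append(Term("beh_casi_13", outcome_join_beta * join_bias, None))
    return PopulationConfig(
        n_population=n_population,
        covariates=default_covariates(),
        outcomes=outcomes,
        response_model=LogisticModel(0.0, (Term("partnership", 0.2, "MarrCohab"),
                                           Term("agegrp", -0.3, "18-24"))),
        joining_model=LogisticModel(-1.8, tuple(join_terms)),
        joint_blocks=(_educ_econ_joint(),),
        latent_sd=latent_sd,
        seed=seed,
    )


def outcome_metas(config: PopulationConfig) -> list[OutcomeMeta]:
    return [OutcomeMeta(name=o.name, scale=o.kind, mode=o.mode, qtype=o.qtype,
                        n_categories=o.n_categories,
                        neutral_categories=frozenset({o.neutral_category}))
            for o in config.outcomes]


# --------------------------------------------------------------------------
# scenario configuration
# --------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    population: PopulationConfig
    prob_n: int = 8969
    web_targets: dict = field(default_factory=lambda: {
        "WS-B1": 2099, "WS-B2": 2000, "WS-M1": 2000, "WS-M2": 2021})
    omnibus_target: int = 9176
    bootstrap_B: int = 100
    alpha: float = 0.05
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        pop = default_population_config(
            n_population=int(doc.get("n_population", 120_000)),
            join_bias=float(doc.get("join_bias", 1.0)),
            outcome_join_beta=float(doc.get("outcome_join_beta", 0.5)),
            latent_sd=float(doc.get("latent_sd", 0.0)),
            seed=int(doc.get("seed", 1)))
        return cls(population=pop,
                   prob_n=int(doc.get("prob_n", 8969)),
                   web_targets=dict(doc.get("web_targets", {
                       "WS-B1": 2099, "WS-B2": 2000,
                       "WS-M1": 2000, "WS-M2": 2021})),
                   omnibus_target=int(doc.get("omnibus_target", 9176)),
                   bootstrap_B=int(doc.get("bootstrap_B", 100)),
                   alpha=float(doc.get("alpha", 0.05)),
                   seed=int(doc.get("seed", 1)))


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


# --------------------------------------------------------------------------
# scenario run
# --------------------------------------------------------------------------

def _subset_by_sex(sample: SurveySample, sex: str) -> SurveySample:
    sub = sample.data[sample.data["sex"] == sex].reset_index(drop=True)
    return SurveySample(sub.copy(), provenance=sample.provenance,
                        label=f"{sample.label}[{sex}]", meta=dict(sample.meta))


def _sex_benchmarks(pop: Population, sex: str, variables) -> BenchmarkSet:
    sub = Population(pop.data[pop.data["sex"] == sex].reset_index(drop=True),
                     pop.config, pop.digest)
    return true_benchmarks(sub, variables)


def _sociodemo_metas() -> list[OutcomeMeta]:
    reductions = {
        "tenure": {"OwnerOccupier": 0, "Renting": 1},
        "econ_activity": {"Working": 0, "NotWorking": 1},
        "ethnicity": {"White": 0, "Other": 1},
        "gen_health": {"Good": 0, "NotGood": 1},
        "driving": {"Licence": 0, "NoLicence": 1},
        "sexid": {"Hetero": 0, "Other": 1},
    }
    return [OutcomeMeta(name=v, scale="categorical", mode="CAPI",
                        qtype="behavior", binary_reduction=reductions[v])
            for v in TABLE2_VARIABLES]


def run_scenario(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Run the full replica; writes the report bundle and returns it.

    Deterministic given the master seed: every stage draws from a child
    seed split off the master, so stages can be rerun in isolation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 16)
    bundle: dict = {"seed": config.seed}
    run_log: list[str] = []

    def note(msg):
        log.info(msg)
        run_log.append(msg)

    # ---- population, benchmark survey, panel ---------------------------
    pop_config = replace(config.population, seed=seeds[0])
    pop = generate_population(pop_config)
    bundle["config_digest"] = pop.digest
    note(f"population generated: n={len(pop)} digest={pop.digest}")

    bench_vars = list(BASIC_GROUPINGS) + list(TABLE2_VARIABLES) + \
        list(WSM1_CANDIDATES) + list(WSM2_CANDIDATES) + ["sex"]
    census = true_benchmarks(pop, bench_vars)
    census.to_json(outdir / "census_benchmarks.json")

    prob = draw_probability_sample(pop, config.prob_n, seed=seeds[1])
    prob.label = "probability"
    note(f"probability sample drawn: n={len(prob)} (target {config.prob_n})")

    panel = recruit_panel(pop, seed=seeds[2])
    note(f"panel recruited: n={len(panel)} "
         f"({100 * len(panel) / len(pop):.1f}% of population)")

    # ---- basic quota surveys -------------------------------------------
    surveys: dict[str, SurveySample] = {}
    fill_reports = {}
    for i, name in enumerate(("WS-B1", "WS-B2")):
        spec = build_quota_spec(census, BASIC_GROUPINGS, config.web_targets[name])
        s, rlog = run_quota_survey(panel, spec, seed=seeds[3 + i])
        s.label = name
        surveys[name] = s
        fill_reports[name] = fill_rate(s.meta["quota_spec"])
        rlog.to_json_lines(outdir / f"relaxation_{name}.jsonl")
        note(f"{name}: accepted {len(s)}, shortfall {rlog.shortfall}, "
             f"relaxations {sum(e['action'] == 'relax' for e in rlog.events)}")

    # ---- poststratification --------------------------------------------
    prob_w = rake(prob, census, [POSTSTRAT_CELLS, "region"])
    note("probability sample raked to age-within-sex and region")

    # ---- WS-M1: stepwise selection against WS-B2 ------------------------
    sel1 = stepwise_membership_selection(prob, surveys["WS-B2"],
                                         list(WSM1_CANDIDATES),
                                         alpha=config.alpha)
    (outdir / "selection_wsm1.json").write_text(json.dumps(sel1.to_dict(), indent=2))
    note(f"WS-M1 selection: {sel1.selected_names} "
         f"(dropped for collinearity: {[d for d, _, _ in sel1.dropped_for_collinearity]})")

    m1_groupings = list(BASIC_GROUPINGS) + [(v,) for v in sel1.selected_names]
    m1_margins = _quota_margins(census, prob_w, sel1.selected_names)
    spec_m1 = build_quota_spec(m1_margins, m1_groupings, config.web_targets["WS-M1"])
    s, rlog = run_quota_survey(panel, spec_m1, seed=seeds[5])
    s.label = "WS-M1"
    surveys["WS-M1"] = s
    fill_reports["WS-M1"] = fill_rate(s.meta["quota_spec"])
    rlog.to_json_lines(outdir / "relaxation_WS-M1.jsonl")
    note(f"WS-M1: accepted {len(s)}, shortfall {rlog.shortfall}, "
         f"relaxations {sum(e['action'] == 'relax' for e in rlog.events)}")

    # ---- WS-M2: omnibus pre-screen + stepwise + bivariate screen --------
    screened = omnibus_prescreen(panel, list(WSM2_CANDIDATES),
                                 min(config.omnibus_target, len(panel)),
                                 seed=seeds[6])
    omnibus = SurveySample(
        screened.data[screened.data["omnibus_flagged"]]
        .drop(columns=["omnibus_flagged", "p_respond", "p_join"])
        .reset_index(drop=True).copy(),
        provenance="panel-omnibus", label="omnibus")
    note(f"omnibus pre-screen: {len(omnibus)} of {len(panel)} panel members")

    metas = outcome_metas(pop_config)
    key_behaviors = [m for m in metas if m.qtype == "behavior"][:8]
    screen_table = bivariate_screen(prob, key_behaviors,
                                    list(WSM2_CANDIDATES), alpha=config.alpha)
    screen_table.to_csv(outdir / "bivariate_screen.csv", index=False)

    sel2 = omnibus_membership_selection(prob, omnibus, list(WSM2_CANDIDATES),
                                        alpha=config.alpha)
    (outdir / "selection_wsm2.json").write_text(json.dumps(sel2.to_dict(), indent=2))
    note(f"WS-M2 selection: {sel2.selected_names}")

    m2_groupings = [("sex", "agegrp"), ("sex", "partnership")] + \
        [(v,) for v in sel2.selected_names]
    m2_margins = _quota_margins(census, prob_w, sel2.selected_names)
    spec_m2 = build_quota_spec(m2_margins, m2_groupings, config.web_targets["WS-M2"])
    s, rlog = run_quota_survey(panel, spec_m2, seed=seeds[7])
    s.label = "WS-M2"
    surveys["WS-M2"] = s
    fill_reports["WS-M2"] = fill_rate(s.meta["quota_spec"])
    rlog.to_json_lines(outdir / "relaxation_WS-M2.jsonl")
    note(f"WS-M2: accepted {len(s)}, shortfall {rlog.shortfall}, "
         f"relaxations {sum(e['action'] == 'relax' for e in rlog.events)}")

    # fill-rate report
    fill_all = pd.concat([r.assign(survey=k) for k, r in fill_reports.items()],
                         ignore_index=True)
    fill_all.to_csv(outdir / "quota_fill_rates.csv", index=False)

    # ---- weighting ------------------------------------------------------
    weighted = {"probability": prob_w}
    for name, s in surveys.items():
        weighted[name] = poststratify(s, census, POSTSTRAT_CELLS)
    note("all surveys poststratified to census age within sex")

    # ---- exports --------------------------------------------------------
    for name, s in weighted.items():
        s.to_csv(outdir / f"sample_{name}.csv")

    # ---- participant characteristics vs aggregate benchmarks -----------
    sociodemo = _sociodemo_metas()
    char_rows = []
    for sex in ("Male", "Female"):
        sex_bench = _sex_benchmarks(pop, sex, list(TABLE2_VARIABLES))
        for name in ("WS-B1", "WS-B2", "WS-M1", "WS-M2", "probability"):
            sub = _subset_by_sex(weighted[name], sex)
            results = survey_or_results(sub, sex_bench, sociodemo, continuity=True)
            block = summarize(results, alpha=config.alpha,
                              groups=(("All", None, None),))[0]
            char_rows.append({"sex": sex, "survey": name,
                              "avg_abs_or": block.avg_abs_or,
                              "largest_abs_or": block.largest_abs_or,
                              "n_sig": block.n_sig, "n_total": block.n_total})
    chars = pd.DataFrame(char_rows)
    chars.insert(0, "config_digest", pop.digest)
    chars.to_csv(outdir / "participant_characteristics.csv", index=False)
    bundle["participant_characteristics"] = chars

    # ---- behavior/opinion battery vs probability microdata -------------
    battery_rows = []
    or_detail = []
    for sex in ("Male", "Female"):
        prob_sub = _subset_by_sex(weighted["probability"], sex)
        for name in ("WS-B1", "WS-B2", "WS-M1", "WS-M2"):
            sub = _subset_by_sex(weighted[name], sex)
            results = []
            for meta in metas:
                try:
                    results.extend(survey_or_results(sub, prob_sub, [meta]))
                except ValueError as exc:
                    note(f"{name} [{sex}]: outcome {meta.name} skipped ({exc})")
            for r in results:
                or_detail.append({"sex": sex, "survey": name,
                                  "outcome": r.outcome.name, "or": r.or_value,
                                  "ci_low": r.ci_low, "ci_high": r.ci_high,
                                  "p": r.p_value, "abs_or": r.abs_or,
                                  "method": r.method})
            for block in summarize(results, alpha=config.alpha):
                battery_rows.append({"sex": sex, "survey": name,
                                     "group": block.label,
                                     "avg_abs_or": block.avg_abs_or,
                                     "largest_abs_or": block.largest_abs_or,
                                     "n_sig": block.n_sig,
                                     "n_total": block.n_total})
    battery = pd.DataFrame(battery_rows)
    battery.insert(0, "config_digest", pop.digest)
    battery.to_csv(outdir / "behavior_opinion_battery.csv", index=False)
    pd.DataFrame(or_detail).to_csv(outdir / "or_detail.csv", index=False)
    bundle["battery"] = battery

    # ---- bootstrap comparison: basic combined vs each modified ---------
    boot_rows = []
    for sex_i, sex in enumerate(("Male", "Female")):
        prob_sub = _subset_by_sex(weighted["probability"], sex)
        sex_census = _sex_benchmarks(pop, sex, [("agegrp",)])
        entries = {}
        combined = bootstrap_avg_abs_or(
            [_subset_by_sex(weighted["WS-B1"], sex),
             _subset_by_sex(weighted["WS-B2"], sex)],
            prob_sub, metas, B=config.bootstrap_B,
            margins=sex_census, cells="agegrp", seed=seeds[8] + sex_i)
        entries["basic-combined"] = combined
        for j, name in enumerate(("WS-M1", "WS-M2")):
            entries[name] = bootstrap_avg_abs_or(
                [_subset_by_sex(weighted[name], sex)], prob_sub, metas,
                B=config.bootstrap_B, margins=sex_census, cells="agegrp",
                seed=seeds[9 + j] + sex_i)
        for name in ("WS-M1", "WS-M2"):
            z, p = compare_avg_abs_or(
                (entries[name].avg_abs_or, entries[name].se),
                (combined.avg_abs_or, combined.se))
            boot_rows.append({
                "sex": sex, "comparison": f"{name} vs basic-combined",
                "modified_avg_abs_or": entries[name].avg_abs_or,
                "modified_se": entries[name].se,
                "basic_avg_abs_or": combined.avg_abs_or,
                "basic_se": combined.se, "z": z, "p": p,
                "unreliable": entries[name].unreliable or combined.unreliable})
    boot = pd.DataFrame(boot_rows)
    boot.insert(0, "config_digest", pop.digest)
    boot.to_csv(outdir / "modified_vs_basic_bootstrap.csv", index=False)
    bundle["bootstrap_comparison"] = boot

    # ---- GEE consistency of the two basic surveys ----------------------
    gee_metas = [m for m in metas if m.scale == "binary"][:12]
    stack = stack_for_gee(surveys["WS-B1"], surveys["WS-B2"], gee_metas)
    gee_res = gee_consistency_test(stack)
    (outdir / "gee_consistency.json").write_text(
        json.dumps(gee_res.to_dict(), indent=2, default=float))
    gee_res.per_question.to_csv(outdir / "gee_per_question.csv", index=False)
    note(f"GEE consistency: joint Wald {gee_res.joint_stat:.2f} "
         f"df={gee_res.joint_df} p={gee_res.joint_p:.4g}")
    bundle["gee"] = gee_res

    # ---- neutral-point share on opinion items --------------------------
    neutral_rows = []
    for name in ("WS-B1", "WS-B2", "WS-M1", "WS-M2", "probability"):
        for m in metas:
            if m.scale == "ordinal":
                neutral_rows.append({"survey": name, "outcome": m.name,
                                     "neutral_share": neutral_share(
                                         weighted[name], m)})
    pd.DataFrame(neutral_rows).to_csv(outdir / "neutral_shares.csv", index=False)

    manifest = {
        "config_digest": pop.digest, "seed": config.seed,
        "n_population": len(pop), "n_panel": len(panel),
        "n_probability": len(prob),
        "web_sizes": {k: len(v) for k, v in surveys.items()},
        "bootstrap_B": config.bootstrap_B,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "run.log").write_text("\n".join(run_log) + "\n")
    bundle["manifest"] = manifest
    return bundle


def _quota_margins(census: BenchmarkSet, prob_w, extra_vars) -> BenchmarkSet:
    """Quota targets: census margins for the basic groupings, the weighted
    probability-survey distribution for the selected modification variables."""
    tables = census.to_dict()
    for v in extra_vars:
        tables[v] = weighted_tabulation(prob_w, v)
    return BenchmarkSet(tables)
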