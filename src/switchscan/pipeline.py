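"""Configuration-driven orchestration of a full diet-switch analysis run.

Stages: (optionally simulated) expression + survival inputs → life tables,
hazards and mortality-switch detection → paired differential expression with
pooled FDR → temporal-response categorization → optional direction-aware
enrichment → optional cross-study concordance. Every stage's outputs are
written as TSV, and a consolidated report is written as both JSON and text.
Reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import categorize, concordance, demography, enrichment, expression, simulate

log = logging.getLogger("switchscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Full-run settings; see the YAML example in the package README."""

    out_dir: str = "switchscan_run"
    seed: int = 0
    fdr: float = 0.05
    # expression input: simulate (dict of ExprSimConfig overrides) or paths
    expression_sim: dict | None = field(default_factory=dict)
    expression_path: str | None = None
    metadata_path: str | None = None
    quantile_normalize: bool = False
    variance_floor: float | None = None
    # survival input: simulate (dict of CohortSimConfig overrides) or path
    cohort_sim: dict | None = field(default_factory=dict)
    events_path: str | None = None
    # demography settings
    hazard_window: int = 5
    separation_fold: float = 1.5
    separation_k: int = 3
    convergence_tol: float = 0.25
    convergence_k: int = 2
    switch_day: int = 40
    # categorization rules
    nonresponding_max_frac: float = 0.25
    variability_sd_multiple: float = 3.0
    late_hours: int = 3
    fast_switch_cutoff_h: float = 8.0
    # optional enrichment
    gmt_path: str | None = None
    enrich_categories: tuple[str, ...] = ("I",)
    # optional cross-study concordance
    concordance_a: str | None = None
    concordance_b: str | None = None
    concordance_universe: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise PipelineError("fdr must lie in (0, 1)")
        if (self.expression_path is None) == (self.expression_sim is None):
            raise PipelineError(
                "provide exactly one of expression_path or expression_sim")
        if (self.events_path is None) == (self.cohort_sim is None):
            raise PipelineError("provide exactly one of events_path or cohort_sim")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "enrich_categories" in raw:
            raw["enrich_categories"] = tuple(raw["enrich_categories"])
        # presence of a path key switches that input off simulation
        if raw.get("expression_path") is not None:
            raw.setdefault("expression_sim", None)
        if raw.get("events_path") is not None:
            raw.setdefault("cohort_sim", None)
        return cls(**raw)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return decorate


@_stage("expression-input")
def _expression_input(config: RunConfig, out: Path):
    if config.expression_path is not None:
        matrix = expression.read_expression(config.expression_path,
                                            config.metadata_path)
        truth = None
    else:
        sim_cfg = simulate.ExprSimConfig(seed=config.seed, **config.expression_sim)
        matrix, truth = simulate.generate_expression(sim_cfg)
        simulate.write_truth(truth, out / "expression_truth.tsv")
    if config.variance_floor:
        matrix = expression.variance_filter(matrix, config.variance_floor)
    if config.quantile_normalize:
        matrix = expression.ExpressionMatrix(
            expression.quantile_normalize(matrix.values), matrix.metadata)
    expression.write_expression(matrix, out / "expression.tsv",
                                out / "metadata.tsv")
    return matrix, truth


@_stage("survival-input")
def _survival_input(config: RunConfig, out: Path):
    if config.events_path is not None:
        events = simulate.read_events(config.events_path)
    else:
        sim_cfg = simulate.CohortSimConfig(seed=config.seed + 1, **config.cohort_sim)
        events, _ = simulate.generate_cohorts(sim_cfg)
    simulate.write_events(events, out / "events.tsv")
    return events


@_stage("demography")
def _demography(config: RunConfig, events: pd.DataFrame, out: Path) -> dict:
    hazards, summary = {}, {}
    for cohort in sorted(events["cohort"].unique()):
        table = demography.build_life_table(events, cohort=cohort)
        h = demography.hazard(table, window=config.hazard_window)
        hazards[cohort] = h
        demography.write_life_table(table, h, out / f"life_table_{cohort}.tsv")
        cohort_events = events[events["cohort"] == cohort]
        summary[cohort] = {
            "n_flies": int(len(cohort_events)),
            "deaths": int((cohort_events["status"] == "death").sum()),
            "censored": int((cohort_events["status"] == "censored").sum()),
            "max_lifespan_days": demography.max_lifespan(cohort_events),
        }
    result: dict[str, Any] = {"cohorts": summary}
    if {"CF", "RF"} <= hazards.keys():
        result["separation_day"] = demography.detect_separation(
            hazards["CF"], hazards["RF"], fold=config.separation_fold,
            k=config.separation_k)
        stat, p = demography.log_rank(events[events["cohort"] == "CF"],
                                      events[events["cohort"] == "RF"])
        result["log_rank_CF_vs_RF"] = {"statistic": stat, "p": p}
    if {"SF", "RF"} <= hazards.keys():
        result["convergence_lag_days"] = demography.detect_convergence(
            hazards["SF"], hazards["RF"], switch_day=config.switch_day,
            tol=config.convergence_tol, k=config.convergence_k)
    return result


@_stage("differential-expression")
def _diffexp(config: RunConfig, matrix, out: Path) -> pd.DataFrame:
    comparisons = expression.run_comparisons(matrix)
    expression.write_comparisons(comparisons, out / "comparisons.tsv")
    return comparisons


@_stage("categorize")
def _categorize(config: RunConfig, comparisons, matrix, out: Path):
    rules = categorize.IndeterminateRules(
        nonresponding_max_frac=config.nonresponding_max_frac,
        variability_sd_multiple=config.variability_sd_multiple,
        late_hours=config.late_hours)
    assignments = categorize.assign_categories(
        comparisons, fdr=config.fdr, rules=rules, matrix=matrix)
    categorize.write_assignments(assignments, out / "categories.tsv")
    summary = categorize.category_counts(assignments)
    summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
    up, down = categorize.curate_fast_switchers(
        assignments, cutoff_h=config.fast_switch_cutoff_h)
    return assignments, summary, {"up": up, "down": down}


@_stage("enrichment")
def _enrichment(config: RunConfig, assignments, out: Path) -> dict:
    collection = enrichment.read_gmt(config.gmt_path)
    report = {}
    for category in config.enrich_categories:
        tables = enrichment.enrich_by_direction(assignments, category, collection)
        for direction, table in tables.items():
            table.to_csv(out / f"enrichment_{category}_{direction}.tsv",
                         sep="\t", index=False)
            report[f"{category}_{direction}"] = {
                "n_sets_tested": int(len(table)),
                "significant_sets": sorted(table.loc[table["q"] <= 0.05,
                                                     "set_name"].tolist()),
            }
    return report


@_stage("concordance")
def _concordance(config: RunConfig, assignments, out: Path) -> dict:
    list_a = concordance.DirectedGeneList.from_tsv(config.concordance_a, "A")
    list_b = concordance.DirectedGeneList.from_tsv(config.concordance_b, "B")
    summary = concordance.direction_concordance(list_a, list_b)
    summary.table.to_csv(out / "concordance_2x2.tsv", sep="\t")
    report = {
        "n_shared": summary.n_shared,
        "n_same_direction": summary.n_same_direction,
        "n_opposite": summary.n_opposite,
        "pct_same": summary.pct_same,
        "pct_opposite": summary.pct_opposite,
    }
    if config.concordance_universe:
        k, p = concordance.overlap_test(list_a, list_b, config.concordance_universe)
        report["overlap_p"] = p
    if assignments is not None and summary.shared:
        shared_genes = set(summary.shared)
        assigned = set(assignments["gene_id"])
        if shared_genes <= assigned:
            crosstab = concordance.concordance_by_category(summary, assignments)
            crosstab.to_csv(out / "concordance_by_category.tsv", sep="\t",
                            index=False)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run config: %s", dataclasses.asdict(config))
        report: dict[str, Any] = {"config": dataclasses.asdict(config)}
        report["config"]["enrich_categories"] = list(config.enrich_categories)

        matrix, truth = _expression_input(config, out)
        events = _survival_input(config, out)
        report["demography"] = _demography(config, events, out)
        comparisons = _diffexp(config, matrix, out)
        assignments, summary, fast = _categorize(config, comparisons, matrix, out)
        report["categories"] = {
            row["category"]: {"n_genes": int(row["n_genes"]),
                              "n_down": int(row["n_down"]),
                              "n_up": int(row["n_up"])}
            for _, row in summary.iterrows()}
        report["n_genes"] = int(matrix.n_genes)
        report["fast_switchers"] = {"n_up": len(fast["up"]),
                                    "n_down": len(fast["down"])}
        if truth is not None:
            merged = assignments.merge(truth, on="gene_id")
            report["truth_recovery"] = _recovery(merged)
        if config.gmt_path:
            report["enrichment"] = _enrichment(config, assignments, out)
        if config.concordance_a and config.concordance_b:
            report["concordance"] = _concordance(config, assignments, out)

        with open(out / "report.json", "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True, default=_jsonable)
            handle.write("\n")
        _write_text_report(report, out / "report.txt")
        log.info("run complete")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _recovery(merged: pd.DataFrame) -> dict:
    out = {}
    for archetype, sub in merged.groupby("archetype"):
        expected = sub["expected_category"].iloc[0]
        hit = float((sub["category"] == expected).mean())
        out[str(archetype)] = {"n": int(len(sub)), "expected_category": expected,
                               "recovered_fraction": hit}
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["switchscan run report", "=" * 21, ""]
    demo = report.get("demography", {})
    if demo:
        lines.append("Demography")
        for cohort, s in demo.get("cohorts", {}).items():
            lines.append(f"  {cohort}: n={s['n_flies']} deaths={s['deaths']} "
                         f"censored={s['censored']} "
                         f"max_lifespan={s['max_lifespan_days']:.1f} d")
        if "separation_day" in demo:
            lines.append(f"  CF/RF hazard separation day: {demo['separation_day']}")
        if "convergence_lag_days" in demo:
            lines.append(f"  SF->RF convergence lag: {demo['convergence_lag_days']} d")
        lines.append("")
    if "categories" in report:
        lines.append("Temporal-response categories")
        for cat, s in report["categories"].items():
            lines.append(f"  {cat:>4}: {s['n_genes']:6d} genes "
                         f"({s['n_down']} down, {s['n_up']} up)")
        fast = report.get("fast_switchers", {})
        if fast:
            lines.append(f"  fast switchers (<= cutoff): {fast['n_up']} up, "
                         f"{fast['n_down']} down")
        lines.append("")
    if "enrichment" in report:
        lines.append("Enrichment (q <= 0.05)")
        for family, s in report["enrichment"].items():
            sig = ", ".join(s["significant_sets"]) or "none"
            lines.append(f"  {family}: {sig}")
        lines.append("")
    if "concordance" in report:
        c = report["concordance"]
        lines.append("Cross-study concordance")
        lines.append(f"  shared={c['n_shared']} same={c['n_same_direction']} "
                     f"({c['pct_same']}%) opposite={c['n_opposite']} "
                     f"({c['pct_opposite']}%)")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
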