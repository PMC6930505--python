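"""Config-driven orchestration of the full analysis.

Stages run in order: encode -> mine -> select -> subset -> correlate ->
litmine. Intermediates are persisted after each stage so the cheap
selection stages can be re-run with different comparison conventions
without repeating the mining, and a manifest records every threshold
actually applied, all output row counts and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .arm_core import MiningParams, apriori_mine, generate_rules, rules_to_frame
from .cohort_analysis import build_indicator_matrix, conjunction_name, spearman_matrix
from .litmine import (
    lifestyle_filter,
    load_predications,
    load_semantic_filter,
    mine_pair_rules,
    predications_to_transactions,
    filter_predications,
    default_semantic_filter,
)
from .rule_selection import CohortKeywordSpec, subset_by_keywords, top_k_by_lift, two_stage_select
from .survey_io import (
    default_variable_specs,
    encode_transactions,
    load_variable_specs,
    read_survey_table,
    select_cohort,
    write_transactions_csv,
)

log = logging.getLogger("ckdrules.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "write_demo_inputs"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML."""

    survey_path: str
    cohort_condition_code: str
    out_dir: str
    variable_specs_path: str | None = None
    survey_format: str = "csv"
    min_support: float = 0.1
    min_confidence: float = 0.0
    max_len: int = 10
    inclusive_thresholds: bool = False
    lift_gate_before_support_mean: bool = False
    top_k: int = 10
    keywords: Mapping[str, Sequence[str]] = field(default_factory=dict)
    correlation_factors: Sequence[str] | None = None
    predications_path: str | None = None
    semantic_filter_path: str | None = None
    seed_terms: Sequence[str] = ()
    litmine_min_count: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate(self) -> None:
        if not Path(self.survey_path).exists():
            raise FileNotFoundError(f"survey file not found: {self.survey_path}")
        for p in (self.variable_specs_path, self.predications_path, self.semantic_filter_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path not found: {p}")
        MiningParams(self.min_support, self.min_confidence, self.max_len)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    specs = (
        load_variable_specs(cfg.variable_specs_path)
        if cfg.variable_specs_path
        else default_variable_specs()
    )

    # encode: full-population transactions (for correlation) and the cohort
    raw = read_survey_table(cfg.survey_path, format=cfg.survey_format)  # type: ignore[arg-type]
    full_t, full_log = encode_transactions(raw, specs)
    cohort_raw = select_cohort(raw, cfg.cohort_condition_code, specs)
    cohort_t, cohort_log = encode_transactions(cohort_raw, specs)
    write_transactions_csv(cohort_t, out / "cohort_transactions.csv")
    cohort_log.write_csv(out / "cohort_exclusions.csv")
    log.info(
        "encode: %d rows -> cohort %d transactions (%d excluded)",
        raw.n_rows, cohort_t.n, len(cohort_log.excluded),
    )
    manifest["stages"]["encode"] = {
        "status": "ok",
        "input_rows": raw.n_rows,
        "cohort_rows": cohort_raw.n_rows,
        "cohort_transactions": cohort_t.n,
        "cohort_excluded": len(cohort_log.excluded),
        "outputs": ["cohort_transactions.csv", "cohort_exclusions.csv"],
    }

    # mine
    params = MiningParams(cfg.min_support, cfg.min_confidence, cfg.max_len)
    frequent = apriori_mine(cohort_t, params)
    rules = generate_rules(frequent, cohort_t, params)
    rules_to_frame(rules).to_csv(out / "rules.csv", index=False)
    log.info("mine: minSup=%g -> %d frequent itemsets, %d rules",
             cfg.min_support, len(frequent), len(rules))
    manifest["stages"]["mine"] = {
        "status": "ok",
        "min_support": cfg.min_support,
        "min_confidence": cfg.min_confidence,
        "n_frequent_itemsets": len(frequent),
        "n_rules": len(rules),
        "outputs": ["rules.csv"],
    }

    # select
    selected, report = two_stage_select(
        rules,
        inclusive=cfg.inclusive_thresholds,
        lift_gate_before_support_mean=cfg.lift_gate_before_support_mean,
        support_lower_bound=cfg.min_support,
    )
    rules_to_frame(selected).to_csv(out / "selected_rules.csv", index=False)
    (out / "selection_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    log.info("select: mean support %.4f -> %d, mean lift %s -> %d final",
             report.mean_support or float("nan"), report.n_after_stage1,
             f"{report.mean_lift:.4f}" if report.mean_lift else "n/a", report.n_final)
    manifest["stages"]["select"] = {
        "status": "ok",
        **report.to_dict(),
        "outputs": ["selected_rules.csv", "selection_report.json"],
    }

    # subset: per-condition top-k
    subset_outputs = []
    top_rule_variables: set[str] = set()
    for condition, kws in cfg.keywords.items():
        spec = CohortKeywordSpec(condition=condition, keywords=tuple(kws))
        top = top_k_by_lift(subset_by_keywords(selected, spec), k=cfg.top_k)
        fname = f"top{cfg.top_k}_{condition}.csv"
        rules_to_frame(top).to_csv(out / fname, index=False)
        subset_outputs.append(fname)
        for r in top:
            top_rule_variables |= r.items
    manifest["stages"]["subset"] = {
        "status": "ok" if cfg.keywords else "skipped",
        "conditions": list(cfg.keywords),
        "outputs": subset_outputs,
    }

    # correlate (needs condition keywords; factors default to top-rule variables)
    if cfg.keywords:
        condition_codes = [cfg.cohort_condition_code] + [
            kw for kws in cfg.keywords.values() for kw in kws
        ]
        condition_codes = list(dict.fromkeys(condition_codes))
        factors = list(cfg.correlation_factors) if cfg.correlation_factors else sorted(
            top_rule_variables - set(condition_codes)
        )
        if factors:
            conjunctions = [
                (cfg.cohort_condition_code, c)
                for c in condition_codes
                if c != cfg.cohort_condition_code
            ]
            m = build_indicator_matrix(full_t, factors, condition_codes, conjunctions)
            cond_cols = condition_codes + [conjunction_name(a, b) for a, b in conjunctions]
            corr = spearman_matrix(m, factors, cond_cols)
            corr.to_long_frame().to_csv(out / "correlation.csv", index=False)
            manifest["stages"]["correlate"] = {
                "status": "ok",
                "n_factors": len(factors),
                "n_conditions": len(cond_cols),
                "n_undefined_pairs": len(corr.undefined),
                "outputs": ["correlation.csv"],
            }
        else:
            manifest["stages"]["correlate"] = {"status": "skipped", "outputs": []}
    else:
        manifest["stages"]["correlate"] = {"status": "skipped", "outputs": []}

    # litmine
    if cfg.predications_path:
        sem_cfg = (
            load_semantic_filter(cfg.semantic_filter_path)
            if cfg.semantic_filter_path
            else default_semantic_filter()
        )
        records = load_predications(cfg.predications_path)
        filtered = filter_predications(records, sem_cfg, seed_terms=cfg.seed_terms)
        pair_t = predications_to_transactions(filtered)
        lit_rules, lit_report = mine_pair_rules(pair_t, min_count=cfg.litmine_min_count)
        semtypes = {}
        for r in filtered:
            semtypes[r.subject] = r.subject_semtype
            semtypes[r.object] = r.object_semtype
        lifestyle_rules, keyword_list = lifestyle_filter(lit_rules, sem_cfg, semtypes)
        rules_to_frame(lifestyle_rules).to_csv(out / "litmine_rules.csv", index=False)
        (out / "litmine_report.json").write_text(
            json.dumps(
                {**lit_report.to_dict(), "n_lifestyle_rules": len(lifestyle_rules),
                 "n_lifestyle_keywords": len(keyword_list)},
                indent=2,
            )
        )
        log.info("litmine: %d records -> %d filtered -> %d rules (%d lifestyle)",
                 len(records), len(filtered), lit_report.n_final, len(lifestyle_rules))
        manifest["stages"]["litmine"] = {
            "status": "ok",
            "n_records": len(records),
            "n_filtered": len(filtered),
            **lit_report.to_dict(),
            "n_lifestyle_rules": len(lifestyle_rules),
            "outputs": ["litmine_rules.csv", "litmine_report.json"],
        }
    else:
        manifest["stages"]["litmine"] = {"status": "skipped", "outputs": []}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_demo_inputs(out_dir: str | Path, seed: int = 0, n: int = 20_000) -> Path:
    """Write a self-contained synthetic input set and config for a demo run.

    The survey adds a 30%-prevalence cohort condition item ``ckd`` on top of
    the default planted fixture; consequents of the planted rules double as
    'condition' keywords so the subsetting and correlation stages have
    something to chew on. Returns the path to the written config YAML.
    """
    import csv as _csv

    from .litmine import write_predications_csv
    from .synthetic import (
        SyntheticSurveySpec,
        default_predication_spec,
        default_survey_spec,
        generate_predications,
        generate_survey,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = default_survey_spec(n=n)
    spec = SyntheticSurveySpec(
        marginals={**base.marginals, "ckd": 0.30}, planted=base.planted, n=n
    )
    t = generate_survey(spec, seed=seed)
    catalog = sorted(t.catalog)
    with open(out / "survey.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(catalog)
        for tx in t.transactions:
            w.writerow(["1" if c in tx else "2" for c in catalog])

    with open(out / "variable_specs.yaml", "w") as fh:
        yaml.safe_dump(
            {"variables": [
                {"code": c, "positive": ["1"], "negative": ["2"], "missing": [""]}
                for c in catalog
            ]},
            fh,
        )

    write_predications_csv(
        generate_predications(default_predication_spec(), seed=seed),
        out / "predications.csv",
    )

    cfg = {
        "survey_path": str(out / "survey.csv"),
        "variable_specs_path": str(out / "variable_specs.yaml"),
        "cohort_condition_code": "ckd",
        "out_dir": str(out / "results"),
        "min_support": 0.1,
        "keywords": {"y1_condition": ["y1"], "y2_condition": ["y2"], "y3_condition": ["y3"]},
        "predications_path": str(out / "predications.csv"),
        "litmine_min_count": 2,
        "seed": seed,
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg_path
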