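"""End-to-end orchestration: simulate -> LOH -> CN -> six-state -> tables -> expression.

Each stage is importable on its own; this module wires them over an
in-memory :class:`~cnnloh.sim.Cohort` (or a directory written by the
simulator) and collects every output family the analysis reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cn, expression, loh, sim, sixstate, summaries
from .io import write_matrix, write_segments_bed, write_segments_tsv


@dataclass
class RunConfig:
    """Thresholds echoed into every output manifest."""

    window_bp: int = 100_000
    alpha: float = 0.01
    min_group: int = 2
    fold_threshold: float = 2.0
    zero_rule: str = "exact_zero"
    break_on_undefined: bool = False
    min_snps: int = 1
    equal_var: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    cohort: sim.Cohort
    run_config: RunConfig
    loh_tumor: np.ndarray
    cn_tumor: np.ndarray
    cn_normal: np.ndarray
    cn_blood: np.ndarray
    codes: np.ndarray
    segments: pd.DataFrame
    table_case: pd.DataFrame
    table_arm: pd.DataFrame
    noloh_case: pd.DataFrame
    noloh_arm: pd.DataFrame
    concordance: dict
    expression_results: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(cohort: sim.Cohort | None = None,
                 run_config: RunConfig | None = None) -> PipelineResult:
    """Run every analysis stage on a cohort (simulated by default)."""
    run_config = run_config or RunConfig()
    if cohort is None:
        cohort = sim.simulate_cohort(sim.SimConfig(seed=run_config.seed))
    cn_cfg = cn.CnCallerConfig(window_bp=run_config.window_bp)
    loh_tumor = loh.call_loh_matrix(cohort.blood, cohort.tumor)
    cn_tumor = cn.call_cn(cohort.ratio_tumor, cohort.snp_map, cn_cfg)
    cn_normal = cn.call_cn(cohort.ratio_normal, cohort.snp_map, cn_cfg)
    cn_blood = cn.call_cn(cohort.ratio_blood, cohort.snp_map, cn_cfg)
    codes = sixstate.combine(loh_tumor, cn_tumor)
    segments = sixstate.segment_cohort(
        codes, cohort.snp_map, cohort.cases,
        break_on_undefined=run_config.break_on_undefined,
        min_snps=run_config.min_snps)
    table_case = summaries.tabulate_loh_by_cn(codes, cohort.snp_map, cohort.cases, "case")
    table_arm = summaries.tabulate_loh_by_cn(codes, cohort.snp_map, cohort.cases, "arm")
    noloh_case = summaries.tabulate_noloh_cn(codes, cohort.snp_map, cohort.cases, "case")
    noloh_arm = summaries.tabulate_noloh_cn(codes, cohort.snp_map, cohort.cases, "arm")
    concord = summaries.cn_concordance(cn_blood, cn_normal)
    expr_results = None
    if cohort.expr_normal is not None:
        expr_results = expression.analyze_all_classes(
            cohort.expr_normal, cohort.expr_tumor, cohort.genes, segments,
            cohort.snp_map, min_group=run_config.min_group,
            alpha=run_config.alpha, fold_threshold=run_config.fold_threshold,
            equal_var=run_config.equal_var)
    manifest = {
        "parameters": asdict(run_config),
        "sim_config": asdict(cohort.config),
        "n_snps": int(len(cohort.snp_map)),
        "n_cases": len(cohort.cases),
        "n_segments": int(len(segments)),
    }
    return PipelineResult(cohort, run_config, loh_tumor, cn_tumor, cn_normal,
                          cn_blood, codes, segments, table_case, table_arm,
                          noloh_case, noloh_arm, concord, expr_results, manifest)


def write_results(result: PipelineResult, outdir) -> None:
    """Emit all output families plus a manifest into one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    idx = cohort.snp_map["snp_id"]
    write_matrix(pd.DataFrame(result.loh_tumor, index=idx, columns=cohort.cases),
                 outdir / "loh_tumor.tsv")
    write_matrix(pd.DataFrame(result.cn_tumor, index=idx, columns=cohort.cases),
                 outdir / "cn_tumor.tsv")
    write_matrix(pd.DataFrame(result.codes, index=idx, columns=cohort.cases),
                 outdir / "sixstate.tsv")
    write_segments_tsv(result.segments, outdir / "segments.tsv")
    write_segments_bed(result.segments, outdir / "segments.bed")
    result.table_case.to_csv(outdir / "table1.tsv", sep="\t", index=False)
    result.table_arm.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    result.noloh_case.to_csv(outdir / "noloh_case.tsv", sep="\t", index=False)
    result.noloh_arm.to_csv(outdir / "noloh_arm.tsv", sep="\t", index=False)
    pd.DataFrame([result.concordance]).to_csv(outdir / "concordance.tsv",
                                              sep="\t", index=False)
    if result.expression_results is not None:
        result.expression_results.to_csv(outdir / "expression_results.tsv",
                                         sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
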