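"""Synthetic trio-cohort generator with planted six-state events.

Emulates a paired tumor/adjacent-normal/blood SNP-array study design: ~5.8 kb
probe spacing, 27% mean germline heterozygosity, 96% genotype call rate,
30 cases of which 17 carry paired tumor/normal expression profiles. Somatic
events (LOH and/or copy-number change) are planted as contiguous segments and
recorded as ground truth so every downstream stage can be scored.

The genome is a scaled-down set of 22 autosomes (1/25 of human chromosome
lengths, ~115 Mb, ~20k SNPs at default spacing) so a full cohort simulates in
seconds; densities and rates match the emulated design, only the genome length
is reduced.

Tumors are simulated pure (the emulated study micro-dissected tumor tissue);
there is no purity or subclonality knob. Within one planted LOH event the
retained allele is chosen once per segment, not per SNP — a single clonal
event keeps one haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AA, AB, BB, NC, CN_GROUP_NAMES

# GRCh37 autosome lengths // 25 (bp): a 1/25-scale genome.
DEFAULT_CHROM_LENGTHS: dict[int, int] = {
    1: 9970000, 2: 9729000, 3: 7921000, 4: 7646000, 5: 7236000,
    6: 6844000, 7: 6365000, 8: 5854000, 9: 5648000, 10: 5421000,
    11: 5401000, 12: 5354000, 13: 4606000, 14: 4293000, 15: 4101000,
    16: 3614000, 17: 3248000, 18: 3123000, 19: 2365000, 20: 2521000,
    21: 1925000, 22: 2052000,
}

#: The five plantable somatic states (background is retention/neutral).
PLANTABLE_STATES: list[tuple[bool, str]] = [
    (True, "loss"), (True, "neutral"), (True, "gain"),
    (False, "loss"), (False, "gain"),
]


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Rates and spacing default to the emulated 500K-array design; event copy
    numbers default to single-copy loss (c=1) and single-copy gain (c=3),
    with homozygous deletion (c=0) and c=4 available by configuration.
    """

    n_cases: int = 30
    n_expression_pairs: int = 17
    heterozygosity: float = 0.27
    call_rate: float = 0.96
    snp_spacing_bp: int = 5800
    intensity_noise_sd: float = 0.15
    arm_fraction: float = 0.4
    loss_cn: int = 1
    gain_cn: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.heterozygosity < 1 or not 0 < self.call_rate <= 1:
            raise ValueError("rates must lie in (0, 1]")
        if self.n_expression_pairs > self.n_cases:
            raise ValueError("n_expression_pairs must be <= n_cases")
        if self.loss_cn not in (0, 1) or self.gain_cn not in (3, 4):
            raise ValueError("loss_cn in {0,1}, gain_cn in {3,4}")


@dataclass
class ExpressionEffect:
    """Planted LOH-dependent expression shift.

    ``effect_log2`` is added (with a per-gene random sign) to tumor log2
    expression of affected genes lying wholly inside an LOH event;
    ``noise_sd`` is the per-(case, gene) log2 measurement noise.
    """

    effect_log2: float = 2.0
    noise_sd: float = 0.3
    affected_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    # One root seed; each stage gets an independent stream.
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(16)[stage])


def case_ids(config: SimConfig) -> list[str]:
    return [f"case{i + 1:02d}" for i in range(config.n_cases)]


def simulate_snp_map(config: SimConfig,
                     chromosome_lengths: dict[int, int] | None = None) -> pd.DataFrame:
    """Lay SNPs at jittered regular spacing along each chromosome.

    The p/q boundary sits at ``arm_fraction`` of each chromosome length.
    Every chromosome receives at least one SNP.
    """
    lengths = chromosome_lengths or DEFAULT_CHROM_LENGTHS
    if any(length <= 0 for length in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    rng = _stage_rng(config, 0)
    rows = []
    for chrom in sorted(lengths):
        length = lengths[chrom]
        n = max(1, int(round(length / config.snp_spacing_bp)))
        grid = (np.arange(n) + 0.5) * length / n
        jitter = rng.uniform(-0.4, 0.4, size=n) * length / n
        pos = np.clip(np.sort(grid + jitter), 1, length).astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(n))  # enforce strict increase
        boundary = config.arm_fraction * length
        for i, p in enumerate(pos):
            rows.append((f"snp_{chrom}_{i:05d}", chrom, "p" if p <= boundary else "q", int(p)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "arm", "pos"])


def _nocall_overlay(codes: np.ndarray, call_rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    out[rng.random(codes.shape) > call_rate] = NC
    return out


def simulate_germline(snp_map: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Blood genotype codes, shape (n_snps, n_cases).

    Each SNP is i.i.d.: AB with probability ``heterozygosity``, AA/BB equally
    splitting the remainder; NoCall overlaid at rate ``1 - call_rate``.
    """
    rng = rng if rng is not None else _stage_rng(config, 1)
    shape = (len(snp_map), config.n_cases)
    u = rng.random(shape)
    het = config.heterozygosity
    codes = np.where(u < het, AB, np.where(u < het + (1 - het) / 2, AA, BB)).astype(np.int8)
    return _nocall_overlay(codes, config.call_rate, rng)


def plant_events(snp_map: pd.DataFrame, events: pd.DataFrame, config: SimConfig
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Expand an event table into per-SNP truth tracks.

    ``events`` columns: case_id, chrom, start, end, loh (bool), cn_group.
    Returns ``(loh_truth, cn_truth)``: boolean LOH and integer copy number
    (background c=2) arrays of shape (n_snps, n_cases).
    """
    cases = case_ids(config)
    case_index = {c: j for j, c in enumerate(cases)}
    n = len(snp_map)
    loh_truth = np.zeros((n, config.n_cases), dtype=bool)
    cn_truth = np.full((n, config.n_cases), 2, dtype=np.int8)
    group_to_c = {"loss": config.loss_cn, "neutral": 2, "gain": config.gain_cn}
    for (case_id, chrom), sub in events.groupby(["case_id", "chrom"]):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping events for {case_id} chr{chrom}")
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    for row in events.itertuples(index=False):
        j = case_index[row.case_id]
        mask = (chrom_arr == row.chrom) & (pos_arr >= row.start) & (pos_arr <= row.end)
        loh_truth[mask, j] |= bool(row.loh)
        cn_truth[mask, j] = group_to_c[row.cn_group]
    return loh_truth, cn_truth


def default_event_spec(snp_map: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Plant 3-6 events per case, cycling through the five somatic states.

    Event lengths are drawn between 0.8 and 2.5 Mb so that typical events span
    well over 20 informative SNPs at default spacing and heterozygosity. One
    case in ten is left quiet (no events), mirroring the near-silent genomes
    seen in real cohorts.
    """
    rng = _stage_rng(config, 2)
    lengths = snp_map.groupby("chrom")["pos"].max().to_dict()
    chroms = sorted(lengths)
    rows = []
    state_cycle = 0
    for j, case_id in enumerate(case_ids(config)):
        if j % 10 == 9:
            continue  # quiet case
        n_events = rng.integers(3, 7)
        used: dict[int, list[tuple[int, int]]] = {}
        for _ in range(n_events):
            loh, group = PLANTABLE_STATES[state_cycle % len(PLANTABLE_STATES)]
            state_cycle += 1
            for _attempt in range(40):
                chrom = int(rng.choice(chroms))
                span = int(rng.uniform(0.8e6, 2.5e6))
                if span >= lengths[chrom]:
                    continue
                start = int(rng.uniform(1, lengths[chrom] - span))
                end = start + span
                if all(end < s or start > e for s, e in used.get(chrom, [])):
                    used.setdefault(chrom, []).append((start, end))
                    rows.append((case_id, chrom, start, end, loh, group))
                    break
    return pd.DataFrame(rows, columns=["case_id", "chrom", "start", "end", "loh", "cn_group"])


def simulate_tumor_genotypes(blood: np.ndarray, events: pd.DataFrame,
                             snp_map: pd.DataFrame, config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Derive tumor and adjacent-normal genotype matrices from blood.

    Inside each LOH event every heterozygous call collapses to one homozygote
    (retained allele drawn once per event); all other genotypes are copied.
    Tumor and normal each receive an independent NoCall overlay.
    """
    rng = rng if rng is not None else _stage_rng(config, 3)
    case_index = {c: j for j, c in enumerate(case_ids(config))}
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    tumor = blood.copy()
    for row in events.itertuples(index=False):
        if not row.loh:
            continue
        j = case_index[row.case_id]
        mask = (chrom_arr == row.chrom) & (pos_arr >= row.start) & (pos_arr <= row.end)
        retained = AA if rng.random() < 0.5 else BB
        col = tumor[:, j]
        col[mask & (col == AB)] = retained
        tumor[:, j] = col
    tumor = _nocall_overlay(tumor, config.call_rate, rng)
    normal = _nocall_overlay(blood.copy(), config.call_rate, rng)
    return tumor, normal


def simulate_intensities(cn_truth: np.ndarray, config: SimConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP log2 intensity ratios for tumor, adjacent normal, and blood.

    Tumor ratios are Normal(log2(c/2), noise_sd) with the homozygous-deletion
    mean floored at -3 (array background); normal and blood are both diploid
    (mean 0). The blood track exists so blood-vs-adjacent copy-number
    concordance can be computed the way the study design compares its two
    candidate controls.
    """
    rng = rng if rng is not None else _stage_rng(config, 4)
    with np.errstate(divide="ignore"):
        means = np.log2(cn_truth.astype(float) / 2.0)
    means = np.maximum(means, -3.0)
    sd = config.intensity_noise_sd
    tumor = rng.normal(means, sd)
    normal = rng.normal(0.0, sd, size=cn_truth.shape)
    blood = rng.normal(0.0, sd, size=cn_truth.shape)
    return tumor, normal, blood


def simulate_gene_table(snp_map: pd.DataFrame, config: SimConfig,
                        n_genes: int = 600, duplicate_fraction: float = 0.1) -> pd.DataFrame:
    """Place gene regions (5-80 kb) uniformly on the simulated genome.

    A fraction of genes carry a second probe set with a shifted reference
    region, as expression arrays do.
    """
    rng = _stage_rng(config, 5)
    lengths = snp_map.groupby("chrom")["pos"].max().to_dict()
    chroms = np.array(sorted(lengths))
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    ps_counter = 200000
    for g in range(n_genes):
        chrom = int(rng.choice(chroms, p=weights))
        glen = int(rng.uniform(5e3, 8e4))
        start = int(rng.uniform(1, max(2, lengths[chrom] - glen)))
        symbol = f"GENE{g + 1:04d}"
        rows.append((f"{ps_counter}_at", symbol, chrom, start, start + glen))
        ps_counter += 1
        if rng.random() < duplicate_fraction:
            shift = int(rng.uniform(-2e3, 2e3))
            rows.append((f"{ps_counter}_s_at", symbol, chrom,
                         max(1, start + shift), start + glen + shift))
            ps_counter += 1
    df = pd.DataFrame(rows, columns=["probeset_id", "gene_symbol", "chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _gene_in_loh(genes: pd.DataFrame, events: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Boolean (n_probesets, n_cases): gene region wholly inside an LOH event."""
    out = np.zeros((len(genes), config.n_cases), dtype=bool)
    case_index = {c: j for j, c in enumerate(case_ids(config))}
    for row in events.itertuples(index=False):
        if not row.loh:
            continue
        j = case_index[row.case_id]
        inside = ((genes["chrom"] == row.chrom)
                  & (genes["start"] >= row.start) & (genes["end"] <= row.end))
        out[inside.to_numpy(), j] = True
    return out


def simulate_expression(genes: pd.DataFrame, events: pd.DataFrame,
                        effect: ExpressionEffect, config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired log2 expression matrices for the expression subcohort.

    Returns ``(expr_normal, expr_tumor, truth_genes)``. Normal expression is
    Normal(per-gene baseline, noise_sd); tumor adds per-(case, gene) noise
    plus the planted shift for affected genes wholly inside an LOH event of
    that case. The first ``n_expression_pairs`` cases carry expression.
    """
    rng = _stage_rng(config, 6)
    expr_cases = case_ids(config)[: config.n_expression_pairs]
    n_g, n_c = len(genes), len(expr_cases)
    baseline = rng.normal(7.0, 1.2, size=n_g)
    normal = baseline[:, None] + rng.normal(0.0, effect.noise_sd, size=(n_g, n_c))
    tumor = baseline[:, None] + rng.normal(0.0, effect.noise_sd, size=(n_g, n_c))
    affected = rng.random(n_g) < effect.affected_fraction
    sign = np.where(rng.random(n_g) < 0.5, 1.0, -1.0)
    in_loh = _gene_in_loh(genes, events, config)[:, :n_c]
    shift = (affected * sign * effect.effect_log2)[:, None] * in_loh
    tumor = tumor + shift
    idx = genes["probeset_id"]
    truth = pd.DataFrame({
        "probeset_id": idx,
        "gene_symbol": genes["gene_symbol"],
        "affected": affected,
        "effect_log2": np.where(affected, sign * effect.effect_log2, 0.0),
        "n_loh_cases": in_loh.sum(axis=1),
    })
    return (pd.DataFrame(normal, index=idx, columns=expr_cases),
            pd.DataFrame(tumor, index=idx, columns=expr_cases),
            truth)


@dataclass
class Cohort:
    """Everything one simulated study produces, in memory."""

    config: SimConfig
    snp_map: pd.DataFrame
    events: pd.DataFrame
    loh_truth: np.ndarray
    cn_truth: np.ndarray
    blood: np.ndarray
    tumor: np.ndarray
    normal: np.ndarray
    ratio_tumor: np.ndarray
    ratio_normal: np.ndarray
    ratio_blood: np.ndarray
    genes: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    expr_normal: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    expr_tumor: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    truth_genes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def cases(self) -> list[str]:
        return case_ids(self.config)


def simulate_cohort(config: SimConfig | None = None,
                    effect: ExpressionEffect | None = None,
                    events: pd.DataFrame | None = None,
                    chromosome_lengths: dict[int, int] | None = None,
                    with_expression: bool = True) -> Cohort:
    """Run the full generator: map, events, genotypes, intensities, expression."""
    config = config or SimConfig()
    effect = effect or ExpressionEffect()
    snp_map = simulate_snp_map(config, chromosome_lengths)
    if events is None:
        events = default_event_spec(snp_map, config)
    loh_truth, cn_truth = plant_events(snp_map, events, config)
    blood = simulate_germline(snp_map, config)
    tumor, normal = simulate_tumor_genotypes(blood, events, snp_map, config)
    rt, rn, rb = simulate_intensities(cn_truth, config)
    cohort = Cohort(config, snp_map, events, loh_truth, cn_truth,
                    blood, tumor, normal, rt, rn, rb)
    if with_expression:
        cohort.genes = simulate_gene_table(snp_map, config)
        cohort.expr_normal, cohort.expr_tumor, cohort.truth_genes = simulate_expression(
            cohort.genes, events, effect, config)
    return cohort


def write_cohort(cohort: Cohort, outdir) -> None:
    """Emit the directory layout consumed by the downstream stages."""
    from pathlib import Path

    from .io import decode_genotypes, write_matrix, write_snp_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_snp_map(cohort.snp_map, outdir / "snp_map.tsv")
    idx = cohort.snp_map["snp_id"]
    cases = cohort.cases
    for name, codes in (("blood", cohort.blood), ("normal", cohort.normal),
                        ("tumor", cohort.tumor)):
        write_matrix(decode_genotypes(codes, idx, cases), outdir / f"genotypes_{name}.tsv")
    for name, arr in (("tumor", cohort.ratio_tumor), ("normal", cohort.ratio_normal),
                      ("blood", cohort.ratio_blood)):
        write_matrix(pd.DataFrame(np.round(arr, 5), index=idx, columns=cases),
                     outdir / f"logratio_{name}.tsv")
    cohort.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    if cohort.genes is not None:
        cohort.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        cohort.expr_normal.round(5).to_csv(outdir / "expression_normal.tsv", sep="\t")
        cohort.expr_tumor.round(5).to_csv(outdir / "expression_tumor.tsv", sep="\t")
        cohort.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
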