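"""LOH-conditioned differential gene expression.

For each case with paired expression data, the per-gene log2 fold change is
tumor log2 expression minus matched-normal log2 expression. Each probe set
is assigned, per case, the (LOH, CN-group) state of the unique LOH/CN
segment that fully contains its reference region; a probe set overlapping a
segment boundary or a gap is undefined in that case. Within one CN class
(neutral, loss, or gain), probe sets with at least two LOH-positive and at
least two LOH-negative cases are eligible, and a two-sided unpaired t-test
(pooled variance by default) compares the log2 fold changes between the two
groups; p < 0.01 is reported as significant, without multiple-testing
correction. Group fold changes are reported as 2**(group mean log2fc) —
geometric-mean tumor/normal ratios.

Probe sets are tested independently even when they share a gene symbol:
distinct probe sets of one gene may have distinct reference regions, hence
distinct segment assignments and distinct SNP counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

UNDEF = -1  # per-(gene, case) state when no single segment contains the region

RESULT_COLUMNS = [
    "probeset_id", "gene_symbol", "cn_class", "n_loh", "n_noloh", "snp_count",
    "mean_fc_loh", "mean_fc_noloh", "t_statistic", "p_value", "direction",
    "twofold", "significant", "untestable",
]


def fold_changes(expr_normal: pd.DataFrame, expr_tumor: pd.DataFrame) -> pd.DataFrame:
    """Per-(probe set, case) log2 fold change: tumor minus matched normal."""
    if list(expr_normal.columns) != list(expr_tumor.columns):
        raise ValueError("normal/tumor expression matrices have unmatched cases")
    if not expr_normal.index.equals(expr_tumor.index):
        raise ValueError("normal/tumor expression matrices have unmatched probe sets")
    return expr_tumor - expr_normal


def map_genes(genes: pd.DataFrame, segments: pd.DataFrame,
              cases: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Assign each (probe set, case) the state of its containing segment.

    Returns ``(loh, group)`` int8 arrays of shape (n_probesets, n_cases):
    ``loh`` is 0/1 and ``group`` 0/1/2 (loss/neutral/gain) where a unique
    segment fully contains the gene region, else both are -1 (undefined).
    """
    n_g, n_c = len(genes), len(cases)
    loh = np.full((n_g, n_c), UNDEF, dtype=np.int8)
    group = np.full((n_g, n_c), UNDEF, dtype=np.int8)
    case_index = {c: j for j, c in enumerate(cases)}
    group_code = {"loss": 0, "neutral": 1, "gain": 2}
    g_chrom = genes["chrom"].to_numpy()
    g_start = genes["start"].to_numpy()
    g_end = genes["end"].to_numpy()
    for (case_id, chrom), sub in segments.groupby(["case_id", "chrom"]):
        if case_id not in case_index:
            continue
        j = case_index[case_id]
        on_chrom = np.nonzero(g_chrom == chrom)[0]
        if len(on_chrom) == 0:
            continue
        s = sub.sort_values("start")
        seg_start = s["start"].to_numpy()
        seg_end = s["end"].to_numpy()
        # Candidate segment: last one starting at or before the gene start.
        k = np.searchsorted(seg_start, g_start[on_chrom], side="right") - 1
        ok = (k >= 0) & (g_end[on_chrom] <= np.where(k >= 0, seg_end[np.maximum(k, 0)], -1))
        hit = on_chrom[ok]
        kk = k[ok]
        if len(kk):
            loh[hit, j] = s["loh"].to_numpy()[kk].astype(np.int8)
            group[hit, j] = np.array(
                [group_code[x] for x in s["cn_group"].to_numpy()[kk]], dtype=np.int8)
    return loh, group


def eligible(loh: np.ndarray, group: np.ndarray, cn_class: int,
             min_group: int = 2) -> pd.DataFrame:
    """Probe sets testable within one CN class.

    A case enters a probe set's comparison only if the gene's state is
    defined and in ``cn_class`` there; the probe set is eligible when both
    the LOH-positive and LOH-negative groups reach ``min_group`` cases.
    Returns a frame with probeset row index plus per-class group masks.
    """
    in_class = group == cn_class
    pos = in_class & (loh == 1)
    neg = in_class & (loh == 0)
    n_pos = pos.sum(axis=1)
    n_neg = neg.sum(axis=1)
    keep = (n_pos >= min_group) & (n_neg >= min_group)
    return pd.DataFrame({
        "gene_row": np.nonzero(keep)[0],
        "n_loh": n_pos[keep],
        "n_noloh": n_neg[keep],
        "loh_mask": [pos[i] for i in np.nonzero(keep)[0]],
        "noloh_mask": [neg[i] for i in np.nonzero(keep)[0]],
    })


def pooled_t_test(x: np.ndarray, y: np.ndarray, equal_var: bool = True
                  ) -> tuple[float, float]:
    """Two-sided unpaired t-test on two samples; (nan, nan) if variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def loh_t_test(log2fc_loh: np.ndarray, log2fc_noloh: np.ndarray,
               equal_var: bool = True, alpha: float = 0.01,
               fold_threshold: float = 2.0) -> dict:
    """Compare log2 fold changes between LOH+ and LOH- groups for one probe set.

    The reported t statistic follows the (non-LOH minus LOH) orientation, so
    lower expression in the LOH group gives a positive t. Zero pooled
    variance makes the test undefined; such probe sets are flagged
    untestable and excluded from significance counts.
    """
    x = np.asarray(log2fc_loh, dtype=float)
    y = np.asarray(log2fc_noloh, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 cases")
    mean_loh = x.mean()
    mean_noloh = y.mean()
    untestable = np.allclose(x.var(ddof=0) + y.var(ddof=0), 0.0)
    if untestable:
        t = p = float("nan")
    else:
        t, p = pooled_t_test(y, x, equal_var=equal_var)
    mean_fc_loh = float(2.0 ** mean_loh)
    mean_fc_noloh = float(2.0 ** mean_noloh)
    return {
        "n_loh": len(x),
        "n_noloh": len(y),
        "mean_fc_loh": mean_fc_loh,
        "mean_fc_noloh": mean_fc_noloh,
        "t_statistic": t,
        "p_value": p,
        "direction": "lower_in_LOH" if mean_loh < mean_noloh else "higher_in_LOH",
        "twofold": twofold_filter(mean_fc_loh, fold_threshold),
        "significant": (not untestable) and p < alpha,
        "untestable": untestable,
    }


def twofold_filter(mean_fc_loh: float, fold_threshold: float = 2.0) -> bool:
    """At-least-2-fold rule on the LOH group's tumor/normal fold change."""
    return mean_fc_loh >= fold_threshold or mean_fc_loh <= 1.0 / fold_threshold


def expected_false_positives(n_tested: int, alpha: float) -> int:
    """Genes expected significant by chance alone: integer part of n * alpha."""
    if n_tested < 0 or not 0 < alpha < 1:
        raise ValueError("n_tested >= 0 and alpha in (0,1) required")
    return int(n_tested * alpha)


def count_snps_in_region(chrom: int, start: int, end: int,
                         snp_map: pd.DataFrame) -> int:
    """Number of array SNPs whose position falls within [start, end]."""
    sub = snp_map.loc[snp_map["chrom"] == chrom, "pos"].to_numpy()
    return int(np.searchsorted(sub, end, side="right")
               - np.searchsorted(sub, start, side="left"))


CN_CLASS_NAMES = {1: "neutral", 0: "loss", 2: "gain"}


def analyze_class(log2fc: pd.DataFrame, genes: pd.DataFrame, loh: np.ndarray,
                  group: np.ndarray, snp_map: pd.DataFrame, cn_class: int,
                  min_group: int = 2, alpha: float = 0.01,
                  fold_threshold: float = 2.0, equal_var: bool = True) -> pd.DataFrame:
    """Run the eligibility filter and per-probe-set t-tests for one CN class."""
    fc = log2fc.to_numpy()
    elig = eligible(loh, group, cn_class, min_group)
    rows = []
    for rec in elig.itertuples(index=False):
        i = rec.gene_row
        res = loh_t_test(fc[i][rec.loh_mask], fc[i][rec.noloh_mask],
                         equal_var=equal_var, alpha=alpha,
                         fold_threshold=fold_threshold)
        res["probeset_id"] = genes["probeset_id"].iat[i]
        res["gene_symbol"] = genes["gene_symbol"].iat[i]
        res["cn_class"] = CN_CLASS_NAMES[cn_class]
        res["snp_count"] = count_snps_in_region(
            int(genes["chrom"].iat[i]), int(genes["start"].iat[i]),
            int(genes["end"].iat[i]), snp_map)
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.DataFrame(rows)[RESULT_COLUMNS]


def analyze_all_classes(expr_normal: pd.DataFrame, expr_tumor: pd.DataFrame,
                        genes: pd.DataFrame, segments: pd.DataFrame,
                        snp_map: pd.DataFrame, min_group: int = 2,
                        alpha: float = 0.01, fold_threshold: float = 2.0,
                        equal_var: bool = True) -> pd.DataFrame:
    """Full expression integration: fold changes, mapping, tests in all classes."""
    cases = list(expr_normal.columns)
    log2fc = fold_changes(expr_normal, expr_tumor)
    genes = genes.set_index("probeset_id").loc[log2fc.index].reset_index()
    loh, group = map_genes(genes, segments, cases)
    parts = [analyze_class(log2fc, genes, loh, group, snp_map, c,
                           min_group, alpha, fold_threshold, equal_var)
             for c in (1, 0, 2)]  # neutral first, as the primary comparison
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(parts, ignore_index=True)
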