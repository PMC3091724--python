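"""Cohort summary tables: LOH counts and fractions by CN group.

Reproduces the study-style reporting: one row per case (or per chromosome
arm, pooling all cases) giving the number of informative LOH-positive SNPs
in each CN group (loss / neutral / gain) with its fraction of the row total,
plus footer statistics (zero-fraction unit count, range, median, pooled
global average). A parallel table covers LOH-negative SNPs by CN state.

Display fractions are rounded half-up to two decimals; the ``rounded_zero``
rule counts a unit as LOH-free in a group when its rounded fraction is 0.00,
the ``exact_zero`` rule when its count is literally zero. Medians and ranges
use unrounded fractions, with zero-total units contributing fraction 0.

The package ships the reference ESCC cohort's published per-case and per-arm
count tables (30 cases / 39 autosomal arms) so the footer arithmetic can be
exercised against real printed counts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .cn import cn_concordance  # noqa: F401  (re-exported summary operation)
from .sixstate import loh_mask, noloh_mask

GROUPS = ("loss", "neutral", "gain")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def load_reference_case_counts() -> pd.DataFrame:
    """Published per-case LOH SNP counts by CN group (30 ESCC cases)."""
    with resources.files("cnnloh.data").joinpath("escc_case_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"unit_id": str})


def load_reference_arm_counts() -> pd.DataFrame:
    """Published per-arm LOH SNP counts by CN group (39 autosomal arms)."""
    with resources.files("cnnloh.data").joinpath("escc_arm_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"unit_id": str})


def summary_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach totals and rounded fractions to a (unit_id, loss, neutral, gain) table."""
    out = counts.copy()
    out["total"] = out[list(GROUPS)].sum(axis=1)
    for g in GROUPS:
        frac = np.where(out["total"] > 0, out[g] / out["total"].replace(0, 1), 0.0)
        out[f"{g}_frac"] = frac
        out[f"{g}_frac_display"] = [round_half_up(f) for f in frac]
    cols = ["unit_id", "total"] + [c for g in GROUPS
                                   for c in (g, f"{g}_frac", f"{g}_frac_display")]
    return out[cols]


def _arm_labels(snp_map: pd.DataFrame) -> np.ndarray:
    return (snp_map["chrom"].astype(str) + snp_map["arm"]).to_numpy()


def _tabulate(codes: np.ndarray, snp_map: pd.DataFrame, cases: list[str],
              group_by: str, mask_fn) -> pd.DataFrame:
    """Count masked SNPs by CN group per case or per arm (pooled over cases)."""
    if codes.shape != (len(snp_map), len(cases)):
        raise ValueError("six-state matrix not aligned to map/cases")
    sel = mask_fn(codes)
    group_of = np.where(sel, np.asarray(codes) % 3, -1)  # cn group where selected
    if group_by == "case":
        units = cases
        rows = []
        for j, unit in enumerate(units):
            counts = [(group_of[:, j] == g).sum() for g in range(3)]
            rows.append((unit, *counts))
    elif group_by == "arm":
        labels = _arm_labels(snp_map)
        units = list(dict.fromkeys(labels))  # map order
        rows = []
        for unit in units:
            on_arm = labels == unit
            counts = [(group_of[on_arm] == g).sum() for g in range(3)]
            rows.append((unit, *counts))
    else:
        raise ValueError("group_by must be 'case' or 'arm'")
    counts_df = pd.DataFrame(rows, columns=["unit_id", *GROUPS])
    out = summary_from_counts(counts_df)
    assert (out[list(GROUPS)].sum(axis=1) == out["total"]).all()  # row conservation
    return out


def tabulate_loh_by_cn(codes: np.ndarray, snp_map: pd.DataFrame, cases: list[str],
                       group_by: str = "case") -> pd.DataFrame:
    """LOH-positive informative SNPs split by CN group, per case or per arm."""
    return _tabulate(codes, snp_map, cases, group_by, loh_mask)


def tabulate_noloh_cn(codes: np.ndarray, snp_map: pd.DataFrame, cases: list[str],
                      group_by: str = "case") -> pd.DataFrame:
    """LOH-negative informative SNPs split by CN group (companion table)."""
    return _tabulate(codes, snp_map, cases, group_by, noloh_mask)


def footer_stats(rows: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Footer block of a summary table, per CN group.

    ``n_zero_fraction`` counts units whose *rounded* fraction is 0.00 (true
    zeros included); range and median are over unrounded per-unit fractions
    (zero-total units contribute 0); ``global_average`` is the pooled-count
    ratio, not the mean of per-unit fractions.
    """
    if len(rows) == 0:
        raise ValueError("footer_stats requires at least one row")
    total = rows["total"].sum()
    out = {}
    for g in GROUPS:
        frac = rows[f"{g}_frac"].to_numpy(dtype=float)
        disp = rows[f"{g}_frac_display"].to_numpy(dtype=float)
        out[g] = {
            "n_zero_fraction": int((disp == 0.0).sum()),
            "n_exact_zero": int((rows[g] == 0).sum()),
            "min": float(frac.min()),
            "max": float(frac.max()),
            "median": float(np.median(frac)),
            "global_average": float(rows[g].sum() / total) if total else 0.0,
        }
    return out


def percent_cases_with_loh(rows: pd.DataFrame, cn_group: str,
                           zero_rule: str = "exact_zero") -> int:
    """Percent of units showing any LOH in one CN group, whole-percent rounded.

    ``exact_zero``: a unit counts as LOH-free when its count is 0;
    ``rounded_zero``: when its displayed fraction rounds to 0.00.
    """
    if len(rows) == 0:
        raise ValueError("no rows")
    if zero_rule == "exact_zero":
        n_zero = int((rows[cn_group] == 0).sum())
    elif zero_rule == "rounded_zero":
        n_zero = int((rows[f"{cn_group}_frac_display"] == 0.0).sum())
    else:
        raise ValueError("zero_rule must be exact_zero or rounded_zero")
    return int(round_half_up(100.0 * (1 - n_zero / len(rows)), 0))


def pooling_consistency(per_case_by_arm: list[pd.DataFrame],
                        pooled: pd.DataFrame) -> bool:
    """Check that summed per-case arm tables equal the pooled arm table."""
    acc = None
    for t in per_case_by_arm:
        part = t.set_index("unit_id")[list(GROUPS)]
        acc = part if acc is None else acc.add(part, fill_value=0)
    return bool((acc.astype(int) == pooled.set_index("unit_id")[list(GROUPS)]).all().all())
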