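"""Scoring simulated runs against planted truth, and calibration experiments.

These routines measure what the pipeline is supposed to guarantee on
synthetic cohorts: per-SNP six-state recovery inside planted events, segment
boundary placement in informative-SNP units, type-I error of the expression
t-test under a null, and power under a planted shift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import loh_t_test
from .io import AB
from .sim import Cohort
from .sixstate import sixstate_code


def true_sixstate_codes(cohort: Cohort) -> np.ndarray:
    """Per-SNP true six-state codes (n_snps, n_cases) from the planted truth."""
    from .io import cn_group_array

    groups = cn_group_array(cohort.cn_truth)
    return (cohort.loh_truth.astype(np.int8) * 3 + groups).astype(np.int8)


def snp_recovery(cohort: Cohort, inferred: np.ndarray,
                 min_informative: int = 20) -> dict[str, float]:
    """Fraction of planted-event informative SNPs receiving their true state.

    Only events spanning at least ``min_informative`` informative SNPs count
    (tiny events are below the designed resolution of a 100-kb window).
    Inferred-undefined SNPs (e.g. tumor no-calls) are excluded: recovery is
    judged where the pipeline makes a call.
    """
    truth = true_sixstate_codes(cohort)
    chrom_arr = cohort.snp_map["chrom"].to_numpy()
    pos_arr = cohort.snp_map["pos"].to_numpy()
    case_index = {c: j for j, c in enumerate(cohort.cases)}
    n_match = n_called = n_events = 0
    for ev in cohort.events.itertuples(index=False):
        j = case_index[ev.case_id]
        in_ev = (chrom_arr == ev.chrom) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
        informative = in_ev & (cohort.blood[:, j] == AB)
        if informative.sum() < min_informative:
            continue
        n_events += 1
        called = informative & (inferred[:, j] >= 0)
        n_called += int(called.sum())
        n_match += int((inferred[called, j] == truth[called, j]).sum())
    return {
        "recovery": n_match / n_called if n_called else float("nan"),
        "n_events": n_events,
        "n_informative_called": n_called,
    }


def boundary_errors(cohort: Cohort, segments: pd.DataFrame,
                    min_informative: int = 20) -> pd.DataFrame:
    """Per-event boundary placement error, in informative-SNP units.

    For each scored planted event, the inferred segment of the event's state
    with the largest overlap is matched; the error is the rank distance (among
    that case's informative SNPs on the chromosome) between inferred and true
    first/last informative SNP. Events with no matching segment get infinite
    error.
    """
    chrom_arr = cohort.snp_map["chrom"].to_numpy()
    pos_arr = cohort.snp_map["pos"].to_numpy()
    case_index = {c: j for j, c in enumerate(cohort.cases)}
    group_name = {"loss": 0, "neutral": 1, "gain": 2}
    rows = []
    for ev in cohort.events.itertuples(index=False):
        j = case_index[ev.case_id]
        on_chrom = chrom_arr == ev.chrom
        info_pos = pos_arr[on_chrom & (cohort.blood[:, j] == AB)]
        in_ev = (info_pos >= ev.start) & (info_pos <= ev.end)
        if in_ev.sum() < min_informative:
            continue
        true_first, true_last = info_pos[in_ev][0], info_pos[in_ev][-1]
        state = sixstate_code(ev.loh, group_name[ev.cn_group])
        cand = segments[(segments["case_id"] == ev.case_id)
                        & (segments["chrom"] == ev.chrom)
                        & (segments["loh"].astype(int) * 3
                           + segments["cn_group"].map(group_name) == state)]
        overlap = (np.minimum(cand["end"], ev.end)
                   - np.maximum(cand["start"], ev.start)).clip(lower=0)
        if len(cand) == 0 or overlap.max() <= 0:
            rows.append((ev.case_id, ev.chrom, np.inf))
            continue
        best = cand.loc[overlap.idxmax()]
        err_start = abs(np.searchsorted(info_pos, best["start"])
                        - np.searchsorted(info_pos, true_first))
        err_end = abs(np.searchsorted(info_pos, best["end"])
                      - np.searchsorted(info_pos, true_last))
        rows.append((ev.case_id, ev.chrom, float(max(err_start, err_end))))
    return pd.DataFrame(rows, columns=["case_id", "chrom", "boundary_error"])


def null_ttest_experiment(n_probesets: int, rng: np.random.Generator,
                          n_cases: int = 17, noise_sd: float = 0.3,
                          alpha: float = 0.01) -> dict[str, float]:
    """Type-I calibration: no planted effect, count probe sets at p < alpha.

    Group sizes mimic the eligibility regime (2-8 LOH-positive of 17 paired
    cases); log2 fold changes are pure noise, so the significant count should
    be Binomial(n_probesets, alpha).
    """
    n_sig = 0
    for _ in range(n_probesets):
        n_loh = int(rng.integers(2, 9))
        fc = rng.normal(0.0, noise_sd * np.sqrt(2), size=n_cases)
        res = loh_t_test(fc[:n_loh], fc[n_loh:], alpha=alpha)
        n_sig += res["significant"]
    return {"n_tested": n_probesets, "n_significant": n_sig,
            "rate": n_sig / n_probesets}


def power_experiment(n_genes: int, effect_log2: float, noise_sd: float,
                     rng: np.random.Generator, n_loh: int = 3, n_noloh: int = 5,
                     alpha: float = 0.01) -> dict[str, float]:
    """Power to recover a planted LOH-dependent shift with correct direction."""
    n_hit = n_dir = 0
    for _ in range(n_genes):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        per_pair_sd = noise_sd * np.sqrt(2)  # tumor and normal each carry noise
        fc_loh = rng.normal(sign * effect_log2, per_pair_sd, size=n_loh)
        fc_noloh = rng.normal(0.0, per_pair_sd, size=n_noloh)
        res = loh_t_test(fc_loh, fc_noloh, alpha=alpha)
        want = "higher_in_LOH" if sign > 0 else "lower_in_LOH"
        if res["significant"]:
            n_hit += 1
            n_dir += res["direction"] == want
    return {"n_genes": n_genes, "power": n_hit / n_genes,
            "correct_direction": n_dir / max(n_hit, 1)}
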