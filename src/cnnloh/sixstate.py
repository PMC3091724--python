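"""Six-state LOH x copy-number classification and segment construction.

The six states are the cross of LOH status (positive/negative) with the CN
group (loss / neutral / gain); LOH-positive diploid SNPs are the
copy-number-neutral LOH (CNNLOH) class. The state is defined only at
informative SNPs with a determinate LOH call; all other SNPs carry an
undefined state and sit interstitially between segments.

Segments are maximal runs of *defined* SNPs sharing one state, taken in map
order: by default, interstitial undefined SNPs do not break a run (they lie
between segment endpoints, which are always informative SNPs). The stricter
reading — an undefined SNP severs adjacency — is available via
``break_on_undefined``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (CN_GROUP_NAMES, GAIN, LOSS, NEUTRAL, UNDEFINED,
                 cn_group_array, validate_segments)

#: Six-state codes: loh * 3 + cn_group; -1 = undefined.
SIXSTATE_UNDEFINED = -1
CNNLOH_CODE = 1 * 3 + NEUTRAL  # LOH-positive, diploid


def sixstate_code(loh: bool, group: int) -> int:
    return int(loh) * 3 + group


def decode_sixstate(code: int) -> tuple[bool, str]:
    """Return (loh, cn_group_name) for a defined six-state code."""
    if code < 0 or code > 5:
        raise ValueError(f"undefined or invalid six-state code {code}")
    return bool(code // 3), CN_GROUP_NAMES[code % 3]


def combine(loh_status: np.ndarray, cn_states: np.ndarray) -> np.ndarray:
    """Cross per-SNP LOH status with CN states into six-state codes.

    Undefined LOH (uninformative SNP or target no-call) yields an undefined
    six-state regardless of the CN call.
    """
    loh_status = np.asarray(loh_status)
    cn_states = np.asarray(cn_states)
    if loh_status.shape != cn_states.shape:
        raise ValueError("LOH and CN tracks are not aligned")
    groups = cn_group_array(cn_states)
    codes = (loh_status.astype(np.int16) * 3 + groups).astype(np.int8)
    codes[loh_status == UNDEFINED] = SIXSTATE_UNDEFINED
    return codes


def segment(codes: np.ndarray, snp_map: pd.DataFrame, case_id: str,
            break_on_undefined: bool = False, min_snps: int = 1) -> pd.DataFrame:
    """Build LOH/CN segments from a per-SNP six-state track.

    A segment is a maximal run of defined SNPs with equal state that are
    consecutive among defined SNPs on one chromosome; its endpoints are the
    positions of the run's first and last (informative) SNPs. With
    ``break_on_undefined`` any undefined SNP in between splits the run.
    Runs shorter than ``min_snps`` are dropped.
    """
    codes = np.asarray(codes)
    if codes.shape[0] != len(snp_map):
        raise ValueError("six-state track not aligned to SNP map")
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    rows = []
    for chrom in np.unique(chrom_arr):
        on_chrom = np.nonzero(chrom_arr == chrom)[0]
        c = codes[on_chrom]
        defined = np.nonzero(c != SIXSTATE_UNDEFINED)[0]
        if len(defined) == 0:
            continue
        breaks = c[defined[1:]] != c[defined[:-1]]
        if break_on_undefined:
            breaks = breaks | (np.diff(defined) > 1)
        run_starts = np.concatenate([[0], np.nonzero(breaks)[0] + 1])
        run_ends = np.concatenate([np.nonzero(breaks)[0], [len(defined) - 1]])
        for s, e in zip(run_starts, run_ends):
            n = e - s + 1
            if n < min_snps:
                continue
            first, last = on_chrom[defined[s]], on_chrom[defined[e]]
            loh, group = decode_sixstate(int(c[defined[s]]))
            rows.append((case_id, int(chrom), int(pos_arr[first]),
                         int(pos_arr[last]), loh, group, int(n)))
    out = pd.DataFrame(rows, columns=["case_id", "chrom", "start", "end",
                                      "loh", "cn_group", "n_snps"])
    return validate_segments(out) if len(out) else out


def segment_cohort(codes: np.ndarray, snp_map: pd.DataFrame, cases: list[str],
                   **kwargs) -> pd.DataFrame:
    """Segment every case column of an (n_snps, n_cases) six-state matrix."""
    parts = [segment(codes[:, j], snp_map, case_id, **kwargs)
             for j, case_id in enumerate(cases)]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["case_id", "chrom", "start", "end", "loh", "cn_group", "n_snps"])


def expand_segments(segments: pd.DataFrame, snp_map: pd.DataFrame,
                    defined_mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`segment` for one case: per-SNP codes from segments.

    ``defined_mask`` marks the SNPs that carried a defined state; only those
    inside a segment's span receive the segment's code.
    """
    codes = np.full(len(snp_map), SIXSTATE_UNDEFINED, dtype=np.int8)
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos"].to_numpy()
    group_code = {name: i for i, name in enumerate(CN_GROUP_NAMES)}
    for row in segments.itertuples(index=False):
        mask = ((chrom_arr == row.chrom) & (pos_arr >= row.start)
                & (pos_arr <= row.end) & defined_mask)
        codes[mask] = sixstate_code(row.loh, group_code[row.cn_group])
    return codes


def loh_mask(codes: np.ndarray) -> np.ndarray:
    """Defined LOH-positive SNPs (codes 3, 4, 5)."""
    return np.asarray(codes) >= 3


def noloh_mask(codes: np.ndarray) -> np.ndarray:
    """Defined LOH-negative SNPs (codes 0, 1, 2)."""
    codes = np.asarray(codes)
    return (codes >= 0) & (codes <= 2)
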