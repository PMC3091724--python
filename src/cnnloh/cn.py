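"""Copy-number state calling from per-SNP log2 intensity ratios.

A centered 100-kb boxcar mean smooths the raw tumor-vs-germline log2 ratios
(the window is defined in base pairs and never crosses a chromosome), and
each smoothed value is classified to the nearest of five CN-state centers:

    state   0      1      2      3       4
    center -3.0   -1.0    0.0   +0.585  +1.0   (log2 of c/2)

State 2 is diploid; states 0-1 are loss, 3-4 gain. State 0's center is a
-3 floor rather than log2(0): arrays report a residual background signal for
homozygous deletions. Ties between two equidistant centers resolve toward
the diploid state (the less extreme call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CnCallerConfig:
    window_bp: int = 100_000
    state_centers: tuple[float, ...] = (-3.0, -1.0, 0.0, 0.585, 1.0)

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not all(a < b for a, b in zip(self.state_centers, self.state_centers[1:])):
            raise ValueError("state centers must be strictly increasing")


def smooth_ratios(ratios: np.ndarray, snp_map: pd.DataFrame,
                  config: CnCallerConfig | None = None) -> np.ndarray:
    """Mean of raw ratios over all SNPs within ±window/2 bp, per chromosome.

    ``ratios`` may be a vector (one sample) or an (n_snps, n_samples) matrix
    aligned to ``snp_map``. Windows are centered on each SNP's position.
    """
    config = config or CnCallerConfig()
    ratios = np.asarray(ratios, dtype=float)
    vector = ratios.ndim == 1
    mat = ratios[:, None] if vector else ratios
    if mat.shape[0] != len(snp_map):
        raise ValueError("ratios not aligned to SNP map")
    out = np.empty_like(mat)
    half = config.window_bp / 2
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_all = snp_map["pos"].to_numpy()
    for chrom in np.unique(chrom_arr):
        idx = np.nonzero(chrom_arr == chrom)[0]
        pos = pos_all[idx]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        csum = np.vstack([np.zeros(mat.shape[1]), np.cumsum(mat[idx], axis=0)])
        out[idx] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out[:, 0] if vector else out


def assign_states(smoothed: np.ndarray, config: CnCallerConfig | None = None) -> np.ndarray:
    """Nearest-center CN state per smoothed value; ties break toward state 2.

    A tie between two non-diploid states (e.g. the exact midpoint of the
    state-3 and state-4 centers) resolves to the state nearer 2.
    """
    config = config or CnCallerConfig()
    smoothed = np.asarray(smoothed, dtype=float)
    if not np.isfinite(smoothed).all():
        bad = np.argwhere(~np.isfinite(smoothed))[0]
        raise ValueError(f"non-finite smoothed ratio at index {tuple(bad)}")
    centers = np.asarray(config.state_centers)
    n_states = len(centers)
    dist = np.abs(smoothed[..., None] - centers)  # (..., n_states)
    min_d = dist.min(axis=-1, keepdims=True)
    # Among (near-)minimal distances prefer the less extreme state, then the
    # lower one: rank = |state-2| major, state minor.
    states = np.arange(n_states)
    tie_rank = np.abs(states - 2) * (2 * n_states) + states
    rank = np.where(dist <= min_d + 1e-12, tie_rank, 10 * n_states)
    return rank.argmin(axis=-1).astype(np.int8)


def call_cn(ratios: np.ndarray, snp_map: pd.DataFrame,
            config: CnCallerConfig | None = None) -> np.ndarray:
    """Smooth then classify: per-SNP CN states aligned to ``snp_map``."""
    config = config or CnCallerConfig()
    return assign_states(smooth_ratios(ratios, snp_map, config), config)


def cn_concordance(cn_a: np.ndarray, cn_b: np.ndarray) -> dict[str, float]:
    """Agreement between two CN tracks over the same SNPs.

    Returns the percent of positions with identical state and the percent of
    diploid (state 2) calls in each track — the comparison used to decide
    whether blood and adjacent-normal DNA are interchangeable controls.
    """
    cn_a = np.asarray(cn_a)
    cn_b = np.asarray(cn_b)
    if cn_a.shape != cn_b.shape:
        raise ValueError("CN tracks are not aligned")
    return {
        "pct_identical": 100.0 * float((cn_a == cn_b).mean()),
        "pct_neutral_a": 100.0 * float((cn_a == 2).mean()),
        "pct_neutral_b": 100.0 * float((cn_b == 2).mean()),
    }
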