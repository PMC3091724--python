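"""Per-chromosome LOH visualization.

One row per case; a marker at each LOH-positive SNP, colored by CN group:
black = copy-number-neutral LOH, blue = LOH with CN loss, red = LOH with CN
gain. Positions are drawn in Mb.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .sixstate import sixstate_code  # noqa: E402

logger = logging.getLogger(__name__)

LOH_COLORS = {  # six-state code -> color, LOH-positive states only
    sixstate_code(True, 1): "black",  # CNNLOH
    sixstate_code(True, 0): "blue",   # LOH + loss
    sixstate_code(True, 2): "red",    # LOH + gain
}


def plot_chromosome(codes: np.ndarray, snp_map: pd.DataFrame, cases: list[str],
                    chromosome: int, out_path=None):
    """Scatter the cohort's LOH landscape on one chromosome.

    ``codes`` is the (n_snps, n_cases) six-state matrix. Returns the figure;
    saves it when ``out_path`` is given.
    """
    on_chrom = (snp_map["chrom"] == chromosome).to_numpy()
    if not on_chrom.any():
        logger.warning("chromosome %s has no SNPs; emitting empty plot", chromosome)
    pos_mb = snp_map["pos"].to_numpy()[on_chrom] / 1e6
    fig, ax = plt.subplots(figsize=(10, 0.28 * max(len(cases), 4) + 1.2))
    for j, case_id in enumerate(cases):
        row = codes[on_chrom, j] if on_chrom.any() else np.empty(0, dtype=np.int8)
        for code, color in LOH_COLORS.items():
            hit = row == code
            if hit.any():
                ax.plot(pos_mb[hit], np.full(hit.sum(), j), ".",
                        color=color, markersize=3, rasterized=True)
    ax.set_yticks(range(len(cases)))
    ax.set_yticklabels(cases, fontsize=6)
    ax.set_ylim(len(cases) - 0.5, -0.5)
    ax.set_xlabel(f"chromosome {chromosome} position (Mb)")
    ax.set_title("LOH by copy-number group: black CNNLOH, blue CN loss, red CN gain",
                 fontsize=9)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def marker_color_table(codes: np.ndarray, snp_map: pd.DataFrame,
                       cases: list[str], chromosome: int) -> pd.DataFrame:
    """The (case, position, color) triples the plot renders — testable form."""
    on_chrom = (snp_map["chrom"] == chromosome).to_numpy()
    pos = snp_map["pos"].to_numpy()[on_chrom]
    rows = []
    for j, case_id in enumerate(cases):
        row = codes[on_chrom, j]
        for code, color in LOH_COLORS.items():
            for p in pos[row == code]:
                rows.append((case_id, int(p), color))
    return pd.DataFrame(rows, columns=["case_id", "pos", "color"])
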