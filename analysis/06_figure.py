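"""Chromosome-level LOH landscape figure for the simulated cohort.

One row per case; LOH-positive SNPs colored black (CNNLOH), blue (CN loss),
red (CN gain). Written to results/figures/.
"""

from pathlib import Path

from cnnloh import io, plot

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "figures"
OUT.mkdir(parents=True, exist_ok=True)

snp_map = io.read_snp_map(ROOT / "cohort" / "snp_map.tsv")
codes_df = io.read_numeric_matrix(ROOT / "sixstate.tsv", snp_map).astype(int)

for chrom in (3, 8):
    out = OUT / f"chromosome_{chrom}.png"
    plot.plot_chromosome(codes_df.to_numpy(), snp_map, list(codes_df.columns),
                         chrom, out)
    print(f"wrote {out}")
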