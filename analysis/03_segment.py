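"""Combine LOH and CN tracks into six-state calls and build segments.

Per-SNP six-state codes and per-case contiguous segments (endpoints at
informative SNPs) are written to results/segments*.
"""

from pathlib import Path

import pandas as pd

from cnnloh import io, sixstate

ROOT = Path(__file__).resolve().parents[1] / "results"

snp_map = io.read_snp_map(ROOT / "cohort" / "snp_map.tsv")
loh_m = io.read_numeric_matrix(ROOT / "tracks" / "loh_tumor.tsv", snp_map).astype(int)
cn_m = io.read_numeric_matrix(ROOT / "tracks" / "cn_tumor.tsv", snp_map).astype(int)

codes = sixstate.combine(loh_m.to_numpy(), cn_m.to_numpy())
segments = sixstate.segment_cohort(codes, snp_map, list(loh_m.columns))

io.write_matrix(pd.DataFrame(codes, index=snp_map["snp_id"], columns=loh_m.columns),
                ROOT / "sixstate.tsv")
io.write_segments_tsv(segments, ROOT / "segments.tsv")
io.write_segments_bed(segments, ROOT / "segments.bed")

by_state = segments.groupby(["loh", "cn_group"])["n_snps"].sum()
print(f"{len(segments)} segments over {int(segments['n_snps'].sum())} defined SNPs")
print("informative SNPs by state:")
print(by_state.to_string())
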