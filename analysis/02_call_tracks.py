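"""Call per-SNP LOH and CN tracks from the simulated cohort directory.

LOH: paired zygosity of tumor against matched blood at informative SNPs.
CN: 100-kb boxcar smoothing of log2 ratios, nearest-center state assignment,
for tumor, adjacent normal, and blood. Outputs land in results/tracks/.
"""

from pathlib import Path

import pandas as pd

from cnnloh import cn, io, loh

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT, OUT = ROOT / "cohort", ROOT / "tracks"
OUT.mkdir(parents=True, exist_ok=True)

snp_map = io.read_snp_map(COHORT / "snp_map.tsv")
blood = io.encode_genotypes(io.read_genotype_matrix(COHORT / "genotypes_blood.tsv", snp_map))
tumor = io.encode_genotypes(io.read_genotype_matrix(COHORT / "genotypes_tumor.tsv", snp_map))
cases = list(pd.read_csv(COHORT / "genotypes_blood.tsv", sep="\t", index_col=0, nrows=0))

status = loh.call_loh_matrix(blood, tumor)
io.write_matrix(pd.DataFrame(status, index=snp_map["snp_id"], columns=cases),
                OUT / "loh_tumor.tsv")
frac_loh = (status == io.LOH).sum() / max((status >= 0).sum(), 1)
print(f"LOH: {(status >= 0).sum()} determinate informative calls; "
      f"{frac_loh:.1%} show LOH")

for tissue in ("tumor", "normal", "blood"):
    ratios = io.read_numeric_matrix(COHORT / f"logratio_{tissue}.tsv", snp_map)
    states = cn.call_cn(ratios.to_numpy(), snp_map)
    io.write_matrix(pd.DataFrame(states, index=snp_map["snp_id"], columns=cases),
                    OUT / f"cn_{tissue}.tsv")
    print(f"CN ({tissue}): {(states == 2).mean():.2%} of SNP calls diploid")
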