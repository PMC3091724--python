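"""Simulate the default trio cohort and write its input-data layout.

30 cases on a 1/25-scale 22-autosome genome (~20k SNPs at 5.8 kb spacing,
27% heterozygosity, 96% call rate), with planted LOH/CN events in all five
somatic states and 17 paired expression profiles carrying LOH-dependent
shifts. Outputs land in results/cohort/.
"""

from pathlib import Path

from cnnloh import sim

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

cohort = sim.simulate_cohort(sim.SimConfig(seed=0))
sim.write_cohort(cohort, OUT)

n_events = len(cohort.events)
print(f"simulated {len(cohort.snp_map)} SNPs x {cohort.config.n_cases} cases; "
      f"{n_events} planted events "
      f"({int(cohort.events['loh'].sum())} with LOH); wrote {OUT}")
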