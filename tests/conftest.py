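import numpy as np
import pandas as pd
import pytest

from cnnloh import pipeline, sim


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run on the default simulated cohort (30 cases), seed 0."""
    return pipeline.run_pipeline(run_config=pipeline.RunConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A two-chromosome cohort for fast per-stage tests."""
    config = sim.SimConfig(n_cases=6, n_expression_pairs=4, seed=11)
    lengths = {1: 4_000_000, 2: 3_000_000}
    return sim.simulate_cohort(config, chromosome_lengths=lengths)


@pytest.fixture
def toy_map():
    """Ten evenly spaced SNPs on one chromosome, p/q split at 550."""
    pos = np.arange(100, 1100, 100)
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(10)],
        "chrom": 1,
        "arm": ["p"] * 5 + ["q"] * 5,
        "pos": pos,
    })
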