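import numpy as np
import pandas as pd
import pytest

from cnnloh import io, sim
from cnnloh.io import AA, AB, BB, NC


def small_config(**kw):
    defaults = dict(n_cases=4, seed=5)
    defaults.update(kw)
    defaults.setdefault("n_expression_pairs", min(3, defaults["n_cases"]))
    return sim.SimConfig(**defaults)


class TestSnpMap:
    def test_snp_count_tracks_spacing(self):
        m = sim.simulate_snp_map(small_config(), {1: 58_000})
        assert 8 <= len(m) <= 12

    def test_deterministic_under_seed(self):
        m1 = sim.simulate_snp_map(small_config(), {1: 500_000, 2: 300_000})
        m2 = sim.simulate_snp_map(small_config(), {1: 500_000, 2: 300_000})
        pd.testing.assert_frame_equal(m1, m2)

    def test_spacing_larger_than_chromosome_still_one_snp(self):
        m = sim.simulate_snp_map(small_config(), {1: 1000})
        assert len(m) == 1

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_snp_map(small_config(), {1: 0})

    def test_map_satisfies_io_invariants(self):
        m = sim.simulate_snp_map(small_config(), {1: 2_000_000, 21: 900_000})
        io.validate_snp_map(m)  # must not raise


class TestGermline:
    def test_het_fraction_matches_config(self):
        config = sim.SimConfig(n_cases=1, n_expression_pairs=1, seed=3)
        m = sim.simulate_snp_map(config, {1: 58_000_000})  # ~10,000 SNPs
        blood = sim.simulate_germline(m, config)
        called = blood[blood != NC]
        het = (called == AB).mean()
        assert abs(het - 0.27) < 0.02
        assert abs((blood == NC).mean() - 0.04) < 0.01

    def test_call_rate_one_gives_no_nocalls(self, toy_map):
        blood = sim.simulate_germline(toy_map, small_config(call_rate=1.0))
        assert (blood != NC).all()

    def test_low_heterozygosity_gives_no_het(self, toy_map):
        blood = sim.simulate_germline(toy_map, small_config(heterozygosity=1e-12))
        assert (blood != AB).all()


class TestPlantedEvents:
    def events(self):
        return pd.DataFrame(
            [("case01", 1, 150, 450, True, "neutral")],
            columns=["case_id", "chrom", "start", "end", "loh", "cn_group"])

    def test_event_labels_snps_inside_only(self, toy_map):
        loh_truth, cn_truth = sim.plant_events(toy_map, self.events(), small_config())
        assert loh_truth[1:4, 0].all() and not loh_truth[4:, 0].any()
        assert (cn_truth == 2).all()  # CNNLOH: copy number stays diploid

    def test_zero_events_all_background(self, toy_map):
        empty = self.events().iloc[:0]
        loh_truth, cn_truth = sim.plant_events(toy_map, empty, small_config())
        assert not loh_truth.any() and (cn_truth == 2).all()

    def test_overlapping_events_rejected(self, toy_map):
        ev = pd.concat([self.events(), self.events().assign(start=300, end=700)])
        with pytest.raises(ValueError, match="overlap"):
            sim.plant_events(toy_map, ev, small_config())

    def test_truth_track_is_partition(self):
        cohort = sim.simulate_cohort(small_config(), with_expression=False,
                                     chromosome_lengths={1: 3_000_000, 2: 2_000_000})
        # every (snp, case) has exactly one state: arrays are total functions
        assert cohort.loh_truth.shape == cohort.cn_truth.shape
        assert set(np.unique(cohort.cn_truth)) <= {0, 1, 2, 3, 4}

    def test_default_spec_plants_all_five_somatic_states(self):
        config = sim.SimConfig(seed=2)
        m = sim.simulate_snp_map(config)
        ev = sim.default_event_spec(m, config)
        states = set(zip(ev["loh"], ev["cn_group"]))
        assert states == set(sim.PLANTABLE_STATES)


class TestTumorGenotypes:
    def setup_case(self, toy_map):
        config = small_config(call_rate=1.0, n_cases=1)
        events = pd.DataFrame([("case01", 1, 150, 450, True, "neutral")],
                              columns=["case_id", "chrom", "start", "end", "loh", "cn_group"])
        blood = np.array([[AA], [AB], [AB], [AB], [BB], [AB], [AA], [AB], [BB], [AB]],
                         dtype=np.int8)
        tumor, normal = sim.simulate_tumor_genotypes(blood, events, toy_map, config)
        return blood, tumor, normal

    def test_het_inside_loh_collapses_to_one_homozygote(self, toy_map):
        blood, tumor, _ = self.setup_case(toy_map)
        inside_het = tumor[[1, 2, 3], 0]
        assert set(inside_het) in ({AA}, {BB})  # one retained allele per event

    def test_homozygotes_and_outside_unchanged(self, toy_map):
        blood, tumor, normal = self.setup_case(toy_map)
        assert tumor[0, 0] == AA and tumor[4, 0] == BB  # hom inside event
        assert (tumor[[5, 7, 9], 0] == AB).all()  # het outside event
        assert (normal == blood).all()  # call_rate 1: no overlay


class TestIntensities:
    @pytest.mark.parametrize("c,expected", [(2, 0.0), (1, -1.0), (3, np.log2(1.5))])
    def test_noiseless_means(self, c, expected):
        config = small_config(intensity_noise_sd=1e-9, n_cases=1)
        cn_truth = np.full((50, 1), c, dtype=np.int8)
        tumor, normal, blood = sim.simulate_intensities(cn_truth, config)
        assert np.allclose(tumor, expected, atol=1e-6)
        assert np.allclose(normal, 0, atol=1e-6) and np.allclose(blood, 0, atol=1e-6)

    def test_homozygous_deletion_floor(self):
        config = small_config(intensity_noise_sd=1e-9, n_cases=1, loss_cn=0)
        tumor, _, _ = sim.simulate_intensities(np.zeros((5, 1), dtype=np.int8), config)
        assert np.allclose(tumor, -3.0, atol=1e-6)


class TestDeterminismAndOutput:
    def test_same_seed_byte_identical(self, tmp_path):
        lengths = {1: 1_500_000}
        c1 = sim.simulate_cohort(small_config(), chromosome_lengths=lengths)
        c2 = sim.simulate_cohort(small_config(), chromosome_lengths=lengths)
        assert (c1.blood == c2.blood).all() and (c1.tumor == c2.tumor).all()
        assert np.array_equal(c1.ratio_tumor, c2.ratio_tumor)
        pd.testing.assert_frame_equal(c1.expr_tumor, c2.expr_tumor)
        for c, d in ((c1, tmp_path / "a"), (c2, tmp_path / "b")):
            sim.write_cohort(c, d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_written_cohort_loads_back(self, tmp_path, small_cohort):
        sim.write_cohort(small_cohort, tmp_path)
        m = io.read_snp_map(tmp_path / "snp_map.tsv")
        g = io.read_genotype_matrix(tmp_path / "genotypes_blood.tsv", m)
        assert (io.encode_genotypes(g) == small_cohort.blood).all()


class TestExpressionSimulation:
    def test_affected_genes_shift_only_in_loh_cases(self, small_cohort):
        truth = small_cohort.truth_genes
        fc = (small_cohort.expr_tumor - small_cohort.expr_normal).to_numpy()
        hit = truth["affected"] & (truth["n_loh_cases"] > 0)
        if hit.any():
            i = int(np.nonzero(hit.to_numpy())[0][0])
            assert np.abs(fc[i]).max() > 1.0  # planted 2-fold-plus shift visible

    def test_effect_zero_means_no_shift(self):
        config = small_config()
        cohort = sim.simulate_cohort(
            config, effect=sim.ExpressionEffect(effect_log2=0.0, noise_sd=0.3),
            chromosome_lengths={1: 2_000_000})
        fc = (cohort.expr_tumor - cohort.expr_normal).to_numpy()
        assert np.abs(fc).max() < 0.3 * 6  # pure noise, no planted effect
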