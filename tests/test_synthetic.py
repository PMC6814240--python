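"""Generators: planted statistical structure and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segnoise import synthetic as syn


class TestFlowEvents:
    def test_zero_fano_gives_constant_log_signal(self):
        spec = syn.FlowPopulationSpec(n_events=500, mu_log=2.0, fano_pct=0.0,
                                      seed=1)
        ev = syn.simulate_flow_events(spec)
        assert np.allclose(np.log10(ev["GFP"]), 2.0)

    def test_recovers_target_fano_within_monte_carlo_error(self):
        n = 50_000
        spec = syn.FlowPopulationSpec(n_events=n, mu_log=2.0, fano_pct=5.0,
                                      seed=2)
        x = np.log10(syn.simulate_flow_events(spec)["GFP"].to_numpy())
        fano = 100.0 * x.var(ddof=1) / x.mean()
        se = 5.0 * np.sqrt(2.0 / (n - 1))
        assert abs(fano - 5.0) < 3 * se

    def test_same_seed_same_table(self):
        spec = syn.FlowPopulationSpec(n_events=2000, debris_frac=0.1,
                                      doublet_frac=0.1, seed=3)
        pd.testing.assert_frame_equal(syn.simulate_flow_events(spec),
                                      syn.simulate_flow_events(spec))

    def test_contaminant_fractions_validated(self):
        with pytest.raises(ValueError, match="debris_frac"):
            syn.FlowPopulationSpec(n_events=10, debris_frac=0.7,
                                   doublet_frac=0.6)
        with pytest.raises(ValueError, match="finite"):
            syn.FlowPopulationSpec(n_events=10, mu_log=np.nan)
        with pytest.raises(ValueError, match="fano_pct"):
            syn.FlowPopulationSpec(n_events=10, fano_pct=-1.0)


class TestCross:
    def test_null_cross_phenotype_is_base_noise(self):
        spec = syn.CrossSpec(n_segregants=50, n_markers=5, residual_sd=0.0,
                             base_noise=10.0, seed=4)
        seg = syn.simulate_cross(spec)
        assert np.allclose(seg.noise_phenotype, 10.0)

    def test_neutral_allele_frequency_near_half(self):
        n = 10_000
        spec = syn.CrossSpec(n_segregants=n, n_markers=20, seed=5)
        seg = syn.simulate_cross(spec)
        freq = seg.genotypes.mean(axis=0)
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(freq - 0.5) < 3 * se + 1e-12)

    def test_single_causal_locus_without_noise_gives_two_phenotypes(self):
        spec = syn.CrossSpec(n_segregants=200, n_markers=3,
                             causal_markers=(1,), causal_effects=(20.0,),
                             residual_sd=0.0, base_noise=10.0, seed=6)
        seg = syn.simulate_cross(spec)
        values = np.unique(seg.noise_phenotype)
        assert values.tolist() == [10.0, 30.0]

    def test_linked_markers_recombine_at_the_stated_fraction(self):
        n = 20_000
        r = np.array([0.1, 0.4])
        spec = syn.CrossSpec(n_segregants=n, n_markers=3, linkage_model=r,
                             seed=7)
        seg = syn.simulate_cross(spec)
        for i, ri in enumerate(r):
            observed = (seg.genotypes[:, i] != seg.genotypes[:, i + 1]).mean()
            se = np.sqrt(ri * (1 - ri) / n)
            assert abs(observed - ri) < 4 * se

    def test_bad_recombination_fraction_rejected(self):
        with pytest.raises(ValueError, match="recombination"):
            syn.CrossSpec(n_segregants=10, n_markers=3,
                          linkage_model=[0.1, 0.7])

    def test_seed_determinism(self):
        spec = syn.CrossSpec(n_segregants=100, n_markers=10, seed=8)
        a, b = syn.simulate_cross(spec), syn.simulate_cross(spec)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.noise_phenotype, b.noise_phenotype)


class TestPooledReads:
    @staticmethod
    def _pair_cross(n_markers, seed):
        """Four segregants alternating 1/0 at every marker (pool freq 0.5)."""
        markers = syn.spike_background_mutations(n_markers, seed=seed)
        spec = syn.CrossSpec(n_segregants=4, n_markers=n_markers,
                             marker_positions=markers, seed=seed)
        seg = syn.simulate_cross(spec)
        seg.genotypes = np.tile(np.array([[1], [0], [1], [0]], dtype=np.int8),
                                (1, n_markers))
        return seg

    def test_fixed_allele_reads_at_frequency_one(self):
        seg = self._pair_cross(50, seed=9)
        pools = syn.PoolAssignment((0, 2), (1, 3))
        table = syn.simulate_pooled_reads(seg, pools, 80, seed=10)
        # evolved-like members all carry the alt allele at every marker
        assert (table["evo_alt"] == table["evo_cov"]).all()
        assert (table["anc_alt"] == 0).all()

    def test_observed_frequency_sd_matches_binomial_mixture(self):
        # pool frequency 0.5: closed-form SD sqrt(0.25/cov) corrected for
        # Poisson coverage dispersion by direct mixture enumeration
        n_markers = 100_000
        seg = self._pair_cross(n_markers, seed=11)
        pools = syn.PoolAssignment((0, 1), (2, 3))
        table = syn.simulate_pooled_reads(seg, pools, 150, seed=12)
        freqs = table["evo_alt"] / table["evo_cov"]
        covs = np.arange(60, 300)
        pmf = stats.poisson.pmf(covs, 150)
        pmf /= pmf.sum()
        oracle_sd = np.sqrt(np.sum(pmf * 0.25 / covs))
        naive_sd = np.sqrt(0.25 / 150)
        assert abs(oracle_sd - naive_sd) < 0.002  # dispersion correction small
        mc_se = oracle_sd / np.sqrt(2 * n_markers)
        assert abs(freqs.std(ddof=1) - oracle_sd) < 4 * mc_se

    def test_seed_determinism(self):
        seg = self._pair_cross(30, seed=13)
        pools = syn.PoolAssignment((0, 1), (2, 3))
        a = syn.simulate_pooled_reads(seg, pools, 150, seed=14)
        b = syn.simulate_pooled_reads(seg, pools, 150, seed=14)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_pool_rejected(self):
        seg = self._pair_cross(5, seed=15)
        with pytest.raises(ValueError, match="non-empty"):
            syn.simulate_pooled_reads(
                seg, syn.PoolAssignment((), (1,)), 150, seed=16)

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            syn.PoolAssignment((1, 2), (2, 3))


class TestBackgroundMutations:
    def test_empty_request_gives_empty_table(self):
        table = syn.spike_background_mutations(0, seed=17)
        assert len(table) == 0

    def test_default_fractions_reproduce_class_counts(self):
        table = syn.spike_background_mutations(1022, seed=18)
        counts = table["effect"].value_counts()
        assert counts["nonsynonymous"] == 494
        assert counts["synonymous"] == 256
        assert counts["intergenic"] == 271

    def test_positions_unique_on_default_layout(self):
        table = syn.spike_background_mutations(10_000, seed=19)
        assert not table.duplicated(subset=["chrom", "pos"]).any()
        assert (table["pos"] >= 1).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            syn.spike_background_mutations(
                10, class_fractions={"nonsynonymous": 0.5}, seed=20)

    def test_overfull_genome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            syn.spike_background_mutations(
                100, genome_layout={"chr1": 10}, seed=21)

    def test_ems_signature_substitutions(self):
        table = syn.spike_background_mutations(200, seed=22)
        assert set(zip(table["ref"], table["alt"])) <= {("G", "A"), ("C", "T")}
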