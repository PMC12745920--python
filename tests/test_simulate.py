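"""Synthetic-data generators: coalescent oracle limits, observed-spectrum
sampling, RADseq dataset round trips and determinism contracts."""

import numpy as np
import pytest
from scipy.stats import chisquare

from refugia.engine import expected_sfs
from refugia.filters import FilterConfig, apply_filters
from refugia.genotypes import write_vcf
from refugia.sfs import build_jsfs
from refugia.simulate import (SimConfig, sample_observed_jsfs,
                              simulate_coalescent_jsfs,
                              simulate_genotype_dataset)
from refugia.spectrum import Spectrum2D


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        {"model_name": "not_a_model"},
        {"n1": 3},
        {"n_sites": 0},
        {"theta_per_dataset": 0.0},
        {"missing_rate": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestCoalescentOracle:
    def test_t_zero_single_pool_entry(self):
        # at T=0 both samples come from one equilibrium population:
        # S(1,0) = C(2,1)C(2,0)/(C(4,1)*1) = 0.5 per unit theta
        cfg = SimConfig(model_name="vic_no_mig",
                        params={"s": 0.5, "T": 0.0}, n1=2, n2=2, seed=3)
        spec = simulate_coalescent_jsfs(cfg, 20_000)
        assert abs(spec.data[1, 0] - 0.5) <= 3 * spec.mc_se[1, 0]
        assert abs(spec.data[1, 1] - 1 / 3) <= 3 * spec.mc_se[1, 1]

    def test_symmetric_split_gives_symmetric_spectrum(self):
        cfg = SimConfig(model_name="vic_no_mig",
                        params={"s": 0.5, "T": 0.3}, n1=8, n2=8, seed=5)
        spec = simulate_coalescent_jsfs(cfg, 10_000)
        se = np.sqrt(spec.mc_se ** 2 + spec.mc_se.T ** 2)
        dev = np.abs(spec.data - spec.data.T)
        assert np.mean(dev[~spec.mask] <= 3 * se[~spec.mask]) >= 0.95

    def test_replicate_count_validated(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_coalescent_jsfs(cfg, 0)


class TestObservedSampling:
    def test_zero_theta(self):
        exp = Spectrum2D(np.ones((4, 4)))
        assert sample_observed_jsfs(exp, 0.0, seed=0).sum() == 0

    def test_determinism(self):
        exp = Spectrum2D(np.random.default_rng(0).random((5, 5)))
        a = sample_observed_jsfs(exp, 80.0, seed=7)
        b = sample_observed_jsfs(exp, 80.0, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_mean_tracks_intensity(self):
        exp = Spectrum2D(np.full((3, 3), 1.5))
        vals = np.array([sample_observed_jsfs(exp, 4.0, seed=s).data[1, 1]
                         for s in range(8000)])
        lam = 6.0
        assert abs(vals.mean() - lam) <= 3 * np.sqrt(lam / len(vals))


class TestGenotypeDataset:
    def test_permissive_filters_keep_every_site(self):
        cfg = SimConfig(model_name="vic_no_mig",
                        params={"s": 0.5, "T": 0.3}, n1=8, n2=8,
                        n_sites=2000, theta_per_dataset=60.0,
                        coverage_mean=30, coverage_sd=3,
                        missing_rate=0.0, seed=11)
        gm = simulate_genotype_dataset(cfg)
        filtered, tally = apply_filters(gm, FilterConfig(max_obs_het=1.0))
        assert tally["kept"] == gm.n_sites

    def test_same_seed_identical_vcf_bytes(self, tmp_path):
        cfg = SimConfig(n_sites=500, theta_per_dataset=40.0, n1=8, n2=8,
                        seed=21)
        for name in ("a", "b"):
            write_vcf(simulate_genotype_dataset(cfg), tmp_path / name)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_jsfs_roundtrip_chi2(self):
        """The joint SFS rebuilt from the genotype matrix is consistent
        with the generating expected spectrum (chi-squared homogeneity
        not rejected at alpha=0.01)."""
        params = {"s": 0.5, "T": 0.5}
        cfg = SimConfig(model_name="vic_no_mig", params=params,
                        n1=10, n2=10, n_sites=20_000,
                        theta_per_dataset=800.0, seed=13)
        gm = simulate_genotype_dataset(cfg)
        rebuilt = build_jsfs(gm, "pop1", "pop2", 10, 10)
        exp = expected_sfs("vic_no_mig", params, 10, 10)
        m = ~exp.mask
        expected = exp.data[m] / exp.data[m].sum() * rebuilt.data[m].sum()
        observed = rebuilt.data[m]
        # pool cells with small expectation for test validity
        order = np.argsort(expected)
        obs_p, exp_p, acc_o, acc_e = [], [], 0.0, 0.0
        for idx in order:
            acc_o += observed[idx]
            acc_e += expected[idx]
            if acc_e >= 5:
                obs_p.append(acc_o)
                exp_p.append(acc_e)
                acc_o = acc_e = 0.0
        obs_p[-1] += acc_o
        exp_p[-1] += acc_e
        stat, p = chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_multi_snp_loci_exercise_single_snp_filter(self):
        cfg = SimConfig(n_sites=600, theta_per_dataset=50.0, n1=8, n2=8,
                        snps_per_locus=3, seed=31)
        gm = simulate_genotype_dataset(cfg)
        filtered, tally = apply_filters(
            gm, FilterConfig(min_dp=0, max_dp=10 ** 6, min_gq=0,
                             max_obs_het=1.0, min_presence=0.0))
        assert tally["dropped_extra_snps"] > 0
        assert len(set(filtered.locus_id.tolist())) == filtered.n_sites

    def test_too_small_n_sites_rejected(self):
        cfg = SimConfig(n_sites=5, theta_per_dataset=500.0, n1=8, n2=8,
                        seed=1)
        with pytest.raises(ValueError):
            simulate_genotype_dataset(cfg)
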