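"""Genotype/phenotype generator statistics, median dichotomisation and the
power / type-I experiment machinery."""

import numpy as np
import pytest

from hiscom_pca import (
    PipelineConfig,
    SimulationConfig,
    dichotomize_median,
    effect_size_for_r2,
    run_power_experiment,
    run_type1_experiment,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotype,
)


def small_config(**kw):
    base = dict(n_samples=120, n_pathways=6, genes_per_pathway=(2, 4),
                snps_per_gene=(2, 4), causal_pathway_size=4,
                n_causal_genes=3, effect_size=0.8, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_allele_frequency_matches_target_maf(self):
        """At rho=0 each SNP's empirical allele frequency is binomial around
        its target MAF (within 3 standard errors at n=10000)."""
        cfg = SimulationConfig(n_samples=10_000, n_pathways=2,
                               causal_pathway_size=2, n_causal_genes=1,
                               snps_per_gene=(3, 3), ld_rho=0.0, seed=5)
        ds = simulate_dataset(cfg)
        rng_check = np.random.default_rng(5)
        _, _, n_snps, mafs = __import__(
            "hiscom_pca.simulate", fromlist=["_gene_layout"]
        )._gene_layout(cfg, rng_check)
        freqs = ds.genotypes.dosages.mean(axis=0) / 2.0
        j = 0
        for gene in ds.annotation.records["gene"]:
            for maf in mafs[gene]:
                se = np.sqrt(maf * (1 - maf) / (2 * cfg.n_samples))
                assert abs(freqs[j] - maf) < 3.5 * se
                j += 1

    def test_ld_parameter_raises_within_gene_correlation(self):
        cfg_hi = SimulationConfig(n_samples=4000, n_pathways=2,
                                  causal_pathway_size=2, n_causal_genes=1,
                                  snps_per_gene=(2, 2), ld_rho=0.9, seed=6)
        cfg_lo = SimulationConfig(n_samples=4000, n_pathways=2,
                                  causal_pathway_size=2, n_causal_genes=1,
                                  snps_per_gene=(2, 2), ld_rho=0.0, seed=6)
        def mean_abs_corr(cfg):
            ds = simulate_dataset(cfg)
            cors = []
            # per-gene column blocks are contiguous and 2 wide here
            d = ds.genotypes.dosages
            for g0 in range(0, d.shape[1], 2):
                c = np.corrcoef(d[:, g0], d[:, g0 + 1])[0, 1]
                cors.append(abs(c))
            return float(np.mean(cors))
        assert mean_abs_corr(cfg_hi) > mean_abs_corr(cfg_lo)

    def test_same_seed_identical_matrix(self):
        cfg = small_config()
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_structure_matches_config(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        assert len(ds.pathways) == 6
        pw = list(ds.pathways)
        assert len(pw[0].genes) == len(pw[1].genes)  # size-matched null
        assert not set(pw[0].genes) & set(pw[1].genes)
        assert set(ds.causal_genes) <= set(pw[0].genes)
        assert len(ds.causal_genes) == 3

    def test_missing_rate_injects_nans(self):
        cfg = small_config(missing_rate=0.05)
        ds = simulate_dataset(cfg)
        frac = np.isnan(ds.genotypes.dosages).mean()
        assert 0.02 < frac < 0.08


class TestPhenotype:
    def test_zero_effects_give_pure_noise(self):
        cfg = small_config(effect_size=0.0, n_samples=4000,
                           noise_variance=2.0)
        ds = simulate_dataset(cfg)
        pheno, info = simulate_phenotype(ds)
        assert info["signal_variance"] == 0.0
        assert np.var(pheno.y) == pytest.approx(2.0, rel=0.1)

    def test_noiseless_single_snp_is_rank_correlated(self):
        cfg = small_config(n_causal_genes=1, causal_snps_per_gene=1,
                           effect_size=1.0, noise_variance=1e-12)
        ds = simulate_dataset(cfg)
        pheno, _ = simulate_phenotype(ds)
        col = list(ds.genotypes.snp_meta["snp_id"]).index(ds.causal_snps[0])
        d = ds.genotypes.dosages[:, col]
        # dosages are heavily tied, so check the linear correlation and that
        # ordering never inverts across dosage groups
        assert np.corrcoef(pheno.y, d)[0, 1] > 0.999
        assert pheno.y[d == d.max()].min() > pheno.y[d == d.min()].max()

    def test_target_r2_bookkeeping(self):
        """Effects sized for R^2 = 0.3 realize within 0.05 at n = 5000."""
        m = 3
        e = effect_size_for_r2(0.3, m, noise_variance=1.0)
        cfg = small_config(n_samples=5000, n_causal_genes=3,
                           causal_snps_per_gene=1, effect_size=e,
                           noise_variance=1.0)
        ds = simulate_dataset(cfg)
        _, info = simulate_phenotype(ds)
        assert info["realized_r2"] == pytest.approx(0.3, abs=0.05)


class TestDichotomize:
    def test_worked_example(self):
        np.testing.assert_array_equal(dichotomize_median(np.array([1., 2, 3, 4])),
                                      [0, 0, 1, 1])

    def test_odd_n_counts(self):
        y = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        b = dichotomize_median(y)
        assert b.sum() == 2  # (n-1)/2, median tie assigned 0

    def test_prevalence_near_half(self):
        y = np.random.default_rng(1).standard_normal(101)
        b = dichotomize_median(y)
        assert abs(b.sum() - 50.5) <= 0.5

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize_median(np.ones(10))


class TestExperiments:
    def test_single_replicate_estimate_is_binary(self):
        res = run_power_experiment(small_config(), replicates=1,
                                   pipeline=PipelineConfig(B=19), seed=1)
        assert res.estimate in (0.0, 1.0)
        assert res.replicates == 1

    def test_alpha_one_rejects_everything(self):
        res = run_type1_experiment(small_config(), replicates=3, alpha=1.0,
                                   pipeline=PipelineConfig(B=19), seed=2)
        assert res.estimate == 1.0

    def test_bit_reproducible_under_seed(self):
        kw = dict(replicates=4, pipeline=PipelineConfig(B=19), seed=9)
        r1 = run_power_experiment(small_config(), **kw)
        r2 = run_power_experiment(small_config(), **kw)
        assert r1.p_values == r2.p_values
        assert r1.estimate == r2.estimate

    def test_power_monotone_in_effect_size(self):
        """Rejection fraction is non-decreasing in the causal effect size
        (up to a small Monte-Carlo allowance at 40 replicates)."""
        powers = []
        for e in (0.0, 0.1, 0.3, 0.6):
            res = run_power_experiment(
                small_config(effect_size=e, n_samples=150), replicates=40,
                pipeline=PipelineConfig(B=49), seed=33)
            powers.append(res.estimate)
        assert all(b >= a - 0.075 for a, b in zip(powers, powers[1:]))
        assert powers[-1] > powers[0]

    def test_continuous_at_least_as_powerful_as_binary(self):
        """Median dichotomisation discards information, so continuous-trait
        power dominates binary-trait power up to one-sided binomial noise."""
        cfg = small_config(effect_size=0.25, n_samples=150)
        cont = run_power_experiment(cfg, replicates=60,
                                    pipeline=PipelineConfig(B=49), seed=44)
        binr = run_power_experiment(cfg, replicates=60,
                                    pipeline=PipelineConfig(B=49, binary=True),
                                    seed=44)
        n = 60
        se = np.sqrt((cont.estimate * (1 - cont.estimate)
                      + binr.estimate * (1 - binr.estimate)) / n + 1e-12)
        assert cont.estimate >= binr.estimate - 1.645 * max(se, 0.05)

    def test_type1_with_active_causal_pathway_elsewhere(self):
        """Strong effects in the causal pathway must not inflate the
        size-matched (gene-disjoint) null pathway's rejection rate."""
        cfg = small_config(effect_size=0.6, n_samples=150)
        res = run_type1_experiment(cfg, replicates=60,
                                   pipeline=PipelineConfig(B=49), seed=55)
        # exact binomial 99% acceptance band around 0.05 at n=60: [0, 9]/60
        assert res.rejections <= 9

    def test_cumvar_criterion_pipeline_runs(self):
        res = run_power_experiment(
            small_config(), replicates=2,
            pipeline=PipelineConfig(B=19, pc_criterion="cumvar"), seed=3)
        assert 0.0 <= res.estimate <= 1.0


class TestConfigValidation:
    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="ld_rho"):
            SimulationConfig(ld_rho=1.0)

    def test_causal_genes_must_fit(self):
        with pytest.raises(ValueError, match="causal genes"):
            SimulationConfig(causal_pathway_size=5, n_causal_genes=9)

    def test_effect_for_r2_bounds(self):
        with pytest.raises(ValueError):
            effect_size_for_r2(1.5, 3)
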