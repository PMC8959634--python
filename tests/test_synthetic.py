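"""Tests of the synthetic-data generator: sampling distributions, the
reaction-norm variance structure, and the liability-threshold case status."""

import numpy as np
import pytest
from scipy import stats

from rnmkit.qc import compute_grm
from rnmkit.reml import VarianceComponents
from rnmkit.synthetic import (
    SimulationConfig,
    simulate_case_status,
    simulate_covariate,
    simulate_dataset,
    simulate_genotypes,
    simulate_phenotype,
)


def make_config(**kw):
    defaults = dict(n_individuals=100, n_snps=50, seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_individuals=1),
            dict(n_snps=0),
            dict(maf_range=(0.0, 0.1)),
            dict(maf_range=(0.1, 0.6)),
            dict(prevalence=0.0),
            dict(vc_true=VarianceComponents(sigma2_a0=-0.1, sigma2_t0=0.5)),
            # covariance exceeding sqrt(v0*v1): block not PSD
            dict(vc_true=VarianceComponents(sigma2_a0=0.1, sigma_a01=0.5,
                                            sigma2_a1=0.1, sigma2_t0=0.5)),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            make_config(**kw)


class TestGenotypes:
    def test_allele_frequency_matches_target(self):
        # at p=0.5 the per-SNP sample frequency should stay within 3 binomial
        # standard errors for the vast majority of SNPs
        cfg = make_config(n_individuals=1000, n_snps=200, maf_range=(0.5, 0.5))
        g = simulate_genotypes(cfg)
        freq = g.dosages.mean(axis=0) / 2.0
        se = np.sqrt(0.5 * 0.5 / (2 * 1000))
        frac_ok = np.mean(np.abs(freq - 0.5) <= 3 * se)
        assert frac_ok >= 0.95

    def test_dosage_domain_and_determinism(self):
        cfg = make_config(n_individuals=2, n_snps=1, maf_range=(0.01, 0.01))
        g = simulate_genotypes(cfg)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        g2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g.dosages, g2.dosages)


class TestCovariate:
    def test_normal_moments(self):
        cfg = make_config(n_individuals=10_000)
        c = simulate_covariate(cfg)
        assert abs(c.mean()) < 0.05
        assert 0.95 < c.std(ddof=1) < 1.05

    def test_ordinal_level_counts(self):
        n = 9000
        cfg = make_config(
            n_individuals=n, covariate_spec=("ordinal", {"n_levels": 3})
        )
        c = simulate_covariate(cfg)
        se = np.sqrt(n * (1 / 3) * (2 / 3))
        for level in (0.0, 1.0, 2.0):
            assert abs((c == level).sum() - n / 3) <= 3 * se

    def test_single_sample_and_unknown_distribution(self):
        cfg = make_config(n_individuals=2)
        cfg.n_individuals = 1
        assert simulate_covariate(cfg).shape == (1,)
        cfg.covariate_spec = ("cauchy", None)
        with pytest.raises(ValueError, match="unknown covariate"):
            simulate_covariate(cfg)


class TestPhenotype:
    def test_degenerate_noise_gives_pure_fixed_effect(self):
        # all variance components zero: y is exactly beta * standardized c
        cfg = make_config(
            n_individuals=50,
            vc_true=VarianceComponents(),
            fixed_effects_spec=[("covariate", 2.0)],
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        y, _ = simulate_phenotype(g, cov, cfg)
        c_std = (cov - cov.mean()) / cov.std(ddof=1)
        np.testing.assert_allclose(y, 2.0 * c_std, atol=1e-12)

    def test_gxe_variance_increases_with_covariate_magnitude(self):
        # with a genetic slope variance, Var(y | c) grows as c^2: the
        # regression of squared centered y on c^2 has positive slope
        cfg = make_config(
            n_individuals=10_000,
            n_snps=100,
            vc_true=VarianceComponents(sigma2_a0=0.2, sigma2_a1=0.6,
                                       sigma2_t0=0.2),
        )
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        y, _ = simulate_phenotype(g, cov, cfg)
        c_std = (cov - cov.mean()) / cov.std(ddof=1)
        y2 = (y - y.mean()) ** 2
        slope = np.polyfit(c_std**2, y2, 1)[0]
        assert slope > 0

    def test_variance_profile_matches_reaction_norm_formula(self):
        # binning c, the empirical phenotype variance should follow
        # s2_a0 + 2 s_a01 c + s2_a1 c^2 + s2_t0 + 2 s_t01 c + s2_t1 c^2
        vc = VarianceComponents(sigma2_a0=0.3, sigma_a01=0.1, sigma2_a1=0.25,
                                sigma2_t0=0.3, sigma_t01=-0.05, sigma2_t1=0.15)
        cfg = make_config(n_individuals=40_000, n_snps=50, vc_true=vc)
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        y, _ = simulate_phenotype(g, cov, cfg)
        c = (cov - cov.mean()) / cov.std(ddof=1)
        edges = np.quantile(c, np.linspace(0, 1, 9))
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (c >= lo) & (c <= hi)
            cm = c[sel].mean()
            expected = (
                vc.sigma2_a0 + 2 * vc.sigma_a01 * cm + vc.sigma2_a1 * cm**2
                + vc.sigma2_t0 + 2 * vc.sigma_t01 * cm + vc.sigma2_t1 * cm**2
            )
            observed = y[sel].var(ddof=1)
            assert observed == pytest.approx(expected, rel=0.25, abs=0.05)

    def test_truth_record_consistency(self):
        cfg = make_config(n_individuals=200, n_snps=80)
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        y, truth = simulate_phenotype(g, cov, cfg)
        c = (cov - cov.mean()) / cov.std(ddof=1)
        rebuilt = truth.g0 + truth.g1 * c + truth.fixed_part + truth.e0 + truth.e1 * c
        np.testing.assert_allclose(y, rebuilt, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        cfg = make_config()
        g = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="dimensions"):
            simulate_phenotype(g, np.zeros(cfg.n_individuals + 1), cfg)


class TestCaseStatus:
    def test_case_count_follows_prevalence(self):
        cfg = make_config(n_individuals=10_000, n_snps=20, prevalence=0.05)
        d = simulate_dataset(cfg)
        assert abs(d["status"].sum() - 500) <= 1

    def test_no_signal_no_case_control_difference(self):
        # liability carries no weight on the true risk: the genetic values of
        # cases and controls should agree within sampling noise
        cfg = make_config(n_individuals=5000, n_snps=100, liability_h2=0.0,
                          prevalence=0.2)
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        _, truth = simulate_phenotype(g, cov, cfg)
        status = simulate_case_status(truth, cov, 0.2, seed=5, liability_h2=0.0)
        cases, controls = truth.g0[status == 1], truth.g0[status == 0]
        se = np.sqrt(cases.var(ddof=1) / cases.size
                     + controls.var(ddof=1) / controls.size)
        assert abs(cases.mean() - controls.mean()) < 3 * se

    def test_strong_signal_separates_cases(self):
        # high liability heritability: predicted (true) risk must be clearly
        # higher in cases
        cfg = make_config(n_individuals=5000, n_snps=100, liability_h2=0.8,
                          prevalence=0.1)
        g = simulate_genotypes(cfg)
        cov = simulate_covariate(cfg)
        _, truth = simulate_phenotype(g, cov, cfg)
        status = simulate_case_status(truth, cov, 0.1, seed=6, liability_h2=0.8)
        c = (cov - cov.mean()) / cov.std(ddof=1)
        risk = truth.risk(c)
        t, p = stats.ttest_ind(risk[status == 1], risk[status == 0],
                               alternative="greater")
        assert p < 0.01


def test_null_simulation_heritability_recovery():
    """Additive-only data at h2=0.5: GREML recovers the phenotypic variance
    split and heritability to within sampling error."""
    from rnmkit.pheno import standardize
    from rnmkit.reml import MODEL_SPECS, reml_fit
    from rnmkit.heritability import heritability

    h2s, vars_ = [], []
    for rep in range(5):
        cfg = make_config(
            n_individuals=500, n_snps=500, seed=40 + rep,
            vc_true=VarianceComponents(sigma2_a0=0.5, sigma2_t0=0.5),
        )
        d = simulate_dataset(cfg)
        vars_.append(d["phenotype"].var(ddof=1))
        K = compute_grm(d["genotypes"]).values
        c = standardize(d["covariate"]).values
        fit = reml_fit(d["phenotype"], K, c, MODEL_SPECS["NULL"])
        h2s.append(heritability(fit.vc_hat))
    assert np.mean(vars_) == pytest.approx(1.0, abs=0.1)
    assert np.mean(h2s) == pytest.approx(0.5, abs=0.1)
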