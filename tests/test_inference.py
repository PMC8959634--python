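"""Interaction inference: LRT closed forms, the five-test battery, the
legitimacy rule, Fisher/inverse-variance meta-analysis, Bonferroni control
and the grid scan with a planted signal."""

import numpy as np
import pytest

from rnmkit.inference import (
    TEST_TYPES,
    bonferroni_threshold,
    fisher_meta,
    legitimacy_check,
    lrt,
    meta_estimates,
    run_five_tests,
    run_grid,
)
from rnmkit.qc import compute_grm
from rnmkit.reml import MODEL_SPECS, ModelFit, VarianceComponents
from rnmkit.synthetic import (
    SimulationConfig,
    simulate_covariate,
    simulate_genotypes,
    simulate_phenotype,
)


def stub_fit(spec_name, logL, converged=True, **vc_kw):
    spec = MODEL_SPECS[spec_name]
    return ModelFit(
        spec=spec, vc_hat=VarianceComponents(**vc_kw), logL=logL,
        vc_cov=np.eye(spec.n_free), n_iter=1, converged=converged,
        beta_hat=0.0, grad_norm=0.0,
    )


class TestLrt:
    def test_equal_likelihoods_give_null_result(self):
        chi2, df, p = lrt(stub_fit("FULL", -10.0), stub_fit("NULL", -10.0))
        assert chi2 == 0.0 and df == 4 and p == 1.0

    def test_chi2_survival_closed_form(self):
        # delta logL = 2 with 2 df: p = exp(-chi2/2) = e^-2
        chi2, df, p = lrt(stub_fit("FULL", -8.0), stub_fit("RXE_ONLY", -10.0))
        assert chi2 == pytest.approx(4.0)
        assert df == 2
        assert p == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_tiny_negative_difference_clipped(self):
        chi2, _, p = lrt(stub_fit("FULL", -10.0 - 1e-9), stub_fit("NULL", -10.0))
        assert chi2 == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            lrt(stub_fit("GXE_ONLY", -9.0), stub_fit("RXE_ONLY", -10.0))

    def test_likelihood_inversion_rejected(self):
        with pytest.raises(ValueError, match="convergence"):
            lrt(stub_fit("FULL", -11.0), stub_fit("NULL", -10.0))

    def test_unconverged_fit_rejected(self):
        with pytest.raises(ValueError, match="converged"):
            lrt(stub_fit("FULL", -9.0, converged=False), stub_fit("NULL", -10.0))


class TestFiveTests:
    def test_five_results_with_expected_df(self, interaction_fits):
        results = run_five_tests(interaction_fits)
        assert {r.test_type for r in results} == set(TEST_TYPES)
        df_by_type = {r.test_type: r.df for r in results}
        assert df_by_type["OVERALL"] == 4
        assert all(df_by_type[t] == 2 for t in TEST_TYPES if t != "OVERALL")

    def test_overall_chi2_dominates_orthogonal(self, interaction_fits):
        res = {r.test_type: r for r in run_five_tests(interaction_fits)}
        assert res["OVERALL"].chi2 >= res["GXE_ORTHOGONAL"].chi2 - 1e-6
        assert res["OVERALL"].chi2 >= res["RXE_ORTHOGONAL"].chi2 - 1e-6

    def test_unconverged_fit_drops_only_its_tests(self):
        fits = {
            "NULL": stub_fit("NULL", -12.0),
            "GXE_ONLY": stub_fit("GXE_ONLY", -11.0),
            "RXE_ONLY": stub_fit("RXE_ONLY", -11.5),
            "FULL": stub_fit("FULL", -10.0, converged=False),
        }
        got = {r.test_type for r in run_five_tests(fits)}
        assert got == {"GXE_UNADJ", "RXE_UNADJ"}

    def test_collinearity_inflates_unadjusted_gxe(self):
        # both interaction variances planted: the unadjusted GxE statistic
        # absorbs RxE signal, so it must exceed the orthogonal one
        cfg = SimulationConfig(
            n_individuals=400, n_snps=400, seed=15,
            vc_true=VarianceComponents(sigma2_a0=0.3, sigma2_a1=0.25,
                                       sigma2_t0=0.25, sigma2_t1=0.2),
        )
        from rnmkit.pheno import standardize
        from rnmkit.reml import fit_nested_models
        from rnmkit.synthetic import simulate_dataset

        d = simulate_dataset(cfg)
        K = compute_grm(d["genotypes"]).values
        c = standardize(d["covariate"]).values
        res = {r.test_type: r
               for r in run_five_tests(fit_nested_models(d["phenotype"], K, c))}
        assert res["GXE_UNADJ"].chi2 > res["GXE_ORTHOGONAL"].chi2


class TestLegitimacy:
    @pytest.mark.parametrize(
        "a1,t1,expected",
        [(0.02, 0.01, True), (-0.03, 0.01, False), (-0.01, 0.01, True)],
    )
    def test_nonnegative_sum_rule(self, a1, t1, expected):
        fit = stub_fit("FULL", -1.0, sigma2_a1=a1, sigma2_t1=t1)
        assert legitimacy_check(fit) is expected


class TestFisherMeta:
    def test_single_unit_p(self):
        assert fisher_meta([1.0]) == pytest.approx(1.0)

    def test_two_halves_closed_form(self):
        # X = -2*2*ln(0.5) = 2.7726, df 4: p = e^(-X/2) (1 + X/2) = 0.5966
        assert fisher_meta([0.5, 0.5]) == pytest.approx(0.5966, abs=5e-5)

    def test_combination_never_exceeds_identical_inputs(self):
        for k in (2, 3, 5):
            assert fisher_meta([1e-4] * k) <= 1e-4

    def test_zero_p_clipped(self):
        assert 0.0 < fisher_meta([0.0, 0.5]) < 1e-5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_meta([])
        with pytest.raises(ValueError):
            fisher_meta([1.5])


class TestMetaEstimates:
    def test_equal_weights_average(self):
        est, se = meta_estimates([2.0, 2.0], [0.5, 0.5])
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.5 / np.sqrt(2))

    def test_unequal_weights_hand_value(self):
        est, _ = meta_estimates([0.0, 4.0], [1.0, 2.0])
        assert est == pytest.approx(0.8)

    def test_single_estimate_unchanged(self):
        assert meta_estimates([1.3], [0.2]) == (1.3, 0.2)

    def test_simple_mean_case(self):
        est, _ = meta_estimates([1.0, 3.0], [1.0, 1.0])
        assert est == pytest.approx(2.0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 96, 5.21e-4), (0.05, 1, 0.05), (0.05, 10, 0.005)],
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-2)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestRunGrid:
    def test_planted_gxe_cell_flagged(self):
        # 2x2 grid, GxE planted only in traitA x cov1: that cell must be
        # GXE_ORTHOGONAL-significant at the grid Bonferroni level and the
        # null cells must not be
        cfg = SimulationConfig(
            n_individuals=500, n_snps=500, seed=77,
            vc_true=VarianceComponents(sigma2_a0=0.4, sigma2_a1=0.6,
                                       sigma2_t0=0.3),
        )
        g = simulate_genotypes(cfg)
        grm = compute_grm(g)
        cov1 = simulate_covariate(cfg)
        cov2 = np.random.default_rng(99).normal(size=500)
        yA, _ = simulate_phenotype(g, cov1, cfg)
        null_cfg = SimulationConfig(
            n_individuals=500, n_snps=500, seed=78,
            vc_true=VarianceComponents(sigma2_a0=0.4, sigma2_t0=0.3),
        )
        yB, _ = simulate_phenotype(g, cov1, null_cfg)
        tbl = run_grid({"traitA": yA, "traitB": yB},
                       {"cov1": cov1, "cov2": cov2}, grm)
        assert tbl.attrs["n_cells"] == 4
        assert tbl.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 4)
        orth = tbl[tbl.test_type == "GXE_ORTHOGONAL"].set_index(
            ["trait", "covariate"]
        )
        assert bool(orth.loc[("traitA", "cov1"), "significant"])
        for cell in [("traitA", "cov2"), ("traitB", "cov1"), ("traitB", "cov2")]:
            if cell in orth.index:
                assert not bool(orth.loc[cell, "significant"])

    def test_single_cell_threshold_is_alpha(self):
        cfg = SimulationConfig(n_individuals=150, n_snps=150, seed=5)
        g = simulate_genotypes(cfg)
        grm = compute_grm(g)
        cov = simulate_covariate(cfg)
        y, _ = simulate_phenotype(g, cov, cfg)
        tbl = run_grid({"t": y}, {"c": cov}, grm, alpha=0.05)
        assert tbl.attrs["bonferroni_threshold"] == pytest.approx(0.05)

    def test_split_metaanalysis_produces_meta_p(self):
        cfg = SimulationConfig(n_individuals=300, n_snps=300, seed=6)
        g = simulate_genotypes(cfg)
        grm = compute_grm(g)
        cov = simulate_covariate(cfg)
        y, _ = simulate_phenotype(g, cov, cfg)
        from rnmkit.qc import split_samples

        splits = split_samples(grm.sample_ids, 2, seed=1)
        tbl = run_grid({"t": y}, {"c": cov}, grm, splits=splits)
        ok = tbl[tbl.test_type != "ERROR"]
        assert (ok.meta_p <= 1).all() and (ok.meta_p >= 0).all()
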