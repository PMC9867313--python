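import numpy as np
import pytest

from semfi import INDICATORS
from semfi.cfa import (
    CfaModelSpec,
    build_default_model,
    correlated_factors_model,
    fit_cfa,
    modification_indices,
    squared_multiple_correlation,
)
from semfi.synthetic import DEFAULT_LOADINGS, SyntheticSpec

from conftest import TRUTH_LOADINGS

POP_SIGMA = SyntheticSpec().implied_correlation()


def one_factor_spec(names=("x1", "x2", "x3")):
    return CfaModelSpec(
        observed=tuple(names),
        first_order_factors={"F": tuple(names)},
    )


class TestModelSpec:
    def test_default_structure(self):
        spec = build_default_model()
        assert spec.first_order_factors["TotalNutrients"] == ("som", "tn", "tp")
        assert spec.first_order_factors["AvailableNutrients"] == ("an", "ap", "ak")
        assert spec.second_order_factor == "SoilFertility"

    def test_default_parameter_count(self):
        spec = build_default_model()
        # 6 loadings + 1 shared gamma + 6 error variances under unit-variance
        # identification with the equal-gamma constraint
        assert spec.q == 13
        assert spec.q <= 21
        assert spec.df == 8

    def test_error_covariance_adds_one_parameter(self):
        spec = build_default_model()
        assert spec.with_error_covariance("som", "an").q == spec.q + 1

    def test_double_assignment_rejected(self):
        with pytest.raises(ValueError, match="two factors"):
            CfaModelSpec(
                observed=("a", "b"),
                first_order_factors={"F": ("a", "b"), "G": ("a",)},
            )

    def test_overparameterized_spec_rejected(self):
        spec = one_factor_spec()
        with pytest.raises(ValueError, match="identified"):
            spec.with_error_covariance("x1", "x2")

    def test_round_trips_through_dict(self):
        spec = build_default_model().with_error_covariance("som", "an")
        assert CfaModelSpec.from_dict(spec.to_dict()) == spec


class TestFitAtPopulation:
    def test_recovers_generating_loadings(self):
        fit = fit_cfa(correlated_factors_model(), sample_cov=POP_SIGMA, n=10**6)
        np.testing.assert_allclose(fit.std_loading_list(), TRUTH_LOADINGS, atol=1e-4)
        assert fit.factor_corr[0, 1] == pytest.approx(0.306, abs=1e-4)
        assert fit.fmin < 1e-8  # chi2 / (n-1)
        assert fit.grad_norm < 1e-6

    def test_second_order_equal_gamma_matches_factor_correlation(self):
        fit = fit_cfa(build_default_model(), sample_cov=POP_SIGMA, n=10**6)
        # equal gamma paths imply factor correlation gamma^2
        gam = fit.std_gamma["TotalNutrients"]
        assert gam**2 == pytest.approx(0.306, abs=1e-4)
        assert fit.fmin < 1e-8

    def test_implied_covariance_positive_definite(self):
        fit = fit_cfa(correlated_factors_model(), sample_cov=POP_SIGMA, n=10**6)
        assert np.linalg.eigvalsh(fit.sigma_hat).min() > 0
        np.testing.assert_allclose(fit.sigma_hat, fit.sigma_hat.T)


class TestSaturatedAndTriad:
    R = np.array([[1.0, 0.56, 0.48], [0.56, 1.0, 0.42], [0.48, 0.42, 1.0]])

    def test_saturated_model_gives_zero_chi2(self):
        fit = fit_cfa(one_factor_spec(), sample_cov=self.R, n=200)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_loadings_solve_triad_equations(self):
        """ML loadings of the 1-factor/3-indicator model obey the closed form
        lambda_1 = sqrt(r12 * r13 / r23) etc."""
        fit = fit_cfa(one_factor_spec(), sample_cov=self.R, n=200)
        r12, r13, r23 = self.R[0, 1], self.R[0, 2], self.R[1, 2]
        expected = [
            np.sqrt(r12 * r13 / r23),
            np.sqrt(r12 * r23 / r13),
            np.sqrt(r13 * r23 / r12),
        ]
        np.testing.assert_allclose(
            np.abs(fit.std_loading_list()), expected, atol=1e-6
        )


class TestFitOnSamples:
    def test_chi2_invariant_to_indicator_order(self, homogeneous_table):
        data = homogeneous_table[list(INDICATORS)]
        fit1 = fit_cfa(correlated_factors_model(), data)
        perm = ["ap", "som", "ak", "tn", "an", "tp"]
        spec2 = CfaModelSpec(
            observed=tuple(perm),
            first_order_factors={
                "TotalNutrients": ("som", "tn", "tp"),
                "AvailableNutrients": ("an", "ap", "ak"),
            },
        )
        fit2 = fit_cfa(spec2, data[perm])
        assert fit2.chi2 == pytest.approx(fit1.chi2, abs=1e-6)

    def test_standardized_solution_scale_invariant(self, homogeneous_table):
        data = homogeneous_table[list(INDICATORS)].copy()
        fit1 = fit_cfa(correlated_factors_model(), data)
        scaled = data * np.array([100.0, 0.01, 3.0, 0.5, 10.0, 7.0])
        fit2 = fit_cfa(correlated_factors_model(), scaled)
        np.testing.assert_allclose(
            fit2.std_loading_list(), fit1.std_loading_list(), atol=1e-6
        )
        assert fit2.chi2 == pytest.approx(fit1.chi2, abs=1e-6)

    def test_freeing_a_parameter_never_worsens_fit(self, homogeneous_table):
        data = homogeneous_table[list(INDICATORS)]
        base = fit_cfa(correlated_factors_model(), data)
        for spec in [
            base.spec.with_error_covariance("som", "an"),
            base.spec.with_cross_loading("tp", "AvailableNutrients"),
        ]:
            nested = fit_cfa(spec, data)
            assert nested.fmin <= base.fmin + 1e-9

    def test_recovery_unbiased_over_seeds(self):
        """Generate -> fit closure: mean recovered loading matches the
        generating loading (no systematic bias)."""
        import warnings

        from semfi.synthetic import generate

        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for seed in range(60):
                table = generate(SyntheticSpec.homogeneous(seed=seed))
                fit = fit_cfa(correlated_factors_model(), table[list(INDICATORS)])
                errs.append(np.array(fit.std_loading_list()) - TRUTH_LOADINGS)
        bias = np.abs(np.mean(errs, axis=0))
        assert bias.max() < 0.02


class TestSmc:
    def test_smc_equals_squared_standardized_loading(self):
        fit = fit_cfa(correlated_factors_model(), sample_cov=POP_SIGMA, n=10**6)
        smc = squared_multiple_correlation(fit)
        for ind, lam in zip(INDICATORS, fit.std_loading_list()):
            assert smc[ind] == pytest.approx(lam**2, abs=1e-8)

    def test_factor_smc_is_squared_gamma(self):
        fit = fit_cfa(build_default_model(), sample_cov=POP_SIGMA, n=10**6)
        smc = squared_multiple_correlation(fit)
        for fac, gam in fit.std_gamma.items():
            assert smc[fac] == pytest.approx(gam**2, abs=1e-12)


class TestModificationIndices:
    def test_known_missing_error_covariance_ranks_first(self):
        # population covariance of the default model plus one error covariance
        sigma = POP_SIGMA.copy()
        i, j = INDICATORS.index("som"), INDICATORS.index("an")
        sigma[i, j] = sigma[j, i] = sigma[i, j] + 0.15
        fit = fit_cfa(correlated_factors_model(), sample_cov=sigma, n=500)
        ranked = modification_indices(
            fit,
            candidates=[
                ("error_covariance", "som", "an"),
                ("error_covariance", "tp", "ak"),
                ("error_covariance", "tn", "ap"),
            ],
        )
        top, mi = ranked[0]
        assert top[0] == "error_covariance" and {top[1], top[2]} == {"som", "an"}
        assert mi > 3.84

    def test_all_indices_vanish_for_correct_model(self):
        fit = fit_cfa(correlated_factors_model(), sample_cov=POP_SIGMA, n=1000)
        ranked = modification_indices(fit)
        assert all(mi < 1e-6 for _, mi in ranked)

    def test_refit_reproduces_chi2_drop(self, homogeneous_table):
        import warnings

        data = homogeneous_table[list(INDICATORS)]
        fit = fit_cfa(correlated_factors_model(), data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ranked = modification_indices(fit)
            (kind, a, b), mi = ranked[0]
            if kind == "error_covariance":
                new_spec = fit.spec.with_error_covariance(a, b)
            else:
                new_spec = fit.spec.with_cross_loading(a, b)
            refit = fit_cfa(new_spec, data)
        assert refit.chi2 == pytest.approx(fit.chi2 - mi, abs=1e-6)

    def test_already_free_candidate_rejected(self):
        spec = correlated_factors_model().with_error_covariance("som", "an")
        fit = fit_cfa(spec, sample_cov=POP_SIGMA, n=500)
        with pytest.raises(ValueError, match="already"):
            modification_indices(fit, candidates=[("error_covariance", "som", "an")])
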