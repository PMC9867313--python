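import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semfi import INDICATORS, bartlett_sphericity, cronbach_alpha, kmo, screen
from semfi.exceptions import SingularMatrixError
from semfi.reliability import bartlett_from_corr, kmo_from_corr
from semfi.synthetic import SyntheticSpec, generate

# fixed 5 x 3 item matrix used for the brute-force alpha oracle
ALPHA_MATRIX = np.array(
    [[2, 4, 3], [4, 5, 5], [3, 4, 4], [1, 2, 2], [5, 5, 4]], dtype=float
)


def brute_force_alpha(x):
    """Direct evaluation of k/(k-1) * (1 - sum item var / total var)."""
    n, k = x.shape
    item_vars = [np.var(x[:, j], ddof=1) for j in range(k)]
    total_var = np.var(x.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestCronbachAlpha:
    def test_duplicated_column_gives_one(self, rng):
        x = rng.normal(size=(50, 1))
        assert cronbach_alpha(np.hstack([x, x])) == pytest.approx(1.0)

    def test_uncorrelated_items_give_near_zero(self, rng):
        x = rng.standard_normal((20000, 4))
        assert abs(cronbach_alpha(x)) < 0.05

    def test_matches_brute_force_formula(self):
        assert cronbach_alpha(ALPHA_MATRIX) == pytest.approx(
            brute_force_alpha(ALPHA_MATRIX), abs=1e-12
        )

    def test_matches_pingouin(self):
        """Cross-check against an independently implemented alpha."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        expected = pingouin.cronbach_alpha(data=pd.DataFrame(ALPHA_MATRIX))[0]
        assert cronbach_alpha(ALPHA_MATRIX) == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(-100, 100))
    def test_invariant_to_item_shift(self, shift):
        shifted = ALPHA_MATRIX.copy()
        shifted[:, 1] += shift
        assert cronbach_alpha(shifted) == pytest.approx(
            cronbach_alpha(ALPHA_MATRIX), abs=1e-9
        )


class TestKmo:
    # fixed 3-variable correlation matrix for the hand oracle
    R3 = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.3], [0.4, 0.3, 1.0]])

    def brute_force_kmo(self, r):
        """Oracle: partial correlations via explicit matrix inversion."""
        inv = np.linalg.inv(r)
        p = r.shape[0]
        num = den_q = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                q = -inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])
                num += r[i, j] ** 2
                den_q += q**2
        return num / (num + den_q)

    def test_matches_hand_computation(self):
        overall, _ = kmo_from_corr(self.R3)
        assert overall == pytest.approx(self.brute_force_kmo(self.R3), abs=1e-12)

    def test_strong_one_factor_data_is_adequate(self, rng):
        lam = 0.9
        f = rng.standard_normal(2000)
        x = np.column_stack(
            [lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(2000) for _ in range(5)]
        )
        overall, _ = kmo(x)
        assert overall > 0.7

    def test_overall_between_per_variable_extremes(self, homogeneous_table):
        overall, per_var = kmo(homogeneous_table[list(INDICATORS)].to_numpy())
        assert np.all((per_var >= 0) & (per_var <= 1))
        assert per_var.min() <= overall <= per_var.max()

    def test_singular_matrix_rejected(self, rng):
        x = rng.normal(size=(30, 2))
        with pytest.raises(SingularMatrixError):
            kmo(np.hstack([x, x[:, :1]]))  # exact linear dependence

    def test_invariant_to_affine_rescaling(self, homogeneous_table):
        x = homogeneous_table[list(INDICATORS)].to_numpy()
        y = x * np.array([1e3, 2.0, 0.01, 5.0, 7.0, 0.5]) + 3.0
        assert kmo(y)[0] == pytest.approx(kmo(x)[0], abs=1e-12)


class TestBartlett:
    def test_identity_population_matrix(self):
        chi2, df, p = bartlett_from_corr(np.eye(4), n=100)
        assert chi2 == 0.0
        assert df == 6
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        r = TestKmo.R3
        n, p = 100, 3
        chi2, df, pval = bartlett_from_corr(r, n=n)
        expected = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(r))
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert df == 3

    @pytest.mark.parametrize("rho_pair", [(0.1, 0.3), (0.3, 0.6), (0.6, 0.9)])
    def test_chi2_grows_with_correlation(self, rho_pair):
        lo, hi = rho_pair
        make = lambda rho: np.array([[1, rho, rho], [rho, 1, rho], [rho, rho, 1]])
        assert bartlett_from_corr(make(hi), 50)[0] > bartlett_from_corr(make(lo), 50)[0]

    def test_invariant_to_affine_rescaling(self, homogeneous_table):
        x = homogeneous_table[list(INDICATORS)].to_numpy()
        y = x * 17.0 - 4.0
        assert bartlett_sphericity(y)[0] == pytest.approx(
            bartlett_sphericity(x)[0], abs=1e-9
        )


def test_screening_gates_hold_across_seeds():
    """Factor-model data at n = 500 passes every adequacy gate in >= 95% of seeds."""
    from semfi import zscore_normalize

    n_pass = 0
    seeds = range(40)
    for seed in seeds:
        table = generate(SyntheticSpec(seed=seed))
        ztable, _ = zscore_normalize(table, INDICATORS)
        report = screen(ztable[list(INDICATORS)])
        ok = (
            report.cronbach_alpha > 0.5
            and report.kmo_overall > 0.5
            and report.bartlett_p < 0.05
        )
        n_pass += ok
    assert n_pass / len(seeds) >= 0.95


def test_screen_report_structure(default_table):
    report = screen(
        default_table[list(INDICATORS)],
        groups={"total": ["som", "tn", "tp"], "available": ["an", "ap", "ak"]},
    )
    assert report.bartlett_df == 15  # p(p-1)/2 for p = 6
    assert 0 <= report.bartlett_p <= 1
    assert set(report.group_alphas) == {"total", "available"}
    frame = report.to_frame()
    assert {"criterion", "value", "reference", "verdict"} <= set(frame.columns)
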