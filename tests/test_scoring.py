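import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semfi import INDICATORS
from semfi.exceptions import IndicatorMismatchError, ScoringDomainError
from semfi.scoring import (
    ScoringConfig,
    compute_sfi,
    nonlinear_score,
    score_indicators,
    score_table,
    summarize_sfi,
)
from semfi.weighting import compute_weights

WEIGHTS = compute_weights(
    {"TotalNutrients": 0.51, "AvailableNutrients": 0.60},
    {
        "TotalNutrients": {"som": 0.89, "tn": 0.96, "tp": 0.46},
        "AvailableNutrients": {"an": 0.42, "ap": 0.78, "ak": 0.77},
    },
)


class TestNonlinearScore:
    def test_mean_scores_half(self):
        assert nonlinear_score(7.3, 7.3, b=-2.5) == 0.5
        assert nonlinear_score(7.3, 7.3, b=2.5) == 0.5

    def test_double_the_mean(self):
        assert nonlinear_score(2.0, 1.0, b=-2.5) == pytest.approx(
            1 / (1 + 2**-2.5), abs=1e-12
        )
        # 1 / (1 + 2^-2.5) = 1 / (1 + 1/(4*sqrt(2)))
        assert round(nonlinear_score(2.0, 1.0, b=-2.5), 5) == 0.84978

    def test_half_the_mean_is_log_symmetric_complement(self):
        assert round(nonlinear_score(0.5, 1.0, b=-2.5), 5) == 0.15022
        assert nonlinear_score(2.0, 1.0, b=-2.5) + nonlinear_score(0.5, 1.0, b=-2.5) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_zero_value_limit(self):
        assert nonlinear_score(0.0, 5.0, b=-2.5) == 0.0
        assert nonlinear_score(0.0, 5.0, b=2.5) == 1.0

    @pytest.mark.parametrize("x, x0", [(-0.1, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, x, x0):
        with pytest.raises(ScoringDomainError):
            nonlinear_score(x, x0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3))
    def test_self_duality(self, x, x0):
        up = nonlinear_score(x, x0, b=-2.5)
        down = nonlinear_score(x, x0, b=2.5)
        assert up + down == pytest.approx(1.0, abs=1e-9)
        assert 0 < up < 1

    def test_strictly_monotone(self):
        xs = np.linspace(0.01, 50, 200)
        up = nonlinear_score(xs, 10.0, b=-2.5)
        down = nonlinear_score(xs, 10.0, b=2.5)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)


class TestSfi:
    def test_sample_at_dataset_means_scores_half(self, default_table):
        means = {ind: float(default_table[ind].mean()) for ind in INDICATORS}
        row = default_table.iloc[:1].copy()
        for ind, mu in means.items():
            row[ind] = mu
        scored, _ = score_table(row, WEIGHTS, config=ScoringConfig(x0_values=means))
        assert scored["sfi"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_sfi_is_weighted_sum_of_scores(self, default_table):
        scored, _ = score_table(default_table, WEIGHTS)
        manual = sum(
            WEIGHTS.combined_weights[ind] * scored[f"s_{ind}"] for ind in INDICATORS
        )
        np.testing.assert_allclose(scored["sfi"].to_numpy(), manual.to_numpy(), atol=1e-12)
        assert ((scored["sfi"] > 0) & (scored["sfi"] < 1)).all()

    def test_all_unit_scores_give_unit_sfi(self):
        frame = pd.DataFrame({f"s_{ind}": [1.0] for ind in INDICATORS})
        out = compute_sfi(frame, WEIGHTS)
        assert out["sfi"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_raising_an_indicator_raises_sfi(self, default_table):
        scored, x0 = score_table(default_table, WEIGHTS)
        bumped = default_table.copy()
        bumped["ak"] = bumped["ak"] * 1.5
        rescored, _ = score_table(
            bumped, WEIGHTS, config=ScoringConfig(x0_values=x0)
        )
        assert (rescored["sfi"].to_numpy() > scored["sfi"].to_numpy()).all()

    def test_indicator_mismatch_rejected(self):
        frame = pd.DataFrame({"s_som": [0.5]})
        with pytest.raises(IndicatorMismatchError, match="tn"):
            compute_sfi(frame, WEIGHTS)

    def test_scores_use_raw_scale_reference(self, default_table):
        _, x0 = score_indicators(default_table)
        for ind in INDICATORS:
            assert x0[ind] == pytest.approx(float(default_table[ind].mean()))


class TestSummaries:
    def test_depth_decline_reflected_in_sfi(self, default_table):
        """Cell means decline with depth, so mean SFI does too in each age group."""
        scored, _ = score_table(default_table, WEIGHTS)
        summary = summarize_sfi(scored)
        for age, block in summary.groupby("age_group", observed=True):
            means = block.sort_values("depth_layer")["mean_sfi"].to_numpy()
            assert means[0] > means[-1]  # topsoil beats deepest layer

    def test_single_sample_cell(self):
        frame = pd.DataFrame(
            {
                "age_group": ["I"],
                "depth_layer": ["0-15"],
                "sfi": [0.42],
            }
        )
        summary = summarize_sfi(frame)
        row = summary[(summary["age_group"] == "I") & (summary["depth_layer"] == "0-15")]
        assert row["n"].iloc[0] == 1
        assert row["mean_sfi"].iloc[0] == pytest.approx(0.42)
        assert np.isnan(row["sd_sfi"].iloc[0])

    def test_row_permutation_invariance(self, default_table):
        scored, _ = score_table(default_table, WEIGHTS)
        shuffled = scored.sample(frac=1.0, random_state=3)
        pd.testing.assert_frame_equal(summarize_sfi(scored), summarize_sfi(shuffled))

    def test_deterministic_row_order(self, default_table):
        scored, _ = score_table(default_table, WEIGHTS)
        summary = summarize_sfi(scored)
        ages = summary["age_group"].astype(str).tolist()
        assert ages == sorted(ages, key=["I", "II", "III", "IV", "V"].index)
        assert summary.groupby("age_group", observed=True)["depth_layer"].apply(
            lambda s: list(s.astype(str)) == ["0-15", "15-30", "30-45", "45-60"]
        ).all()

    def test_sfi_band_is_plausible(self, default_table):
        """All cell means stay inside the plausible (0.1, 0.95) band."""
        scored, _ = score_table(default_table, WEIGHTS)
        summary = summarize_sfi(scored)
        assert summary["mean_sfi"].between(0.1, 0.95).all()
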