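import numpy as np
import pandas as pd
import pytest

from vibrohist.history_analysis import (
    ITIBinSpec,
    InsufficientGroupsError,
    add_lagged_columns,
    bias_vs_previous_delta,
    curves_by_history,
    exclude_iti_outliers,
    history_glm,
    iti_conditioned_bias,
    residualize_previous_choice,
)


def _toy_two_sessions():
    rows = []
    for sid, n in (("a", 6), ("b", 5)):
        for i in range(n):
            rows.append(
                {
                    "subject_id": "r1",
                    "session_id": sid,
                    "trial_index": i + 1,
                    "sp_mm_per_s": 103.0,
                    "delta_speed": (i % 9) - 4,
                    "choice": i % 2,
                    "rewarded": 1,
                    "iti_s": np.nan if i == 0 else 5.0 + i,
                }
            )
    return pd.DataFrame(rows)


class TestLaggedColumns:
    def test_no_leak_across_sessions(self):
        df = add_lagged_columns(_toy_two_sessions(), 2)
        first_b = df[df.session_id == "b"].iloc[0]
        assert np.isnan(first_b["delta_lag1"]) and np.isnan(first_b["delta_lag2"])
        second_b = df[df.session_id == "b"].iloc[1]
        assert second_b["delta_lag1"] == df[df.session_id == "b"].iloc[0]["delta_speed"]


class TestCurvesByHistory:
    def test_continuous_observer_pse_monotone_in_previous_delta(self, continuous_dataset):
        fits = curves_by_history(continuous_dataset, lag=1, min_group_trials=200)
        pses = [f.pse for _, f in sorted(fits.items())]
        assert len(pses) >= 7
        # overall monotone attraction of the midpoint toward the previous
        # stimulus; adjacent noise allowed, endpoints must be ordered
        assert pses[-1] > pses[0]
        assert np.polyfit(sorted(fits), pses, 1)[0] > 0

    def test_memoryless_observer_groups_overlap(self, memoryless_dataset):
        fits = curves_by_history(memoryless_dataset, lag=1, min_group_trials=200)
        pses = np.array([f.pse for f in fits.values()])
        assert pses.max() - pses.min() < 0.4


class TestBiasRegression:
    def test_memoryless_slope_near_zero(self, memoryless_dataset):
        res = bias_vs_previous_delta(memoryless_dataset, lag=1, min_group_trials=200)
        assert abs(res.slope) < 0.05
        assert res.ci[0] < 0 < res.ci[1]

    def test_continuous_slope_positive_and_decaying(self, continuous_dataset):
        r1 = bias_vs_previous_delta(continuous_dataset, lag=1, min_group_trials=200)
        r4 = bias_vs_previous_delta(continuous_dataset, lag=4, min_group_trials=200)
        assert r1.slope > 0
        assert r4.slope < r1.slope

    def test_too_few_groups_rejected(self):
        with pytest.raises(InsufficientGroupsError):
            bias_vs_previous_delta(_toy_two_sessions(), lag=1, min_group_trials=1000)


class TestHistoryGLM:
    def test_recovers_generative_probit_coefficients(self):
        """Choices generated directly from a probit GLM with known lagged
        weights are recovered within 2 SE."""
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        beta = {"const": 0.1, "lag0": 0.9, "lag1": -0.3, "lag2": -0.12}
        rows = []
        for sid in range(8):
            d = rng.integers(-4, 5, 600).astype(float)
            for i in range(600):
                lin = beta["const"] + beta["lag0"] * d[i]
                if i >= 1:
                    lin += beta["lag1"] * d[i - 1]
                if i >= 2:
                    lin += beta["lag2"] * d[i - 2]
                choice = int(rng.random() < norm.cdf(lin))
                rows.append(
                    {
                        "subject_id": "g",
                        "session_id": f"s{sid}",
                        "trial_index": i + 1,
                        "sp_mm_per_s": 0.0,
                        "delta_speed": d[i],
                        "choice": choice,
                        "rewarded": 1,
                        "iti_s": np.nan if i == 0 else 8.0,
                    }
                )
        df = pd.DataFrame(rows)
        res = history_glm(df, n_lags=2)
        for name, true in (
            ("intercept", 0.1),
            ("delta_lag0", 0.9),
            ("delta_lag1", -0.3),
            ("delta_lag2", -0.12),
        ):
            i = res.names.index(name)
            assert abs(res.beta[i] - true) < 2 * res.se[i] + 0.02

    def test_memoryless_lagged_terms_null(self, memoryless_dataset):
        res = history_glm(memoryless_dataset, n_lags=4)
        lagged = res.lagged_coefficients()
        assert np.all(np.abs(lagged) < 0.05)

    def test_discrete_observer_coefficients_decay_geometrically(self, discrete_dataset):
        """A tau = 4 (trials) discrete observer embeds past stimuli with
        weights decaying by e^(-1/4) per lag; fitted lagged GLM weights
        must be negative and decay at about that ratio."""
        res = history_glm(discrete_dataset, n_lags=4)
        lagged = res.lagged_coefficients()
        assert np.all(lagged[:3] < 0)
        ratios = lagged[1:3] / lagged[:2]
        assert np.allclose(ratios, np.exp(-1 / 4), atol=0.25)

    def test_interaction_terms_present(self, continuous_dataset):
        res = history_glm(continuous_dataset, n_lags=2, interactions={"prev_reward", "iti"})
        assert "delta_lag1_x_prev_reward" in res.names
        assert "delta_lag1_x_iti" in res.names
        assert len(res.beta) == len(res.names)


class TestITIOutliers:
    def test_exact_retention_count(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "subject_id": "r1",
                "session_id": "s1",
                "trial_index": np.arange(1, 1002),
                "sp_mm_per_s": 103.0,
                "delta_speed": 0,
                "choice": 0,
                "rewarded": 1,
                "iti_s": np.concatenate([[np.nan], rng.lognormal(2, 0.4, 1000)]),
            }
        )
        kept = exclude_iti_outliers(df, 0.2)
        assert kept["iti_s"].notna().sum() == 800
        assert kept["iti_s"].max() <= df["iti_s"].quantile(0.8) + 1e-9

    def test_ties_resolved_by_stable_order(self):
        df = pd.DataFrame(
            {
                "subject_id": "r1",
                "session_id": "s1",
                "trial_index": np.arange(1, 11),
                "sp_mm_per_s": 103.0,
                "delta_speed": 0,
                "choice": 0,
                "rewarded": 1,
                "iti_s": [np.nan] + [5.0] * 9,
            }
        )
        kept = exclude_iti_outliers(df, 0.2)
        # ceil(0.8 * 9) = 8 ITI rows retained, earliest rows win ties
        assert kept["iti_s"].notna().sum() == 8
        assert kept["trial_index"].tolist() == list(range(1, 10))


class TestITIConditionedBias:
    def test_continuous_observer_long_iti_steeper(self, continuous_dataset):
        res = iti_conditioned_bias(
            continuous_dataset, ITIBinSpec(n_bins=2), min_group_trials=150
        )
        assert res[1].slope > res[0].slope

    def test_discrete_observer_iti_blind(self, discrete_dataset):
        res = iti_conditioned_bias(
            discrete_dataset, ITIBinSpec(n_bins=2), min_group_trials=150
        )
        # discrete updating has no time dependence: bin slopes agree
        assert abs(res[1].slope - res[0].slope) < 0.06


class TestResidualization:
    def test_constructed_offset_removed(self):
        rng = np.random.default_rng(1)
        prev_choice = np.repeat([0, 1], 20)
        base = rng.normal(0, 0.02, 40)
        pses = base + 0.5 * prev_choice
        adj = residualize_previous_choice(pses, prev_choice)
        assert abs(adj[prev_choice == 1].mean() - adj[prev_choice == 0].mean()) < 0.05

    def test_zero_effect_noop(self):
        rng = np.random.default_rng(2)
        prev_choice = np.repeat([0, 1], 20)
        pses = rng.normal(0.3, 0.01, 40)
        adj = residualize_previous_choice(pses, prev_choice)
        assert np.allclose(adj, pses, atol=0.05)

    def test_single_level_warns_and_passes_through(self):
        pses = np.array([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning):
            adj = residualize_previous_choice(pses, np.zeros(3))
        assert np.array_equal(adj, pses)

    def test_orthogonal_design_preserves_stimulus_slope(self):
        # previous stimulus and previous choice fully crossed: residualizing
        # the choice effect leaves the stimulus-history slope intact
        prev_delta = np.tile(np.arange(-4, 5), 2)
        prev_choice = np.repeat([0, 1], 9)
        pses = 0.15 * prev_delta + 0.4 * prev_choice
        adj = residualize_previous_choice(pses, prev_choice)
        slope = np.polyfit(prev_delta, adj, 1)[0]
        assert slope == pytest.approx(0.15, abs=1e-8)
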