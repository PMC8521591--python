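import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibrohist.model_evaluation import (
    auroc,
    brier_score,
    corrected_resampled_ttest,
    cross_validate,
    fit_tau,
    predict_sessions,
)
from vibrohist.psychometrics import fit_psychometric
from vibrohist.synthetic_data import ObserverParams, simulate_dataset


class TestBrier:
    def test_perfect_and_uninformative(self):
        assert brier_score([1.0, 0.0], [1, 0]) == 0.0
        assert brier_score([0.5, 0.5], [1, 0]) == 0.25

    def test_hand_computed(self):
        assert brier_score([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            brier_score([], [])


class TestAUROC:
    def test_extremes(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_brute_force_pairs(self):
        # pairs: (0.9,0.8)+, (0.9,0.3)+, (0.4,0.8)-, (0.4,0.3)+ -> 3/4
        assert auroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.3, 0.7], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=30))
    def test_invariant_to_monotone_transform(self, probs):
        rng = np.random.default_rng(0)
        choices = rng.integers(0, 2, len(probs))
        if len(np.unique(choices)) < 2:
            choices[0], choices[1] = 0, 1
        p = np.asarray(probs)
        assert auroc(p, choices) == pytest.approx(auroc(p**3 / 2, choices), abs=1e-12)


class TestFitTau:
    def test_recovers_continuous_tau(self, continuous_dataset):
        """tau recovery within +/-30% from 60 sessions generated at tau=30 s."""
        full = fit_psychometric(continuous_dataset)
        tau_hat, _, at_bound = fit_tau(
            continuous_dataset, "continuous", full.sigma, full.gamma, full.lam
        )
        assert not at_bound
        assert tau_hat == pytest.approx(30.0, rel=0.30)

    def test_memoryless_data_hits_upper_bound(self, memoryless_dataset):
        full = fit_psychometric(memoryless_dataset)
        tau_hat, _, at_bound = fit_tau(
            memoryless_dataset, "continuous", full.sigma, full.gamma, full.lam
        )
        assert at_bound
        assert tau_hat > 400

    def test_annealing_backend_agrees_with_grid(self):
        df = simulate_dataset(n_sessions=6, trials_per_session=100, seed=88)
        full = fit_psychometric(df)
        args = ("continuous", full.sigma, full.gamma, full.lam)
        _, brier_grid, _ = fit_tau(df, *args, optimizer="grid")
        _, brier_anneal, _ = fit_tau(df, *args, optimizer="anneal", seed=0)
        assert brier_anneal == pytest.approx(brier_grid, abs=1e-4)

    def test_matches_fine_grid_oracle(self):
        df = simulate_dataset(n_sessions=8, trials_per_session=150, seed=77)
        full = fit_psychometric(df)
        args = ("continuous", full.sigma, full.gamma, full.lam)
        tau_hat, brier, _ = fit_tau(df, *args)
        grid = np.geomspace(0.5, 500, 400)
        choices = df.choice.to_numpy(float)
        vals = [
            brier_score(predict_sessions(df, "continuous", t, *args[1:]), choices)
            for t in grid
        ]
        assert brier <= min(vals) + 1e-6


@pytest.fixture(scope="module")
def cv_results(continuous_dataset):
    return cross_validate(
        continuous_dataset,
        ("continuous", "no-history"),
        n_rounds=8,
        seed=0,
    )


class TestCrossValidate:

    def test_partitions_disjoint_and_cover(self, cv_results, continuous_dataset):
        all_ids = set(continuous_dataset.session_id.unique())
        for r in cv_results:
            train, test = set(r.train_session_ids), set(r.test_session_ids)
            assert train.isdisjoint(test)
            assert train | test == all_ids

    def test_history_model_wins_on_history_data(self, cv_results):
        briers = {}
        aurocs = {}
        for m in ("continuous", "no-history"):
            rows = [r for r in cv_results if r.model_type == m]
            briers[m] = np.median([r.brier_test for r in rows])
            aurocs[m] = np.median([r.auroc_test for r in rows])
        assert briers["continuous"] < briers["no-history"]
        assert aurocs["continuous"] > aurocs["no-history"]

    def test_reproducible(self, continuous_dataset):
        a = cross_validate(continuous_dataset, ("no-history",), n_rounds=2, seed=3)
        b = cross_validate(continuous_dataset, ("no-history",), n_rounds=2, seed=3)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_memoryless_data_no_model_advantage(self, memoryless_dataset):
        res = cross_validate(
            memoryless_dataset, ("continuous", "no-history"), n_rounds=4, seed=1
        )
        diffs = [
            a.auroc_test - b.auroc_test
            for a, b in zip(
                [r for r in res if r.model_type == "continuous"],
                [r for r in res if r.model_type == "no-history"],
            )
        ]
        assert abs(np.mean(diffs)) < 0.02

    def test_too_few_sessions_rejected(self, continuous_dataset):
        small = continuous_dataset[
            continuous_dataset.session_id.isin(["s001", "s002", "s003"])
        ]
        with pytest.raises(ValueError):
            cross_validate(small, ("no-history",), n_rounds=1)


class TestCorrectedTTest:
    def test_identical_vectors(self):
        a = np.array([0.2, 0.3, 0.25])
        t, p, d = corrected_resampled_ttest(a, a)
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_correction_factor(self):
        # J=100, train_frac=0.8: variance multiplier 1/100 + 0.25 = 0.26,
        # i.e. t is shrunk by sqrt(0.26 / (1/100)) vs the naive paired test
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 0.01, 100)
        b = a - 0.005 + rng.normal(0, 0.002, 100)
        t, p, _ = corrected_resampled_ttest(a, b, train_frac=0.8)
        d = a - b
        naive_t = d.mean() / np.sqrt(d.var(ddof=1) / 100)
        assert t == pytest.approx(naive_t * np.sqrt(0.01 / 0.26))

    def test_correction_is_conservative(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.30, 0.02, 50)
        b = rng.normal(0.28, 0.02, 50)
        t_corr, p_corr, _ = corrected_resampled_ttest(a, b, train_frac=0.8)
        d = a - b
        naive_t = d.mean() / np.sqrt(d.var(ddof=1) / 50)
        from scipy import stats

        naive_p = 2 * stats.t.sf(abs(naive_t), df=49)
        assert p_corr > naive_p

    def test_zero_variance_nonzero_mean_flagged(self):
        a = np.full(10, 0.3)
        b = np.full(10, 0.2)
        t, p, d = corrected_resampled_ttest(a, b)
        assert np.isinf(t) and p == 0.0
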