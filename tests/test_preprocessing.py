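"""Outlier filtering, scaling, differencing and variable selection."""

import numpy as np
import pytest

from ensorc import (
    ConfigurationError,
    DegenerateDataError,
    TimeDifferencer,
    detect_outliers,
    fit_standardizer,
    lasso_select,
    select_auxiliary,
    time_difference,
    vip_scores,
)


class TestHampel:
    def test_clean_gaussian_false_flag_rate_below_one_percent(self):
        # Monte-Carlo expectation under normality, window wide enough for
        # the rolling MAD to be a stable sigma estimate
        rates = [
            detect_outliers(np.random.default_rng(s).standard_normal(1000), 51, 3.0)[0].mean()
            for s in range(10)
        ]
        assert np.mean(rates) <= 0.01

    def test_planted_ten_sigma_spikes_all_flagged_and_repaired(self, rng):
        x = rng.standard_normal(500)
        spikes = [40, 120, 260, 333, 480]
        x[spikes] += 10.0
        mask, cleaned = detect_outliers(x, 7, 3.0)
        assert all(mask[i] for i in spikes)
        assert np.abs(cleaned[spikes]).max() < 5.0  # replaced by local median

    def test_constant_series_flags_nothing(self):
        mask, cleaned = detect_outliers(np.full(50, 3.14), 7, 3.0)
        assert not mask.any()
        assert np.array_equal(cleaned, np.full(50, 3.14))

    @pytest.mark.parametrize("window", [2, 4, 1])
    def test_even_or_tiny_window_rejected(self, window):
        with pytest.raises(ConfigurationError):
            detect_outliers(np.zeros(10), window, 3.0)


class TestStandardizer:
    def test_training_moments_and_roundtrip(self, rng):
        X = rng.normal(5.0, 3.0, size=(200, 4))
        sc = fit_standardizer(X)
        Z = sc.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-10
        assert np.abs(sc.inverse_transform(Z) - X).max() < 1e-12

    def test_test_span_uses_training_statistics(self, rng):
        X = rng.standard_normal((100, 2))
        sc = fit_standardizer(X)
        shift = sc.transform(X + 2.0) - sc.transform(X)
        assert np.allclose(shift, 2.0 / sc.scale)

    def test_zero_variance_variable_named_in_error(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 7.0
        with pytest.raises(DegenerateDataError, match="flow"):
            fit_standardizer(X, names=["cod", "flow", "ph"])


class TestDifferencing:
    def test_linear_ramp_becomes_constant(self):
        d, init = time_difference(np.arange(10.0), lag=1)
        assert np.allclose(d, 1.0)
        assert d.shape[0] == 9

    @pytest.mark.parametrize("lag", [1, 2, 5])
    def test_difference_then_integrate_roundtrip(self, rng, lag):
        X = rng.standard_normal((60, 3))
        td = TimeDifferencer(lag)
        D = td.transform(X)
        assert D.shape == (60 - lag, 3)
        assert np.abs(td.inverse_transform(D) - X).max() < 1e-12

    def test_lag_not_smaller_than_series_raises(self):
        with pytest.raises(ConfigurationError):
            TimeDifferencer(10).transform(np.zeros((10, 1)))


class TestVIP:
    def test_mean_squared_vip_is_one(self, rng):
        X = rng.standard_normal((80, 6))
        y = X @ rng.standard_normal(6) + 0.5 * rng.standard_normal(80)
        vip = vip_scores(X, y, n_components=3)
        assert np.all(vip >= 0)
        assert abs(np.mean(vip**2) - 1.0) < 1e-8

    def test_planted_relevant_variable_ranks_first(self, rng):
        X = rng.standard_normal((200, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(200)
        vip = vip_scores(X, y, n_components=2)
        assert vip.argmax() == 0 and vip[0] > 1

    def test_duplicating_noise_variable_keeps_signal_on_top(self, rng):
        X = rng.standard_normal((200, 5))
        y = X[:, 0] + 0.1 * rng.standard_normal(200)
        X2 = np.column_stack([X, X[:, 3]])  # duplicate an irrelevant column
        vip = vip_scores(X2, y, n_components=2)
        assert vip.argmax() == 0

    def test_constant_target_is_degenerate(self, rng):
        with pytest.raises(DegenerateDataError):
            vip_scores(rng.standard_normal((30, 3)), np.ones(30))


class TestLasso:
    def test_huge_penalty_selects_nothing(self, rng):
        X = rng.standard_normal((100, 6))
        y = X[:, 0] + 0.1 * rng.standard_normal(100)
        sel, path = lasso_select(X, y, penalty_grid=[1e3], seed=0)
        assert sel == []

    def test_zero_penalty_selects_everything(self, rng):
        X = rng.standard_normal((100, 6))
        y = X @ rng.standard_normal(6) + 0.1 * rng.standard_normal(100)
        sel, _ = lasso_select(X, y, penalty_grid=[0.0], seed=0)
        assert sel == list(range(6))

    def test_planted_two_of_eight_recovered_in_most_seeds(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 8))
            y = X[:, 1] + X[:, 5] + 0.1 * rng.standard_normal(200)
            sel, _ = lasso_select(X, y, seed=seed)
            hits += set(sel) >= {1, 5} and len(sel) <= 4
        assert hits >= 45

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.standard_normal((120, 5))
        y = X[:, 2] + 0.2 * rng.standard_normal(120)
        a, _ = lasso_select(X, y, seed=7)
        b, _ = lasso_select(X, y, seed=7)
        assert a == b

    def test_fewer_samples_than_folds_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            lasso_select(rng.standard_normal((3, 2)), np.zeros(3), cv_folds=5)


class TestSelectAuxiliary:
    VIP = {"a": 1.8, "b": 1.2, "c": 0.4, "d": 0.9, "e": 1.1}

    def test_agreeing_sets_survive_any_rule(self):
        for rule in ("union", "intersection"):
            rep = select_auxiliary(self.VIP, ["a", "b", "e"], rule=rule)
            assert rep.final_selected == ["a", "b", "e"]

    def test_target_cardinality_trims_by_vip_rank(self):
        rep = select_auxiliary(self.VIP, ["a", "b", "d", "e"], rule="union", target_count=2)
        assert rep.final_selected == ["a", "b"]

    def test_domain_variables_always_retained(self):
        rep = select_auxiliary(self.VIP, ["a"], domain_list=["c"], rule="intersection")
        assert "c" in rep.final_selected

    def test_disjoint_sets_under_intersection_error(self):
        with pytest.raises(ConfigurationError, match="empty"):
            select_auxiliary(self.VIP, ["c"], rule="intersection")

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            select_auxiliary(self.VIP, ["zz"])
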