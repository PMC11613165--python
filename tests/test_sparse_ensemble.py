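"""STLS sparsification, the bagging ensemble, and the EnSO composition."""

import numpy as np
import pytest

from conftest import planted_linear12
from ensorc import (
    ConfigurationError,
    SparsityConfig,
    bootstrap_indices,
    ensemble_sparse_fit,
    fit_batch,
    sparse_then_online,
    stls,
)


def _half_min_coef(truth):
    return 0.5 * np.abs(truth.W[truth.support]).min()


class TestSTLS:
    def test_zero_threshold_reproduces_dense_fit(self, planted_quadratic):
        fm, Y, _ = planted_quadratic
        cfg = SparsityConfig(lambda1=0.0, lambda2=1e-6)
        assert np.array_equal(stls(fm, Y, cfg).W, fit_batch(fm, Y, ridge=1e-6).W)

    def test_threshold_above_all_coefficients_gives_zero_matrix(self, planted_quadratic):
        fm, Y, _ = planted_quadratic
        dense = fit_batch(fm, Y, ridge=1e-6).W
        cfg = SparsityConfig(lambda1=2 * np.abs(dense).max(), lambda2=1e-6)
        with pytest.warns(UserWarning, match="emptied"):
            W = stls(fm, Y, cfg).W
        assert np.array_equal(W, np.zeros_like(W))

    def test_recovers_planted_support_with_light_noise(self):
        fm, Y, truth = planted_linear12(seed=42, noise=0.01)
        cfg = SparsityConfig(lambda1=_half_min_coef(truth), lambda2=1e-8)
        W = stls(fm, Y, cfg).W
        assert np.array_equal(W != 0, truth.support)

    def test_support_size_nonincreasing_over_iterations(self):
        # stls with i iterations is the prefix of the run with i+1 iterations,
        # so comparing final supports across stls_iters probes the loop itself
        fm, Y, truth = planted_linear12(seed=3, noise=0.3)
        sizes = []
        for iters in (1, 2, 3, 5, 10):
            cfg = SparsityConfig(lambda1=0.15, lambda2=1e-8, stls_iters=iters)
            sizes.append(int((stls(fm, Y, cfg).W != 0).sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestBootstrap:
    def test_shape_and_index_range(self):
        idx = bootstrap_indices(37, 5, seed=0)
        assert idx.shape == (5, 37)
        assert idx.min() >= 0 and idx.max() < 37

    def test_same_seed_identical_draws(self):
        assert np.array_equal(bootstrap_indices(50, 8, seed=9), bootstrap_indices(50, 8, seed=9))

    def test_unique_fraction_approaches_one_minus_e_inverse(self):
        # expected fraction of distinct indices in a size-n resample -> 1 - 1/e
        n = 100
        idx = bootstrap_indices(n, 10_000, seed=1)
        frac = np.mean([np.unique(row).size / n for row in idx])
        assert abs(frac - (1 - np.exp(-1))) < 0.01

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_indices(0, 5)
        with pytest.raises(ConfigurationError):
            SparsityConfig(q=0)


class TestEnsemble:
    def test_output_contract(self):
        fm, Y, truth = planted_linear12(seed=5, noise=0.05)
        cfg = SparsityConfig(lambda1=0.1, lambda2=1e-8, q=20, lambda3=0.6, seed=0)
        summ = ensemble_sparse_fit(fm, Y, cfg)
        assert np.all((summ.p_ip >= 0) & (summ.p_ip <= 1))
        assert np.all(summ.W_final[summ.p_ip < cfg.lambda3] == 0)
        assert np.array_equal(summ.support_final, summ.W_final != 0)
        assert summ.member_supports.shape == (20, 2, 12)

    def test_single_member_reduces_to_stls_support(self):
        fm, Y, truth = planted_linear12(seed=6, noise=0.02)
        cfg = SparsityConfig(lambda1=_half_min_coef(truth), lambda2=1e-8, q=1, lambda3=1.0, seed=4)
        summ = ensemble_sparse_fit(fm, Y, cfg)
        boot = bootstrap_indices(fm.n_valid, 1, seed=4)[0]
        W_single = stls(fm.values[:, boot], Y[:, boot], cfg).W
        assert np.array_equal(summ.p_ip, (W_single != 0).astype(float))

    def test_inclusion_probabilities_separate_true_from_false_support(self):
        hits = 0
        for seed in range(10):
            fm, Y, truth = planted_linear12(seed=200 + seed, noise=0.05)
            cfg = SparsityConfig(
                lambda1=_half_min_coef(truth), lambda2=1e-8, q=50, lambda3=0.6, seed=seed
            )
            summ = ensemble_sparse_fit(fm, Y, cfg)
            on = summ.p_ip[truth.support]
            off = summ.p_ip[~truth.support]
            if (on.size == 0 or on.min() >= 0.9) and (off.size == 0 or off.max() <= 0.3):
                hits += 1
        assert hits >= 9

    def test_lambda3_monotonicity_support_never_grows(self):
        fm, Y, _ = planted_linear12(seed=8, noise=0.2)
        sizes = []
        for lam3 in (0.0, 0.3, 0.6, 0.9, 1.0):
            cfg = SparsityConfig(lambda1=0.1, lambda2=1e-8, q=30, lambda3=lam3, seed=2)
            sizes.append(int(ensemble_sparse_fit(fm, Y, cfg).support_final.sum()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_bagging_cuts_false_positives_at_aggressive_threshold(self):
        """The ensemble's false-positive support rate is no worse than single
        STLS at matched lambda1, averaged over seeds (variance reduction)."""
        fp_single, fp_ens = [], []
        for seed in range(20):
            fm, Y, truth = planted_linear12(seed=400 + seed, noise=0.4)
            cfg = SparsityConfig(lambda1=0.08, lambda2=1e-8, q=30, lambda3=0.6, seed=seed)
            off = ~truth.support
            fp_single.append((stls(fm, Y, cfg).W[off] != 0).mean())
            fp_ens.append(ensemble_sparse_fit(fm, Y, cfg).support_final[off].mean())
        assert np.mean(fp_ens) <= np.mean(fp_single)

    def test_mean_coefficient_rule_available(self):
        fm, Y, truth = planted_linear12(seed=9, noise=0.02)
        cfg = SparsityConfig(
            lambda1=_half_min_coef(truth), lambda2=1e-8, q=10, lambda3=0.6, seed=1,
            coef_rule="mean",
        )
        summ = ensemble_sparse_fit(fm, Y, cfg)
        assert np.all(summ.W_final[summ.p_ip < cfg.lambda3] == 0)


class TestSparseThenOnline:
    def _stream(self, fm, Y, n0, block):
        H0, Y0 = fm.values[:, :n0], Y[:, :n0]
        blocks = [
            (fm.values[:, i : i + block], Y[:, i : i + block])
            for i in range(n0, fm.n_valid, block)
        ]
        return H0, Y0, blocks

    def test_sparsity_disabled_matches_plain_online_recursion(self):
        from ensorc import init_online_state, update_online

        fm, Y, _ = planted_linear12(seed=10, noise=0.1)
        H0, Y0, blocks = self._stream(fm, Y, 100, 25)
        cfg = SparsityConfig(lambda1=0.0, lambda2=1e-6, q=5, lambda3=0.0, seed=0)
        state, _ = sparse_then_online(H0, Y0, blocks, cfg)
        plain = init_online_state(H0, Y0, ridge=1e-6)
        for Hb, Yb in blocks:
            plain = update_online(plain, Hb, Yb)
        assert np.abs(state.W - plain.W).max() < 1e-8

    def test_off_support_entries_stay_exactly_zero(self):
        fm, Y, truth = planted_linear12(seed=11, noise=0.05)
        H0, Y0, blocks = self._stream(fm, Y, 150, 10)
        cfg = SparsityConfig(lambda1=_half_min_coef(truth), lambda2=1e-8, q=20, seed=3)
        state, summ = sparse_then_online(H0, Y0, blocks, cfg)
        off = ~(summ.p_ip >= cfg.lambda3)
        assert np.all(state.W[off] == 0)

    def test_final_weights_match_support_restricted_batch_oracle(self):
        fm, Y, truth = planted_linear12(seed=12, noise=0.01)
        H0, Y0, blocks = self._stream(fm, Y, 150, 25)
        cfg = SparsityConfig(lambda1=_half_min_coef(truth), lambda2=1e-10, q=20, seed=5)
        state, summ = sparse_then_online(H0, Y0, blocks, cfg)
        assert np.array_equal(summ.p_ip >= cfg.lambda3, truth.support)
        # oracle: per-row unrestricted least squares on the true support
        for j in range(2):
            act = np.flatnonzero(truth.support[j])
            Wj = np.linalg.lstsq(fm.values[act].T, Y[j], rcond=None)[0]
            assert np.abs(state.W[j, act] - Wj).max() < 1e-6

    def test_periodic_resparsification_runs(self):
        fm, Y, truth = planted_linear12(seed=13, noise=0.05)
        H0, Y0, blocks = self._stream(fm, Y, 150, 50)
        cfg = SparsityConfig(lambda1=_half_min_coef(truth), lambda2=1e-8, q=10, seed=6)
        state, summ = sparse_then_online(H0, Y0, blocks, cfg, resparsify_every=2)
        assert state.n_seen == fm.n_valid
        assert np.all(state.W[~(summ.p_ip >= cfg.lambda3)] == 0)
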