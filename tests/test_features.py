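"""Delay embedding and polynomial library construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensorc import (
    ConfigurationError,
    FeatureConfig,
    FeatureMatrix,
    NGRCFeaturizer,
    SeriesLengthError,
    TimeSeriesDataset,
    assemble_total_features,
    build_features,
    build_linear_features,
    build_nonlinear_features,
    feature_dimension,
    n_monomials,
)
from ensorc.exceptions import AlignmentError


def _ds(u):
    u = np.atleast_2d(np.asarray(u, dtype=float))
    return TimeSeriesDataset(u=u, y=np.zeros((1, u.shape[1])))


class TestLinearFeatures:
    def test_single_tap_is_identity(self, rng):
        u = rng.standard_normal((2, 20))
        lin = build_linear_features(_ds(u), FeatureConfig(n_delays=1))
        assert np.array_equal(lin.values, u)
        assert lin.n_valid == 20

    def test_two_tap_hand_enumeration(self):
        # columns for t=1..3 stack the current value over the previous one
        lin = build_linear_features(_ds([1.0, 2, 3, 4]), FeatureConfig(n_delays=2))
        assert np.array_equal(lin.values, [[2, 3, 4], [1, 2, 3]])
        assert np.array_equal(lin.valid_times, [1, 2, 3])

    @pytest.mark.parametrize("m,k,s", [(1, 3, 1), (2, 2, 2), (3, 4, 3)])
    def test_shape_forced_by_construction(self, rng, m, k, s):
        n = 40
        lin = build_linear_features(
            _ds(rng.standard_normal((m, n))), FeatureConfig(n_delays=k, spacing=s)
        )
        assert lin.values.shape == (m * k, n - s * (k - 1))

    def test_spacing_selects_strided_taps(self):
        u = np.arange(10.0)
        lin = build_linear_features(_ds(u), FeatureConfig(n_delays=2, spacing=3))
        assert np.array_equal(lin.values[0], u[3:])
        assert np.array_equal(lin.values[1], u[:-3])

    def test_too_short_series_raises(self):
        with pytest.raises(SeriesLengthError):
            build_linear_features(_ds([1.0, 2]), FeatureConfig(n_delays=4))

    @pytest.mark.parametrize("bad", [dict(n_delays=0), dict(spacing=0), dict(poly_order=0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            FeatureConfig(**bad)


class TestNonlinearFeatures:
    def test_order_one_gives_empty_block(self):
        lin = FeatureMatrix(values=np.ones((3, 5)), valid_times=np.arange(5))
        assert build_nonlinear_features(lin, 1).values.shape == (0, 5)

    def test_quadratic_monomials_by_enumeration(self):
        lin = FeatureMatrix(values=np.array([[2.0], [3.0]]), valid_times=[0])
        nlin = build_nonlinear_features(lin, 2)
        assert np.array_equal(nlin.values.ravel(), [4, 6, 9])  # a^2, ab, b^2

    def test_cubic_matches_brute_force(self, rng):
        vals = rng.standard_normal((3, 7))
        lin = FeatureMatrix(values=vals, valid_times=np.arange(7))
        nlin = build_nonlinear_features(lin, 3)
        import itertools

        expect = [
            np.prod(vals[list(c)], axis=0)
            for deg in (2, 3)
            for c in itertools.combinations_with_replacement(range(3), deg)
        ]
        assert np.allclose(nlin.values, expect)

    @pytest.mark.parametrize("d_lin", [1, 2, 5])
    def test_quadratic_row_count(self, rng, d_lin):
        lin = FeatureMatrix(values=rng.standard_normal((d_lin, 4)), valid_times=np.arange(4))
        assert build_nonlinear_features(lin, 2).d == d_lin * (d_lin + 1) // 2


class TestAssembly:
    def test_stacks_constant_linear_nonlinear(self):
        ds = _ds([1.0, 2, 3, 4])
        cfg = FeatureConfig(n_delays=2, poly_order=2)
        tot = build_features(ds, cfg)
        assert np.array_equal(tot.values[:, -1], [1, 4, 3, 16, 12, 9])
        assert tot.blocks == {"constant": (0, 1), "linear": (1, 3), "nonlinear": (3, 6)}

    def test_constant_toggle_changes_dimension_only(self, rng):
        ds = _ds(rng.standard_normal((2, 15)))
        on = build_features(ds, FeatureConfig(poly_order=2, include_constant=True))
        off = build_features(ds, FeatureConfig(poly_order=2, include_constant=False))
        assert on.d == off.d + 1
        assert np.allclose(on.values[1:], off.values)

    def test_all_zero_input_gives_unit_constant_column(self):
        tot = build_features(_ds(np.zeros((2, 6))), FeatureConfig())
        expect = np.zeros(tot.d)
        expect[0] = 1.0
        assert np.allclose(tot.values, expect[:, None])

    def test_column_mismatch_raises(self):
        lin = FeatureMatrix(values=np.ones((2, 5)), valid_times=np.arange(5))
        nlin = FeatureMatrix(values=np.ones((3, 4)), valid_times=np.arange(4))
        with pytest.raises(AlignmentError):
            assemble_total_features(lin, nlin, FeatureConfig())


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    m=st.integers(1, 3),
    k=st.integers(1, 3),
    s=st.integers(1, 2),
    p=st.integers(1, 3),
    const=st.booleans(),
)
def test_dimension_formula_exhaustive(m, k, s, p, const):
    """d = const + M*k + (number of degree-2..p monomials over M*k variables)."""
    cfg = FeatureConfig(n_delays=k, spacing=s, poly_order=p, include_constant=const)
    n = s * (k - 1) + 5
    u = np.random.default_rng(0).standard_normal((m, n))
    tot = build_features(_ds(u), cfg)
    assert tot.d == feature_dimension(m, cfg) == int(const) + m * k + n_monomials(p, m * k)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(t_perturb=st.integers(0, 19), k=st.integers(1, 3), p=st.integers(1, 2))
def test_causality_future_perturbation_never_leaks_backward(t_perturb, k, p):
    """Changing u at time t+1 must leave all feature columns at times <= t intact."""
    cfg = FeatureConfig(n_delays=k, poly_order=p)
    rng = np.random.default_rng(7)
    u = rng.standard_normal((2, 20))
    base = build_features(_ds(u), cfg)
    u2 = u.copy()
    u2[:, t_perturb] += 5.0
    pert = build_features(_ds(u2), cfg)
    before = base.valid_times < t_perturb
    assert np.array_equal(base.values[:, before], pert.values[:, before])


def test_feature_construction_bit_identical(rng):
    u = rng.standard_normal((3, 30))
    cfg = FeatureConfig(n_delays=2, poly_order=3)
    a = build_features(_ds(u), cfg)
    b = build_features(_ds(u.copy()), cfg)
    assert np.array_equal(a.values, b.values)
    assert a.feature_names == b.feature_names


class TestFeaturizerEstimator:
    def test_transform_matches_functional_path(self, rng):
        X = rng.standard_normal((25, 2))
        fz = NGRCFeaturizer(n_delays=2, poly_order=2).fit(X)
        fm = build_features(_ds(X.T), FeatureConfig(n_delays=2, poly_order=2))
        assert np.allclose(fz.transform(X), fm.values.T)
        assert fz.d_ == fm.d
        assert list(fz.get_feature_names_out()) == fm.feature_names

    def test_sklearn_clone_and_params_roundtrip(self):
        from sklearn.base import clone

        fz = NGRCFeaturizer(n_delays=3, spacing=2, poly_order=1, include_constant=False)
        assert clone(fz).get_params() == fz.get_params()
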