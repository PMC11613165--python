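"""Output-weight training: batch ridge solve and exact online block updates.

With features H (d x n) and targets Y (L x n), the readout solves

    min_W ||Y - W H||_F^2 + lambda2 ||W||_F^2
    W = Y H^T (H H^T + lambda2 I)^{-1}

Online updating keeps Phi = T^{-1} with T the regularized Gram of all data
seen so far.  When a block H_b of n_b new columns arrives, the Woodbury
matrix identity gives an exact rank-n_b update,

    Phi'  = Phi - Phi H_b (I + H_b^T Phi H_b)^{-1} H_b^T Phi
    W'    = W + (Y_b - W H_b) H_b^T Phi'

so the streamed solution is mathematically identical to refitting on the
concatenation of every block (with the ridge baked into the initial T0).
The inner inverse is applied through a linear solve and Phi is
re-symmetrized after every update to keep recursive round-off in check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, MultiOutputMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix, NGRCFeaturizer
from .exceptions import AlignmentError, ConditioningError, ConfigurationError

__all__ = [
    "OutputWeights",
    "OnlineState",
    "fit_batch",
    "init_online_state",
    "update_online",
    "predict",
    "NGRCRegressor",
    "OnlineNGRCRegressor",
]

# 1/cond above which a Gram matrix is treated as numerically singular
_RCOND_FLOOR = 1e-13


@dataclass
class OutputWeights:
    """Linear readout W (L x d) with the ridge it was fit at."""

    W: np.ndarray
    ridge: float = 0.0
    feature_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if not np.all(np.isfinite(self.W)):
            raise ConfigurationError("output weights contain non-finite entries")


@dataclass
class OnlineState:
    """Current readout W plus Phi = (Gram + ridge I)^{-1} for exact updates."""

    W: np.ndarray
    Phi: np.ndarray
    n_seen: int
    ridge: float = 0.0

    def copy(self) -> "OnlineState":
        return OnlineState(self.W.copy(), self.Phi.copy(), self.n_seen, self.ridge)


def _as_matrix(H) -> np.ndarray:
    if isinstance(H, FeatureMatrix):
        return H.values
    return np.atleast_2d(np.asarray(H, dtype=float))


def _check_aligned(H: np.ndarray, Y: np.ndarray) -> None:
    if H.shape[1] != Y.shape[1]:
        raise AlignmentError(
            f"features have {H.shape[1]} columns but targets have {Y.shape[1]}"
        )


def _solve_gram(G: np.ndarray, B: np.ndarray, ridge: float) -> np.ndarray:
    """Solve G X = B for symmetric positive (semi)definite G, loudly refusing
    numerically singular systems."""
    try:
        c, low = scipy.linalg.cho_factor(G, check_finite=False)
        x = scipy.linalg.cho_solve((c, low), B, check_finite=False)
    except scipy.linalg.LinAlgError as err:
        raise ConditioningError(
            "Gram matrix is singular; increase the ridge penalty (lambda2 > 0) "
            "or supply more initial samples than features"
        ) from err
    # Cholesky can succeed on barely-positive matrices; reject those too.
    diag = np.diag(c)
    rcond = (diag.min() / diag.max()) ** 2
    if not np.isfinite(rcond) or rcond < _RCOND_FLOOR:
        raise ConditioningError(
            f"Gram matrix is numerically singular (rcond ~ {rcond:.2e}); "
            "increase the ridge penalty (lambda2 > 0)"
        )
    return x


def fit_batch(H, Y, ridge: float = 0.0) -> OutputWeights:
    """Ridge (or, at ridge=0, ordinary) least-squares readout W = Y H^T (H H^T + ridge I)^{-1}.

    Parameters
    ----------
    H : FeatureMatrix or ndarray (d, n)
    Y : ndarray (L, n) or (n,)
    ridge : float
        lambda2 >= 0.  Zero reproduces the plain normal-equation solution and
        raises :class:`ConditioningError` when the Gram is singular.
    """
    if ridge < 0:
        raise ConfigurationError("ridge must be >= 0")
    blocks = H.blocks if isinstance(H, FeatureMatrix) else {}
    names = H.feature_names if isinstance(H, FeatureMatrix) else []
    Hm = _as_matrix(H)
    Ym = np.atleast_2d(np.asarray(Y, dtype=float))
    _check_aligned(Hm, Ym)
    d = Hm.shape[0]
    G = Hm @ Hm.T + ridge * np.eye(d)
    W = _solve_gram(G, Hm @ Ym.T, ridge).T
    return OutputWeights(W=W, ridge=ridge, feature_blocks=dict(blocks), feature_names=list(names))


def init_online_state(H0, Y0, ridge: float = 0.0) -> OnlineState:
    """Initial online state: Phi = (H0 H0^T + ridge I)^{-1}, W = batch solution."""
    if ridge < 0:
        raise ConfigurationError("ridge must be >= 0")
    Hm = _as_matrix(H0)
    Ym = np.atleast_2d(np.asarray(Y0, dtype=float))
    _check_aligned(Hm, Ym)
    d = Hm.shape[0]
    T0 = Hm @ Hm.T + ridge * np.eye(d)
    Phi = _solve_gram(T0, np.eye(d), ridge)
    Phi = (Phi + Phi.T) / 2.0
    W = (Ym @ Hm.T) @ Phi
    return OnlineState(W=W, Phi=Phi, n_seen=Hm.shape[1], ridge=ridge)


def update_online(state: OnlineState, H_block, Y_block) -> OnlineState:
    """Exact Woodbury rank-update of the online state with one new block.

    Returns a new state; the input state is not mutated.  The result equals
    the batch ridge fit on all columns seen so far, up to floating-point
    round-off.
    """
    Hb = _as_matrix(H_block)
    Yb = np.atleast_2d(np.asarray(Y_block, dtype=float))
    _check_aligned(Hb, Yb)
    if Hb.shape[0] != state.Phi.shape[0]:
        raise AlignmentError(
            f"block has {Hb.shape[0]} features, state expects {state.Phi.shape[0]}"
        )
    if Yb.shape[0] != state.W.shape[0]:
        raise AlignmentError(
            f"block has {Yb.shape[0]} targets, state expects {state.W.shape[0]}"
        )
    nb = Hb.shape[1]
    if nb < 1:
        raise AlignmentError("update block must contain at least one sample")
    PhiH = state.Phi @ Hb                       # d x nb
    S = np.eye(nb) + Hb.T @ PhiH                # small inner system
    Phi_new = state.Phi - PhiH @ np.linalg.solve(S, PhiH.T)
    Phi_new = (Phi_new + Phi_new.T) / 2.0
    W_new = state.W + (Yb - state.W @ Hb) @ (Hb.T @ Phi_new)
    if not (np.all(np.isfinite(Phi_new)) and np.all(np.isfinite(W_new))):
        raise ConditioningError(
            "non-finite values during online update; the running Gram has "
            "become ill-conditioned (consider a larger ridge or larger blocks)"
        )
    return OnlineState(W=W_new, Phi=Phi_new, n_seen=state.n_seen + nb, ridge=state.ridge)


def predict(W, H) -> np.ndarray:
    """Readout predictions Y_hat = W H, shape (L, n_valid)."""
    Wm = W.W if isinstance(W, OutputWeights) else np.atleast_2d(np.asarray(W, dtype=float))
    Hm = _as_matrix(H)
    if Wm.shape[1] != Hm.shape[0]:
        raise AlignmentError(
            f"weights expect {Wm.shape[1]} features, features have {Hm.shape[0]}"
        )
    return Wm @ Hm


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise AlignmentError("X must be 2-D (time points x variables)")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != X.shape[0]:
        raise AlignmentError(
            f"X has {X.shape[0]} time points but y has {y.shape[0]}"
        )
    return X, y


class NGRCRegressor(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """Batch-trained NG-RC soft sensor (sklearn estimator).

    Builds the NG-RC feature library from chronologically ordered rows of
    ``X`` and fits the linear readout by ridge least squares.  Because the
    delay embedding consumes ``spacing*(n_delays-1)`` warm-up rows,
    :meth:`predict` returns one row per valid time point, i.e.
    ``len(X) - warmup_`` rows; pass ``y`` aligned with the rows of ``X`` and
    the warm-up targets are trimmed internally.

    Parameters
    ----------
    n_delays, spacing, poly_order, include_constant :
        Feature-library settings, see :class:`~ensorc.features.NGRCFeaturizer`.
    ridge : float, default=1e-6
        Readout regularization lambda2.

    Attributes
    ----------
    coef_ : ndarray (n_targets, d)
        Fitted readout weights.
    featurizer_ : NGRCFeaturizer
    warmup_ : int
    """

    def __init__(
        self,
        n_delays: int = 2,
        spacing: int = 1,
        poly_order: int = 2,
        include_constant: bool = True,
        ridge: float = 1e-6,
    ):
        self.n_delays = n_delays
        self.spacing = spacing
        self.poly_order = poly_order
        self.include_constant = include_constant
        self.ridge = ridge

    def _make_featurizer(self) -> NGRCFeaturizer:
        return NGRCFeaturizer(
            n_delays=self.n_delays,
            spacing=self.spacing,
            poly_order=self.poly_order,
            include_constant=self.include_constant,
        )

    def fit(self, X, y) -> "NGRCRegressor":
        X, y = _validate_xy(X, y)
        self.featurizer_ = self._make_featurizer().fit(X)
        self.warmup_ = self.featurizer_.warmup_
        self.n_features_in_ = X.shape[1]
        fm = self.featurizer_.transform_matrix(X)
        Y = y[fm.valid_times].T
        self.weights_ = fit_batch(fm, Y, ridge=self.ridge)
        self.coef_ = self.weights_.W
        self.n_targets_ = Y.shape[0]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        fm = self.featurizer_.transform_matrix(np.asarray(X, dtype=float))
        out = predict(self.coef_, fm).T
        return out[:, 0] if self.n_targets_ == 1 else out


class OnlineNGRCRegressor(NGRCRegressor):
    """NG-RC soft sensor with exact online (streaming) weight updates.

    :meth:`fit` initializes from an initial window; :meth:`partial_fit`
    folds in each newly measured block with the Woodbury recursion, which
    keeps the weights identical (to round-off) to a batch refit on all data
    seen.  A short tail of raw samples is buffered so the delay embedding
    of a new block can reach back across the block boundary.
    """

    def fit(self, X, y) -> "OnlineNGRCRegressor":
        X, y = _validate_xy(X, y)
        self.featurizer_ = self._make_featurizer().fit(X)
        self.warmup_ = self.featurizer_.warmup_
        self.n_features_in_ = X.shape[1]
        fm = self.featurizer_.transform_matrix(X)
        Y = y[fm.valid_times].T
        self.state_ = init_online_state(fm, Y, ridge=self.ridge)
        self.n_targets_ = Y.shape[0]
        self._tail_X = X[X.shape[0] - self.warmup_ :] if self.warmup_ else X[:0]
        return self

    def partial_fit(self, X, y) -> "OnlineNGRCRegressor":
        check_is_fitted(self, "state_")
        X, y = _validate_xy(X, y)
        if y.shape[1] != self.n_targets_:
            raise AlignmentError(
                f"block has {y.shape[1]} targets, model expects {self.n_targets_}"
            )
        ctx = np.vstack([self._tail_X, X])
        fm = self.featurizer_.transform_matrix(ctx)
        # keep only columns belonging to the new block
        new_cols = fm.valid_times >= self._tail_X.shape[0]
        Hb = fm.values[:, new_cols]
        Yb = y[fm.valid_times[new_cols] - self._tail_X.shape[0]].T
        self.state_ = update_online(self.state_, Hb, Yb)
        if self.warmup_:
            self._tail_X = ctx[ctx.shape[0] - self.warmup_ :]
        return self

    @property
    def coef_(self) -> np.ndarray:
        check_is_fitted(self, "state_")
        return self.state_.W

    @property
    def weights_(self) -> OutputWeights:
        return OutputWeights(W=self.state_.W, ridge=self.ridge)
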