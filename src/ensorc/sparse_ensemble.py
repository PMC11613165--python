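"""Sparse identification of the readout and its bagging ensemble.

The dense ridge readout of an NG-RC model is prone to overfitting when the
polynomial library is large relative to the data.  Two remedies are
composed here:

* **STLS** (sequential thresholded least squares, the SINDy workhorse):
  repeatedly zero every coefficient with |w| < lambda1 and refit each
  output row by (ridge) least squares on its surviving features.

* **Bagging**: run the dense-fit + STLS pipeline on ``q`` bootstrap
  resamples of the time points; the *inclusion probability* p_ip of a
  coefficient is the fraction of ensemble members in which it survived.
  Coefficients with p_ip below lambda3 are zeroed; the final values are a
  full-data refit restricted to the surviving support (per output row),
  which avoids the bias of averaging bootstrap coefficients.  The
  ensemble-mean alternative is available via ``coef_rule="mean"``.

``sparse_then_online`` composes ensemble sparsification with the exact
online recursion: the ensemble fit on an initial window fixes the support,
and subsequent blocks update each output row's weights *within* its
support, so the streamed row equals the restricted batch ridge solution on
all data seen (off-support entries stay structurally zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError
from .features import FeatureMatrix
from .training import (
    NGRCRegressor,
    OnlineState,
    OutputWeights,
    _as_matrix,
    _check_aligned,
    _validate_xy,
    fit_batch,
    init_online_state,
    update_online,
)

__all__ = [
    "SparsityConfig",
    "EnsembleSummary",
    "stls",
    "bootstrap_indices",
    "ensemble_sparse_fit",
    "sparse_then_online",
    "EnSOState",
    "EnsembleSparseNGRC",
    "EnSONGRC",
]


@dataclass(frozen=True)
class SparsityConfig:
    """Thresholds and ensemble settings for sparse identification.

    lambda1: hard threshold on |coefficient| inside STLS.
    lambda2: ridge penalty used for every (re)fit.
    lambda3: inclusion-probability threshold in [0, 1].
    q: number of bootstrap resamples.
    stls_iters: STLS sweep count (threshold + refit per sweep).
    coef_rule: "refit" (full-data restricted refit) or "mean"
        (ensemble mean of member coefficients).
    """

    lambda1: float = 0.1
    lambda2: float = 1e-6
    lambda3: float = 0.6
    q: int = 50
    stls_iters: int = 10
    seed: int | None = None
    coef_rule: str = "refit"

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ConfigurationError("lambda1 must be >= 0")
        if self.lambda2 < 0:
            raise ConfigurationError("lambda2 must be >= 0")
        if not 0.0 <= self.lambda3 <= 1.0:
            raise ConfigurationError("lambda3 must lie in [0, 1]")
        if self.q < 1:
            raise ConfigurationError("q must be >= 1")
        if self.stls_iters < 1:
            raise ConfigurationError("stls_iters must be >= 1")
        if self.coef_rule not in ("refit", "mean"):
            raise ConfigurationError("coef_rule must be 'refit' or 'mean'")


@dataclass
class EnsembleSummary:
    """Outcome of an ensemble sparse fit.

    W_final is zero wherever p_ip < lambda3; support_final == (W_final != 0)
    may be smaller than (p_ip >= lambda3) if a restricted refit returns an
    exact zero, which has probability zero in practice.
    """

    W_final: np.ndarray
    p_ip: np.ndarray
    member_supports: np.ndarray  # (q, L, d) boolean
    support_final: np.ndarray
    config: SparsityConfig
    feature_names: list[str] = field(default_factory=list)


def _row_restricted_fit(H: np.ndarray, Y: np.ndarray, support: np.ndarray, ridge: float) -> np.ndarray:
    """Per-row least squares restricted to each row's surviving features."""
    L, d = support.shape
    W = np.zeros((L, d))
    for j in range(L):
        active = np.flatnonzero(support[j])
        if active.size == 0:
            continue
        Wj = fit_batch(H[active], Y[j], ridge=ridge)
        W[j, active] = Wj.W[0]
    return W


def stls(H, Y, cfg: SparsityConfig) -> OutputWeights:
    """Sequential thresholded least squares on the NG-RC readout.

    Starts from the dense ridge fit; each of ``cfg.stls_iters`` sweeps
    zeroes coefficients with |w| < lambda1 and refits every output row on
    its surviving features.  A row whose support empties is returned
    all-zero with a warning rather than raising.
    """
    blocks = H.blocks if isinstance(H, FeatureMatrix) else {}
    names = H.feature_names if isinstance(H, FeatureMatrix) else []
    Hm = _as_matrix(H)
    Ym = np.atleast_2d(np.asarray(Y, dtype=float))
    _check_aligned(Hm, Ym)
    W = fit_batch(Hm, Ym, ridge=cfg.lambda2).W
    if cfg.lambda1 == 0:
        return OutputWeights(W=W, ridge=cfg.lambda2, feature_blocks=dict(blocks), feature_names=list(names))
    emptied: set[int] = set()
    for _ in range(cfg.stls_iters):
        small = np.abs(W) < cfg.lambda1
        W[small] = 0.0
        support = ~small
        for j in range(support.shape[0]):
            if support[j].sum() == 0 and j not in emptied:
                emptied.add(j)
                warnings.warn(
                    f"STLS emptied the support of output row {j}; "
                    "row returned all-zero (lambda1 may be too large)",
                    UserWarning,
                    stacklevel=2,
                )
        W = _row_restricted_fit(Hm, Ym, support, cfg.lambda2)
    return OutputWeights(W=W, ridge=cfg.lambda2, feature_blocks=dict(blocks), feature_names=list(names))


def bootstrap_indices(n: int, q: int, seed=None) -> np.ndarray:
    """q bootstrap resamples (with replacement) of range(n), shape (q, n).

    Accepts an int seed or a ``numpy.random.Generator``; a fixed seed gives
    identical resamples on every call.
    """
    if n < 1 or q < 1:
        raise ConfigurationError("n and q must both be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, n, size=(q, n))


def ensemble_sparse_fit(H, Y, cfg: SparsityConfig) -> EnsembleSummary:
    """Bagged STLS with inclusion-probability thresholding.

    For each of ``cfg.q`` bootstrap column-resamples of the time points, run
    dense fit + STLS; p_ip[j, i] is the fraction of members in which
    coefficient (j, i) is nonzero.  The final support keeps p_ip >= lambda3
    and final coefficients come from ``cfg.coef_rule``.
    """
    names = H.feature_names if isinstance(H, FeatureMatrix) else []
    Hm = _as_matrix(H)
    Ym = np.atleast_2d(np.asarray(Y, dtype=float))
    _check_aligned(Hm, Ym)
    L, d = Ym.shape[0], Hm.shape[0]
    idx = bootstrap_indices(Hm.shape[1], cfg.q, cfg.seed)
    member_supports = np.zeros((cfg.q, L, d), dtype=bool)
    member_W = np.zeros((cfg.q, L, d))
    with warnings.catch_warnings():
        # emptied-row warnings from individual members are expected noise
        warnings.simplefilter("ignore", UserWarning)
        for b in range(cfg.q):
            Wb = stls(Hm[:, idx[b]], Ym[:, idx[b]], cfg).W
            member_W[b] = Wb
            member_supports[b] = Wb != 0
    p_ip = member_supports.mean(axis=0)
    keep = p_ip >= cfg.lambda3
    if cfg.coef_rule == "mean":
        W_final = member_W.mean(axis=0)
        W_final[~keep] = 0.0
    else:
        W_final = _row_restricted_fit(Hm, Ym, keep, cfg.lambda2)
    return EnsembleSummary(
        W_final=W_final,
        p_ip=p_ip,
        member_supports=member_supports,
        support_final=W_final != 0,
        config=cfg,
        feature_names=list(names),
    )


@dataclass
class EnSOState:
    """Support-restricted online state: one reduced recursion per output row."""

    support: np.ndarray                     # (L, d) boolean, fixed between re-sparsifications
    row_states: list[OnlineState]           # reduced (d_j) states, one per output row
    d: int
    n_seen: int
    ridge: float

    @property
    def W(self) -> np.ndarray:
        W = np.zeros((self.support.shape[0], self.d))
        for j, st in enumerate(self.row_states):
            if st is not None:
                W[j, np.flatnonzero(self.support[j])] = st.W[0]
        return W

    def update(self, Hb: np.ndarray, Yb: np.ndarray) -> "EnSOState":
        rows = []
        for j, st in enumerate(self.row_states):
            if st is None:
                rows.append(None)
                continue
            active = np.flatnonzero(self.support[j])
            rows.append(update_online(st, Hb[active], Yb[j : j + 1]))
        return EnSOState(self.support, rows, self.d, self.n_seen + Hb.shape[1], self.ridge)


def _init_enso_state(Hm: np.ndarray, Ym: np.ndarray, support: np.ndarray, ridge: float) -> EnSOState:
    rows: list[OnlineState | None] = []
    for j in range(support.shape[0]):
        active = np.flatnonzero(support[j])
        rows.append(
            init_online_state(Hm[active], Ym[j : j + 1], ridge=ridge) if active.size else None
        )
    return EnSOState(support.copy(), rows, Hm.shape[0], Hm.shape[1], ridge)


def sparse_then_online(H0, Y0, blocks, cfg: SparsityConfig, resparsify_every: int | None = None):
    """EnSO schedule: ensemble-sparse fit fixes the support, online updates follow.

    Parameters
    ----------
    H0, Y0 : initial window (features d x n0, targets L x n0).
    blocks : iterable of (H_block, Y_block) pairs streamed chronologically.
    cfg : SparsityConfig.
    resparsify_every : int or None
        Re-run the ensemble sparsification on all data seen after every r
        blocks; None (default) keeps the initial support for the whole
        stream.

    Returns
    -------
    state : EnSOState with the final support-restricted weights (state.W).
    summary : EnsembleSummary of the most recent sparsification.
    """
    if resparsify_every is not None and resparsify_every < 1:
        raise ConfigurationError("resparsify_every must be >= 1 or None")
    Hm = _as_matrix(H0)
    Ym = np.atleast_2d(np.asarray(Y0, dtype=float))
    _check_aligned(Hm, Ym)
    summary = ensemble_sparse_fit(Hm, Ym, cfg)
    state = _init_enso_state(Hm, Ym, summary.p_ip >= cfg.lambda3, cfg.lambda2)
    keep_history = resparsify_every is not None
    H_all, Y_all = (Hm, Ym) if keep_history else (None, None)
    for i, (Hb, Yb) in enumerate(blocks, start=1):
        Hb = _as_matrix(Hb)
        Yb = np.atleast_2d(np.asarray(Yb, dtype=float))
        state = state.update(Hb, Yb)
        if keep_history:
            H_all = np.hstack([H_all, Hb])
            Y_all = np.hstack([Y_all, Yb])
            if i % resparsify_every == 0:
                summary = ensemble_sparse_fit(H_all, Y_all, cfg)
                state = _init_enso_state(H_all, Y_all, summary.p_ip >= cfg.lambda3, cfg.lambda2)
    return state, summary


class EnsembleSparseNGRC(NGRCRegressor):
    """Ensemble-sparse NG-RC soft sensor (batch EnS variant).

    Fits the NG-RC feature library, then replaces the dense readout by the
    bagged-STLS sparse readout with inclusion-probability thresholding.

    Additional parameters
    ---------------------
    lambda1, lambda3, q, stls_iters, coef_rule, random_state :
        See :class:`SparsityConfig`; ``ridge`` plays the role of lambda2.

    Attributes
    ----------
    coef_ : ndarray (n_targets, d), sparse.
    inclusion_proba_ : ndarray (n_targets, d)
    summary_ : EnsembleSummary
    """

    def __init__(
        self,
        n_delays: int = 2,
        spacing: int = 1,
        poly_order: int = 2,
        include_constant: bool = True,
        ridge: float = 1e-6,
        lambda1: float = 0.1,
        lambda3: float = 0.6,
        q: int = 50,
        stls_iters: int = 10,
        coef_rule: str = "refit",
        random_state: int | None = None,
    ):
        super().__init__(
            n_delays=n_delays,
            spacing=spacing,
            poly_order=poly_order,
            include_constant=include_constant,
            ridge=ridge,
        )
        self.lambda1 = lambda1
        self.lambda3 = lambda3
        self.q = q
        self.stls_iters = stls_iters
        self.coef_rule = coef_rule
        self.random_state = random_state

    def _sparsity_config(self) -> SparsityConfig:
        return SparsityConfig(
            lambda1=self.lambda1,
            lambda2=self.ridge,
            lambda3=self.lambda3,
            q=self.q,
            stls_iters=self.stls_iters,
            seed=self.random_state,
            coef_rule=self.coef_rule,
        )

    def fit(self, X, y) -> "EnsembleSparseNGRC":
        X, y = _validate_xy(X, y)
        self.featurizer_ = self._make_featurizer().fit(X)
        self.warmup_ = self.featurizer_.warmup_
        self.n_features_in_ = X.shape[1]
        fm = self.featurizer_.transform_matrix(X)
        Y = y[fm.valid_times].T
        self.summary_ = ensemble_sparse_fit(fm, Y, self._sparsity_config())
        self.coef_ = self.summary_.W_final
        self.inclusion_proba_ = self.summary_.p_ip
        self.weights_ = OutputWeights(
            W=self.coef_, ridge=self.ridge, feature_blocks=dict(fm.blocks),
            feature_names=list(fm.feature_names),
        )
        self.n_targets_ = Y.shape[0]
        return self


class EnSONGRC(EnsembleSparseNGRC):
    """Ensemble sparse *online* NG-RC soft sensor (the EnSO composition).

    :meth:`fit` runs the ensemble sparsification on the initial window,
    fixing the support; :meth:`partial_fit` streams new blocks through the
    exact online recursion restricted to that support, so each output row
    tracks the batch ridge solution on its surviving features.  Set
    ``resparsify_every=r`` to re-run the ensemble sparsification on all
    data seen after every r blocks.
    """

    def __init__(
        self,
        n_delays: int = 2,
        spacing: int = 1,
        poly_order: int = 2,
        include_constant: bool = True,
        ridge: float = 1e-6,
        lambda1: float = 0.1,
        lambda3: float = 0.6,
        q: int = 50,
        stls_iters: int = 10,
        coef_rule: str = "refit",
        random_state: int | None = None,
        resparsify_every: int | None = None,
    ):
        super().__init__(
            n_delays=n_delays,
            spacing=spacing,
            poly_order=poly_order,
            include_constant=include_constant,
            ridge=ridge,
            lambda1=lambda1,
            lambda3=lambda3,
            q=q,
            stls_iters=stls_iters,
            coef_rule=coef_rule,
            random_state=random_state,
        )
        self.resparsify_every = resparsify_every

    def fit(self, X, y) -> "EnSONGRC":
        X, y = _validate_xy(X, y)
        self.featurizer_ = self._make_featurizer().fit(X)
        self.warmup_ = self.featurizer_.warmup_
        self.n_features_in_ = X.shape[1]
        fm = self.featurizer_.transform_matrix(X)
        Y = y[fm.valid_times].T
        cfg = self._sparsity_config()
        self.summary_ = ensemble_sparse_fit(fm, Y, cfg)
        support = self.summary_.p_ip >= cfg.lambda3
        self.state_ = _init_enso_state(fm.values, Y, support, cfg.lambda2)
        self.inclusion_proba_ = self.summary_.p_ip
        self.n_targets_ = Y.shape[0]
        self._tail_X = X[X.shape[0] - self.warmup_ :] if self.warmup_ else X[:0]
        self._blocks_seen = 0
        if self.resparsify_every is not None:
            self._H_all, self._Y_all = fm.values, Y
        return self

    def partial_fit(self, X, y) -> "EnSONGRC":
        check_is_fitted(self, "state_")
        X, y = _validate_xy(X, y)
        ctx = np.vstack([self._tail_X, X])
        fm = self.featurizer_.transform_matrix(ctx)
        new_cols = fm.valid_times >= self._tail_X.shape[0]
        Hb = fm.values[:, new_cols]
        Yb = y[fm.valid_times[new_cols] - self._tail_X.shape[0]].T
        self.state_ = self.state_.update(Hb, Yb)
        if self.warmup_:
            self._tail_X = ctx[ctx.shape[0] - self.warmup_ :]
        self._blocks_seen += 1
        if self.resparsify_every is not None:
            self._H_all = np.hstack([self._H_all, Hb])
            self._Y_all = np.hstack([self._Y_all, Yb])
            if self._blocks_seen % self.resparsify_every == 0:
                cfg = self._sparsity_config()
                self.summary_ = ensemble_sparse_fit(self._H_all, self._Y_all, cfg)
                self.state_ = _init_enso_state(
                    self._H_all, self._Y_all, self.summary_.p_ip >= cfg.lambda3, cfg.lambda2
                )
                self.inclusion_proba_ = self.summary_.p_ip
        return self

    @property
    def coef_(self) -> np.ndarray:
        check_is_fitted(self, "state_")
        return self.state_.W
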