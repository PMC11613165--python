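"""Preprocessing and auxiliary-variable selection for soft-sensor data.

Sensor series from treatment plants carry spikes (sampling and transmission
faults), wildly different physical scales, and slow trends.  The pipeline
therefore offers

* Hampel outlier filtering (rolling median / MAD),
* train-span standardization (fitted statistics reused on the test span),
* lag differencing with exact inversion,

and two complementary relevance screens for choosing auxiliary variables:
PLS-based VIP scores and LASSO selection, combined with a domain list.
All fitting uses the training span only; nothing is estimated from test
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "detect_outliers",
    "Scaler",
    "fit_standardizer",
    "TimeDifferencer",
    "time_difference",
    "vip_scores",
    "lasso_select",
    "SelectionReport",
    "select_auxiliary",
]

# consistency factor making the MAD estimate sigma for Gaussian data
_MAD_TO_SIGMA = 1.4826


def detect_outliers(series, window: int = 7, n_sigmas: float = 3.0):
    """Hampel filter: flag and replace spikes against a rolling median.

    A point is flagged when |x - med| > n_sigmas * 1.4826 * MAD, both
    statistics taken over a centered window of ``window`` samples (edges use
    the partial window).  Flagged points are replaced by the rolling median.
    Windows with MAD = 0 (locally constant signal) flag nothing.

    Returns
    -------
    mask : boolean ndarray, True where a point was flagged.
    cleaned : ndarray with flagged points replaced.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    x = pd.Series(np.asarray(series, dtype=float))
    roll = x.rolling(window, center=True, min_periods=1)
    med = roll.median()
    mad = roll.apply(lambda v: np.median(np.abs(v - np.median(v))), raw=True)
    dev = (x - med).abs()
    mask = (mad > 0) & (dev > n_sigmas * _MAD_TO_SIGMA * mad)
    cleaned = x.where(~mask, med)
    return mask.to_numpy(), cleaned.to_numpy()


@dataclass
class Scaler:
    """Per-variable center/scale learned on the training span only."""

    center: np.ndarray
    scale: np.ndarray
    names: list[str] = field(default_factory=list)

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def inverse_transform(self, Z) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.center

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "names": list(self.names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(np.asarray(d["center"]), np.asarray(d["scale"]), list(d.get("names", [])))


def fit_standardizer(train, names: list[str] | None = None) -> Scaler:
    """Fit zero-mean unit-variance scaling on training rows (samples x variables)."""
    X = np.atleast_2d(np.asarray(train, dtype=float))
    ss = StandardScaler().fit(X)
    scale = np.asarray(ss.scale_, dtype=float)
    names = list(names) if names else [f"x{i + 1}" for i in range(X.shape[1])]
    zero = np.flatnonzero(np.asarray(ss.var_) <= 0)
    if zero.size:
        bad = ", ".join(names[i] for i in zero)
        raise DegenerateDataError(
            f"zero variance on the training span for variable(s): {bad}"
        )
    return Scaler(center=np.asarray(ss.mean_, dtype=float), scale=scale, names=names)


class TimeDifferencer:
    """Lag differencing x'_t = x_t - x_{t-lag}, invertible via stored initials."""

    def __init__(self, lag: int = 1):
        if lag < 1:
            raise ConfigurationError("lag must be >= 1")
        self.lag = lag

    def transform(self, X):
        """Difference rows (samples x variables); output has n - lag rows."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= self.lag:
            raise ConfigurationError(f"need more than lag={self.lag} samples, got {n}")
        self.initial_ = X[: self.lag].copy()
        return X[self.lag :] - X[: n - self.lag]

    def inverse_transform(self, D, initial=None):
        """Cumulatively re-integrate; ``initial`` defaults to the stored rows."""
        D = np.asarray(D, dtype=float)
        init = np.asarray(self.initial_ if initial is None else initial, dtype=float)
        out = np.concatenate([init, np.empty_like(D)], axis=0)
        for t in range(D.shape[0]):
            out[self.lag + t] = D[t] + out[t]
        return out


def time_difference(series, lag: int = 1):
    """Functional form of :class:`TimeDifferencer`; returns (differenced, initials)."""
    td = TimeDifferencer(lag)
    d = td.transform(series)
    return d, td.initial_


def _loo_press(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    """Leave-one-out squared prediction error of a PLS fit."""
    n = X.shape[0]
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[keep], y[keep])
        press += float(np.sum((y[i] - pls.predict(X[i : i + 1])[0]) ** 2))
    return press


def vip_scores(X, y, n_components: int | None = None) -> np.ndarray:
    """Variable importance in projection from a PLS regression.

    VIP_j aggregates, over PLS components, the share of explained target
    variance attributed to predictor j; by construction mean(VIP^2) = 1, so
    VIP > 1 marks above-average relevance.  ``n_components=None`` picks the
    component count minimizing leave-one-out prediction error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    p = X.shape[1]
    max_comp = min(p, X.shape[0] - 1)
    if max_comp < 1:
        raise DegenerateDataError("not enough samples for a PLS fit")
    if np.allclose(np.std(y, axis=0), 0) or np.allclose(np.std(X, axis=0), 0):
        raise DegenerateDataError("degenerate PLS: zero-variance inputs or target")
    if n_components is None:
        errs = [_loo_press(X, y, a) for a in range(1, max_comp + 1)]
        n_components = int(np.argmin(errs)) + 1
    if n_components > max_comp:
        raise ConfigurationError(
            f"n_components={n_components} exceeds the usable rank {max_comp}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    Wmat = pls.x_weights_                      # (p, A)
    T = pls.x_scores_                          # (n, A)
    Q = pls.y_loadings_                        # (L, A)
    ssy = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)   # variance explained per component
    if ssy.sum() <= 0:
        raise DegenerateDataError("degenerate PLS: no explained target variance")
    wnorm2 = np.sum(Wmat**2, axis=0)
    vip = np.sqrt(p * (Wmat**2 / wnorm2) @ ssy / ssy.sum())
    return vip


def lasso_select(
    X,
    y,
    penalty_grid=None,
    cv_folds: int = 5,
    seed: int | None = None,
    alpha_rule: str = "1se",
    rel_tol: float = 0.05,
):
    """LASSO variable selection at a cross-validated penalty.

    The penalty is chosen by K-fold CV: ``alpha_rule="min"`` takes the
    CV-error minimizer; the default ``"1se"`` takes the largest penalty
    whose CV error is within one standard error of the minimum (the usual
    parsimony rule — the CV minimizer of the lasso notoriously over-selects).
    Selection then keeps coefficients above ``rel_tol`` times the largest
    |coefficient| (thresholded lasso: prunes the barely-nonzero remnants of
    L1 shrinkage near the selection boundary).  A penalty of exactly 0
    falls back to ordinary least squares, where no shrinkage remnants exist
    and every variable is selected (n > p).

    Returns ``(selected, path)``: the sorted index list at the chosen
    penalty and a DataFrame with one row per penalty on the grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < cv_folds:
        raise ConfigurationError(
            f"need at least cv_folds={cv_folds} samples, got {X.shape[0]}"
        )
    if alpha_rule not in ("min", "1se"):
        raise ConfigurationError("alpha_rule must be 'min' or '1se'")
    if penalty_grid is not None:
        penalty_grid = np.asarray(penalty_grid, dtype=float)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    def _coefs(alpha: float) -> np.ndarray:
        if alpha == 0:
            return LinearRegression().fit(X, y).coef_
        return Lasso(alpha=alpha, max_iter=50_000).fit(X, y).coef_

    def _select(alpha: float) -> list[int]:
        coef = np.abs(_coefs(alpha))
        if alpha == 0:
            return np.flatnonzero(coef > 0).tolist()
        if coef.max() == 0:
            return []
        return np.flatnonzero(coef > rel_tol * coef.max()).tolist()

    if penalty_grid is not None and len(penalty_grid) == 1:
        best_alpha = float(penalty_grid[0])
    else:
        kwargs = {} if penalty_grid is None else {"alphas": penalty_grid}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lcv = LassoCV(cv=cv, max_iter=50_000, random_state=seed, **kwargs)
            lcv.fit(X, y)
        if alpha_rule == "min":
            best_alpha = float(lcv.alpha_)
        else:
            mse = lcv.mse_path_.mean(axis=1)
            se = lcv.mse_path_.std(axis=1) / np.sqrt(lcv.mse_path_.shape[1])
            i = int(mse.argmin())
            best_alpha = float(lcv.alphas_[mse <= mse[i] + se[i]].max())
        if penalty_grid is None:
            penalty_grid = lcv.alphas_
    rows = []
    for alpha in np.sort(np.asarray(penalty_grid, dtype=float))[::-1]:
        sel = _select(float(alpha))
        rows.append({"penalty": float(alpha), "n_selected": len(sel), "selected": sel})
    path = pd.DataFrame(rows)
    return sorted(_select(best_alpha)), path


@dataclass
class SelectionReport:
    """Audit record of auxiliary-variable selection."""

    vip: dict[str, float]
    lasso_selected: list[str]
    domain_list: list[str]
    rule: str
    final_selected: list[str]
    lasso_path: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "vip": {k: float(v) for k, v in self.vip.items()},
            "lasso_selected": list(self.lasso_selected),
            "domain_list": list(self.domain_list),
            "rule": self.rule,
            "final_selected": list(self.final_selected),
        }


def select_auxiliary(
    vip: dict[str, float],
    lasso_selected: list[str],
    domain_list: list[str] | None = None,
    rule: str = "union",
    target_count: int | None = None,
    vip_threshold: float = 1.0,
) -> SelectionReport:
    """Combine VIP, LASSO and domain knowledge into a final variable set.

    rule="union": variables with VIP > vip_threshold OR LASSO-selected.
    rule="intersection": in both sets.
    rule="rank-merge": rank by VIP, keep the top ``target_count``.
    Domain-list variables are always retained.  ``target_count`` trims the
    result to a fixed cardinality by descending VIP (domain variables are
    never trimmed).
    """
    if rule not in ("union", "intersection", "rank-merge"):
        raise ConfigurationError(f"unknown rule {rule!r}")
    domain_list = list(domain_list or [])
    candidates = list(vip.keys())
    unknown = [v for v in list(lasso_selected) + domain_list if v not in candidates]
    if unknown:
        raise ConfigurationError(f"names outside the candidate set: {unknown}")
    vip_set = [v for v in candidates if vip[v] > vip_threshold]
    if rule == "union":
        chosen = [v for v in candidates if v in vip_set or v in lasso_selected]
    elif rule == "intersection":
        chosen = [v for v in candidates if v in vip_set and v in lasso_selected]
    else:  # rank-merge
        k = target_count if target_count is not None else max(len(vip_set), 1)
        chosen = sorted(candidates, key=lambda v: -vip[v])[:k]
    final = list(dict.fromkeys(domain_list + chosen))
    if target_count is not None and len(final) > target_count:
        trimmable = sorted(
            (v for v in final if v not in domain_list), key=lambda v: -vip[v]
        )
        final = list(dict.fromkeys(domain_list + trimmable))[:target_count]
    # keep candidate order for reproducibility of reports
    final = [v for v in candidates if v in final]
    if not final:
        raise ConfigurationError(
            "selection produced an empty set; relax the rule or supply a domain list"
        )
    return SelectionReport(
        vip={k: float(v) for k, v in vip.items()},
        lasso_selected=list(lasso_selected),
        domain_list=domain_list,
        rule=rule,
        final_selected=final,
    )
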