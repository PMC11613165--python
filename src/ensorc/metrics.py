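"""Prediction-quality metrics for multi-output soft sensors.

Per-target MAE, RMSE and Pearson correlation, the overall RMSSD

    RMSSD = sqrt( trace((Y - Yhat)^T (Y - Yhat)) / n_test ),

which collapses to RMSE for a single target and satisfies
RMSSD^2 = sum_targets RMSE^2, plus the statistics behind Taylor diagrams
(reference/prediction standard deviation, correlation, centered RMSE with
cRMSE^2 = s_ref^2 + s_pred^2 - 2 s_ref s_pred rho) and Tukey box-plot
summaries of the absolute errors.  Standard deviations and correlations use
the sample (n-1) normalization throughout so the Taylor identity holds
exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConfigurationError

__all__ = [
    "rmssd",
    "basic_metrics",
    "taylor_stats",
    "ae_summary",
    "EvalReport",
    "evaluate",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise AlignmentError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def rmssd(Y, Yhat) -> float:
    """Overall multi-output error sqrt(trace(E^T E) / n_test), E = Y - Yhat."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    if Y.shape != Yhat.shape:
        raise AlignmentError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    if Y.shape[1] < 1:
        raise ConfigurationError("need at least one test sample")
    E = Y - Yhat
    return float(np.sqrt(np.trace(E.T @ E) / Y.shape[1]))


def basic_metrics(y, yhat) -> dict[str, float]:
    """MAE, RMSE and Pearson correlation for one target series.

    PCC on a zero-variance series is undefined; it is reported as NaN with
    a warning instead of an arbitrary value.
    """
    y, yhat = _pair(y, yhat)
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if y.size < 2 or np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("PCC undefined for constant series; reported as NaN", UserWarning)
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(y, yhat).statistic)
    return {"mae": mae, "rmse": rmse, "pcc": pcc}


def taylor_stats(y, yhat) -> dict[str, float]:
    """Taylor-diagram triple plus centered RMSE (all with ddof=1)."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ConfigurationError("need at least two samples")
    s_ref = float(np.std(y, ddof=1))
    s_pred = float(np.std(yhat, ddof=1))
    if s_ref == 0 or s_pred == 0:
        warnings.warn("correlation undefined for constant series", UserWarning)
        rho = float("nan")
    else:
        rho = float(stats.pearsonr(y, yhat).statistic)
    e = (yhat - yhat.mean()) - (y - y.mean())
    crmse = float(np.sqrt(np.sum(e**2) / (y.size - 1)))
    return {"sigma_ref": s_ref, "sigma_pred": s_pred, "pcc": rho, "crmse": crmse}


def ae_summary(y, yhat) -> dict[str, float]:
    """Tukey box-plot statistics of the absolute errors |y - yhat|.

    Whiskers extend to the most extreme points within 1.5 IQR of the
    quartiles; everything beyond is counted as an outlier.
    """
    y, yhat = _pair(y, yhat)
    ae = np.abs(y - yhat)
    q1, med, q3 = np.percentile(ae, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = ae[(ae >= lo_fence) & (ae <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if inside.size else float(q1),
        "whisker_high": float(inside.max()) if inside.size else float(q3),
        "n_outliers": int(np.sum((ae < lo_fence) | (ae > hi_fence))),
    }


@dataclass
class EvalReport:
    """Full evaluation of one model on one test span (original scale)."""

    target_names: list[str]
    per_target: dict[str, dict[str, float]]
    taylor: dict[str, dict[str, float]]
    ae: dict[str, dict[str, float]]
    rmssd: float
    n_test: int
    scale: str = "original"
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per target with MAE/RMSE/PCC and the shared RMSSD."""
        rows = []
        for name in self.target_names:
            row = {"target": name, **self.per_target[name], "rmssd": self.rmssd}
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "target_names": list(self.target_names),
            "per_target": self.per_target,
            "taylor": self.taylor,
            "ae": self.ae,
            "rmssd": self.rmssd,
            "n_test": self.n_test,
            "scale": self.scale,
            "extra": self.extra,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate(Y, Yhat, target_names: list[str] | None = None, scale: str = "original") -> EvalReport:
    """Assemble an :class:`EvalReport` from true and predicted target matrices (L x n)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    if Y.shape != Yhat.shape:
        raise AlignmentError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    names = target_names or [f"y{i + 1}" for i in range(Y.shape[0])]
    per_target = {n: basic_metrics(Y[i], Yhat[i]) for i, n in enumerate(names)}
    taylor = {n: taylor_stats(Y[i], Yhat[i]) for i, n in enumerate(names)}
    ae = {n: ae_summary(Y[i], Yhat[i]) for i, n in enumerate(names)}
    return EvalReport(
        target_names=list(names),
        per_target=per_target,
        taylor=taylor,
        ae=ae,
        rmssd=rmssd(Y, Yhat),
        n_test=Y.shape[1],
        scale=scale,
    )
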