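"""End-to-end soft-sensor workflow.

``run_pipeline`` executes the full chain on one dataset: chronological
train/test split, train-span-fitted preprocessing (Hampel outlier cleaning,
optional lag differencing, standardization), optional auxiliary-variable
selection, NG-RC feature construction, one of four model variants

* ``ngrc``   — batch ridge readout,
* ``online`` — same model with exact Woodbury updates while the test
  stream arrives (when ``adapt_on_test``),
* ``ens``    — ensemble-sparse (bagged STLS) readout,
* ``enso``   — ensemble-sparse support + online updates on the stream,

then chronological test prediction (online variants predict each block
*before* folding its true targets in) and metric computation on the
original physical scale.  Every stage that estimates parameters sees the
training span only; everything downstream of the split is causal, so test
predictions at time t never use samples after t.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datasets import TimeSeriesDataset
from .exceptions import ConfigurationError, EnsorcError
from .features import FeatureConfig, build_features
from .metrics import EvalReport, evaluate
from .preprocessing import (
    Scaler,
    detect_outliers,
    fit_standardizer,
    lasso_select,
    select_auxiliary,
    vip_scores,
)
from .sparse_ensemble import (
    EnSOState,
    SparsityConfig,
    _init_enso_state,
    ensemble_sparse_fit,
)
from .synthetic import SyntheticSpec, generate
from .training import fit_batch, init_online_state, update_online

__all__ = ["PreprocessConfig", "SelectionConfig", "PipelineConfig", "run_pipeline", "compare_variants"]

VARIANTS = ("ngrc", "online", "ens", "enso")


@dataclass(frozen=True)
class PreprocessConfig:
    clean_outliers: bool = True
    outlier_window: int = 7
    outlier_n_sigmas: float = 3.0
    difference_lag: int | None = None
    standardize: bool = True


@dataclass(frozen=True)
class SelectionConfig:
    enabled: bool = False
    rule: str = "union"
    target_count: int | None = None
    domain_list: tuple[str, ...] = ()
    n_components: int | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable description of one soft-sensor run."""

    csv_path: str | None = None
    names_u: tuple[str, ...] = ()
    names_y: tuple[str, ...] = ()
    synthetic: SyntheticSpec | None = None
    train_fraction: float = 0.6
    variant: str = "enso"
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    ridge: float = 1e-6
    lambda1: float = 0.1
    lambda3: float = 0.6
    q: int = 50
    stls_iters: int = 10
    coef_rule: str = "refit"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    block_size: int = 1
    adapt_on_test: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"variant must be one of {VARIANTS}")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        if self.csv_path is None and self.synthetic is None:
            raise ConfigurationError("either csv_path or synthetic must be given")

    def sparsity(self) -> SparsityConfig:
        return SparsityConfig(
            lambda1=self.lambda1,
            lambda2=self.ridge,
            lambda3=self.lambda3,
            q=self.q,
            stls_iters=self.stls_iters,
            seed=self.seed,
            coef_rule=self.coef_rule,
        )

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["names_u"] = list(self.names_u)
        d["names_y"] = list(self.names_y)
        d["selection"]["domain_list"] = list(self.selection.domain_list)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if syn.get("feature") is not None:
                syn["feature"] = FeatureConfig(**syn["feature"])
            d["synthetic"] = SyntheticSpec(**syn)
        if d.get("feature") is not None:
            d["feature"] = FeatureConfig(**d["feature"])
        if d.get("preprocess") is not None:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if d.get("selection") is not None:
            sel = dict(d["selection"])
            sel["domain_list"] = tuple(sel.get("domain_list", ()))
            d["selection"] = SelectionConfig(**sel)
        d["names_u"] = tuple(d.get("names_u", ()))
        d["names_y"] = tuple(d.get("names_y", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage(name):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EnsorcError as err:
                raise type(err)(f"[stage: {name}] {err}") from err

        return inner

    return wrap


@_stage("load")
def _load(cfg: PipelineConfig) -> TimeSeriesDataset:
    if cfg.csv_path is not None:
        if not cfg.names_u or not cfg.names_y:
            raise ConfigurationError("names_u and names_y are required with csv_path")
        return TimeSeriesDataset.from_csv(cfg.csv_path, list(cfg.names_u), list(cfg.names_y))
    out = generate(cfg.synthetic)
    return out[0] if isinstance(out, tuple) else out


@dataclass
class _Prepared:
    """Preprocessed series plus everything needed to undo the transforms."""

    u_std: np.ndarray            # (M_sel, n_eff) standardized (maybe differenced)
    y_std: np.ndarray            # (L, n_eff)
    y_raw: np.ndarray            # (L, n) original-scale targets
    names_u: list[str]
    names_y: list[str]
    n_train_eff: int             # training samples in effective (differenced) index
    lag: int                     # differencing lag (0 = off)
    scaler_u: Scaler | None
    scaler_y: Scaler | None
    selection: dict | None


@_stage("preprocess")
def _preprocess(cfg: PipelineConfig, ds: TimeSeriesDataset) -> _Prepared:
    n = ds.n_samples
    n_train = int(np.floor(cfg.train_fraction * n))
    pp = cfg.preprocess
    u = ds.u.copy()
    y_raw = ds.y.copy()
    y = ds.y.copy()
    if pp.clean_outliers:
        # training span only: the fitted model must not depend on test values
        for mat in (u, y):
            for i in range(mat.shape[0]):
                _, cleaned = detect_outliers(
                    mat[i, :n_train], window=pp.outlier_window, n_sigmas=pp.outlier_n_sigmas
                )
                mat[i, :n_train] = cleaned
    lag = pp.difference_lag or 0
    if lag:
        if n_train <= lag:
            raise ConfigurationError("difference_lag must be smaller than the training span")
        u = u[:, lag:] - u[:, :-lag]
        y = y[:, lag:] - y[:, :-lag]
    n_train_eff = n_train - lag
    scaler_u = scaler_y = None
    if pp.standardize:
        scaler_u = fit_standardizer(u[:, :n_train_eff].T, names=ds.names_u)
        scaler_y = fit_standardizer(y[:, :n_train_eff].T, names=ds.names_y)
        u = scaler_u.transform(u.T).T
        y = scaler_y.transform(y.T).T
    return _Prepared(
        u_std=u,
        y_std=y,
        y_raw=y_raw,
        names_u=list(ds.names_u),
        names_y=list(ds.names_y),
        n_train_eff=n_train_eff,
        lag=lag,
        scaler_u=scaler_u,
        scaler_y=scaler_y,
        selection=None,
    )


@_stage("selection")
def _select(cfg: PipelineConfig, prep: _Prepared) -> _Prepared:
    sel = cfg.selection
    if not sel.enabled:
        return prep
    Xtr = prep.u_std[:, : prep.n_train_eff].T
    Ytr = prep.y_std[:, : prep.n_train_eff].T
    vip = vip_scores(Xtr, Ytr, n_components=sel.n_components)
    vip_map = dict(zip(prep.names_u, vip))
    lasso_idx, _ = lasso_select(Xtr, Ytr[:, 0], cv_folds=5, seed=cfg.seed)
    report = select_auxiliary(
        vip_map,
        [prep.names_u[i] for i in lasso_idx],
        domain_list=list(sel.domain_list),
        rule=sel.rule,
        target_count=sel.target_count,
    )
    keep = [prep.names_u.index(v) for v in report.final_selected]
    prep.u_std = prep.u_std[keep]
    prep.names_u = [prep.names_u[i] for i in keep]
    prep.selection = report.to_dict()
    return prep


@_stage("train")
def _train_and_predict(cfg: PipelineConfig, prep: _Prepared):
    """Fit the requested variant and produce chronological test predictions
    in standardized target space."""
    ds_std = TimeSeriesDataset(
        u=prep.u_std, y=prep.y_std, names_u=prep.names_u, names_y=prep.names_y
    )
    fm = build_features(ds_std, cfg.feature)
    is_train = fm.valid_times < prep.n_train_eff
    H_tr, H_te = fm.values[:, is_train], fm.values[:, ~is_train]
    Y = prep.y_std[:, fm.valid_times]
    Y_tr, Y_te = Y[:, is_train], Y[:, ~is_train]
    test_times = fm.valid_times[~is_train]

    model_info: dict = {"feature_names": fm.feature_names, "blocks": fm.blocks}
    adaptive = cfg.adapt_on_test and cfg.variant in ("online", "enso")

    if cfg.variant == "ngrc":
        W = fit_batch(fm_sub(fm, H_tr), Y_tr, ridge=cfg.ridge).W
        state = None
    elif cfg.variant == "online":
        state = init_online_state(H_tr, Y_tr, ridge=cfg.ridge)
        W = state.W
    elif cfg.variant == "ens":
        summary = ensemble_sparse_fit(fm_sub(fm, H_tr), Y_tr, cfg.sparsity())
        W = summary.W_final
        state = None
        model_info["inclusion_proba"] = summary.p_ip.tolist()
    else:  # enso
        summary = ensemble_sparse_fit(H_tr, Y_tr, cfg.sparsity())
        state = _init_enso_state(H_tr, Y_tr, summary.p_ip >= cfg.lambda3, cfg.ridge)
        W = state.W
        model_info["inclusion_proba"] = summary.p_ip.tolist()

    n_te = H_te.shape[1]
    Yhat = np.empty_like(Y_te)
    if not adaptive or state is None:
        Yhat[:] = W @ H_te
    else:
        for start in range(0, n_te, cfg.block_size):
            stop = min(start + cfg.block_size, n_te)
            Hb, Yb = H_te[:, start:stop], Y_te[:, start:stop]
            Yhat[:, start:stop] = state.W @ Hb       # predict before updating
            state = (
                state.update(Hb, Yb)
                if isinstance(state, EnSOState)
                else update_online(state, Hb, Yb)
            )
        W = state.W
    model_info["W"] = W.tolist()
    model_info["variant"] = cfg.variant
    return Yhat, Y_te, test_times, model_info


def fm_sub(fm, values):
    """FeatureMatrix metadata carried over a column subset (helper)."""
    from .features import FeatureMatrix

    return FeatureMatrix(
        values=values,
        valid_times=np.arange(values.shape[1]),
        blocks=dict(fm.blocks),
        feature_names=list(fm.feature_names),
    )


@_stage("evaluate")
def _to_original_scale(prep: _Prepared, Yhat_std: np.ndarray, test_times: np.ndarray):
    """Undo standardization and differencing; return (Y_true, Y_hat) raw."""
    Yhat = Yhat_std
    if prep.scaler_y is not None:
        Yhat = prep.scaler_y.inverse_transform(Yhat.T).T
    orig_times = test_times + prep.lag
    if prep.lag:
        # invert x'_t = x_t - x_{t-lag} with the measured past targets,
        # which are available by the time the prediction is scored
        Yhat = Yhat + prep.y_raw[:, orig_times - prep.lag]
    Y_true = prep.y_raw[:, orig_times]
    return Y_true, Yhat


def run_pipeline(cfg: PipelineConfig) -> tuple[EvalReport, dict]:
    """Execute the configured workflow; returns (report, serializable model).

    When ``cfg.outdir`` is set, writes ``report.json``, ``report.csv``,
    ``model.json`` and the resolved ``config.yaml`` there.
    """
    ds = _load(cfg)
    prep = _select(cfg, _preprocess(cfg, ds))
    Yhat_std, Y_te_std, test_times, model_info = _train_and_predict(cfg, prep)
    Y_true, Yhat = _to_original_scale(prep, Yhat_std, test_times)
    report = evaluate(Y_true, Yhat, target_names=prep.names_y, scale="original")
    report.extra = {
        "variant": cfg.variant,
        "n_train": int(prep.n_train_eff),
        "adapt_on_test": bool(cfg.adapt_on_test),
        "selection": prep.selection,
        "test_times": (test_times + prep.lag).tolist(),
        "predictions": Yhat.tolist(),
    }
    model = {
        "schema_version": 1,
        "variant": cfg.variant,
        "W": model_info["W"],
        "feature_names": model_info["feature_names"],
        "feature_blocks": {k: list(v) for k, v in model_info["blocks"].items()},
        "ridge": cfg.ridge,
        "names_u": prep.names_u,
        "names_y": prep.names_y,
        "scaler_u": prep.scaler_u.to_dict() if prep.scaler_u else None,
        "scaler_y": prep.scaler_y.to_dict() if prep.scaler_y else None,
        "difference_lag": prep.lag or None,
        "inclusion_proba": model_info.get("inclusion_proba"),
        "config": cfg.to_dict(),
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_frame().to_csv(out / "report.csv", index=False)
        with open(out / "model.json", "w") as fh:
            json.dump(model, fh, indent=2, sort_keys=True)
        cfg.to_yaml(out / "config.yaml")
    return report, model


def compare_variants(cfg: PipelineConfig, variants=VARIANTS):
    """Run several variants on the same data; returns a tidy comparison table.

    One row per variant x target with MAE/RMSE/PCC, the variant's RMSSD and
    the relative RMSSD reduction against the first variant listed.
    """
    import pandas as pd

    variants = list(variants)
    if len(variants) < 2:
        raise ConfigurationError("compare_variants needs at least two variants")
    rows = []
    base_rmssd = None
    for variant in variants:
        rep, _ = run_pipeline(dataclasses.replace(cfg, variant=variant, outdir=None))
        if base_rmssd is None:
            base_rmssd = rep.rmssd
        for name in rep.target_names:
            rows.append(
                {
                    "variant": variant,
                    "target": name,
                    **rep.per_target[name],
                    "rmssd": rep.rmssd,
                    "rmssd_reduction_vs_base": (base_rmssd - rep.rmssd) / base_rmssd
                    if base_rmssd
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)
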