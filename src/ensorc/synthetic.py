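"""Synthetic benchmark generators with retained ground truth.

Three families of inputs, each fully determined by an integer seed:

* :func:`gen_chaotic` — the Lorenz-63 system (sigma=10, rho=28, beta=8/3)
  integrated with fixed-step fourth-order Runge-Kutta; the classic
  benchmark for NG-RC one-step forecasting.
* :func:`gen_planted_sparse` — a driven system whose targets are an exactly
  sparse linear readout of the NG-RC feature library of random inputs,
  plus Gaussian noise; the true weights are returned so support and weight
  recovery can be scored exactly.
* :func:`gen_wwtp_like` — treatment-plant-flavoured series: six auxiliary
  variables with seasonal cycles, slow drift and autocorrelated noise, and
  target quality variables produced by a known sparse lag-2 polynomial map
  of the (internally standardized) auxiliaries, with optional spike
  outliers.  Because the map is polynomial of degree <= 2 in an affine
  transform of the inputs, an NG-RC library with k=2, p=2 and a constant
  term can represent it exactly regardless of how a pipeline re-centers
  the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import TimeSeriesDataset
from .exceptions import ConfigurationError
from .features import FeatureConfig, build_features

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "gen_chaotic",
    "gen_planted_sparse",
    "gen_wwtp_like",
    "generate",
]

_LORENZ = dict(sigma=10.0, rho=28.0, beta=8.0 / 3.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Settings shared by the generators; unused fields are ignored per kind."""

    kind: str = "wwtp_like"
    n: int = 500
    dt: float = 1.0
    seed: int = 0
    n_aux: int = 6
    n_targets: int = 2
    noise_sigma: float = 0.05
    density: float = 0.2
    season_amplitude: float = 1.0
    season_period: float = 96.0
    drift_amplitude: float = 0.5
    outlier_rate: float = 0.0
    outlier_magnitude: float = 10.0
    feature: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("chaotic", "planted_sparse", "wwtp_like"):
            raise ConfigurationError(f"unknown kind {self.kind!r}")
        for name in ("density",):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigurationError("outlier_rate must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth retained by a generator for downstream scoring."""

    W: np.ndarray                       # true readout over the library
    feature_config: FeatureConfig
    support: np.ndarray                 # boolean (L, d)
    input_center: np.ndarray | None = None   # affine map u -> (u-center)/scale
    input_scale: np.ndarray | None = None    # under which W applies
    target_center: np.ndarray | None = None
    target_scale: np.ndarray | None = None
    outlier_mask_u: np.ndarray | None = None
    outlier_mask_y: np.ndarray | None = None
    rescaled: bool = False


def _lorenz_rhs(state: np.ndarray) -> np.ndarray:
    x, y, z = state
    return np.array(
        [
            _LORENZ["sigma"] * (y - x),
            x * (_LORENZ["rho"] - z) - y,
            x * y - _LORENZ["beta"] * z,
        ]
    )


def _rk4_step(state: np.ndarray, dt: float) -> np.ndarray:
    k1 = _lorenz_rhs(state)
    k2 = _lorenz_rhs(state + 0.5 * dt * k1)
    k3 = _lorenz_rhs(state + 0.5 * dt * k2)
    k4 = _lorenz_rhs(state + dt * k3)
    return state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def gen_chaotic(spec: SyntheticSpec, transient: int = 1000) -> TimeSeriesDataset:
    """Lorenz-63 trajectory; targets are the state one step ahead.

    The auxiliary block holds the state (x, y, z) at time t, the target
    block the state at t+1, so a one-step forecaster can be trained and
    scored directly.  ``spec.dt`` must be <= 0.05 for the fixed-step
    integrator to stay on the attractor.
    """
    if spec.dt > 0.05 or spec.dt <= 0:
        raise ConfigurationError("chaotic generator requires 0 < dt <= 0.05")
    rng = np.random.default_rng(spec.seed)
    state = np.array([1.0, 1.0, 20.0]) + 0.5 * rng.standard_normal(3)
    for _ in range(transient):
        state = _rk4_step(state, spec.dt)
    traj = np.empty((3, spec.n + 1))
    for t in range(spec.n + 1):
        traj[:, t] = state
        state = _rk4_step(state, spec.dt)
    return TimeSeriesDataset(
        u=traj[:, : spec.n],
        y=traj[:, 1 : spec.n + 1],
        names_u=["x", "y", "z"],
        names_y=["x_next", "y_next", "z_next"],
        dt=spec.dt,
    )


def _draw_sparse_weights(
    rng: np.random.Generator, L: int, d: int, density: float
) -> np.ndarray:
    nnz = max(1, round(density * L * d))
    flat = rng.choice(L * d, size=nnz, replace=False)
    W = np.zeros(L * d)
    W[flat] = rng.uniform(0.5, 1.5, size=nnz) * rng.choice([-1.0, 1.0], size=nnz)
    return W.reshape(L, d)


def gen_planted_sparse(spec: SyntheticSpec) -> tuple[TimeSeriesDataset, PlantedTruth]:
    """Driven system with an exactly sparse readout over the NG-RC library.

    Inputs are i.i.d. standard normal (well-conditioned polynomial Gram);
    targets are y_t = W* H_total(t) + eps with eps ~ N(0, noise_sigma^2).
    Target columns inside the delay warm-up replicate the first valid
    column so the dataset stays rectangular; training code never sees them
    because feature columns are trimmed to valid times.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.feature
    M, L, n = spec.n_aux, spec.n_targets, spec.n
    u = rng.standard_normal((M, n))
    ds_u = TimeSeriesDataset(u=u, y=np.zeros((1, n)), dt=spec.dt)
    fm = build_features(ds_u, cfg)
    W = _draw_sparse_weights(rng, L, fm.d, spec.density)
    clean = W @ fm.values
    rescaled = False
    # unreachable for bounded driven inputs; guards a future autoregressive mode
    while np.max(np.abs(clean)) > 1e6:
        W *= 0.1
        clean = W @ fm.values
        rescaled = True
    y_valid = clean + spec.noise_sigma * rng.standard_normal(clean.shape)
    y = np.empty((L, n))
    y[:, fm.valid_times] = y_valid
    y[:, : cfg.warmup] = y_valid[:, :1]
    ds = TimeSeriesDataset(
        u=u,
        y=y,
        names_u=[f"u{i + 1}" for i in range(M)],
        names_y=[f"y{i + 1}" for i in range(L)],
        dt=spec.dt,
    )
    truth = PlantedTruth(W=W, feature_config=cfg, support=W != 0, rescaled=rescaled)
    return ds, truth


_WWTP_AUX = ["cod_in", "nh3n_in", "tp_in", "tn_in", "ss_in", "flow_q"]
_WWTP_BASE = np.array([320.0, 28.0, 4.5, 38.0, 180.0, 2.1e4])
_WWTP_SD = np.array([45.0, 5.0, 0.9, 6.0, 30.0, 2.5e3])
_WWTP_TARGETS = ["cod_eff", "bod_eff", "tn_eff"]
_WWTP_T_BASE = np.array([30.0, 8.0, 12.0])
_WWTP_T_SD = np.array([6.0, 1.6, 2.5])


def gen_wwtp_like(spec: SyntheticSpec) -> tuple[TimeSeriesDataset, PlantedTruth]:
    """Treatment-plant-like multivariate series with a known target map.

    Auxiliary variables combine a seasonal sinusoid (period
    ``season_period`` samples, amplitude ``season_amplitude`` in units of
    each variable's nominal spread), a slow drift (linear trend plus an
    integrated random walk, total ``drift_amplitude`` spreads over the
    record) and AR(1) noise.  Targets apply a sparse degree-2 polynomial
    map with two delay taps to the internally standardized auxiliaries,
    then are placed on physical-looking scales.  ``outlier_rate`` injects
    isolated spikes of ``outlier_magnitude`` nominal spreads into both
    blocks; masks are returned for recall scoring.
    """
    if spec.n < 100:
        raise ConfigurationError("wwtp_like generator needs n >= 100")
    rng = np.random.default_rng(spec.seed)
    M = min(spec.n_aux, len(_WWTP_AUX))
    L = min(spec.n_targets, len(_WWTP_TARGETS))
    n = spec.n
    t = np.arange(n)
    base, sd = _WWTP_BASE[:M], _WWTP_SD[:M]

    phases = rng.uniform(0, 2 * np.pi, size=M)
    season = spec.season_amplitude * np.sin(
        2 * np.pi * t[None, :] / spec.season_period + phases[:, None]
    )
    trend = np.linspace(0, 1, n)[None, :] * rng.uniform(-1, 1, size=(M, 1))
    walk = np.cumsum(rng.standard_normal((M, n)), axis=1)
    walk /= np.maximum(np.abs(walk).max(axis=1, keepdims=True), 1.0)
    drift = spec.drift_amplitude * (trend + 0.5 * walk)
    ar = np.empty((M, n))
    eps = rng.standard_normal((M, n))
    ar[:, 0] = eps[:, 0]
    for k in range(1, n):
        ar[:, k] = 0.7 * ar[:, k - 1] + eps[:, k]
    ar *= 0.4
    u_std = season + drift + ar                       # dimensionless aux signal
    u = base[:, None] + sd[:, None] * u_std

    # known sparse degree-2 map of the standardized auxiliaries, lag taps k=2
    cfg = FeatureConfig(n_delays=2, spacing=1, poly_order=2, include_constant=True)
    center, scale = u.mean(axis=1), u.std(axis=1)
    z = (u - center[:, None]) / scale[:, None]
    fm = build_features(TimeSeriesDataset(u=z, y=np.zeros((1, n))), cfg)
    W = _draw_sparse_weights(rng, L, fm.d, spec.density)
    lo, hi = fm.blocks["nonlinear"]
    W[:, lo:hi] *= 0.5                                # temper quadratic terms
    clean = W @ fm.values
    y_valid = clean + spec.noise_sigma * rng.standard_normal(clean.shape)
    y_std = np.empty((L, n))
    y_std[:, fm.valid_times] = y_valid
    y_std[:, : cfg.warmup] = y_valid[:, :1]
    y = _WWTP_T_BASE[:L, None] + _WWTP_T_SD[:L, None] * y_std

    mask_u = np.zeros((M, n), dtype=bool)
    mask_y = np.zeros((L, n), dtype=bool)
    if spec.outlier_rate > 0:
        mask_u = rng.random((M, n)) < spec.outlier_rate
        mask_y = rng.random((L, n)) < spec.outlier_rate
        sign_u = rng.choice([-1.0, 1.0], size=(M, n))
        sign_y = rng.choice([-1.0, 1.0], size=(L, n))
        u = u + mask_u * sign_u * spec.outlier_magnitude * sd[:, None]
        y = y + mask_y * sign_y * spec.outlier_magnitude * _WWTP_T_SD[:L, None]

    ds = TimeSeriesDataset(
        u=u,
        y=y,
        names_u=_WWTP_AUX[:M],
        names_y=_WWTP_TARGETS[:L],
        dt=spec.dt,
    )
    truth = PlantedTruth(
        W=W,
        feature_config=cfg,
        support=W != 0,
        input_center=center,
        input_scale=scale,
        target_center=_WWTP_T_BASE[:L].copy(),
        target_scale=_WWTP_T_SD[:L].copy(),
        outlier_mask_u=mask_u,
        outlier_mask_y=mask_y,
    )
    return ds, truth


def generate(spec: SyntheticSpec):
    """Dispatch on ``spec.kind``; chaotic returns a dataset, the others (dataset, truth)."""
    if spec.kind == "chaotic":
        return gen_chaotic(spec)
    if spec.kind == "planted_sparse":
        return gen_planted_sparse(spec)
    return gen_wwtp_like(spec)
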