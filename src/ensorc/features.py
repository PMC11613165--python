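"""NG-RC feature construction: delay embedding plus a polynomial library.

Next-generation reservoir computing replaces a random recurrent reservoir
with deterministic feature vectors built from time-delayed copies of the
input variables and their polynomial monomials; only a linear readout is
ever trained.  The total feature vector at time ``t`` is

    H_total(t) = [1; H_lin(t); H_nlin(t)]

where ``H_lin(t)`` stacks the inputs at times ``t, t-s, ..., t-(k-1)s``
(current values first, older taps below) and ``H_nlin(t)`` contains all
unique monomials of the linear features of total degree 2..p, in a fixed
deterministic order (degree ascending, then lexicographic in the index
tuple).  Columns before the warm-up ``s*(k-1)`` are dropped, never padded,
so every feature column depends on past and present samples only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import TimeSeriesDataset
from .exceptions import AlignmentError, ConfigurationError, SeriesLengthError

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "NGRCFeaturizer",
    "build_linear_features",
    "build_nonlinear_features",
    "assemble_total_features",
    "build_features",
    "n_monomials",
    "feature_dimension",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Delay-embedding and polynomial-library settings.

    ``n_delays`` is the number of time taps k, ``spacing`` the stride s
    between taps in samples, ``poly_order`` the highest monomial degree p.
    """

    n_delays: int = 2
    spacing: int = 1
    poly_order: int = 2
    include_constant: bool = True

    def __post_init__(self) -> None:
        if self.n_delays < 1 or self.spacing < 1:
            raise ConfigurationError("n_delays and spacing must both be >= 1")
        if self.poly_order < 1:
            raise ConfigurationError("poly_order must be >= 1")

    @property
    def warmup(self) -> int:
        """Samples consumed before the first valid feature column."""
        return self.spacing * (self.n_delays - 1)


@dataclass
class FeatureMatrix:
    """A d x n_valid feature matrix with block and provenance metadata.

    ``blocks`` maps block name ("constant", "linear", "nonlinear") to the
    half-open row range it occupies; ``valid_times`` gives, per column, the
    index of the source-series time point the column describes.
    """

    values: np.ndarray
    valid_times: np.ndarray
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.valid_times = np.asarray(self.valid_times, dtype=int)
        if self.values.shape[1] != self.valid_times.shape[0]:
            raise AlignmentError(
                f"{self.values.shape[1]} feature columns but "
                f"{self.valid_times.shape[0]} valid_times entries"
            )
        if not self.feature_names:
            self.feature_names = [f"h{i}" for i in range(self.values.shape[0])]

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n_valid(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.blocks[name]
        return self.values[lo:hi]


def n_monomials(poly_order: int, d_lin: int) -> int:
    """Count of unique monomials of degree 2..p over d_lin variables."""
    return sum(math.comb(d_lin + deg - 1, deg) for deg in range(2, poly_order + 1))


def feature_dimension(n_aux: int, cfg: FeatureConfig) -> int:
    """Total feature dimension d for M input variables under ``cfg``."""
    d_lin = n_aux * cfg.n_delays
    return int(cfg.include_constant) + d_lin + n_monomials(cfg.poly_order, d_lin)


def _monomial_index_tuples(poly_order: int, d_lin: int) -> list[tuple[int, ...]]:
    combos: list[tuple[int, ...]] = []
    for deg in range(2, poly_order + 1):
        combos.extend(itertools.combinations_with_replacement(range(d_lin), deg))
    return combos


def build_linear_features(ds: TimeSeriesDataset, cfg: FeatureConfig) -> FeatureMatrix:
    """Stack delayed copies of the auxiliary variables.

    Column ``t`` holds ``u`` at times ``t, t-s, ..., t-(k-1)s`` with the
    current values in the top M rows.  Columns that would need samples
    before the start of the series are dropped.
    """
    u = ds.u
    m, n = u.shape
    warmup = cfg.warmup
    if n <= warmup:
        raise SeriesLengthError(
            f"series of length {n} is shorter than the delay warm-up "
            f"{warmup + 1} (spacing*(n_delays-1)+1)"
        )
    rows = [u[:, warmup - r * cfg.spacing : n - r * cfg.spacing] for r in range(cfg.n_delays)]
    names = []
    for r in range(cfg.n_delays):
        tag = "t" if r == 0 else f"t-{r * cfg.spacing}"
        names.extend(f"{v}[{tag}]" for v in ds.names_u)
    values = np.vstack(rows)
    return FeatureMatrix(
        values=values,
        valid_times=np.arange(warmup, n),
        blocks={"linear": (0, values.shape[0])},
        feature_names=names,
    )


def build_nonlinear_features(lin: FeatureMatrix, poly_order: int) -> FeatureMatrix:
    """All unique monomials of the linear features, degrees 2..p.

    ``poly_order=1`` yields an empty (0-row) block.  Order is deterministic:
    degree ascending, then lexicographic in the tuple of feature indices.
    """
    if poly_order < 1:
        raise ConfigurationError("poly_order must be >= 1")
    combos = _monomial_index_tuples(poly_order, lin.d)
    if combos:
        values = np.empty((len(combos), lin.n_valid))
        for i, combo in enumerate(combos):
            values[i] = np.prod(lin.values[list(combo)], axis=0)
    else:
        values = np.empty((0, lin.n_valid))
    names = ["*".join(lin.feature_names[i] for i in combo) for combo in combos]
    return FeatureMatrix(
        values=values,
        valid_times=lin.valid_times.copy(),
        blocks={"nonlinear": (0, values.shape[0])},
        feature_names=names,
    )


def assemble_total_features(
    lin: FeatureMatrix, nlin: FeatureMatrix, cfg: FeatureConfig
) -> FeatureMatrix:
    """Vertical stack [constant?; linear; nonlinear] with block metadata."""
    if lin.n_valid != nlin.n_valid or not np.array_equal(lin.valid_times, nlin.valid_times):
        raise AlignmentError("linear and nonlinear blocks are not column-aligned")
    parts, names, blocks = [], [], {}
    row = 0
    if cfg.include_constant:
        parts.append(np.ones((1, lin.n_valid)))
        names.append("1")
        blocks["constant"] = (0, 1)
        row = 1
    parts.append(lin.values)
    names.extend(lin.feature_names)
    blocks["linear"] = (row, row + lin.d)
    row += lin.d
    parts.append(nlin.values)
    names.extend(nlin.feature_names)
    blocks["nonlinear"] = (row, row + nlin.d)
    return FeatureMatrix(
        values=np.vstack(parts),
        valid_times=lin.valid_times.copy(),
        blocks=blocks,
        feature_names=names,
    )


def build_features(ds: TimeSeriesDataset, cfg: FeatureConfig) -> FeatureMatrix:
    """Linear embedding + polynomial library + optional constant, assembled."""
    lin = build_linear_features(ds, cfg)
    nlin = build_nonlinear_features(lin, cfg.poly_order)
    return assemble_total_features(lin, nlin, cfg)


class NGRCFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer building NG-RC total feature vectors.

    Rows of ``X`` are time points in chronological order, columns are input
    variables.  ``transform`` returns one row per *valid* time point (the
    first ``warmup_`` rows of ``X`` only provide delay context), with
    ``feature_dimension`` columns.

    Parameters
    ----------
    n_delays : int, default=2
        Number of time taps k in the delay embedding.
    spacing : int, default=1
        Stride between taps, in samples.
    poly_order : int, default=2
        Highest monomial degree p of the nonlinear library.
    include_constant : bool, default=True
        Prepend a constant-1 feature (bias term of the readout).
    """

    def __init__(
        self,
        n_delays: int = 2,
        spacing: int = 1,
        poly_order: int = 2,
        include_constant: bool = True,
    ):
        self.n_delays = n_delays
        self.spacing = spacing
        self.poly_order = poly_order
        self.include_constant = include_constant

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            n_delays=self.n_delays,
            spacing=self.spacing,
            poly_order=self.poly_order,
            include_constant=self.include_constant,
        )

    def fit(self, X, y=None) -> "NGRCFeaturizer":
        X = check_array(X, ensure_2d=True)
        cfg = self._config()
        self.n_features_in_ = X.shape[1]
        self.warmup_ = cfg.warmup
        self.d_ = feature_dimension(self.n_features_in_, cfg)
        ds = TimeSeriesDataset(u=X[: cfg.warmup + 1].T, y=np.zeros((1, cfg.warmup + 1)))
        self.feature_names_ = build_features(ds, cfg).feature_names
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "d_")
        fm = self.transform_matrix(X)
        return fm.values.T

    def transform_matrix(self, X) -> FeatureMatrix:
        """Like :meth:`transform` but returns the full :class:`FeatureMatrix`."""
        check_is_fitted(self, "d_")
        X = check_array(X, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"X has {X.shape[1]} variables, expected {self.n_features_in_}"
            )
        ds = TimeSeriesDataset(u=X.T, y=np.zeros((1, X.shape[0])))
        return build_features(ds, self._config())

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)
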