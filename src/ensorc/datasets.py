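"""Aligned multivariate time-series container and CSV I/O.

A :class:`TimeSeriesDataset` holds auxiliary (easy-to-measure) process
variables ``u`` and target quality variables ``y`` on a shared, regularly
sampled time axis.  Arrays are stored variables-by-time (M x n and L x n),
the orientation in which delay embeddings and output-weight algebra are
written throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError

__all__ = ["TimeSeriesDataset"]


@dataclass
class TimeSeriesDataset:
    """Aligned auxiliary and target series.

    Parameters
    ----------
    u : ndarray of shape (M, n)
        Auxiliary variables, one row per variable, in physical units.
    y : ndarray of shape (L, n)
        Target variables on the same time axis.
    names_u, names_y : list of str
        Unique variable names.
    dt : float
        Sampling interval (whatever time unit the data uses).
    t0 : float
        Time stamp of the first column.
    """

    u: np.ndarray
    y: np.ndarray
    names_u: list[str] = field(default_factory=list)
    names_y: list[str] = field(default_factory=list)
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.u.shape[1] != self.y.shape[1]:
            raise AlignmentError(
                f"u and y must share the time axis: u has {self.u.shape[1]} "
                f"samples, y has {self.y.shape[1]}"
            )
        if not self.names_u:
            self.names_u = [f"u{i + 1}" for i in range(self.u.shape[0])]
        if not self.names_y:
            self.names_y = [f"y{i + 1}" for i in range(self.y.shape[0])]
        if len(self.names_u) != self.u.shape[0] or len(self.names_y) != self.y.shape[0]:
            raise ConfigurationError("variable name lists must match row counts")
        names = self.names_u + self.names_y
        if len(set(names)) != len(names):
            raise ConfigurationError("variable names must be unique")

    @property
    def n_samples(self) -> int:
        return self.u.shape[1]

    @property
    def n_aux(self) -> int:
        return self.u.shape[0]

    @property
    def n_targets(self) -> int:
        return self.y.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    def slice(self, start: int, stop: int | None = None) -> "TimeSeriesDataset":
        """Chronological slice [start, stop) keeping names and sampling metadata."""
        sl = slice(start, stop)
        return TimeSeriesDataset(
            u=self.u[:, sl],
            y=self.y[:, sl],
            names_u=list(self.names_u),
            names_y=list(self.names_y),
            dt=self.dt,
            t0=self.t0 + self.dt * start,
        )

    def to_frame(self) -> pd.DataFrame:
        """One column per variable, a leading ``time`` column, rows = time points."""
        data = {"time": self.times}
        for name, row in zip(self.names_u, self.u):
            data[name] = row
        for name, row in zip(self.names_y, self.y):
            data[name] = row
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        names_u: list[str],
        names_y: list[str],
        time_column: str | None = "time",
    ) -> "TimeSeriesDataset":
        missing = [c for c in names_u + names_y if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"columns not found in table: {missing}")
        if frame[names_u + names_y].isna().any().any():
            raise ConfigurationError("missing values present; preprocess before loading")
        dt, t0 = 1.0, 0.0
        if time_column is not None and time_column in frame.columns:
            t = pd.to_numeric(frame[time_column], errors="coerce").to_numpy(dtype=float)
            if len(t) > 1 and np.all(np.isfinite(t)):
                steps = np.diff(t)
                if steps.size and np.allclose(steps, steps[0]):
                    dt, t0 = float(steps[0]), float(t[0])
        return cls(
            u=frame[names_u].to_numpy(dtype=float).T,
            y=frame[names_y].to_numpy(dtype=float).T,
            names_u=list(names_u),
            names_y=list(names_y),
            dt=dt,
            t0=t0,
        )

    @classmethod
    def from_csv(
        cls,
        path,
        names_u: list[str],
        names_y: list[str],
        time_column: str | None = "time",
    ) -> "TimeSeriesDataset":
        return cls.from_frame(pd.read_csv(path), names_u, names_y, time_column)
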