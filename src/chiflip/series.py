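"""Uniform-grid time series containers shared by every pipeline stage.

All series live on a strictly uniform time grid (``t0 + k*dt``); the grid is
stored as ``(t0, dt, n)`` rather than an explicit array so that multi-million
frame synthetic trajectories stay cheap to hold in memory.  Angles are stored
in degrees on ``[0, 360)``; conversion to ``[-180, 180)`` happens only at the
density-estimation boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DihedralSeries",
    "DistanceSeries",
    "DiscreteStateSeries",
    "trim_equilibration",
    "wrap_degrees",
]


def wrap_degrees(angles: np.ndarray, domain_start: float = 0.0) -> np.ndarray:
    """Wrap angles (degrees) into ``[domain_start, domain_start + 360)``."""
    a = np.asarray(angles, dtype=float)
    return (a - domain_start) % 360.0 + domain_start


@dataclass(frozen=True)
class _UniformSeries:
    t0: float
    dt: float
    n: int

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        if self.n < 1:
            raise ValueError("series must contain at least one frame")

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Total spanned time (ns), counting each frame as one dt of coverage."""
        return self.n * self.dt

    def same_grid(self, other: "_UniformSeries", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and np.isclose(self.t0, other.t0, rtol=rtol, atol=1e-12)
            and np.isclose(self.dt, other.dt, rtol=rtol, atol=1e-12)
        )

    def require_same_grid(self, other: "_UniformSeries") -> None:
        if not self.same_grid(other):
            raise ValueError(
                "series are defined on different time grids: "
                f"(t0={self.t0}, dt={self.dt}, n={self.n}) vs "
                f"(t0={other.t0}, dt={other.dt}, n={other.n})"
            )


@dataclass(frozen=True)
class DihedralSeries(_UniformSeries):
    """Angular observable (phi, psi or chi1) for one residue.

    Parameters
    ----------
    residue : residue identifier (number or string label).
    kind : one of ``"phi"``, ``"psi"``, ``"chi1"``.
    angles : degrees, wrapped to ``[0, 360)`` on construction.
    """

    residue: str | int = ""
    kind: str = "chi1"
    angles: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        super().__post_init__()
        ang = wrap_degrees(np.asarray(self.angles, dtype=float))
        if ang.shape != (self.n,):
            raise ValueError(f"angles shape {ang.shape} does not match n={self.n}")
        if not np.all(np.isfinite(ang)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles", ang)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value": self.angles})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, residue: str | int = "", kind: str = "chi1") -> "DihedralSeries":
        df = pd.read_csv(path)
        t = df["time_ns"].to_numpy(float)
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(t0=float(t[0]), dt=dt, n=len(t), residue=residue, kind=kind,
                   angles=df["value"].to_numpy(float))


@dataclass(frozen=True)
class DistanceSeries(_UniformSeries):
    """Scalar distance observable (Angstrom), e.g. M274-CA to Zn."""

    label: str = ""
    distances: np.ndarray = field(default_factory=lambda: np.zeros(1))
    reducer: str = "single"  # single | min

    def __post_init__(self) -> None:
        super().__post_init__()
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (self.n,):
            raise ValueError(f"distances shape {d.shape} does not match n={self.n}")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "distances", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "value": self.distances})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DiscreteStateSeries(_UniformSeries):
    """Rotamer-state labels on a uniform grid.

    States are stored as small-integer codes into ``state_labels`` so that
    very long synthetic trajectories remain compact; ``labels`` decodes on
    demand.
    """

    residue: str | int = ""
    state_labels: tuple[str, ...] = ("g-",)
    codes: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int8))

    def __post_init__(self) -> None:
        super().__post_init__()
        codes = np.asarray(self.codes)
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError("codes must be integers")
        if codes.shape != (self.n,):
            raise ValueError(f"codes shape {codes.shape} does not match n={self.n}")
        if codes.size and (codes.min() < 0 or codes.max() >= len(self.state_labels)):
            raise ValueError("codes reference labels outside state_labels")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.state_labels, dtype=object)[self.codes]

    @classmethod
    def from_labels(cls, times_or_t0, dt: float, labels: Sequence[str],
                    residue: str | int = "", state_labels: Sequence[str] | None = None
                    ) -> "DiscreteStateSeries":
        t0 = float(np.asarray(times_or_t0).ravel()[0]) if np.ndim(times_or_t0) else float(times_or_t0)
        labels = list(labels)
        if state_labels is None:
            state_labels = tuple(dict.fromkeys(labels))  # stable order of appearance
        idx = {s: i for i, s in enumerate(state_labels)}
        codes = np.fromiter((idx[s] for s in labels), dtype=np.int8, count=len(labels))
        return cls(t0=t0, dt=dt, n=len(labels), residue=residue,
                   state_labels=tuple(state_labels), codes=codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "state_label": self.labels})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, residue: str | int = "") -> "DiscreteStateSeries":
        df = pd.read_csv(path)
        t = df["time_ns"].to_numpy(float)
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls.from_labels(float(t[0]), dt, df["state_label"].astype(str).tolist(),
                               residue=residue)


def trim_equilibration(series, t_eq: float):
    """Drop frames with ``time < t_eq`` (ns), preserving the uniform grid.

    The equilibration period is a configuration value; the study conventions
    are 2 us (wild type), 1.8 us (S39E) and 2.5 us (I19S).
    """
    if t_eq < 0:
        raise ValueError("t_eq must be non-negative")
    times = series.times
    if t_eq > times[-1]:
        raise ValueError(f"t_eq={t_eq} ns is beyond the end of the series ({times[-1]} ns)")
    keep = times >= t_eq
    start = int(np.argmax(keep))
    n_new = int(keep.sum())
    kw: dict = {"t0": float(times[start]), "n": n_new}
    if isinstance(series, DihedralSeries):
        return replace(series, angles=series.angles[start:], **kw)
    if isinstance(series, DistanceSeries):
        return replace(series, distances=series.distances[start:], **kw)
    if isinstance(series, DiscreteStateSeries):
        return replace(series, codes=series.codes[start:], **kw)
    raise TypeError(f"unsupported series type {type(series)!r}")
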