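"""Markov state modelling of composite side-chain flip dynamics.

A six-state space is the tensor product of the H143 chi1 factor {g-, t} and
the Y306 chi1 factor {g-, t, g+}.  Transitions are counted at a lag time with
a sliding window, row-normalised into T, symmetrised in count space into a
reversible T-tilde, and validated through the lag-independence of the slowest
implied timescale t_i = -tau_lag / log(lambda_i) (Chapman-Kolmogorov).  A
continuous-time generator is then fitted by least squares so that
exp(tau_lag * Q) matches T-tilde, with only single-flip transitions allowed
(either residue flips, never both simultaneously).

Sign convention: internally Q is a standard generator (non-negative
off-diagonals, zero row sums) with T-tilde ~ exp(tau_lag * Q); the rate
matrix written as exp(-tau * Gamma) in the field's notation is Gamma = -Q.

The module exposes both the individual operations and a statsmodels-style
``MarkovStateModel`` whose :meth:`~MarkovStateModel.fit` returns an
:class:`MSMResults` carrying estimates, diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares

from .presets import composite_label
from .series import DiscreteStateSeries

__all__ = [
    "CompositeStateSpace",
    "TransitionCounts",
    "TransitionModel",
    "SpectralSummary",
    "RateModel",
    "CKReport",
    "compose_states",
    "count_transitions",
    "transition_matrix",
    "symmetrize",
    "spectral_timescales",
    "ck_convergence",
    "fit_rate_matrix",
    "MarkovStateModel",
    "MSMResults",
]


@dataclass(frozen=True)
class CompositeStateSpace:
    """Product state space of two chi1 factors (default H143 x Y306)."""

    h_labels: tuple[str, ...] = ("g-", "t")
    y_labels: tuple[str, ...] = ("g-", "t", "g+")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(composite_label(h, y) for h in self.h_labels for y in self.y_labels)

    @property
    def size(self) -> int:
        return len(self.h_labels) * len(self.y_labels)

    def index(self, h: str, y: str) -> int:
        return self.h_labels.index(h) * len(self.y_labels) + self.y_labels.index(y)

    def factors(self, idx: int) -> tuple[str, str]:
        ny = len(self.y_labels)
        return self.h_labels[idx // ny], self.y_labels[idx % ny]

    def single_flip_mask(self) -> np.ndarray:
        """Boolean mask of allowed off-diagonal transitions.

        A transition is allowed iff exactly one factor changes: all Y-factor
        moves among its rotamers, and H-factor moves, but never simultaneous
        flips of both side chains.
        """
        k = self.size
        mask = np.zeros((k, k), dtype=bool)
        for i in range(k):
            hi, yi = self.factors(i)
            for j in range(k):
                if i == j:
                    continue
                hj, yj = self.factors(j)
                if (hi == hj) != (yi == yj):  # exactly one factor differs
                    mask[i, j] = True
        return mask


def compose_states(h: DiscreteStateSeries, y: DiscreteStateSeries,
                   space: CompositeStateSpace | None = None) -> DiscreteStateSeries:
    """Frame-wise pairing of two per-residue series into composite labels."""
    h.require_same_grid(y)
    space = space or CompositeStateSpace(h.state_labels, y.state_labels)
    if tuple(h.state_labels) != space.h_labels or tuple(y.state_labels) != space.y_labels:
        raise ValueError("series labels do not match the composite state space")
    ny = len(space.y_labels)
    codes = (h.codes.astype(np.int16) * ny + y.codes).astype(np.int8)
    return DiscreteStateSeries(t0=h.t0, dt=h.dt, n=h.n,
                               residue=f"{h.residue}x{y.residue}",
                               state_labels=space.labels, codes=codes)


@dataclass(frozen=True)
class TransitionCounts:
    lag_ns: float
    labels: tuple[str, ...]
    C: np.ndarray
    dt: float

    @property
    def total(self) -> int:
        return int(self.C.sum())


def count_transitions(series: DiscreteStateSeries, lag_ns: float) -> TransitionCounts:
    """Sliding-window transition counts at one lag time.

    Every frame pair (k, k + lag/dt) contributes one count; the lag must be a
    positive integer multiple of the sampling interval and shorter than the
    series.
    """
    steps = lag_ns / series.dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(f"lag {lag_ns} ns is not a positive multiple of dt={series.dt} ns")
    steps = int(round(steps))
    if steps >= series.n:
        raise ValueError("lag leaves no usable frame pairs")
    k = len(series.state_labels)
    c = np.zeros((k, k), dtype=np.int64)
    np.add.at(c, (series.codes[:-steps], series.codes[steps:]), 1)
    return TransitionCounts(lag_ns=float(lag_ns), labels=series.state_labels,
                            C=c, dt=series.dt)


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix at one lag, optionally symmetrised."""

    lag_ns: float
    labels: tuple[str, ...]
    T: np.ndarray
    T_sym: np.ndarray | None = None
    stationary: np.ndarray | None = None
    unvisited: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for m in (self.T, self.T_sym):
            if m is None:
                continue
            if np.any(m < -1e-12) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("transition matrix must be row-stochastic")


def _normalise_rows(c: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    rows = c.sum(axis=1)
    if not rows.any():
        raise ValueError("count matrix is all zero")
    t = np.array(c, dtype=float)
    unvisited = tuple(int(i) for i in np.flatnonzero(rows == 0))
    for i in range(len(rows)):
        if rows[i] > 0:
            t[i] /= rows[i]
        else:
            t[i, i] = 1.0  # unvisited state: identity row, flagged
    return t, unvisited


def transition_matrix(counts: TransitionCounts) -> TransitionModel:
    """Row-normalise raw counts into T."""
    t, unvisited = _normalise_rows(counts.C)
    return TransitionModel(lag_ns=counts.lag_ns, labels=counts.labels, T=t,
                           unvisited=unvisited)


def symmetrize(counts: TransitionCounts) -> TransitionModel:
    """Count-space symmetrisation: C~ = (C + C^T)/2, then row-normalise.

    The resulting chain is reversible by construction; its stationary vector
    is the row sums of C~ over the total count, and detailed balance
    pi_i T~_ij = pi_j T~_ji holds exactly.
    """
    c_sym = 0.5 * (counts.C + counts.C.T)
    t_raw, _ = _normalise_rows(counts.C)
    t_sym, unvisited = _normalise_rows(c_sym)
    total = c_sym.sum()
    pi = c_sym.sum(axis=1) / total
    return TransitionModel(lag_ns=counts.lag_ns, labels=counts.labels, T=t_raw,
                           T_sym=t_sym, stationary=pi, unvisited=unvisited)


@dataclass(frozen=True)
class SpectralSummary:
    """Eigenvalues (descending modulus) and implied relaxation times."""

    lag_ns: float
    eigenvalues: np.ndarray
    timescales_ns: np.ndarray  # NaN where lambda <= 0 or lambda ~ 1

    @property
    def slowest_ns(self) -> float:
        finite = self.timescales_ns[np.isfinite(self.timescales_ns)]
        return float(finite.max()) if finite.size else float("nan")


def spectral_timescales(model: TransitionModel, which: str = "sym") -> SpectralSummary:
    """Implied timescales t_i = -tau_lag / log(lambda_i).

    ``which`` selects the symmetrised matrix (default, falling back to the
    raw T when no symmetrisation is present) or ``"raw"`` for T itself.
    """
    m = model.T_sym if (which == "sym" and model.T_sym is not None) else model.T
    lam = np.linalg.eigvals(m)
    if np.abs(lam.imag).max(initial=0.0) < 1e-10:
        lam = lam.real
    order = np.argsort(-np.abs(lam))
    lam = lam[order]
    if abs(lam[0] - 1.0) > 1e-10:
        raise ValueError("leading eigenvalue is not 1; input not row-stochastic?")
    ts = np.full(len(lam), np.nan)
    lr = np.real(lam)
    ok = (lr > 0) & (lr < 1.0 - 1e-12)
    ts[ok] = -model.lag_ns / np.log(lr[ok])
    return SpectralSummary(lag_ns=model.lag_ns, eigenvalues=lam, timescales_ns=ts)


@dataclass(frozen=True)
class CKReport:
    """Lag-independence (Chapman-Kolmogorov) diagnostic of the slowest mode."""

    lag_grid_ns: tuple[float, ...]
    slowest_ns: tuple[float, ...]
    selected_lag_ns: float | None
    plateau_tol: float

    @property
    def converged(self) -> bool:
        return self.selected_lag_ns is not None


def ck_convergence(series: DiscreteStateSeries, lag_grid_ns: Sequence[float],
                   plateau_tol: float = 0.05) -> CKReport:
    """Slowest implied timescale across a lag grid and the convergence lag.

    The selected lag is the smallest grid point from which the slowest
    timescale stays within ``plateau_tol`` (relative) at all later grid
    points; ``selected_lag_ns`` is None when no plateau is found.
    """
    grid = tuple(float(x) for x in lag_grid_ns)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("lag grid must be strictly increasing")
    slowest = []
    for lag in grid:
        model = symmetrize(count_transitions(series, lag))
        slowest.append(spectral_timescales(model).slowest_ns)
    selected = None
    for k, t_k in enumerate(slowest):
        later = slowest[k + 1:]
        if np.isfinite(t_k) and all(
            np.isfinite(t) and abs(t - t_k) / t_k < plateau_tol for t in later
        ):
            selected = grid[k]
            break
    return CKReport(lag_grid_ns=grid, slowest_ns=tuple(slowest),
                    selected_lag_ns=selected, plateau_tol=plateau_tol)


@dataclass(frozen=True)
class RateModel:
    """Continuous-time generator fitted to a lag transition matrix.

    ``Q`` is the standard generator (1/ns); ``Gamma`` is its negative, the
    sign convention used when the propagator is written exp(-tau * Gamma).
    """

    labels: tuple[str, ...]
    Q: np.ndarray
    mask: np.ndarray
    residual: float
    lag_ns: float

    def __post_init__(self) -> None:
        q = self.Q
        if np.any(np.abs(q.sum(axis=1)) > 1e-12):
            raise ValueError("generator rows must sum to zero")
        off = ~np.eye(len(q), dtype=bool)
        if np.any(q[off & ~self.mask] != 0.0):
            raise ValueError("masked-out rates must be exactly zero")

    @property
    def Gamma(self) -> np.ndarray:
        return -self.Q

    def rate(self, i: int, j: int) -> float:
        return float(self.Q[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=list(self.labels), columns=list(self.labels))


def _assemble_q(rates: np.ndarray, mask: np.ndarray) -> np.ndarray:
    q = np.zeros(mask.shape)
    q[mask] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def fit_rate_matrix(model: TransitionModel,
                    space: CompositeStateSpace | None = None,
                    mask: np.ndarray | None = None,
                    max_nfev: int = 10_000) -> RateModel:
    """Least-squares generator fit: minimise ||T~ - exp(tau*Q)||_F^2.

    Rates are bounded below by zero and restricted to the allowed-transition
    mask (single-flip moves for a composite space; all off-diagonals
    otherwise).  Initialisation is the linearised estimate
    max((T~ - I)/tau, 0) on allowed entries, which makes the fit
    deterministic.
    """
    t_target = model.T_sym if model.T_sym is not None else model.T
    k = t_target.shape[0]
    if mask is None:
        mask = (space.single_flip_mask() if space is not None
                else ~np.eye(k, dtype=bool))
    if mask.shape != (k, k):
        raise ValueError("mask shape does not match the transition matrix")
    tau = model.lag_ns
    x0 = np.maximum((t_target - np.eye(k)) / tau, 0.0)[mask]

    def resid(x: np.ndarray) -> np.ndarray:
        return (expm(tau * _assemble_q(x, mask)) - t_target).ravel()

    sol = least_squares(resid, x0, bounds=(0.0, np.inf), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev)
    if not sol.success and sol.status == 0:
        raise RuntimeError(
            f"rate fit did not converge within {max_nfev} evaluations "
            f"(residual {np.sqrt(2 * sol.cost):.3e})"
        )
    q = _assemble_q(sol.x, mask)
    residual = float(np.linalg.norm(expm(tau * q) - t_target))
    return RateModel(labels=model.labels, Q=q, mask=mask, residual=residual,
                     lag_ns=tau)


class MarkovStateModel:
    """Markov state model of a discrete rotamer-state trajectory.

    Parameters
    ----------
    series : DiscreteStateSeries
        Uniformly sampled state labels (typically the composite H x Y series
        from :func:`compose_states`).
    space : CompositeStateSpace, optional
        When given, rate fitting is restricted to single-flip transitions.

    Examples
    --------
    >>> msm = MarkovStateModel.from_chi1_series(h_states, y_states)
    >>> res = msm.fit(lag_ns=2.8, lag_grid_ns=[0.1, 0.4, 1.2, 2.8, 5.6])
    >>> print(res.summary())
    """

    def __init__(self, series: DiscreteStateSeries,
                 space: CompositeStateSpace | None = None):
        self.series = series
        self.space = space

    @classmethod
    def from_chi1_series(cls, h: DiscreteStateSeries, y: DiscreteStateSeries
                         ) -> "MarkovStateModel":
        space = CompositeStateSpace(h.state_labels, y.state_labels)
        return cls(compose_states(h, y, space), space)

    def fit(self, lag_ns: float, lag_grid_ns: Sequence[float] | None = None,
            plateau_tol: float = 0.05, fit_rates: bool = True) -> "MSMResults":
        counts = count_transitions(self.series, lag_ns)
        model = symmetrize(counts)
        spectral = spectral_timescales(model)
        ck = (ck_convergence(self.series, lag_grid_ns, plateau_tol)
              if lag_grid_ns is not None else None)
        rates = fit_rate_matrix(model, space=self.space) if fit_rates else None
        return MSMResults(model=self, counts=counts, transition=model,
                          spectral=spectral, ck=ck, rates=rates)


@dataclass
class MSMResults:
    """Fit products of a :class:`MarkovStateModel`."""

    model: MarkovStateModel
    counts: TransitionCounts
    transition: TransitionModel
    spectral: SpectralSummary
    ck: CKReport | None
    rates: RateModel | None

    @property
    def stationary(self) -> np.ndarray:
        return self.transition.stationary

    @property
    def timescales_ns(self) -> np.ndarray:
        return self.spectral.timescales_ns

    def summary(self) -> str:
        lines = [
            "Markov state model",
            "==================",
            f"states:        {', '.join(self.transition.labels)}",
            f"frames:        {self.model.series.n} at dt = {self.model.series.dt} ns",
            f"lag time:      {self.transition.lag_ns} ns "
            f"({self.counts.total} transition counts)",
        ]
        pi = ", ".join(f"{p:.4f}" for p in self.stationary)
        lines.append(f"stationary:    [{pi}]")
        ts = self.spectral.timescales_ns
        finite = np.sort(ts[np.isfinite(ts)])[::-1]
        lines.append("implied timescales (ns): "
                     + ", ".join(f"{t:.3g}" for t in finite))
        if self.ck is not None:
            sel = self.ck.selected_lag_ns
            lines.append(
                "CK lag scan:   "
                + ("no plateau found" if sel is None else f"converged lag {sel} ns")
            )
        if self.rates is not None:
            lines.append(f"rate fit residual (Frobenius): {self.rates.residual:.3e}")
            lab = self.rates.labels
            for i in range(len(lab)):
                for j in range(len(lab)):
                    if self.rates.mask[i, j] and self.rates.Q[i, j] > 0:
                        lines.append(
                            f"  k({lab[i]} -> {lab[j]}) = {self.rates.Q[i, j]:.4g} /ns"
                        )
        return "\n".join(lines)
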