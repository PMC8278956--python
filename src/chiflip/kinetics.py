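"""Rotamer-state assignment, dwell statistics and state-conditioned analyses.

The chi1 circle is partitioned into three half-open bins around the canonical
wells: g+ = [0, 120), t = [120, 240), g- = [240, 360).  Discretisation is
frame-wise with no smoothing; dwell lifetimes are maximal runs of one label,
with the first and last run censored (they touch the trajectory boundary) and
excluded from mean lifetimes, the usual survival-analysis convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .series import DihedralSeries, DiscreteStateSeries, DistanceSeries, wrap_degrees

__all__ = [
    "StateAssignmentRule",
    "DEFAULT_ROTAMER_RULE",
    "DwellStatistics",
    "JointHistogram",
    "assign_rotamer",
    "discretize_series",
    "dwell_statistics",
    "occupancy",
    "moving_circular_average",
    "joint_histogram",
    "conditional_contact_probability",
]


@dataclass(frozen=True)
class StateAssignmentRule:
    """Ordered half-open bins [edge_i, edge_{i+1}) on [0, 360) -> labels."""

    edges: tuple[float, ...] = (0.0, 120.0, 240.0, 360.0)
    labels: tuple[str, ...] = ("g+", "t", "g-")

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) != len(self.labels) + 1:
            raise ValueError("need exactly one more edge than labels")
        if e[0] != 0.0 or e[-1] != 360.0 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must increase strictly from 0 to 360")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "labels", tuple(self.labels))

    def assign_codes(self, angles_deg: np.ndarray) -> np.ndarray:
        wrapped = wrap_degrees(angles_deg)
        return np.searchsorted(np.asarray(self.edges), wrapped, side="right").astype(np.int8) - 1


DEFAULT_ROTAMER_RULE = StateAssignmentRule()


def assign_rotamer(chi1_deg: float, rule: StateAssignmentRule = DEFAULT_ROTAMER_RULE) -> str:
    """Label of the half-open bin containing the wrapped angle."""
    if not np.isfinite(chi1_deg):
        raise ValueError("angle must be finite")
    return rule.labels[int(rule.assign_codes(np.asarray([chi1_deg]))[0])]


def discretize_series(series: DihedralSeries,
                      rule: StateAssignmentRule = DEFAULT_ROTAMER_RULE) -> DiscreteStateSeries:
    """Frame-wise rotamer assignment of a chi1 series (no smoothing)."""
    codes = rule.assign_codes(series.angles)
    return DiscreteStateSeries(t0=series.t0, dt=series.dt, n=series.n,
                               residue=series.residue, state_labels=rule.labels,
                               codes=codes)


@dataclass(frozen=True)
class DwellStatistics:
    """Per-state dwell (lifetime) statistics of a discrete series."""

    state_labels: tuple[str, ...]
    dwells_ns: Mapping[str, np.ndarray]          # completed dwells only
    censored_counts: Mapping[str, int]
    censored_duration_ns: float
    dt: float

    def n_dwells(self, state: str) -> int:
        return len(self.dwells_ns[state])

    def mean_lifetime(self, state: str) -> float:
        """Arithmetic mean of completed dwells (ns); NaN if none completed."""
        d = self.dwells_ns[state]
        return float(np.mean(d)) if len(d) else float("nan")

    def sem_lifetime(self, state: str) -> float:
        d = self.dwells_ns[state]
        return float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")

    def total_duration(self) -> float:
        """Sum of all dwell durations, completed plus censored (ns)."""
        comp = sum(float(v.sum()) for v in self.dwells_ns.values())
        return comp + self.censored_duration_ns

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "state": s,
                "n_completed": self.n_dwells(s),
                "mean_lifetime_ns": self.mean_lifetime(s),
                "sem_lifetime_ns": self.sem_lifetime(s),
                "n_censored": self.censored_counts[s],
            }
            for s in self.state_labels
        ]
        return pd.DataFrame(rows)


def _run_lengths(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state code, run length) for maximal runs of identical labels."""
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    return codes[starts], ends - starts


def dwell_statistics(series: DiscreteStateSeries) -> DwellStatistics:
    """Dwell lifetimes from maximal runs; boundary runs censored.

    Run duration is run length x dt, so the durations of all runs (completed
    plus censored) add up exactly to the series duration.
    """
    if series.n < 2:
        raise ValueError("need at least 2 frames for dwell statistics")
    states, lengths = _run_lengths(series.codes)
    durations = lengths * series.dt
    censored = np.zeros(len(states), dtype=bool)
    censored[0] = censored[-1] = True  # a single run is doubly censored
    dwells = {}
    cens_counts = {}
    for i, lab in enumerate(series.state_labels):
        sel = (states == i) & ~censored
        dwells[lab] = durations[sel]
        cens_counts[lab] = int(((states == i) & censored).sum())
    return DwellStatistics(
        state_labels=series.state_labels,
        dwells_ns=dwells,
        censored_counts=cens_counts,
        censored_duration_ns=float(durations[censored].sum()),
        dt=series.dt,
    )


def occupancy(series: DiscreteStateSeries) -> dict[str, float]:
    """Fraction of frames per state; fractions sum to 1."""
    counts = np.bincount(series.codes, minlength=len(series.state_labels))
    return {lab: float(c) / series.n for lab, c in zip(series.state_labels, counts)}


def moving_circular_average(series: DihedralSeries, window: float) -> DihedralSeries:
    """Centred moving circular mean over a time window (ns).

    The mean direction is atan2 of the windowed sine/cosine means, so values
    straddling the 0/360 seam average correctly (359 and 1 -> 0, not 180).
    Windows shrink at the boundaries.  Display/diagnostic only; kinetics
    always operate on the raw series.
    """
    if window < series.dt:
        raise ValueError("window must be at least one sampling interval")
    half = int(round(window / series.dt)) // 2
    rad = np.radians(series.angles)
    s, c = np.sin(rad), np.cos(rad)
    kernel = np.ones(2 * half + 1)
    ones = np.ones_like(s)
    norm = np.convolve(ones, kernel, mode="same")
    ms = np.convolve(s, kernel, mode="same") / norm
    mc = np.convolve(c, kernel, mode="same") / norm
    avg = np.degrees(np.arctan2(ms, mc))
    return DihedralSeries(t0=series.t0, dt=series.dt, n=series.n,
                          residue=series.residue, kind=series.kind, angles=avg)


@dataclass(frozen=True)
class JointHistogram:
    """2D histogram over (state-or-angle, distance)."""

    axis_a: str
    axis_b: str
    bins_a: tuple               # labels (categorical) or bin edges (numeric)
    bins_b: np.ndarray          # numeric bin edges
    counts: np.ndarray
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=list(self.bins_a) if self.counts.shape[0] == len(self.bins_a)
                            else None)


def joint_histogram(a: DiscreteStateSeries | DihedralSeries, b: DistanceSeries,
                    bins_a=None, bins_b=20) -> JointHistogram:
    """Joint counts of a state/angle series against a distance series."""
    a.require_same_grid(b)
    edges_b = np.histogram_bin_edges(b.distances, bins=bins_b)
    if isinstance(a, DiscreteStateSeries):
        labels = a.state_labels
        k = len(labels)
        jb = np.clip(np.searchsorted(edges_b, b.distances, side="right") - 1,
                     0, len(edges_b) - 2)
        counts = np.zeros((k, len(edges_b) - 1), dtype=int)
        np.add.at(counts, (a.codes, jb), 1)
        return JointHistogram("state", b.label or "distance", tuple(labels),
                              edges_b, counts, int(counts.sum()))
    edges_a = (np.asarray(bins_a, float) if bins_a is not None
               else np.linspace(0.0, 360.0, 73))
    counts, _, _ = np.histogram2d(a.angles, b.distances, bins=[edges_a, edges_b])
    counts = counts.astype(int)
    return JointHistogram(a.kind, b.label or "distance", tuple(edges_a),
                          edges_b, counts, int(counts.sum()))


def conditional_contact_probability(states: DiscreteStateSeries, dist: DistanceSeries,
                                    cutoff: float = 4.0) -> dict[str, dict]:
    """P(distance < cutoff | state) with per-state frame counts.

    The default 4 A cutoff is the usual salt-bridge criterion between a
    side-chain nitrogen and carboxylate oxygens; states never visited are
    reported with probability NaN.
    """
    states.require_same_grid(dist)
    below = dist.distances < cutoff
    out: dict[str, dict] = {}
    for i, lab in enumerate(states.state_labels):
        sel = states.codes == i
        n = int(sel.sum())
        p = float(below[sel].mean()) if n else float("nan")
        out[lab] = {"probability": p, "n_frames": n}
    return out
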