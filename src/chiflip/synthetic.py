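"""Synthetic trajectory generation.

Continuous-time Markov jump processes stand in for long unbiased MD
trajectories of flipping side chains: exponential waiting times and
embedded-chain jumps (exact Gillespie simulation) are sampled onto a uniform
grid, then decorated with von Mises angular emissions around rotamer-well
centres and, optionally, state-conditioned Gaussian distance emissions that
mimic loop observables.  Small multi-model coordinate fixtures with
prescribed torsions round out the test surface for dihedral extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .geometry import build_chain
from .series import DihedralSeries, DiscreteStateSeries, DistanceSeries

__all__ = [
    "JumpProcessSpec",
    "EmissionSpec",
    "GeometricFixtureSpec",
    "simulate_jump_process",
    "emit_angles",
    "emit_distance",
    "build_dihedral_fixture",
    "write_fixture_pdb",
]


@dataclass(frozen=True)
class JumpProcessSpec:
    """Ground-truth continuous-time generator for a rotamer jump process.

    ``Q_true`` holds transition rates in 1/ns: off-diagonal entries are
    non-negative, each row sums to zero, and the mean dwell time of state i
    is ``-1/Q_true[i, i]``.
    """

    state_labels: tuple[str, ...]
    Q_true: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.Q_true, dtype=float)
        k = len(self.state_labels)
        if q.shape != (k, k):
            raise ValueError(f"Q_true shape {q.shape} does not match {k} states")
        if not np.all(np.isfinite(q)):
            raise ValueError("rates must be finite")
        off = q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.any(np.abs(q.sum(axis=1)) > 1e-12):
            raise ValueError("rows of Q_true must sum to zero")
        object.__setattr__(self, "Q_true", q)
        object.__setattr__(self, "state_labels", tuple(self.state_labels))

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def mean_dwell(self, state: str) -> float:
        """Mean dwell time (ns) of a state; inf for absorbing states."""
        i = self.state_labels.index(state)
        qii = self.Q_true[i, i]
        return np.inf if qii == 0 else -1.0 / qii

    def stationary_distribution(self) -> np.ndarray:
        """Stationary vector pi with pi @ Q = 0, sum(pi) = 1."""
        k = self.n_states
        a = np.vstack([self.Q_true.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass(frozen=True)
class EmissionSpec:
    """Per-state observation model: von Mises angles, optional distances."""

    angle_mean_deg: Mapping[str, float]
    kappa: float = 50.0
    distance_mean: Mapping[str, float] | None = None
    distance_sd: Mapping[str, float] | None = None
    distance_label: str = ""

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if (self.distance_mean is None) != (self.distance_sd is None):
            raise ValueError("distance mean and sd must be given together")
        if self.distance_sd is not None and any(s <= 0 for s in self.distance_sd.values()):
            raise ValueError("distance sd must be positive")

    @property
    def has_distance(self) -> bool:
        return self.distance_mean is not None


@dataclass(frozen=True)
class GeometricFixtureSpec:
    """Target torsions for a multi-frame 4-point chain fixture."""

    torsions_deg: tuple[float, ...]
    bond_length: float = 1.5
    bond_angle_deg: float = 109.5

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.torsions_deg)
        if not t or not all(np.isfinite(t)):
            raise ValueError("target dihedrals must be finite and non-empty")
        object.__setattr__(self, "torsions_deg", t)


def simulate_jump_process(spec: JumpProcessSpec, duration: float, dt: float,
                          seed: int, residue: str | int = "",
                          initial_state: str | None = None) -> DiscreteStateSeries:
    """Exact CTMC simulation sampled on a uniform grid.

    Gillespie simulation (exponential waiting times, embedded-chain jumps)
    generates the continuous-time path; the returned series records the state
    at ``t = k * dt`` for ``k = 0 .. floor(duration/dt) - 1``.  The initial
    state is drawn from the stationary distribution unless given, emulating a
    trajectory recorded at equilibrium.
    """
    if not (duration > dt > 0):
        raise ValueError("require duration > dt > 0")
    rng = np.random.default_rng(seed)
    q = spec.Q_true
    k = spec.n_states
    exit_rates = -np.diag(q)
    # embedded-chain jump probabilities (rows with zero exit are absorbing)
    jump_p = np.zeros_like(q)
    for i in range(k):
        if exit_rates[i] > 0:
            jump_p[i] = q[i] / exit_rates[i]
            jump_p[i, i] = 0.0
    if initial_state is None:
        state = int(rng.choice(k, p=spec.stationary_distribution()))
    else:
        state = spec.state_labels.index(initial_state)

    jump_times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break  # absorbing
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        state = int(rng.choice(k, p=jump_p[state]))
        jump_times.append(t)
        states.append(state)

    n = int(np.floor(duration / dt + 1e-9))
    grid = dt * np.arange(n)
    idx = np.searchsorted(np.asarray(jump_times), grid, side="right") - 1
    codes = np.asarray(states, dtype=np.int8)[idx]
    return DiscreteStateSeries(t0=0.0, dt=dt, n=n, residue=residue,
                               state_labels=spec.state_labels, codes=codes)


def emit_angles(series: DiscreteStateSeries, emission: EmissionSpec, seed: int,
                kind: str = "chi1") -> DihedralSeries:
    """Draw one von Mises angle per frame around the frame's state mean."""
    missing = [s for s in series.state_labels if s not in emission.angle_mean_deg]
    if missing:
        raise ValueError(f"no angular emission for states {missing}")
    rng = np.random.default_rng(seed)
    means = np.array([emission.angle_mean_deg[s] for s in series.state_labels])
    mu = np.radians(means[series.codes])
    ang = np.degrees(rng.vonmises(mu, emission.kappa))
    return DihedralSeries(t0=series.t0, dt=series.dt, n=series.n,
                          residue=series.residue, kind=kind, angles=ang)


def emit_distance(series: DiscreteStateSeries, emission: EmissionSpec,
                  seed: int) -> DistanceSeries:
    """Draw one state-conditioned Gaussian distance per frame (floored at 0)."""
    if not emission.has_distance:
        raise ValueError("emission spec has no distance parameters")
    missing = [s for s in series.state_labels if s not in emission.distance_mean]
    if missing:
        raise ValueError(f"no distance emission for states {missing}")
    rng = np.random.default_rng(seed)
    mean = np.array([emission.distance_mean[s] for s in series.state_labels])
    sd = np.array([emission.distance_sd[s] for s in series.state_labels])
    d = rng.normal(mean[series.codes], sd[series.codes])
    np.clip(d, 0.0, None, out=d)
    return DistanceSeries(t0=series.t0, dt=series.dt, n=series.n,
                          label=emission.distance_label, distances=d)


def synthesize_residue_set(duration_ns: float, dt_ns: float, seed: int,
                           n_passive: int = 8,
                           preset: str = "WT-HY-composite",
                           rate_scale: float = 1.0
                           ) -> dict[int, dict[str, DihedralSeries]]:
    """Per-residue {phi, psi, chi1} bundles emulating one simulation.

    Residues 143 and 306 get chi1 series emitted from the marginals of one
    composite H x Y jump-process realisation; ``n_passive`` additional
    residues get stationary von Mises angles (single-well chi1, unimodal
    backbone) and stand in for the unaffected bulk of the protein.  All
    series share the same uniform grid, as trajectory extraction would
    produce.

    ``rate_scale`` multiplies every rate of the jump process uniformly: a
    pure change of time unit that preserves all dimensionless properties
    (occupancies, branching ratios, coupling).  Null-calibration checks on
    short trajectories need the slowest mode sampled many times over, which
    the literal microsecond-scale kinetics cannot provide in a
    few-microsecond window; see the methods notes.
    """
    from .presets import get_preset  # deferred: presets imports this module

    rng = np.random.default_rng(seed)
    spec, _ = get_preset(preset)
    if rate_scale != 1.0:
        spec = JumpProcessSpec(spec.state_labels, spec.Q_true * rate_scale,
                               spec.description + f" (rates x{rate_scale})")
    composite = simulate_jump_process(spec, duration_ns, dt_ns,
                                      seed=int(rng.integers(2**31)))
    # composite labels are 'H(x)Y(y)'; split into per-residue factor series
    h_of = [lab.split(")Y(")[0][2:] for lab in composite.state_labels]
    y_of = [lab.split(")Y(")[1][:-1] for lab in composite.state_labels]
    h_labels = tuple(dict.fromkeys(h_of))
    y_labels = tuple(dict.fromkeys(y_of))
    h_codes = np.array([h_labels.index(h) for h in h_of], dtype=np.int8)[composite.codes]
    y_codes = np.array([y_labels.index(y) for y in y_of], dtype=np.int8)[composite.codes]
    grid = dict(t0=composite.t0, dt=composite.dt, n=composite.n)
    h_series = DiscreteStateSeries(residue=143, state_labels=h_labels,
                                   codes=h_codes, **grid)
    y_series = DiscreteStateSeries(residue=306, state_labels=y_labels,
                                   codes=y_codes, **grid)
    chi1_em = {
        143: EmissionSpec({"g-": 300.0, "t": 205.0}),
        306: EmissionSpec({"g-": 300.0, "t": 180.0, "g+": 60.0}),
    }
    out: dict[int, dict[str, DihedralSeries]] = {}
    n = composite.n

    def backbone(res: int, kind: str, mean: float) -> DihedralSeries:
        ang = np.degrees(rng.vonmises(np.radians(mean), 10.0, size=n))
        return DihedralSeries(residue=res, kind=kind, angles=ang, **grid)

    for res, states in ((143, h_series), (306, y_series)):
        out[res] = {
            "phi": backbone(res, "phi", -60.0),
            "psi": backbone(res, "psi", -45.0),
            "chi1": emit_angles(states, chi1_em[res], int(rng.integers(2**31))),
        }
    for k in range(n_passive):
        res = 20 + k
        chi1 = np.degrees(rng.vonmises(np.radians(300.0), 50.0, size=n))
        out[res] = {
            "phi": backbone(res, "phi", -60.0),
            "psi": backbone(res, "psi", -45.0),
            "chi1": DihedralSeries(residue=res, kind="chi1", angles=chi1, **grid),
        }
    return out


def build_dihedral_fixture(spec: GeometricFixtureSpec) -> np.ndarray:
    """Coordinates of shape (n_frames, 4, 3) realising the target torsions."""
    return np.stack([
        build_chain(t, spec.bond_length, spec.bond_angle_deg)
        for t in spec.torsions_deg
    ])


def write_fixture_pdb(coords: np.ndarray, path: str | Path,
                      resname: str = "HIS",
                      atom_names: Sequence[str] = ("N", "CA", "CB", "CG")) -> Path:
    """Write a (n_frames, 4, 3) fixture as a multi-model PDB.

    The default atom names form a chi1 quadruple so the fixture can feed
    dihedral extraction end to end.
    """
    import MDAnalysis as mda

    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[1:] != (4, 3):
        raise ValueError("coords must have shape (n_frames, 4, 3)")
    u = mda.Universe.empty(4, n_residues=1, atom_resindex=[0, 0, 0, 0],
                           trajectory=True)
    u.add_TopologyAttr("names", list(atom_names))
    u.add_TopologyAttr("resnames", [resname])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("elements", ["N", "C", "C", "C"])
    u.load_new(coords, order="fac")
    path = Path(path)
    with mda.Writer(str(path), multiframe=True) as w:
        for _ in u.trajectory:
            w.write(u.atoms)
    return path
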