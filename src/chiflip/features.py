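"""Trajectory reading and observable extraction (dihedrals, distances, RMSD).

Built on MDAnalysis: a :class:`TrajectoryHandle` pairs a topology (PDB) with
a coordinate source (multi-model PDB, XTC or DCD) and the frame interval in
ns, which is always supplied by configuration rather than guessed from file
metadata.  Torsions follow the IUPAC sign convention (cis = 0, positive
counterclockwise looking down the central bond) and are stored on [0, 360).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import MDAnalysis as mda
from MDAnalysis.analysis import rms
from MDAnalysis.lib.distances import calc_dihedrals, distance_array

from .series import DihedralSeries, DistanceSeries
from .series import trim_equilibration  # re-exported: it belongs to this stage

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryHandle",
    "CHI1_ATOMS",
    "extract_dihedrals",
    "extract_distance",
    "compute_rmsd_series",
    "trim_equilibration",
]

#: chi1 = N-CA-CB-(gamma atom); Gly and Ala have no chi1 and are absent.
CHI1_ATOMS: dict[str, tuple[str, str, str, str]] = {
    **{res: ("N", "CA", "CB", "CG") for res in
       ("ARG", "LYS", "MET", "PHE", "TYR", "TRP", "HIS", "LEU",
        "GLU", "GLN", "ASP", "ASN", "PRO")},
    "ILE": ("N", "CA", "CB", "CG1"),
    "VAL": ("N", "CA", "CB", "CG1"),
    "SER": ("N", "CA", "CB", "OG"),
    "THR": ("N", "CA", "CB", "OG1"),
    "CYS": ("N", "CA", "CB", "SG"),
}


@dataclass
class TrajectoryHandle:
    """A topology + coordinate source with an explicit time base."""

    universe: mda.Universe
    frame_interval_ns: float

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be positive")

    @classmethod
    def from_files(cls, topology: str | Path, trajectory: str | Path | None = None,
                   frame_interval_ns: float = 0.1) -> "TrajectoryHandle":
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            u = mda.Universe(str(topology), str(trajectory))
        return cls(universe=u, frame_interval_ns=frame_interval_ns)

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    def times(self) -> np.ndarray:
        return self.frame_interval_ns * np.arange(self.n_frames)


def _quad_indices(residue, kind: str) -> np.ndarray | None:
    """Atom indices of the four torsion-defining atoms, or None if undefined."""

    def named(res, names) -> np.ndarray | None:
        sel = []
        for name in names:
            a = res.atoms[res.atoms.names == name]
            if len(a) != 1:
                return None
            sel.append(a.indices[0])
        return np.asarray(sel)

    seg = residue.segment
    if kind == "chi1":
        quad = CHI1_ATOMS.get(residue.resname.upper())
        if quad is None:
            return None
        return named(residue, quad)
    resids = seg.residues.resids
    pos = int(np.flatnonzero(resids == residue.resid)[0])
    if kind == "phi":
        if pos == 0:
            return None
        prev = seg.residues[pos - 1]
        c_prev = named(prev, ("C",))
        rest = named(residue, ("N", "CA", "C"))
        if c_prev is None or rest is None:
            return None
        return np.concatenate([c_prev, rest])
    if kind == "psi":
        if pos == len(resids) - 1:
            return None
        nxt = seg.residues[pos + 1]
        rest = named(residue, ("N", "CA", "C"))
        n_next = named(nxt, ("N",))
        if rest is None or n_next is None:
            return None
        return np.concatenate([rest, n_next])
    raise ValueError(f"unknown dihedral kind {kind!r}")


def extract_dihedrals(traj: TrajectoryHandle,
                      residues: Iterable[int] | None = None,
                      kinds: Sequence[str] = ("chi1",)) -> list[DihedralSeries]:
    """One series per (residue, kind); undefined torsions warn and are omitted.

    Gly/Ala requested for chi1, chain-terminal residues requested for phi/psi,
    and residues with missing atoms are skipped with a logged warning.
    """
    u = traj.universe
    if residues is None:
        res_list = list(u.residues)
    else:
        wanted = set(residues)
        res_list = [r for r in u.residues if r.resid in wanted]
    quads, meta = [], []
    for res in res_list:
        for kind in kinds:
            idx = _quad_indices(res, kind)
            if idx is None:
                logger.warning("omitting %s of %s%d: atoms not defined",
                               kind, res.resname, res.resid)
                continue
            quads.append(idx)
            meta.append((int(res.resid), kind))
    if not quads:
        return []
    quads_arr = np.asarray(quads)
    n_frames = traj.n_frames
    angles = np.empty((n_frames, len(quads)))
    for f, _ in enumerate(u.trajectory):
        pos = u.atoms.positions
        angles[f] = calc_dihedrals(pos[quads_arr[:, 0]], pos[quads_arr[:, 1]],
                                   pos[quads_arr[:, 2]], pos[quads_arr[:, 3]])
    angles = np.degrees(angles) % 360.0
    return [
        DihedralSeries(t0=0.0, dt=traj.frame_interval_ns, n=n_frames,
                       residue=resid, kind=kind, angles=angles[:, k])
        for k, (resid, kind) in enumerate(meta)
    ]


def extract_distance(traj: TrajectoryHandle, group_a: str, group_b: str,
                     reducer: str = "single", label: str = "") -> DistanceSeries:
    """Per-frame distance between two atom selections.

    ``reducer="single"`` requires one atom per selection; ``"min"`` takes the
    minimum over all cross pairs (e.g. side-chain N-zeta against either
    carboxylate oxygen for a salt bridge).
    """
    u = traj.universe
    ga, gb = u.select_atoms(group_a), u.select_atoms(group_b)
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("empty atom selection")
    if reducer == "single" and (len(ga) != 1 or len(gb) != 1):
        raise ValueError("reducer='single' requires exactly one atom per group")
    if reducer not in ("single", "min"):
        raise ValueError(f"unknown reducer {reducer!r}")
    d = np.empty(traj.n_frames)
    for f, _ in enumerate(u.trajectory):
        d[f] = distance_array(ga.positions, gb.positions).min()
    return DistanceSeries(t0=0.0, dt=traj.frame_interval_ns, n=traj.n_frames,
                          label=label or f"{group_a}|{group_b}",
                          distances=d, reducer=reducer)


def compute_rmsd_series(traj: TrajectoryHandle, reference_frame: int = 0,
                        selection: str = "name CA") -> DistanceSeries:
    """RMSD to a reference frame after optimal rigid-body superposition.

    The usual equilibration diagnostic: the configured equilibration time is
    chosen by inspecting this series, then applied with
    :func:`trim_equilibration`.
    """
    u = traj.universe
    sel = u.select_atoms(selection)
    if len(sel) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    u.trajectory[reference_frame]
    ref = sel.positions.copy()
    out = np.empty(traj.n_frames)
    for f, _ in enumerate(u.trajectory):
        out[f] = rms.rmsd(sel.positions, ref, center=True, superposition=True)
    return DistanceSeries(t0=0.0, dt=traj.frame_interval_ns, n=traj.n_frames,
                          label=f"RMSD[{selection}]", distances=out)
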