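"""Configured pipeline orchestration.

A YAML :class:`PipelineConfig` names the input sources (a synthesis preset,
trajectory files, or directories of series tables), the analysis constants
(rotamer rule, lag grid, KDE kappa/bins, block edges, equilibration times,
exclusion list) and explicit seeds for every stochastic step.  Stages run in
dependency order and every run writes a JSON summary that carries provenance
(config hash, seed, package version) so identical configurations reproduce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import (DEFAULT_BLOCK_EDGES_NS, DEFAULT_EXCLUDED_RESIDUES,
                         block_baseline, compare_simulations, paint_structure,
                         records_to_frame)
from .features import TrajectoryHandle, extract_dihedrals
from .kinetics import (DEFAULT_ROTAMER_RULE, discretize_series, dwell_statistics,
                       occupancy)
from .msm import MarkovStateModel, CompositeStateSpace
from .presets import get_preset
from .series import DihedralSeries, DiscreteStateSeries, trim_equilibration
from .synthetic import emit_angles, emit_distance, simulate_jump_process

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationError", "run_pipeline", "load_residue_set"]

STAGE_ORDER = ("simulate", "features", "kinetics", "msm", "divergence", "paint")


class ValidationError(ValueError):
    """Configuration invalid; raised before any stage runs."""


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw, path=path)

    def get(self, *keys, default=None):
        node: Any = self.raw
        for k in keys:
            if not isinstance(node, Mapping) or k not in node:
                return default
            node = node[k]
        return node

    @property
    def seed(self) -> int:
        return int(self.get("seed", default=0))

    @property
    def output_dir(self) -> Path:
        return Path(self.get("output_dir", default="chiflip_out"))

    def sha256(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()

    def validate(self, stages: Sequence[str]) -> None:
        for key in ("topology", "trajectory"):
            p = self.get("features", key)
            if "features" in stages and p and not Path(p).exists():
                raise ValidationError(f"features.{key} does not exist: {p}")
        for key in ("a_dir", "b_dir"):
            p = self.get("divergence", key)
            if "divergence" in stages and p and not Path(p).exists():
                raise ValidationError(f"divergence.{key} does not exist: {p}")
        p = self.get("paint", "structure")
        if "paint" in stages and p and not Path(p).exists():
            raise ValidationError(f"paint.structure does not exist: {p}")
        if "simulate" in stages and self.get("simulate", "preset") is None:
            raise ValidationError("simulate stage requires simulate.preset")


def load_residue_set(directory: str | Path) -> dict[int, dict[str, DihedralSeries]]:
    """Load ``res<id>_<kind>.csv`` series tables from a directory."""
    out: dict[int, dict[str, DihedralSeries]] = {}
    pat = re.compile(r"res(\d+)_(phi|psi|chi1)\.csv$")
    for f in sorted(Path(directory).glob("res*_*.csv")):
        m = pat.match(f.name)
        if not m:
            continue
        resid, kind = int(m.group(1)), m.group(2)
        out.setdefault(resid, {})[kind] = DihedralSeries.from_csv(f, residue=resid,
                                                                  kind=kind)
    if not out:
        raise ValidationError(f"no residue series tables found in {directory}")
    return out


def _stage_simulate(cfg: PipelineConfig, out: Path, summary: dict) -> dict:
    name = cfg.get("simulate", "preset")
    spec, emission = get_preset(name)
    duration = float(cfg.get("simulate", "duration_ns", default=10_000.0))
    dt = float(cfg.get("simulate", "dt_ns", default=0.1))
    seed = int(cfg.get("simulate", "seed", default=cfg.seed))
    states = simulate_jump_process(spec, duration, dt, seed, residue=name)
    states.to_csv(out / "states.csv")
    artefacts = {"states": "states.csv"}
    if emission.angle_mean_deg:
        chi1 = emit_angles(states, emission, seed + 1)
        chi1.to_csv(out / "chi1.csv")
        artefacts["chi1"] = "chi1.csv"
    if emission.has_distance:
        dist = emit_distance(states, emission, seed + 2)
        dist.to_csv(out / "distance.csv")
        artefacts["distance"] = "distance.csv"
    summary["simulate"] = {
        "preset": name, "duration_ns": duration, "dt_ns": dt, "seed": seed,
        "n_frames": states.n, "state_labels": list(states.state_labels),
        "artefacts": artefacts,
    }
    return {"states": states}


def _stage_features(cfg: PipelineConfig, out: Path, summary: dict) -> dict:
    top = cfg.get("features", "topology")
    traj = cfg.get("features", "trajectory")
    handle = TrajectoryHandle.from_files(
        top, traj, float(cfg.get("features", "frame_interval_ns", default=0.1)))
    residues = cfg.get("features", "residues")
    kinds = tuple(cfg.get("features", "kinds", default=("chi1",)))
    series = extract_dihedrals(handle, residues, kinds)
    t_eq = float(cfg.get("equilibration_ns", default=0.0))
    if t_eq > 0:
        series = [trim_equilibration(s, t_eq) for s in series]
    for s in series:
        s.to_csv(out / f"res{s.residue}_{s.kind}.csv")
    summary["features"] = {
        "topology": str(top), "trajectory": str(traj) if traj else None,
        "equilibration_ns": t_eq,
        "series": [f"res{s.residue}_{s.kind}.csv" for s in series],
    }
    return {"dihedrals": series}


def _states_for_kinetics(cfg: PipelineConfig, state: dict) -> list[DiscreteStateSeries]:
    if "states" in state:
        return [state["states"]]
    if "dihedrals" in state:
        return [discretize_series(s, DEFAULT_ROTAMER_RULE)
                for s in state["dihedrals"] if s.kind == "chi1"]
    path = cfg.get("kinetics", "states_csv")
    if path is None:
        raise ValidationError("kinetics stage has no upstream states and no "
                              "kinetics.states_csv")
    return [DiscreteStateSeries.from_csv(path)]


def _stage_kinetics(cfg: PipelineConfig, out: Path, summary: dict, state: dict) -> dict:
    all_series = _states_for_kinetics(cfg, state)
    tables = []
    occs = {}
    for s in all_series:
        stats = dwell_statistics(s)
        df = stats.to_frame()
        df.insert(0, "residue", s.residue)
        tables.append(df)
        occs[str(s.residue)] = occupancy(s)
    dwell_df = pd.concat(tables, ignore_index=True)
    dwell_df.to_csv(out / "dwell_table.csv", index=False)
    summary["kinetics"] = {
        "dwell_table": "dwell_table.csv",
        "occupancy": occs,
        "mean_lifetimes_ns": {
            str(s.residue): {
                row["state"]: None if pd.isna(row["mean_lifetime_ns"])
                else float(row["mean_lifetime_ns"])
                for _, row in dwell_statistics(s).to_frame().iterrows()
            } for s in all_series
        },
    }
    return {"state_series": all_series}


def _stage_msm(cfg: PipelineConfig, out: Path, summary: dict, state: dict) -> dict:
    series = state.get("states")
    if series is None:
        series_list = state.get("state_series") or _states_for_kinetics(cfg, state)
        series = series_list[0]
    lag = float(cfg.get("msm", "lag_ns", default=2.8))
    grid = cfg.get("msm", "lag_grid_ns")
    tol = float(cfg.get("msm", "plateau_tol", default=0.05))
    space = None
    if len(series.state_labels) == 6:
        space = CompositeStateSpace()
    res = MarkovStateModel(series, space).fit(
        lag_ns=lag, lag_grid_ns=grid, plateau_tol=tol)
    pd.DataFrame(res.transition.T, index=list(series.state_labels),
                 columns=list(series.state_labels)).to_csv(out / "T.csv")
    pd.DataFrame(res.transition.T_sym, index=list(series.state_labels),
                 columns=list(series.state_labels)).to_csv(out / "T_sym.csv")
    res.rates.to_frame().to_csv(out / "rates.csv")
    ts = res.timescales_ns
    summary["msm"] = {
        "lag_ns": lag,
        "stationary": [float(x) for x in res.stationary],
        "timescales_ns": [None if not np.isfinite(t) else float(t) for t in ts],
        "ck": None if res.ck is None else {
            "lag_grid_ns": list(res.ck.lag_grid_ns),
            "slowest_ns": [float(x) for x in res.ck.slowest_ns],
            "selected_lag_ns": res.ck.selected_lag_ns,
        },
        "rate_fit_residual": res.rates.residual,
        "artefacts": {"T": "T.csv", "T_sym": "T_sym.csv", "rates": "rates.csv"},
    }
    (out / "msm_summary.txt").write_text(res.summary() + "\n")
    return {"msm": res}


def _stage_divergence(cfg: PipelineConfig, out: Path, summary: dict) -> dict:
    a = load_residue_set(cfg.get("divergence", "a_dir"))
    b = load_residue_set(cfg.get("divergence", "b_dir"))
    kappa = float(cfg.get("divergence", "kappa", default=120.0))
    bins = int(cfg.get("divergence", "bins", default=120))
    edges = tuple(cfg.get("divergence", "block_edges_ns",
                          default=DEFAULT_BLOCK_EDGES_NS))
    mode = cfg.get("divergence", "baseline_mode", default="per-residue")
    excl = cfg.get("divergence", "exclusions", default=DEFAULT_EXCLUDED_RESIDUES)
    baseline = block_baseline(a, edges, kappa, bins, mode=mode)
    records = compare_simulations(a, b, baseline, exclusions=excl,
                                  kappa=kappa, bins=bins)
    df = records_to_frame(records)
    df.to_csv(out / "divergence.csv", index=False)
    summary["divergence"] = {
        "n_residues": len(records),
        "n_significant": int(df["significant"].sum()),
        "records": "divergence.csv",
        "baseline_mode": mode,
    }
    return {"records": records}


def _stage_paint(cfg: PipelineConfig, out: Path, summary: dict, state: dict) -> dict:
    records = state.get("records")
    if records is None:
        df = pd.read_csv(cfg.get("paint", "records_csv"))
        from .divergence import DivergenceRecord
        records = [DivergenceRecord(int(r.residue), r.h_phipsi, r.h_chi1,
                                    r.h_total, r.baseline, bool(r.significant))
                   for r in df.itertuples()]
    painted = paint_structure(records, cfg.get("paint", "structure"),
                              out / "painted.pdb")
    summary["paint"] = {"painted": painted.name}
    return {}


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = STAGE_ORDER) -> dict:
    """Run the requested stages in dependency order; return the summary dict.

    Stage failure aborts with the failing stage named; outputs of completed
    stages are preserved in the output directory.
    """
    stages = [s for s in STAGE_ORDER if s in set(stages)]
    if not stages:
        raise ValidationError("no recognised stages requested")
    config.validate(stages)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "provenance": {
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "chiflip_version": __version__,
            "stages": stages,
        }
    }
    state: dict[str, Any] = {}
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                state.update(_stage_simulate(config, out, summary))
            elif stage == "features":
                state.update(_stage_features(config, out, summary))
            elif stage == "kinetics":
                state.update(_stage_kinetics(config, out, summary, state))
            elif stage == "msm":
                state.update(_stage_msm(config, out, summary, state))
            elif stage == "divergence":
                state.update(_stage_divergence(config, out, summary))
            elif stage == "paint":
                state.update(_stage_paint(config, out, summary, state))
        except ValidationError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
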