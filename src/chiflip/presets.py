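"""Named jump-process presets parameterised by printed lifetimes/occupancies.

The YAML file shipped with the package declares, per preset, the constrained
quantities (mean dwell times in ns, stationary occupancies) and the emission
parameters; this module turns them into explicit rate matrices:

* ``two_state`` — both exit rates fixed by the two mean dwells.
* ``two_state_occupancy`` — one dwell plus the stationary split; the return
  rate follows from detailed balance ``pi_a k_ab = pi_b k_ba``.
* ``star_three_state`` — a hub state exchanging with two spokes; spoke dwell
  times fix the spoke->hub rates, one spoke occupancy plus the hub dwell fix
  the branching out of the hub (flow balance on the star).
* ``composite_hy`` — tensor product of an H-factor and a Y-factor process
  with state-dependent rate modulation, used for six-state property tests.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Mapping

import numpy as np
import yaml

from .synthetic import EmissionSpec, JumpProcessSpec

__all__ = ["available_presets", "get_preset", "composite_label"]


def composite_label(h: str, y: str) -> str:
    return f"H({h})Y({y})"


@lru_cache(maxsize=1)
def _raw() -> dict:
    text = (importlib.resources.files("chiflip") / "presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return list(_raw()["presets"])


def _emission(entry: Mapping, default_kappa: float) -> EmissionSpec:
    em = entry.get("emission", {})
    dist = em.get("distance")
    return EmissionSpec(
        angle_mean_deg=dict(em.get("angle_mean_deg", {})),
        kappa=float(em.get("kappa", default_kappa)),
        distance_mean=dict(dist["mean_A"]) if dist else None,
        distance_sd=dict(dist["sd_A"]) if dist else None,
        distance_label=dist.get("label", "") if dist else "",
    )


def _two_state(states, dwell) -> np.ndarray:
    a, b = states
    ka, kb = 1.0 / dwell[a], 1.0 / dwell[b]
    return np.array([[-ka, ka], [kb, -kb]])


def _two_state_occupancy(states, occ, dwell) -> np.ndarray:
    a, b = states
    if a in dwell:
        ka = 1.0 / dwell[a]
        kb = (occ[a] / occ[b]) * ka
    else:
        kb = 1.0 / dwell[b]
        ka = (occ[b] / occ[a]) * kb
    return np.array([[-ka, ka], [kb, -kb]])


def _star_three_state(states, hub, dwell, occ) -> np.ndarray:
    spokes = [s for s in states if s != hub]
    s_fixed = next(s for s in spokes if s in occ)
    s_free = next(s for s in spokes if s not in occ)
    pf = occ[s_fixed]
    # flow balance: sum_s pi_s / tau_s = pi_hub / tau_hub with pi summing to 1
    x = ((1.0 - pf) / dwell[hub] - pf / dwell[s_fixed]) / (
        1.0 / dwell[s_free] + 1.0 / dwell[hub]
    )
    if x <= 0:
        raise ValueError("inconsistent star parameters: free spoke occupancy <= 0")
    pi = {hub: 1.0 - pf - x, s_fixed: pf, s_free: x}
    k = len(states)
    q = np.zeros((k, k))
    ih = states.index(hub)
    for s in spokes:
        i = states.index(s)
        q[i, ih] = 1.0 / dwell[s]                      # spoke -> hub
        q[ih, i] = pi[s] / (dwell[s] * pi[hub])        # hub -> spoke
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _composite_hy(entry: Mapping) -> tuple[tuple[str, ...], np.ndarray]:
    h_spec, _ = get_preset(entry["h_preset"])
    y_spec, _ = get_preset(entry["y_preset"])
    y_slow = float(entry["y_slow_when_h_t"])
    h_boost = float(entry["h_forward_boost_y_gp"])
    h_drop = float(entry["h_back_drop_y_gp"])
    hl, yl = h_spec.state_labels, y_spec.state_labels
    labels = tuple(composite_label(h, y) for h in hl for y in yl)
    nh, ny = len(hl), len(yl)
    q = np.zeros((nh * ny, nh * ny))
    for i, h in enumerate(hl):
        for j, y in enumerate(yl):
            a = i * ny + j
            for j2, y2 in enumerate(yl):       # Y flips (H fixed)
                if j2 == j:
                    continue
                rate = y_spec.Q_true[j, j2]
                if h == "t":
                    rate *= y_slow
                q[a, i * ny + j2] = rate
            for i2, h2 in enumerate(hl):       # H flips (Y fixed)
                if i2 == i:
                    continue
                rate = h_spec.Q_true[i, i2]
                if y == "g+":
                    rate *= h_boost if h == "g-" else h_drop
                q[a, i2 * ny + j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return labels, q


def get_preset(name: str) -> tuple[JumpProcessSpec, EmissionSpec]:
    """Build (JumpProcessSpec, EmissionSpec) for a named preset."""
    raw = _raw()
    try:
        entry = raw["presets"][name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    kind = entry["kind"]
    default_kappa = float(raw.get("defaults", {}).get("kappa", 50.0))
    if kind == "composite_hy":
        labels, q = _composite_hy(entry)
    else:
        states = list(entry["states"])
        dwell = {k: float(v) for k, v in entry.get("mean_dwell_ns", {}).items()}
        occ = {k: float(v) for k, v in entry.get("occupancy", {}).items()}
        if kind == "two_state":
            q = _two_state(states, dwell)
        elif kind == "two_state_occupancy":
            q = _two_state_occupancy(states, occ, dwell)
        elif kind == "star_three_state":
            q = _star_three_state(states, entry["hub"], dwell, occ)
        else:
            raise ValueError(f"unknown preset kind {kind!r}")
        labels = tuple(states)
    spec = JumpProcessSpec(state_labels=labels, Q_true=q,
                           description=str(entry.get("description", "")).strip())
    return spec, _emission(entry, default_kappa)
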