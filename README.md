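# chiflip

Side-chain rotamer **flip kinetics** from molecular-dynamics trajectories:
dwell-time statistics of χ1 rotamer states, composite Markov state models
with rate-matrix fitting, and per-residue Hellinger-divergence maps that
localise how a mutation reshapes a protein's conformational sampling.

The package targets the analysis layer of long (multi-microsecond) unbiased
MD studies of enzymes whose function is gated by aromatic side-chain flips —
the motivating system is human histone deacetylase 8 (HDAC8), where the χ1
flips of Y306, H143 and F152 open and close the functional loops around the
active site — but every stage works on any trajectory, or on plain CSV
time-series tables, or on synthetic jump-process data generated by the
package itself.

## What it computes

**Rotamer kinetics.** A χ1 time series is discretised into the three
canonical wells, g+ = [0°, 120°), t = [120°, 240°), g− = [240°, 360°).
Maximal runs of one label are dwells; boundary runs are censored and
excluded from mean lifetimes. Occupancies, moving circular averages,
state–distance joint histograms and state-conditioned contact probabilities
round out the single-residue analyses.

**Markov state model.** Two residues' states compose into a six-state space
(e.g. {H143(g−), H143(t)} × {Y306(g−), Y306(t), Y306(g+)}). Transitions are
counted at a lag time τ_lag with a sliding window, row-normalised into
**T**, and symmetrised in count space into a reversible **T̃**. Implied
relaxation times

    t_i = −τ_lag / log λ_i

from the eigenvalues λ_i of T̃ are scanned over a lag grid; the model is
accepted at the smallest lag where the slowest t_i becomes lag-independent
(Chapman–Kolmogorov criterion). Flip rates are then obtained by a bounded
least-squares fit of the generator,

    min_Γ ‖ T̃ − exp(−τ_lag Γ) ‖²_F ,

with only single-flip transitions allowed (either residue flips at a lag,
never both).

**Divergence mapping.** Per residue, backbone {φ,ψ} and side-chain χ1
distributions are estimated with a von Mises kernel (κ = 120, 120 bins on
[−180°, 180°), convolution done spectrally so smoothing wraps the seam) and
two simulations are compared by the Hellinger distance
H² = 1 − Σ_i √(p_i q_i), combined as H_T² = H²_{φψ} + H²_{χ1}. A residue is
flagged only when H_T exceeds the sampling-noise floor obtained from a block
analysis of the reference simulation (default: four 2.5 μs blocks). Flagged
values can be painted into a PDB B-factor column for structure viewing.

**Synthetic data.** Continuous-time Markov jump processes (exact Gillespie
simulation sampled onto a uniform grid) with von Mises angular emissions
stand in for trajectories. Shipped presets are parameterised by the
reference study's printed values — e.g. `WT-F152` (1.4/1.1 ns lifetimes),
`WT-H143-fig4` (11 ns), `WT-Y306` (1.3 μs g− lifetime), `I19S-Y306`
(99.9 %/0.1 % occupancies) — so the whole pipeline is testable end to end
without any deposited trajectory.

## Worked example

Simulate the wild-type H143 two-state preset for 100 μs, run kinetics and
the MSM, all from one config:

```yaml
# demo.yaml
seed: 42
output_dir: demo_out
simulate: {preset: WT-H143-fig4, duration_ns: 100000, dt_ns: 0.1}
kinetics: {}
msm: {lag_ns: 2.8, lag_grid_ns: [0.7, 1.4, 2.8, 5.6, 11.2]}
```

```bash
chiflip run-all demo.yaml
cat demo_out/msm_summary.txt
```

```
Markov state model
==================
states:        g-, t
frames:        1000000 at dt = 0.1 ns
lag time:      2.8 ns (999972 transition counts)
stationary:    [0.5076, 0.4924]
implied timescales (ns): 5.46
CK lag scan:   converged lag 0.7 ns
rate fit residual (Frobenius): 1.415e-16
  k(g- -> t) = 0.09017 /ns
  k(t -> g-) = 0.09295 /ns
```

Reading the numbers: the preset's ground truth is an 11 ns mean dwell in
each state, i.e. exchange rates 1/11 ≈ 0.0909 /ns — the fitted rates
(0.0902, 0.0930 /ns) recover them to ~2 %. The single implied timescale,
5.46 ns, matches the two-state relaxation time 1/(k₁+k₂) = 5.5 ns, and it is
flat across the lag grid (5.49, 5.50, 5.46, 5.39, 5.43 ns), so the chain is
Markovian already at the shortest lag tested. The dwell table in
`demo_out/summary.json` reports mean lifetimes 11.26 ns (g−) and 10.91 ns
(t) with occupancies 0.508/0.492.

The same stages run on real data: point `features:` at a topology +
trajectory (multi-model PDB, XTC, DCD), set the frame interval and
equilibration time, and the extracted per-residue series flow through the
identical kinetics/MSM/divergence code paths. The library API mirrors the
CLI — see `chiflip.MarkovStateModel`, whose `fit()` returns a results object
with the matrices, spectra, CK report, rate fit and `summary()`.

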