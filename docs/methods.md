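# Methods notes

This note records the models, conventions and numerical choices behind
chiflip, what the synthetic-data generator does and does not emulate, and
the known limitations of each stage.

## Synthetic jump processes

State dynamics are continuous-time Markov chains with generator Q (1/ns):
off-diagonal q_ij ≥ 0 are flip rates, rows sum to zero, and the mean dwell
of state i is −1/q_ii. Simulation is exact (Gillespie): exponential waiting
times with the state's exit rate, embedded-chain jumps by the normalised
off-diagonal row. The continuous path is then read out at t = k·dt, which
mirrors how MD analyses sample a trajectory at a fixed stride (the reference
conventions here are 100 ps strides for nanosecond flips, 1 ns for
microsecond flips). The initial state is drawn from the stationary
distribution so every series is a window of an equilibrium record.

Grid read-out biases dwell estimates: a dwell shorter than dt can be missed,
and run lengths are quantised. For exponential dwells the observed mean run
duration is ≈ τ + dt/2 − O(dt²/τ), a relative bias ≤ dt/τ at the sampling
ratios used here (dt/τ between 1/110 and 1/1300 in the shipped presets);
the recovery tests absorb it inside their max(5 %, 3 SE) tolerance.

### Preset parameterisation

Presets are declared in `presets.yaml` by their constrained quantities and
converted to rates:

* **two_state** — both exit rates fixed by the two mean dwells.
* **two_state_occupancy** — one dwell plus the stationary split; the return
  rate follows from detailed balance. Used where only occupancies are
  printed (I19S/S39E Y306); the 1 μs g− dwell is a synthetic choice, since
  the exchange speed is not constrained.
* **star_three_state** — the Y306 wild-type model: a g− hub exchanging with
  t and g+ spokes. Spoke dwells set the spoke→hub rates; the hub dwell
  (1.3 μs) and one spoke occupancy (trans at 0.5 %) close the flow-balance
  equations for the hub branching. The trans dwell (10 ns) and g+ dwell
  (0.3 μs) are synthetic choices; only the g− dwell is a recovery quantity.
* **composite_hy** — the tensor product of the H143 and Y306 factors with
  state-dependent modulation: all Y rates are slowed 20-fold while H is
  trans (the Y flip is essentially frozen there), and while Y is g+ the
  H g−→t rate is doubled and the t→g− rate quartered (H(t) stabilised).
  The coupling constants are qualitative; this preset backs property and
  pipeline tests, not numeric recovery.

Angular emissions are von Mises around the well centres (g− 300°, t
180–205° per residue, g+ 60°) with κ = 50 by default, i.e. ≈ 8° circular
spread — wells separated by ≥ 95° are then ≥ 11 kernel widths apart, so
re-discretisation recovers the state path exactly with overwhelming
probability (mislabel probability < 1e−6 per frame). Distance emissions are
state-conditioned Gaussians floored at zero; they emulate the
state-separated loop observables (e.g. the ~6.2 Å vs ~11.5 Å tyrosine–zinc
distances) only at the level of per-state location/scale, with no
autocorrelation within a state.

What the generator does **not** emulate: intra-well angular autocorrelation
(frames are conditionally independent given the state), transition paths
through barrier regions (state changes are instantaneous, so there is no
recrossing blur at well edges), coupling between backbone and side chain,
and any non-Markovian memory. Passing recovery tests therefore validates
the estimators under the model's own assumptions; on real trajectories,
recrossings at rotamer boundaries shorten apparent dwells, which is the
usual argument for core-set assignments that are deliberately out of scope
here (the reference analyses discretise raw samples, and so does chiflip).

## Rotamer assignment and dwell statistics

Bins are half-open, [0°, 120°) → g+, [120°, 240°) → t, [240°, 360°) → g−,
symmetric around the canonical 60°/180°/300° centres; angles on an edge
belong to the bin on the right (deterministic, documented convention). No
smoothing or hysteresis is applied before counting.

Dwells are maximal runs; duration = run length × dt, so completed plus
censored durations sum exactly to the series duration (asserted as an
invariant). The first and last runs touch the window boundary and are
censored: including them would bias mean lifetimes downward for slow states
(a boundary run is an incomplete draw). States never visited report zero
dwells; a constant series reports one doubly-censored run and an undefined
mean (NaN, serialised as missing).

The moving average shown for display is a *circular* mean (atan2 of
windowed sine/cosine means) over a centred window that shrinks at the
boundaries. A linear moving average of wrapped angles would produce
spurious mid-range values whenever the window straddles the 0°/360° seam;
the circular mean is the standard fix and is used only for display — no
kinetic quantity is computed from smoothed series.

## Markov state model

* **Counting**: sliding window — every frame is a window start, C[i,j]
  accumulates (state_k, state_{k+τ/dt}) pairs. This maximises counts; at
  lags ≫ dt the pairs overlap and are correlated, which inflates nominal
  counts but not the expectation of T.
* **Symmetrisation**: C̃ = (C + Cᵀ)/2, then row-normalise. The resulting
  chain satisfies detailed balance exactly with stationary vector = row
  sums of C̃ / total. This is the simplest reversible estimator; the
  maximum-likelihood reversible estimator is deliberately not implemented.
  For data from a genuinely reversible process the two transition matrices
  agree asymptotically; for non-reversible chains the symmetrised spectrum
  is lag-dependent (measured ~7 % drift on random non-reversible six-state
  generators), which is why Markovianity checks in the test-suite draw
  *reversible* generators — the physically relevant case for equilibrium
  trajectories.
* **Spectra**: eigenvalues sorted by modulus; t_i = −τ_lag/log λ_i only for
  0 < λ_i < 1; the Perron eigenvalue must be 1 within 1e−10 or the input is
  rejected as non-stochastic. Timescales for λ ≤ 0 (noise at long lags) are
  reported as NaN rather than clamped.
* **Lag selection**: the slowest t_i is computed on a lag grid; the chosen
  lag is the smallest grid point from which all later estimates stay within
  a 5 % relative band of it. No plateau ⇒ the report carries a null
  selected lag and a flag, not an exception.
* **Rate fit**: generator Q with non-negative off-diagonals restricted to
  the single-flip mask (18 of 30 off-diagonals in the 6-state space),
  diagonal = −row sum; scipy `least_squares` (trf, bounds [0, ∞)) on the
  residual exp(τQ) − T̃, initialised from max((T̃ − I)/τ, 0) so the result
  is deterministic; tolerances 1e−15, iteration cap 10 000. On exact inputs
  the fit recovers rates over [1e−3, 5]/ns to better than 1e−6 relative.
  Sign convention: the propagator is written exp(−τΓ) in the field's
  notation with Γ = −Q; `RateModel.Gamma` returns that form, everything
  internal uses the standard generator to avoid sign bugs.

## Circular KDE and Hellinger mapping

Densities live on 120 bin centres over [−180°, 180°). Samples are binned,
the histogram is circularly convolved with a von Mises kernel of κ = 120
(≈ 5.2° width) via the DFT, and the result is renormalised. Spectral
convolution makes the wrap at ±180° exact, and the choice of histogram
convolution (rather than a truncated Fourier-series estimator) is recorded
here as the adopted reading of "von Mises estimation in Fourier space" —
both converge to the same smoothed density, and against the analytic von
Mises⁎von Mises convolution (Bessel-coefficient products) the estimator's
total variation error is < 0.01 at n = 1e5. The bivariate {φ,ψ} kernel is
the separable product with the same κ per axis; separability is asserted by
marginalisation tests.

Hellinger distance uses the standard discrete form H² = 1 − Σ√(p_i q_i)
(the only common definition bounded in [0,1] that makes the quadrature
combination H_T² = H²_{φψ} + H²_{χ1} coherent); identical inputs short-cut
to exactly 0. Residues without χ1 (Gly/Ala) contribute H_{χ1} = 0, so H_T
reduces to the backbone term. H_T can exceed 1 by construction (≤ √2).

**Significance baseline.** The reference simulation is cut into consecutive
blocks (default edges 0/2.5/5/7.5/10 μs) and H_T is computed for all
unordered block pairs; the per-residue mean is the noise floor, and a
cross-simulation H_T is significant iff it exceeds that residue's floor.
Config switches offer a global-mean floor and a stricter mean + 2·SD mode.
A per-residue floor is used by default because the comparison itself is
residue-specific. The loop K202–V217 is excluded from reporting by default
(its sampling convergence cannot be established on the reference data).
No multiple-testing correction is applied, deliberately.

**Convergence requirement.** The block baseline is only meaningful when
each block samples every relevant mode many times: blocks one quarter the
trajectory length have roughly twice the sampling noise of the full record,
and that ordering — floor above cross-run noise — is exactly what makes a
null comparison (two realisations of the same process) come out empty. When
a mode's dwell approaches the block length, the floor and the cross-run
divergence both become order-one random variables and the comparison is
uninformative — flags there reflect unconverged sampling, not mechanism.
The end-to-end null test therefore runs the composite process under a
uniform time rescaling (all rates ×200 — a pure change of time unit that
preserves occupancies, branching ratios and coupling) so that the slowest
flip mode completes ~100 dwells per block; at literal microsecond-scale
kinetics a few-microsecond window contains ~2 slow-mode transitions and a
null comparison flags a residue in roughly a third of realisations. This
mirrors the practice, adopted from the reference analysis, of excluding
regions whose convergence cannot be justified.

## Trajectory features

Dihedral and distance extraction and RMSD superposition go through
MDAnalysis. χ1 quadruples follow the IUPAC convention (N–CA–CB–γ with γ =
CG/CG1/OG/OG1/SG per residue type; Gly and Ala have none). Torsions use the
IUPAC sign (cis = 0°, positive counterclockwise viewed A→D) and are stored
in [0°, 360°); conversion to [−180°, 180°) happens only inside the KDE.
Undefined torsions (Gly/Ala χ1, chain-terminal φ/ψ, missing atoms) are
omitted with a logged warning rather than raising. The frame interval is
always a configuration value — file metadata time bases are never trusted.
Equilibration is likewise a config value per simulation (the reference
conventions: 2 μs WT, 1.8 μs S39E, 2.5 μs I19S), chosen by inspecting the
RMSD-to-start diagnostic; no automatic changepoint detection is attempted.

Geometric fixtures place four-point chains by internal-coordinate (NeRF)
construction with fixed bond length (1.5 Å) and angle (109.5°) and a
prescribed torsion; construction and measurement round-trip to < 1e−6°,
and multi-model PDB round-trips are limited only by the format's 1e−3 Å
coordinate precision (≈ 0.02° on these chains).

## Problem sizes used in the shipped checks

Recovery runs use the full stated synthetic lengths (100 μs at 10 ps for
the nanosecond flips through 5 ms at 1 ns for the occupancy target); these
complete in seconds because the jump-process simulator costs per *jump*,
not per frame. The Chapman–Kolmogorov and marginal-consistency property
tests use 100–300 μs of a fast six-state chain (dwells of order 10 ns), and
the null-comparison test uses two 2.5 μs windows of the time-rescaled
composite process with ten residues. All stochastic tests carry fixed seeds
and the simulator is bit-reproducible for a given (spec, duration, dt,
seed).

## Known limitations

* The dwell estimator has no correction for discretisation bias or
  recrossing; both are documented above and absorbed by tolerances.
* The symmetrised transition matrix is an ad-hoc reversible estimator; its
  spectrum is only trustworthy for data from reversible dynamics.
* The rate fit assumes the single-flip mask is correct; a process with
  genuine simultaneous flips would be projected onto the nearest single-flip
  generator with a non-zero residual (reported, not raised).
* The block baseline is a noise floor, not a significance test with
  controlled error rates; see the convergence requirement above.
* `paint_structure` matches records to structure residues by residue number
  only; insertion codes and multi-chain numbering collisions are not
  resolved.
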