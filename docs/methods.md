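# Methods

## The model

`netphase` studies how the structure of a coupled-oscillator network shapes
the timing of its nodes.  Each node `j` of a network with nonnegative
coupling matrix `A` (entry `A[j,k]` couples node `k` onto `j`; weighted
degree `n_j = Σ_k A[j,k]`) carries a phase `θ_j` obeying a Kuramoto model
with phase frustration:

    dθ_j/dt = ω_j + (S/N) Σ_k A[j,k] sin(θ_k − θ_j − β) + ξ_j(t)

The offset `β` is the short-delay approximation of a transmission delay
(`β = ω τ`; at 10 Hz a 4 ms delay is β ≈ 0.25 rad).  In the stationary
state the population rotates at a collective frequency `Ω` and each node
settles at a *relative phase* `ϕ_j = θ_j − Ωt`, measured in the gauge where
the population mean phase `Φ` is zero.

The package's central quantitative claim is the **hub phase-lag
principle**: with identical natural frequencies, the stationary relative
phase of a locked node is

    ϕ_j* = Θ_j − β + arcsin(Δ_j / K_j),     Δ_j = ω_j − Ω,

with effective coupling `K_j = (S/N) n_j R` under the mean-field
approximation (MFA; every node feels the global field `R e^{iΘ}`, `Θ = 0`
in our gauge) or `K_j = (S/N) n_j r_j` under the local-order-parameter
method (LOP; node `j` feels its own field
`r_j e^{iΘ_j} = (1/n_j) Σ_k A[j,k] ⟨e^{iϕ_k}⟩`, which makes the stationary
condition exact rather than approximate).  Since arcsin is increasing,
larger degree ⇒ smaller argument ⇒ smaller (more lagged) phase.  Phase
order propagates to directionality: the directed phase lag index
(dPLI, the time-averaged sign of the wrapped pairwise phase difference) of
a hub against the rest of the network is negative — hubs are targets,
peripheral nodes sources.

A node is *locked* iff `K_j > |Δ_j|`; otherwise it drifts with stationary
density `P(ϕ) ∝ 1/|Δ_j + K_j sin(Θ_j − ϕ − β)|`, whose circular mean has
the closed form `⟨e^{iu}⟩ = i(Δ − sign(Δ)√(Δ²−K²))/K` (in the frame
`u = ϕ − Θ + β`).  Drifting nodes enter the order parameters through that
mean phasor rather than being dropped.

## Solvers

**MFA.**  Scalar self-consistency in `(R, Ω)`: given `R`, `Ω` is found by
Brent root-finding so that the population mean phasor implied by the
locked/drifting node phasors has zero angle (the `Φ = 0` gauge), and the
real part of that phasor is the updated `R` (damping 0.5).  A network with
no coherent solution is reported as `R = 0`, all nodes unlocked — not an
error.  Tolerance 1e-8 on the `R` gap, `max_iter` 10 000.

**LOP.**  The state is the vector of node phasors `z_j = ⟨e^{iϕ_j}⟩`
together with `Ω`, which acts as a nonlinear eigenvalue: at any other `Ω`
no stationary state exists and the iterate precesses instead of
converging.  One sweep computes local fields `h = (A z)/n`, evaluates each
node's stationary phasor under its frozen field, measures the residual
collective rotation `α = arg(mean phasor)`, de-rotates the update by `α`,
blends it into the state (damping λ = 0.3, retried once at λ/3), and
nudges `Ω ← Ω + 0.5 λ α`.  An earlier variant that re-solved `Ω` exactly
by bisection inside every sweep two-cycles whenever a marginally locked
node flips across the locking boundary between sweeps (the arcsin slope
diverges there); the de-rotation scheme converges on every network we
generate, typically in 200–400 sweeps to 1e-10.  Warm start from the MFA
solution by default (`init="zero"` and `"random"` are available; random
starts can land in other fixed points, e.g. mirror states, so only the
self-consistency of the result is guaranteed, not the basin).

The principal arcsin branch is used throughout — it is the
dynamically stable root (`cos(Θ_j − ϕ_j − β) > 0`).

## Simulation

Fixed-step Euler integration at `dt = 1 ms` (≥100 steps per 10 Hz cycle;
the phase equations are non-stiff), initial phases uniform on (−π, π],
first half of the run discarded as burn-in by default.  Delays can be
simulated explicitly (uniform, or distance/velocity from node coordinates)
via per-edge history buffers initialised by backward extrapolation
`θ_j(t<0) = θ_j(0) − ω_j|t|`; the offset mode with `β = ωτ` reproduces the
explicit-delay phase pattern at rank correlation > 0.95 for 4 ms delays.

**Noise.**  `ξ_j` is Gaussian, drawn independently every step.  Two
scalings are supported.  `noise_convention="per_step"` (default)
integrates the draw like the drift (`dθ += dt·noise_sd·ξ`), the convention
of typical fixed-step simulation code; unit SD is then a weak perturbation
that leaves the synchronised state intact, and simulations agree with the
noise-free analytic solvers.  `"white"` treats `noise_sd` as the intensity
of continuous white noise (Euler–Maruyama, `dθ += √dt·noise_sd·ξ`); unit
SD in this convention is a strong perturbation that unlocks most nodes and
destroys the degree–phase relationship, which is inconsistent with the
observation that unit-SD noise leaves the results qualitatively unchanged
— hence the per-step default.  A nonzero noise mean only shifts `Ω` and
cancels in relative phases; the default is 0.

**Ensembles.**  `ensemble_phase_statistics` integrates all runs of a
configuration simultaneously (state matrix runs × nodes; the coupling sum
is two matrix products via
`Σ_k A_jk sin(θ_k−x) = cos x (A sinθ) − sin x (A cosθ)`) and accumulates
statistics online, never storing trajectories: the circular mean of
`θ_j − Φ(t)` over the stationary window (the run-averaged relative phase),
the pairwise dPLI (sampled every 50 ms; `sign(wrap(θ_i−θ_j)) =
sign(sin(θ_i−θ_j))` allows reuse of the integrator's sin/cos), and the
collective frequency as the least-squares slope of the unwrapped mean
phase.

## The comparison protocol

`experiments.COMPARISON_PROTOCOL` fixes the study conditions used by the
benchmark, the acceptance machinery and the examples: 100-node networks
(largest connected component), identical `f = 10 Hz` oscillators,
`β = ω·4 ms`, `S = 5` (deep in the locked regime; the degree–phase sign
pattern is already stable for S > 0.2), unit-SD per-step noise, and 48
runs of 300 s (150 s stationary window) at 1 ms steps.  The run count and
window were chosen as the smallest desk scale at which the Monte Carlo
error of the run-averaged phases is well below the phase spread, so that
the LOP comparison is resolution-limited by the theory rather than by
sampling; larger ensembles change the third decimal only.

Model families: Gilbert `G(N, p)` with `p = (1+ε)log N / N`, ε = 0.1
(approximately Poisson degrees, mean ≈ 5); and an uncorrelated scale-free
configuration model, `P(k) ∝ k^{−2.5}` on `[3, √(⟨k⟩N)]`.  The structural
cutoff guarantees uncorrelated wiring; stub matching is repaired by
degree-preserving double-edge swaps, so the sampled degree sequence is
realised exactly.  `min_degree = 3` makes the scale-free mean degree ≈ 5,
matching the Gilbert family so the two differ in degree *heterogeneity*
rather than density; sparser variants (min degree 2) leave peripheral
nodes marginally locked at S = 5, where run-to-run attractor multiplicity
caps the simulation–theory agreement.

Under this protocol the package reproduces the expected relationships:
LOP–simulation Spearman ≈ 1.00 on both families, MFA–simulation ≈ 0.78 on
the scale-free family and ≈ 0.8–0.9 on Gilbert realisations (the MFA
correlation equals |Spearman(degree, simulated phase)| exactly, because
MFA phases are a monotone function of degree when all ω are equal — it is
a property of the particular graph), and phase–dPLI ≈ 0.97–1.00.

## Signal pipeline

The functional-network chain for multichannel recordings: Welch PSD (2 s
windows, 50 % overlap) averaged over channels selects the band ±2 Hz
around the spectral peak (a flat spectrum — peak below 4× the in-range
median — is an error); fifth-order Butterworth applied forward and
backward (implemented with cascaded second-order sections, `sosfiltfilt`,
for numerical stability at narrow bands); Hilbert-transform phases with a
fixed 1 s trim at each end for filter/Hilbert edge artifacts; relative
phase per channel by subtracting the instantaneous circular-mean phase;
segmentation into 5 s epochs (filtering is done once on the whole
recording rather than per epoch — our synthetic signals are stationary, so
per-epoch filtering would only multiply edge losses); pairwise PLI/dPLI
averaged over epochs; proportional thresholding keeping the strongest 30 %
of PLI edges (deterministic tie-break by edge index) to obtain binary
degrees.

**Synthetic signals.**  `generate_synthetic_eeg` emulates a narrow-band
oscillation with prescribed per-channel lags, independent random-walk
phase jitter, and additive white noise.  It emulates the features the
pipeline consumes — a spectral peak, stable mean phase ordering, partial
decoherence — and none it does not: no 1/f background, no artifacts, no
volume conduction, no amplitude dynamics.  Passing the end-to-end recovery
test therefore shows the pipeline is correct, not that real EEG is this
clean.  The lag ordering is identifiable only while the accumulated jitter
drift (≈ `jitter·√duration`) stays below the inter-channel lag spacing;
defaults (jitter 0.03 rad/√s, spacing ≥ 0.2 rad over a ±0.9 rad gradient,
60 s) respect that with a ≈2× margin.

## Numerical choices and degenerate inputs

- Wrapping convention: (−π, π] everywhere; dPLI wraps before taking the
  sign, exact zeros count as 0.
- Tolerances: solver 1e-8 (residual/step), gauge angle to machine
  precision at the solution; tests assert exact antisymmetry and
  `PLI = |dPLI|` with no tolerance.
- Isolated nodes (`n_j = 0`) have zero local field, are never locked, and
  contribute a zero phasor.
- An uncoupled or incoherent network is a valid result (`R = 0`), not an
  exception; non-convergence of a solver is an exception carrying the last
  residual.
- `functional_network` keeps at least one edge regardless of the
  threshold fraction.
- Noiseless simulations of the fully synchronised state leave ~1e-12
  residual phase differences whose *signs* are consistent, so dPLI of an
  exactly synchronised noiseless run is not meaningful; assess dPLI under
  (weak) noise.

## Known limitations

- The analytic methods assume a stationary, phase-locked-or-drifting
  steady state; they say nothing about transients, multistability basins,
  or amplitude dynamics (no Stuart–Landau/Wilson–Cowan extension).
- Marginally locked nodes (K_j ≈ |Δ_j|) are the accuracy bottleneck:
  simulations show attractor-to-attractor variability there, and the
  frozen-field drift density is only as good as the frozen-field premise.
- The distance-delay mode has no single offset equivalent; the analytic
  solvers require an offset-mode (or uniform-delay) configuration.
- dPLI measures phase lead/lag consistency, not causality; anticipated
  synchronisation and common-drive configurations can dissociate the two.
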