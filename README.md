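# netphase

**Kuramoto phase dynamics and phase-lag directionality on brain-like
networks.**

In many large-scale brain recordings, strongly connected (hub) regions
oscillate with a systematic phase *lag* behind weakly connected
(peripheral) regions, making hubs look like targets and the periphery like
sources of directed functional connectivity.  `netphase` implements the
oscillator-network theory behind that observation and everything needed to
test it: a Kuramoto simulator with phase offsets or transmission delays,
two analytic solvers that predict every node's stationary phase from the
network structure alone, phase-based directionality measures (dPLI/PLI),
and an EEG-style functional-network pipeline with a synthetic-signal
generator.

## The model in brief

Node phases evolve as

    dθⱼ/dt = ωⱼ + (S/N) Σₖ Aⱼₖ sin(θₖ − θⱼ − β) + ξⱼ(t),

where `β` is the phase-offset equivalent of a small transmission delay
(`β = ωτ`).  In the co-rotating frame (collective frequency `Ω`,
population-mean phase pinned to zero) a sufficiently connected node locks
at

    ϕⱼ* = Θⱼ − β + arcsin(Δⱼ / Kⱼ),    Δⱼ = ωⱼ − Ω,

with `Kⱼ = (S/N)·nⱼ·R` under the **mean-field approximation** (MFA) or
`Kⱼ = (S/N)·nⱼ·rⱼ` under the **local order parameter** method (LOP),
where `rⱼ e^{iΘⱼ}` is the degree-normalised field of node *j*'s own
neighbours.  arcsin is increasing, so larger degree ⇒ smaller (lagging)
phase; the LOP version is exact given the stationary state, which is why
it tracks simulations almost perfectly where MFA only gets the trend.
Nodes below the locking threshold (`Kⱼ < |Δⱼ|`) drift with a stationary
density `P(ϕ) ∝ 1/|dϕ/dt|`, also available analytically.

Directionality is quantified by the **directed phase lag index**,
`dPLIᵢⱼ = ⟨sign(wrap(θᵢ−θⱼ))⟩`, whose node-level average rank-orders with
the phases — completing the chain *degree → phase → directionality*.

## Worked example

```python
import numpy as np
from netphase import KuramotoPhaseModel, SimConfig, gilbert_random, largest_component
from scipy.stats import spearmanr

net = largest_component(gilbert_random(100, epsilon=0.1, seed=1))
cfg = SimConfig(coupling=5.0, duration_s=120.0, transient_s=60.0,
                n_runs=8, seed=2)          # 10 Hz oscillators, beta = omega*4 ms
model = KuramotoPhaseModel(net, cfg)

res = model.fit("lop")                     # analytic stationary phases
print(res.summary())

stats = model.simulate_ensemble()          # run-averaged stochastic simulation
print(res.compare_with_simulation(stats))
print("degree vs phase:",
      spearmanr(net.degrees(), stats.mean_phi).statistic)
```

Output (abridged):

```
Kuramoto stationary phase fit
==============================================
method:            LOP
nodes:             99  (locked: 98)
coupling S:        5
phase offset beta: 0.2513 rad
Omega:             62.7662 rad/s (9.990 Hz)
order parameter:   0.9911  (mean local r)
residual:          9.57e-09  after 172 iterations
----------------------------------------------
node_id   degree  phi_star  locked  r_local
     97  11.0000   -0.2429    True   0.9961
     36  10.0000   -0.1222    True   0.9003
...

{'method': 'LOP', 'spearman_phase': 0.9487..., 'spearman_node_dpli': 0.9872...,
 'spearman_sim_phase_vs_dpli': 0.9686..., 'mean_abs_error': 0.0432..., ...}
degree vs phase: -0.7788...
```

The hub with degree 11 sits ~0.24 rad *behind* the population mean while
low-degree nodes lead, and the degree–phase correlation is strongly
negative — the hub phase-lag principle.  Even at this small ensemble size
the LOP prediction rank-matches the simulated phases at ρ ≈ 0.95; at the
full benchmark scale (48 runs × 300 s) it reaches ρ ≈ 1.00.

The same chain is available from the shell:

```
netphase compare --seed 1 --out out/            # both model-network families
netphase connectome --network tracts.txt --out out/
netphase make-eeg --channels 10 --out eeg.csv
netphase eeg-analyze --signal eeg.csv --fs 250 --band auto
```

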