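# aoncb — subthreshold variability of conductance-based neurons under input synchrony

`aoncb` models a single **all-or-none conductance-based (AONCB) neuron**: a
passive membrane whose excitatory and inhibitory conductances switch fully on
for a fixed duration τs per synaptic activation.  It is built for a question
that matters to anyone modeling cortical circuits: *how much subthreshold
membrane-voltage variability can a neuron exhibit, given the number,
strength, and — crucially — the synchrony of its synaptic inputs?*  In vivo
recordings show voltage variances of roughly 4–9 mV², far more than a large
population of independent (asynchronous) inputs can produce; weak but
nonzero spiking correlations (ρ ≈ 0.01–0.04) resolve the discrepancy.

The package provides, as one consistent toolchain:

- **Synchrony modeling** — exchangeable binary spiking with a beta
  de Finetti directing measure: per bin, every synapse of a population fires
  with a shared random probability θ ~ Beta(α, β), giving beta-binomial
  coactivation counts and pairwise correlation ρ = 1/(1+α+β).
- **Compound-Poisson drives** — the rigorous Δt → 0 limit: synaptic *events*
  at Poisson rate b, each coactivating a random number k of synapses
  (aggregate jump W = k·w), with closed-form jump law
  `p_k = C(K,k) B(k, β+K−k) / (ψ(β+K) − ψ(β))` and event rate
  `b = r·β·(ψ(β+K) − ψ(β))`; ρ = 1/(1+β) in continuous time.
- **Exact simulation** — in the instantaneous-synapse limit the voltage
  obeys a Marcus-type jump rule
  `ΔV = ((We·Ve + Wi·Vi)/(We+Wi) − V)·(1 − e^{−(We+Wi)})`
  between exponential relaxations; the event-anchored representation is
  exact (no time step), and stationary moments are accumulated from
  closed-form segment integrals.  A finite-τs Euler scheme, an
  integrate-and-fire variant, and an Ornstein–Uhlenbeck diffusion comparator
  are included.
- **Closed-form stationary moments** — exact mean and variance expressed
  through synaptic efficacies (expectations over the jump law), for example
  `E[V] = (a_{e,1}Ve + a_{i,1}Vi + I/G)/(1 + a_{e,1} + a_{i,1})` with
  `a_{e,1} = bτ E[We/(We+Wi)(1−e^{−(We+Wi)})]`, plus the small-weight
  (effective-time-constant) approximation with its synchrony corrections and
  the beta-process scaling limit ν(dw) = (rβ/w)(1−w/Ω)^{β−1}dw for
  vanishing weights.
- **Experiments** — deterministic parameter sweeps, Monte-Carlo validation
  of the closed forms, and Gaussian-jitter studies that relate instantaneous
  synchrony to spike-count correlations measured in finite time bins.

## Worked example

```python
import aoncb as a

m = a.MembraneParams(tau=15e-3, Ve=60.0, Vi=-10.0)   # VL = 0
for label, (rho_e, rho_i, rho_ei) in {
    "asynchronous": (0.0, 0.0, 0.0),
    "within-corr":  (0.03, 0.03, 0.0),
    "E/I-corr":     (0.03, 0.03, 0.03),
}.items():
    joint = a.build_joint(Ke=100, Ki=25, re=10.0, ri=10.0,
                          we=0.01, wi=0.04,
                          rho_e=rho_e, rho_i=rho_i, rho_ei=rho_ei)
    mom = a.stationary_moments(joint, m)
    print(f"{label:13s} b={joint.b:8.2f} Hz  "
          f"E[V]={mom.mean:.2f} mV  V[V]={mom.variance:.2f} mV^2")
```

prints

```
asynchronous  b= 1250.00 Hz  E[V]=5.77 mV  V[V]=2.24 mV^2
within-corr   b=  646.85 Hz  E[V]=5.71 mV  V[V]=7.30 mV^2
E/I-corr      b=  515.60 Hz  E[V]=5.65 mV  V[V]=4.46 mV^2
```

Reading: 100 large excitatory synapses (w=0.01) and 25 large inhibitory
synapses (w=0.04) firing at 10 Hz depolarize the cell by ~6 mV in all three
conditions — the mean barely notices synchrony.  The variance does: weak
within-population correlations (ρ=0.03) triple it, into the empirically
observed 4–9 mV² range, while correlating excitation with inhibition pulls
it back down (synchronous E/I events partially cancel inside a single jump).
Note the event rate b drops with synchrony at fixed spike rates: spikes
arrive in fewer, larger packets.

A Monte-Carlo cross-check with the exact event-driven simulator

```python
mc_mean, mc_var, _ = a.simulate_moments(joint, m, T=120.0, seed=0, n_batches=12)
```

returns `(5.73, 7.48)` for the within-corr condition (T=120 s), matching the
closed form within sampling error.

## Command line

```bash
aoncb moments  --config params.yml --out out/   # closed-form moments + efficacies
aoncb simulate --config params.yml --seed 1     # Monte-Carlo moments
aoncb drive    --config params.yml              # sample an event list (CSV)
aoncb sweep    --config sweep.yml               # deterministic parameter grids
aoncb validate --seed 1                         # MC vs analytic, 3 synchrony conditions
aoncb jitter   --seed 1                         # jittered-synchrony experiment
aoncb calibrate --config cal.yml                # rho_inf for a target binned correlation
```

Configs are YAML; outputs are CSV tables with JSON metadata sidecars.

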