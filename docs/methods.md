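# Methods

## Model

The membrane obeys `C V̇ = G(VL − V) + ge(Ve − V) + gi(Vi − V) + I` with
passive time constant τ = C/G and VL fixed at 0, so voltages are measured
relative to rest.  Defaults are τ = 15 ms, Ve = 60 mV, Vi = −10 mV, I/G = 0,
chosen as typical cortical values; time is in seconds, rates in Hz,
voltages in mV, and synaptic weights w = ∫g dt /(C·1) are dimensionless.

Synapses are *all-or-none*: a spike delivered to a synapse of weight w
raises the reduced conductance h = g/C by w/τs for a duration τs, so the
transferred charge ∫h dt = w is independent of τs.  This charge-preserving
amplitude is what makes the instantaneous limit τs → 0 nondegenerate, and
it is the convention under which a unitary excitatory input with w = 0.01,
ε = τs/τ = 1/4 produces a somatic peak of

    peak = Ve · (w/ε)/(1 + w/ε) · (1 − e^{−ε(1+w/ε)}) ≈ 0.53 mV

at t = τs = 3.75 ms — the calibration used to map measured PSP amplitudes
to dimensionless weights (large thalamocortical inputs: we ≈ 0.01,
wi ≈ 0.04; moderate cortico-cortical inputs: we ≈ 0.001, wi ≈ 0.004).

## Synchrony: from exchangeable bins to compound Poisson drives

Within a time bin Δt, the K synapses of a population fire conditionally
independently with a shared random probability θ drawn from a beta
directing measure Beta(α, β); the coactivation count is beta-binomial with
mean K·α/(α+β) = K·r·Δt and pairwise spiking correlation
ρ = 1/(1 + α + β).  Letting Δt → 0 at fixed rate r forces α → 0 and yields
a compound Poisson drive: events at rate

    b = r·β·(ψ(β+K) − ψ(β)),        r ≤ b ≤ K·r,

each coactivating k synapses with

    p_k = C(K,k)·B(k, β+K−k) / (ψ(β+K) − ψ(β)),   k = 1..K,

so that b·E[k] = K·r (spike-rate conservation) and the continuous-time
correlation is ρ = 1/(1+β), recoverable from any count law via
ρ = E[k(k−1)]/(E[k](K−1)).  ρ = 0 is represented structurally as the
singleton (Poisson) drive rather than by β = ∞.

Joint excitatory/inhibitory drives come in two closed-form flavors:
independent populations (jump mass on the axes, b = be + bi) and maximal
coupling at a common rate (common θ; grid law with normalizer
ψ(β+Ke+Ki) − ψ(β)), which forces ρe = ρi = ρei.  Arbitrary cross-correlated
laws have no known low-dimensional parametrization and are accepted as
user-supplied pmf tables.  Cross correlation is measured as
ρei = E[ke·ki]/√(Ke·E[ke]·Ki·E[ki]), which saturates at 1 under perfect
synchrony.  Weight heterogeneity can be folded into the jump law as a
count-pmf-weighted mixture of k-fold convolutions of the single-synapse
weight density.

## Exact simulation and moments

For τs → 0 the dynamics is shot-noise driven and admits an exact
event-driven scheme: between events V relaxes exponentially toward I/G;
across an event with aggregate jumps (We, Wi) it updates by the Marcus rule

    V⁺ = V⁻ + ((We·Ve + Wi·Vi)/(We+Wi) − V⁻)·(1 − e^{−(We+Wi)}),

which confines V to [Vi, Ve].  Traces are stored event-anchored (times plus
pre-/post-jump voltages), which determines the path exactly; time averages
of V and V² are computed from closed-form integrals of the exponential
segments, so the Monte-Carlo moment estimator has no discretization bias.
Long horizons are processed in chunks with the voltage carried across
boundaries (memory-free streaming).  The sequential recursions (Marcus
loop, integrate-and-fire, per-event synapse assignment) are numba kernels.

The stationary moments are exact expectations over the jump law:

    E[V] = (ae1·Ve + ai1·Vi + I/G)/(1 + ae1 + ai1)
    V[V] = (ae12(Ve−E[V])² + ai12(Vi−E[V])² − cei(Ve−Vi)²)/(1 + ae2 + ai2)

with efficacies ae1 = bτ·E[We/(We+Wi)(1−e^{−(We+Wi)})],
ae2 = (bτ/2)·E[We/(We+Wi)(1−e^{−2(We+Wi)})], ae12 = ae1 − ae2 (an exact
identity, asserted to machine precision), and
cei = (bτ/2)·E[WeWi/(We+Wi)²(1−e^{−(We+Wi)})²].  All efficacy expectations
are exact sparse sums over the jump table (log-gamma evaluations, no
sampling).  The variance is nonnegative for every admissible table; the
implementation asserts ≥ −1e−12 and clips roundoff.

For w ≪ 1 the small-weight approximation drops exponential corrections:
the mean becomes synchrony-independent and the variance becomes the
effective-time-constant estimate
(Ke re we²(Ve−E)² + Ki ri wi²(Vi−E)²) / (2(1/τ + Ke re we + Ki ri wi))
plus synchrony corrections Δρe, Δρi ≥ 0 (each scaling as ρ(K−1)) and
Δρei ≤ 0.  The `small_weight_error_report` utility quantifies the
discrepancy against the exact forms; no universal accuracy bound is
claimed — for correlated drives with large aggregate jumps the exponential
corrections reach several percent.

In the scaling limit we = Ω/K, K → ∞ at fixed ρ > 0 the jump law converges
weakly to the degenerate beta (Lévy) measure ν(dw) = (rβ/w)(1−w/Ω)^{β−1}dw,
with moments obtained by quadrature after the substitution u = w/Ω removes
the 1/w singularity (adaptive quadrature, relative tolerance 1e−8;
integrands must vanish at 0, otherwise the infinite total mass is exposed
as an error).  Variance is O(ρ) in this limit and vanishes for ρ → 0 —
asynchronous scaling limits cannot sustain subthreshold variability.

## Jittered synchrony

Instantaneous coactivation is an idealization; real pairwise correlations
vanish at fine timescales.  The jitter pipeline expands each synchronous
event into k spikes on k distinct synapses (uniform without replacement),
shifts each spike by an independent N(0, σJ²), trims 4σJ margins, and
measures the binned spike-count correlation with the population identity
ρ̂ = (V[pooled] − Σk V[ck]) / ((Σk sd_k)² − Σk sd_k²) — the sd-weighted
average pairwise Pearson correlation, computed sparsely so millisecond bins
need no dense K×bins matrix.  For an unjittered drive ρ̂ is flat in the bin
width and equals ρ; jittering attenuates it by E[(1−|δ|/Δt)₊] with
δ ~ N(0, 2σJ²) (verified against the estimator).  `calibrate_rho_inf`
inverts this relation by monotone bisection with common random numbers
(tolerance 0.002 by default).

A caveat established by this package's own experiments: matching a
σJ = 50 ms jittered drive (Ke = 1000, re = 10 Hz, we = 1e−3) to the
instantaneous-synchrony model via the 25 ms binned correlation leaves a
residual stationary-variance excess of about 3 % in the jittered drive
(Monte-Carlo SE < 0.5 %).  Two mechanisms contribute: the voltage weighs
pair lags by e^{−|s|/τ_eff} (τ_eff ≈ 13 ms) while count matching uses a
triangular 25 ms kernel — a ≈ 2 % mismatch — and the matched compound
Poisson model saturates its aggregate jumps (1 − e^{−k·we}) whereas the
jittered drive delivers singleton jumps.  Matching at ≈ 25 ms remains the
best single-bin choice for these parameters, but percent-level agreement
should not be expected.

## Synthetic-data generator and defaults

All inputs are generated internally; the drive generator *is* the study
condition.  Canonical parameter sets: large weights Ke = 100, we = 0.01,
Ki = 25, wi = 0.04 and moderate weights Ke = 1000, we = 0.001, Ki = 250,
wi = 0.004 (both with Ke we = Ki wi = 1), rates 0–50 Hz, correlations
0–0.03, jitter experiments at Ke = 1000, re = 10 Hz, we = 1e−3,
σJ = 50 ms.  The generator reproduces exchangeable synchrony with
beta-directing measures and nothing else: no rate nonstationarity, no
negative or lagged E/I correlations, no synaptic saturation or reset-driven
variability.  Passing tests therefore validate the mathematical chain
(discrete model → jump process → voltage moments), not the fidelity of any
particular biological circuit.

## Numerical choices

- All binomial/beta coefficients in log-space (gammaln); pmfs normalized
  and checked to 1e−12; stable up to K ~ 1e6.
- RNG: a single master `SeedSequence` spawns independent substreams for
  event times, jump sizes, synapse assignment, and jitter; every stochastic
  routine is reproducible from (parameters, seed).
- Monte-Carlo horizons: validation runs size T so the relative SE of the
  variance (batch means, voltage decorrelation time ≈ τ) falls below 2–3 %
  (T ≈ 300 s for the canonical conditions); the jitter variance comparison
  uses T = 6400 s for SE < 0.5 %.  Burn-in max(10τ, 0.5 s) with the initial
  condition at the analytic mean.
- Regularized (finite-τs) integration: forward Euler with dt ≤ τs/10;
  pulses add under multi-activation.  The exact event-driven scheme is the
  reference; the Euler path converges to it at O(τs).
- Integrate-and-fire: threshold checked at jump times (between jumps an
  upward crossing is impossible unless I/G ≥ VT, in which case the crossing
  time is solved in closed form); reset to VR, no refractory period.
- Degenerate inputs are rejected with explicit errors: K = 0 counts,
  nonpositive shapes, ρ·(1) = 1 exactly, zero-variance trains, horizons
  shorter than burn-in + 10τ.

## Known limitations

Closed-form moments are available only in the instantaneous-synapse limit
(finite-τs moments are accessible by simulation); spiking reset is excluded
from the moment analysis (the IF mechanism is a simulator option only);
cross-correlation is restricted to the nonnegative, instantaneous, common-
rate case unless a custom jump table is supplied; moments beyond the second
(e.g. the observed positive skewness of cortical voltages) are not
computed.
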