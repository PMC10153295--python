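"""AONCB voltage dynamics: exact Marcus scheme and regularized Euler scheme.

The all-or-none conductance-based (AONCB) neuron obeys

    V' = -V/τ + he(Ve - V) + hi(Vi - V) + I/C,     VL = 0,

where the reduced conductances he, hi switch fully on for a duration τs per
synaptic event (all-or-none activation, amplitude W/τs so the transferred
charge W is independent of τs).  In the instantaneous-synapse limit
τs → 0⁺ the drive becomes shot noise and the dynamics admits an exact
event-driven solution: between events V relaxes exponentially toward the
rest level, and across an event of aggregate jumps (We, Wi) the voltage
updates by the Marcus rule

    J = (We·Ve + Wi·Vi)/(We + Wi) - V) · (1 - exp(-(We + Wi))),

which confines V to [Vi, Ve].  The event-anchored representation is exact:
no discretization error, and stationary moments are computed from
closed-form segment integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .jumps import DriveRealization, JointJumpDistribution, SpikeTrains, sample_drive

__all__ = [
    "MembraneParams",
    "SynapticKinetics",
    "IFParams",
    "VoltageTrace",
    "marcus_jump",
    "simulate_marcus",
    "simulate_moments",
    "simulate_regularized",
    "trains_to_drive",
    "trace_moments",
    "integrate_and_fire",
    "diffusion_reference",
    "default_burn_in",
]


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane skeleton: τ = C/G (s), reversal potentials (mV),
    optional constant-current rest offset I/G (mV).  VL is fixed at 0."""

    tau: float = 15e-3
    Ve: float = 60.0
    Vi: float = -10.0
    I_over_G: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not self.Vi < 0 < self.Ve:
            raise ValueError("need Vi < 0 < Ve")


@dataclass(frozen=True)
class SynapticKinetics:
    """All-or-none synaptic activation time τs and ratio ε = τs/τ."""

    tau_s: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("tau_s must be >= 0")

    @classmethod
    def from_epsilon(cls, epsilon: float, m: MembraneParams) -> "SynapticKinetics":
        return cls(tau_s=epsilon * m.tau, epsilon=epsilon)


@dataclass(frozen=True)
class IFParams:
    """Integrate-and-fire threshold/reset (mV); no refractory period."""

    VT: float
    VR: float

    def __post_init__(self) -> None:
        if not self.VR < self.VT:
            raise ValueError("need VR < VT")


@dataclass(frozen=True)
class VoltageTrace:
    """Voltage path, either exact event-anchored or uniformly sampled.

    Event-anchored traces store the jump times with pre-/post-jump voltages
    plus (v0, v_inf, tau); that fully determines V(t) with no discretization
    error.  Grid traces store sampled values.
    """

    kind: str  # "event_anchored" | "uniform_grid"
    times: np.ndarray
    t_begin: float
    t_end: float
    tau: float
    burn_in: float = 0.0
    # event-anchored payload
    v_pre: np.ndarray | None = None
    v_post: np.ndarray | None = None
    v0: float = 0.0
    v_inf: float = 0.0
    # uniform-grid payload
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("event_anchored", "uniform_grid"):
            raise ValueError("kind must be event_anchored or uniform_grid")

    @property
    def horizon(self) -> float:
        return self.t_end - self.t_begin

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate V at arbitrary times (exact for event-anchored traces)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "uniform_grid":
            return np.interp(t, self.times, self.v)
        idx = np.searchsorted(self.times, t, side="right")
        anchor_t = np.concatenate(([self.t_begin], self.times))[idx]
        anchor_v = np.concatenate(([self.v0], self.v_post))[idx]
        return self.v_inf + (anchor_v - self.v_inf) * np.exp(-(t - anchor_t) / self.tau)


def default_burn_in(m: MembraneParams) -> float:
    """Default transient discard: max(10·τ, 0.5 s)."""
    return max(10.0 * m.tau, 0.5)


def marcus_jump(v: float, W_e: float, W_i: float, m: MembraneParams) -> float:
    """Post-jump voltage under the Marcus rule.

    The update drives V toward the jump-weighted reversal average
    (We·Ve + Wi·Vi)/(We+Wi) by a fraction 1 − exp(−(We+Wi)), so no jump can
    take the voltage outside [Vi, Ve].
    """
    if W_e < 0 or W_i < 0 or (W_e == 0 and W_i == 0):
        raise ValueError("need (W_e, W_i) >= 0 and not both zero")
    wtot = W_e + W_i
    target = (W_e * m.Ve + W_i * m.Vi) / wtot
    return v + (target - v) * (1.0 - math.exp(-wtot))


def simulate_marcus(
    drive: DriveRealization, m: MembraneParams, v0: float = 0.0
) -> VoltageTrace:
    """Exact event-driven simulation of the instantaneous-synapse AONCB neuron.

    Between events V relaxes toward I/G (0 by default) with constant τ; at
    each event :func:`marcus_jump` is applied.  The returned event-anchored
    trace determines the path exactly.
    """
    if not (m.Vi <= v0 <= m.Ve):
        raise ValueError("v0 must lie in [Vi, Ve]")
    v_pre, v_post = _kernels.marcus_path(
        drive.times, drive.We, drive.Wi, m.tau, m.Ve, m.Vi, m.I_over_G, v0, 0.0
    )
    return VoltageTrace(
        kind="event_anchored", times=drive.times, t_begin=0.0, t_end=drive.T,
        tau=m.tau, v_pre=v_pre, v_post=v_post, v0=v0, v_inf=m.I_over_G,
    )


def simulate_moments(
    joint: JointJumpDistribution,
    m: MembraneParams,
    T: float,
    seed: int | np.random.SeedSequence,
    burn_in: float | None = None,
    v0: float | None = None,
    n_batches: int = 1,
) -> tuple[float, float, dict]:
    """Monte-Carlo stationary mean and variance without storing the path.

    Samples the drive in ``n_batches`` consecutive chunks (the voltage is
    carried across chunk boundaries) and accumulates exact segment integrals
    of V and V², so memory stays bounded for long horizons.  The initial
    condition defaults to the analytic stationary mean to shorten the
    transient.  Returns (mean, variance, info) where info carries per-batch
    moments for standard-error estimates.
    """
    from .moments import efficacies, stationary_mean

    if burn_in is None:
        burn_in = default_burn_in(m)
    if T <= burn_in + 10.0 * m.tau:
        raise ValueError("horizon too short: need T > burn_in + 10·tau")
    if v0 is None:
        v0 = stationary_mean(efficacies(joint, m.tau), m)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    edges = np.linspace(0.0, T, n_batches + 1)
    v = float(v0)
    acc = np.zeros(3)
    batch_rows = []
    for child, (t0, t1) in zip(seq.spawn(n_batches), zip(edges[:-1], edges[1:])):
        chunk = sample_drive(joint, t1 - t0, child)
        v, bT, bv, bv2 = _kernels.marcus_integrate(
            chunk.times, chunk.We, chunk.Wi, m.tau, m.Ve, m.Vi, m.I_over_G,
            v, 0.0, t1 - t0, max(0.0, burn_in - t0),
        )
        if bT > 0:
            batch_rows.append((bT, bv, bv2))
            acc += (bT, bv, bv2)
    total_T, total_v, total_v2 = acc
    mean = total_v / total_T
    var = total_v2 / total_T - mean**2
    info = {"batches": batch_rows, "burn_in": burn_in, "T": T}
    return float(mean), float(max(var, 0.0)), info


def trains_to_drive(
    trains: SpikeTrains, w: float, population: str = "e"
) -> DriveRealization:
    """Convert per-synapse spike trains into single-spike drive events.

    Each spike becomes one event of jump (w, 0) or (0, w); exact time ties
    (e.g. unjittered synchronous events) are merged additively.
    """
    t, inv, mult = np.unique(trains.times, return_inverse=True, return_counts=True)
    W = mult.astype(float) * w
    T = trains.t_stop - trains.t_start
    times = t - trains.t_start
    zero = np.zeros_like(W)
    if population == "e":
        return DriveRealization(times=times, We=W, Wi=zero, T=T,
                                counts_e=mult.astype(np.int64))
    return DriveRealization(times=times, We=zero, Wi=W, T=T,
                            counts_i=mult.astype(np.int64))


def trace_moments(trace: VoltageTrace, burn_in: float | None = None) -> tuple[float, float]:
    """Time-weighted stationary mean and variance of a trace.

    Event-anchored traces use closed-form per-segment integrals of V and V²
    (no discretization bias); grid traces use the sample average.
    """
    if burn_in is None:
        burn_in = trace.burn_in
    if trace.horizon <= burn_in + 10.0 * trace.tau:
        raise ValueError("horizon too short: need horizon > burn_in + 10·tau")
    t_acc = trace.t_begin + burn_in
    if trace.kind == "uniform_grid":
        sel = trace.times >= t_acc
        v = trace.v[sel]
        return float(v.mean()), float(v.var())
    starts = np.concatenate(([trace.t_begin], trace.times))
    ends = np.concatenate((trace.times, [trace.t_end]))
    vs = np.concatenate(([trace.v0], trace.v_post))
    keep = ends > t_acc
    starts, ends, vs = starts[keep], ends[keep], vs[keep]
    clipped = np.maximum(starts, t_acc)
    vs = trace.v_inf + (vs - trace.v_inf) * np.exp(-(clipped - starts) / trace.tau)
    d = ends - clipped
    e1 = np.exp(-d / trace.tau)
    dv = vs - trace.v_inf
    vinf = trace.v_inf
    int_v = vinf * d + dv * trace.tau * (1.0 - e1)
    int_v2 = (
        vinf**2 * d
        + 2.0 * vinf * dv * trace.tau * (1.0 - e1)
        + dv**2 * 0.5 * trace.tau * (1.0 - e1**2)
    )
    T = d.sum()
    mean = int_v.sum() / T
    var = int_v2.sum() / T - mean**2
    return float(mean), float(max(var, 0.0))


def simulate_regularized(
    drive: DriveRealization,
    m: MembraneParams,
    kinetics: SynapticKinetics,
    dt: float,
    v0: float = 0.0,
) -> VoltageTrace:
    """Finite-τs AONCB dynamics by forward Euler on a uniform grid.

    Each event's jump W activates a reduced-conductance pulse of amplitude
    W/τs lasting τs (charge-preserving: ∫h dt = W); overlapping pulses add.
    Requires dt ≤ τs/10.
    """
    tau_s = kinetics.tau_s
    if tau_s <= 0:
        raise ValueError("regularized scheme needs tau_s > 0 (use simulate_marcus)")
    if dt > tau_s / 10:
        raise ValueError("dt too coarse: need dt <= tau_s/10")
    n = int(np.ceil(drive.T / dt))
    he = np.zeros(n + 1)
    hi = np.zeros(n + 1)
    i_on = np.minimum((drive.times / dt).astype(np.int64), n)
    i_off = np.minimum(((drive.times + tau_s) / dt).astype(np.int64), n)
    np.add.at(he, i_on, drive.We / tau_s)
    np.subtract.at(he, i_off, drive.We / tau_s)
    np.add.at(hi, i_on, drive.Wi / tau_s)
    np.subtract.at(hi, i_off, drive.Wi / tau_s)
    he = np.cumsum(he)[:n]
    hi = np.cumsum(hi)[:n]
    v = _kernels.euler_voltage(he, hi, dt, m.tau, m.Ve, m.Vi, m.I_over_G / m.tau, v0)
    t = np.arange(n + 1) * dt
    return VoltageTrace(
        kind="uniform_grid", times=t, t_begin=0.0, t_end=t[-1], tau=m.tau, v=v
    )


def integrate_and_fire(
    drive: DriveRealization,
    m: MembraneParams,
    f: IFParams,
    v0: float = 0.0,
) -> tuple[VoltageTrace, np.ndarray]:
    """Event-driven AONCB neuron with threshold/reset spiking.

    Threshold crossings are checked at jump times; between jumps an upward
    crossing is only possible when I/G ≥ VT, in which case the crossing time
    is solved in closed form.  Returns the event-anchored trace and the
    spike times.
    """
    if v0 >= f.VT:
        raise ValueError("v0 must be below threshold")
    max_spikes = drive.n_events + int(drive.T / m.tau) * 10 + 16
    v_pre, v_post, spikes, ns = _kernels.integrate_and_fire_path(
        drive.times, drive.We, drive.Wi, m.tau, m.Ve, m.Vi, m.I_over_G,
        v0, 0.0, drive.T, f.VT, f.VR, max_spikes,
    )
    trace = VoltageTrace(
        kind="event_anchored", times=drive.times, t_begin=0.0, t_end=drive.T,
        tau=m.tau, v_pre=v_pre, v_post=v_post, v0=v0, v_inf=m.I_over_G,
    )
    return trace, spikes[:ns].copy()


def diffusion_reference(
    Ke: int,
    Ki: int,
    re: float,
    ri: float,
    we: float,
    wi: float,
    m: MembraneParams,
    dt: float,
    T: float,
    seed: int | np.random.SeedSequence,
    rho_e: float = 0.0,
    rho_i: float = 0.0,
    rho_ei: float = 0.0,
    f: IFParams | None = None,
    v0: float | None = None,
) -> tuple[VoltageTrace, np.ndarray]:
    """Ornstein-Uhlenbeck comparator via the effective-time-constant estimate.

    Simulates an OU process whose relaxation time is
    τ_eff = 1/(1/τ + Ke·re·we + Ki·ri·wi) and whose stationary mean and
    variance equal the small-weight estimates (synchrony corrections
    included whenever the ρ arguments are nonzero).  Exact one-step OU
    updates; optional threshold/reset.  Convenience comparator only.
    """
    from .moments import small_weight_moments

    mom = small_weight_moments(Ke, Ki, re, ri, we, wi, rho_e, rho_i, rho_ei, m)
    tau_eff = 1.0 / (1.0 / m.tau + Ke * re * we + Ki * ri * wi)
    mu, sig2 = mom.mean, mom.variance
    rng = np.random.default_rng(seed)
    n = int(np.ceil(T / dt))
    a = math.exp(-dt / tau_eff)
    s = math.sqrt(sig2 * (1.0 - a * a))
    noise = rng.normal(0.0, 1.0, size=n)
    v = np.empty(n + 1)
    v[0] = mu if v0 is None else v0
    spikes = []
    x = v[0]
    for i in range(n):
        x = mu + (x - mu) * a + s * noise[i]
        if f is not None and x >= f.VT:
            spikes.append((i + 1) * dt)
            x = f.VR
        v[i + 1] = x
    t = np.arange(n + 1) * dt
    trace = VoltageTrace(
        kind="uniform_grid", times=t, t_begin=0.0, t_end=t[-1], tau=m.tau, v=v
    )
    return trace, np.asarray(spikes)
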