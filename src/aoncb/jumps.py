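"""Synchronous synaptic drives as compound Poisson processes.

In the vanishing-bin-width limit the exchangeable discrete model of
:mod:`aoncb.synchrony` becomes a compound Poisson process: synaptic *events*
occur at Poisson times with rate b, and each event coactivates a random
number of synapses, producing an aggregate conductance jump (We, Wi) =
(k·we, l·wi).  With beta-distributed directing measures the jump-size count
law has the closed form

    pe,k = C(K, k) B(k, β + K − k) / (ψ(β + K) − ψ(β)),   k = 1..K,

with ψ the digamma function, and the event rate is be = re·β·(ψ(β+K) − ψ(β)).
The continuous-time spiking correlation is ρ = 1/(1 + β); single-synapse
jumps (ρ = 0) recover an ordinary Poisson drive with be = K·re.

The module also provides drive sampling, expansion of synchronous events
into per-synapse spike trains with optional Gaussian jitter, and an
empirical spike-count correlation estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, psi

from .synchrony import CountDistribution, JointCountDistribution, correlation_from_counts

__all__ = [
    "JumpDistribution",
    "JointJumpDistribution",
    "DriveRealization",
    "SpikeTrains",
    "marginal_jump_pmf",
    "singleton_jump_pmf",
    "marginal_event_rate",
    "joint_jump_independent",
    "joint_jump_maximal",
    "joint_from_marginal",
    "joint_custom",
    "build_joint",
    "heterogeneous_jump_density",
    "sample_drive",
    "expand_and_jitter",
    "empirical_count_correlation",
]

_PMF_TOL = 1e-12


# ---------------------------------------------------------------------------
# jump-size distributions


@dataclass(frozen=True)
class JumpDistribution:
    """Law of the number of coactivating synapses at a synaptic event.

    Support is k = 1..K (an event has at least one activation); the
    conductance jump is W = k·w.
    """

    K: int
    w: float
    probs: np.ndarray  # probs[j] = P[k = j+1]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (self.K,):
            raise ValueError("probs must have length K")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > _PMF_TOL:
            raise ValueError("jump pmf must sum to 1 within 1e-12")

    @property
    def counts(self) -> np.ndarray:
        return np.arange(1, self.K + 1)

    def mean_count(self) -> float:
        return float(self.counts @ self.probs)

    def as_count_distribution(self) -> CountDistribution:
        """Embed on 0..K (zero mass at 0) for correlation formulas."""
        return CountDistribution(pmf=np.concatenate(([0.0], self.probs)), K=self.K)

    def correlation(self) -> float:
        """Spiking correlation ρ = E[k(k−1)] / (E[k](K−1)) of the drive."""
        return correlation_from_counts(self.as_count_distribution())


@dataclass(frozen=True)
class JointJumpDistribution:
    """Sparse joint law of synchronous jump counts (k, l) plus event rate b.

    Support excludes (0, 0); jumps are (We, Wi) = (k·we, l·wi).  The marginal
    event rates be = b·P[k ≥ 1] and bi = b·P[l ≥ 1] always satisfy
    max(be, bi) ≤ b ≤ be + bi.
    """

    Ke: int
    Ki: int
    we: float
    wi: float
    k: np.ndarray
    l: np.ndarray
    p: np.ndarray
    b: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=np.int64)
        l = np.asarray(self.l, dtype=np.int64)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "p", p)
        if not (k.shape == l.shape == p.shape):
            raise ValueError("k, l, p must have equal shapes")
        if np.any((k == 0) & (l == 0)):
            raise ValueError("support must exclude (0, 0)")
        if np.any(k < 0) or np.any(k > self.Ke) or np.any(l < 0) or np.any(l > self.Ki):
            raise ValueError("counts outside (0..Ke)×(0..Ki)")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _PMF_TOL:
            raise ValueError("joint jump pmf must sum to 1 within 1e-12")
        if not self.b > 0:
            raise ValueError("event rate b must be > 0")

    @property
    def rate_e(self) -> float:
        """Rate be of events with at least one excitatory activation (Hz)."""
        return self.b * float(self.p[self.k >= 1].sum())

    @property
    def rate_i(self) -> float:
        return self.b * float(self.p[self.l >= 1].sum())

    @property
    def We(self) -> np.ndarray:
        return self.k * self.we

    @property
    def Wi(self) -> np.ndarray:
        return self.l * self.wi

    def mean_count_e(self) -> float:
        """E[ke] under the joint law; b·E[ke] = Ke·re (rate conservation)."""
        return float(self.k @ self.p)

    def mean_count_i(self) -> float:
        return float(self.l @ self.p)

    def count_marginal(self, population: str = "e", conditioned: bool = True) -> CountDistribution:
        """Marginal count pmf; ``conditioned`` restricts to events where this
        population participates (k ≥ 1), renormalized."""
        counts = self.k if population == "e" else self.l
        K = self.Ke if population == "e" else self.Ki
        pmf = np.bincount(counts, weights=self.p, minlength=K + 1)
        if conditioned:
            pmf = pmf.copy()
            pmf[0] = 0.0
            s = pmf.sum()
            if s <= 0:
                raise ValueError(f"no mass on population {population!r}")
            pmf = pmf / s
        return CountDistribution(pmf=pmf, K=K)

    def as_joint_count_distribution(self) -> JointCountDistribution:
        pmf = np.zeros((self.Ke + 1, self.Ki + 1))
        np.add.at(pmf, (self.k, self.l), self.p)
        return JointCountDistribution(pmf=pmf, Ke=self.Ke, Ki=self.Ki)

    def rho_ei(self) -> float:
        """Cross correlation E[ke·ki]/sqrt(Ke·E[ke]·Ki·E[ki]) (0 if a
        population is absent)."""
        me, mi = self.mean_count_e(), self.mean_count_i()
        if me <= 0 or mi <= 0:
            return 0.0
        cross = float((self.k * self.l) @ self.p)
        return cross / np.sqrt(self.Ke * me * self.Ki * mi)


@dataclass(frozen=True)
class DriveRealization:
    """One sampled compound-Poisson drive path on [0, T]."""

    times: np.ndarray
    We: np.ndarray
    Wi: np.ndarray
    T: float
    seed: int | None = field(default=None, compare=False)
    counts_e: np.ndarray | None = None  # integer coactivation counts, if known
    counts_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        we = np.asarray(self.We, dtype=float)
        wi = np.asarray(self.Wi, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "We", we)
        object.__setattr__(self, "Wi", wi)
        if not (t.shape == we.shape == wi.shape):
            raise ValueError("times, We, Wi must have equal length")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("event times must be strictly increasing")
        if np.any((we == 0) & (wi == 0)):
            raise ValueError("jump pairs must not be (0, 0)")

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpikeTrains:
    """Per-synapse spike times, stored flat and sorted by time."""

    ids: np.ndarray
    times: np.ndarray
    K: int
    population: str = "e"
    t_start: float = 0.0
    t_stop: float = 0.0

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "times", t)
        if ids.shape != t.shape:
            raise ValueError("ids and times must have equal length")
        if ids.size and (ids.min() < 0 or ids.max() >= self.K):
            raise ValueError("synapse ids out of range")
        if self.t_stop <= self.t_start:
            raise ValueError("need t_stop > t_start")

    @property
    def horizon(self) -> float:
        return self.t_stop - self.t_start

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def per_synapse(self) -> list[np.ndarray]:
        """Sorted spike-time list per synapse."""
        order = np.argsort(self.ids, kind="stable")
        ids, t = self.ids[order], self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.K + 1))
        return [np.sort(t[bounds[j]:bounds[j + 1]]) for j in range(self.K)]


# ---------------------------------------------------------------------------
# closed-form constructors


def marginal_jump_pmf(K: int, beta: float, w: float) -> JumpDistribution:
    """Continuous-time jump-size pmf for a beta directing measure.

    pe,k = C(K, k) B(k, β+K−k) / (ψ(β+K) − ψ(β)), evaluated in log-space.
    The implied spiking correlation is ρ = 1/(1+β).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    k = np.arange(1, K + 1)
    log_choose = gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
    # B(k, beta + K - k) via log-gamma; the argument beta + K - k > 0 always
    logB = gammaln(k) + gammaln(beta + K - k) - gammaln(beta + K)
    log_norm = np.log(psi(beta + K) - psi(beta))
    probs = np.exp(log_choose + logB - log_norm)
    probs = probs / probs.sum()
    return JumpDistribution(K=K, w=w, probs=probs)


def singleton_jump_pmf(K: int, w: float) -> JumpDistribution:
    """Zero-correlation (Poisson) drive: every event is a single activation."""
    if K < 1:
        raise ValueError("K must be >= 1")
    probs = np.zeros(K)
    probs[0] = 1.0
    return JumpDistribution(K=K, w=w, probs=probs)


def marginal_event_rate(K: int, r: float, beta: float | None) -> float:
    """Event rate be = r·β·(ψ(β+K) − ψ(β)) of the synaptic-event process.

    ``beta=None`` denotes the uncorrelated (Poisson) limit β → ∞, for which
    be = K·r.  In general r ≤ be ≤ K·r and be·E[k] = K·r.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if r <= 0:
        raise ValueError("rate must be > 0")
    if beta is None:
        return K * r
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return r * beta * float(psi(beta + K) - psi(beta))


def joint_jump_independent(
    jump_e: JumpDistribution, b_e: float, jump_i: JumpDistribution, b_i: float
) -> JointJumpDistribution:
    """Independent excitation/inhibition: jump mass lives on the axes.

    p(k, 0) = be/(be+bi)·pe(k) and p(0, l) = bi/(be+bi)·pi(l), with total
    event rate b = be + bi and zero cross-correlation.
    """
    if b_e <= 0 or b_i <= 0:
        raise ValueError("marginal event rates must be > 0")
    b = b_e + b_i
    k = np.concatenate([jump_e.counts, np.zeros(jump_i.K, dtype=np.int64)])
    l = np.concatenate([np.zeros(jump_e.K, dtype=np.int64), jump_i.counts])
    p = np.concatenate([(b_e / b) * jump_e.probs, (b_i / b) * jump_i.probs])
    return JointJumpDistribution(
        Ke=jump_e.K, Ki=jump_i.K, we=jump_e.w, wi=jump_i.w, k=k, l=l, p=p, b=b
    )


def joint_jump_maximal(
    Ke: int, Ki: int, beta: float, r: float, we: float, wi: float
) -> JointJumpDistribution:
    """Maximally coupled excitation/inhibition at a common rate r.

    pei(k, l) = C(Ke,k) C(Ki,l) B(k+l, β+Ke+Ki−k−l) / (ψ(β+Ke+Ki) − ψ(β))
    on (0..Ke)×(0..Ki) \\ {(0,0)}, with event rate
    b = r·β·(ψ(β+Ke+Ki) − ψ(β)).
    """
    if Ke < 1 or Ki < 1:
        raise ValueError("Ke and Ki must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if r <= 0:
        raise ValueError("rate must be > 0")
    Kt = Ke + Ki
    kk, ll = np.meshgrid(np.arange(Ke + 1), np.arange(Ki + 1), indexing="ij")
    k = kk.ravel()
    l = ll.ravel()
    keep = (k + l) >= 1
    k, l = k[keep], l[keep]
    s = k + l
    log_choose = (
        gammaln(Ke + 1) - gammaln(k + 1) - gammaln(Ke - k + 1)
        + gammaln(Ki + 1) - gammaln(l + 1) - gammaln(Ki - l + 1)
    )
    logB = gammaln(s) + gammaln(beta + Kt - s) - gammaln(beta + Kt)
    log_norm = np.log(psi(beta + Kt) - psi(beta))
    p = np.exp(log_choose + logB - log_norm)
    p = p / p.sum()
    b = r * beta * float(psi(beta + Kt) - psi(beta))
    return JointJumpDistribution(Ke=Ke, Ki=Ki, we=we, wi=wi, k=k, l=l, p=p, b=b)


def joint_from_marginal(
    jump: JumpDistribution, b: float, population: str = "e"
) -> JointJumpDistribution:
    """Single-population drive wrapped as a joint table (other axis empty)."""
    if b <= 0:
        raise ValueError("event rate must be > 0")
    zero = np.zeros(jump.K, dtype=np.int64)
    if population == "e":
        return JointJumpDistribution(
            Ke=jump.K, Ki=0, we=jump.w, wi=0.0, k=jump.counts, l=zero, p=jump.probs, b=b
        )
    return JointJumpDistribution(
        Ke=0, Ki=jump.K, we=0.0, wi=jump.w, k=zero, l=jump.counts, p=jump.probs, b=b
    )


def joint_custom(
    Ke: int, Ki: int, we: float, wi: float, table: np.ndarray, b: float
) -> JointJumpDistribution:
    """User-supplied dense pmf table over (0..Ke)×(0..Ki); (0,0) must be 0."""
    table = np.asarray(table, dtype=float)
    if table.shape != (Ke + 1, Ki + 1):
        raise ValueError("table must have shape (Ke+1, Ki+1)")
    if table[0, 0] != 0:
        raise ValueError("table must have zero mass at (0, 0)")
    kk, ll = np.meshgrid(np.arange(Ke + 1), np.arange(Ki + 1), indexing="ij")
    keep = table.ravel() > 0
    return JointJumpDistribution(
        Ke=Ke, Ki=Ki, we=we, wi=wi,
        k=kk.ravel()[keep], l=ll.ravel()[keep], p=table.ravel()[keep], b=b,
    )


def build_joint(
    Ke: int,
    Ki: int,
    re: float,
    ri: float,
    we: float,
    wi: float,
    rho_e: float = 0.0,
    rho_i: float = 0.0,
    rho_ei: float = 0.0,
) -> JointJumpDistribution:
    """Assemble the joint jump law for stated rates and correlations.

    ρei = 0 combines two independent marginal drives (beta-derived when
    ρ > 0, Poisson singleton when ρ = 0).  ρei > 0 uses the maximally
    coupled construction, which requires re = ri and ρe = ρi = ρei.
    Single-population drives are requested with Ke = 0 or Ki = 0.
    """
    for name, rho in (("rho_e", rho_e), ("rho_i", rho_i), ("rho_ei", rho_ei)):
        if not 0 <= rho < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if rho_ei > 0:
        if not (Ke >= 1 and Ki >= 1):
            raise ValueError("cross-correlated drive needs both populations")
        if not (re == ri and rho_e == rho_i == rho_ei):
            raise ValueError(
                "the maximally coupled construction requires re = ri and "
                "rho_e = rho_i = rho_ei; other cross-correlated laws must be "
                "supplied as custom tables"
            )
        return joint_jump_maximal(Ke, Ki, 1.0 / rho_ei - 1.0, re, we, wi)

    def _marginal(K: int, r: float, w: float, rho: float):
        if rho > 0:
            beta = 1.0 / rho - 1.0
            return marginal_jump_pmf(K, beta, w), marginal_event_rate(K, r, beta)
        return singleton_jump_pmf(K, w), marginal_event_rate(K, r, None)

    if Ke >= 1 and Ki >= 1:
        je, be = _marginal(Ke, re, we, rho_e)
        ji, bi = _marginal(Ki, ri, wi, rho_i)
        return joint_jump_independent(je, be, ji, bi)
    if Ke >= 1:
        je, be = _marginal(Ke, re, we, rho_e)
        return joint_from_marginal(je, be, "e")
    if Ki >= 1:
        ji, bi = _marginal(Ki, ri, wi, rho_i)
        return joint_from_marginal(ji, bi, "i")
    raise ValueError("need at least one population")


def heterogeneous_jump_density(
    q: np.ndarray, dx: float, p_count: JumpDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Jump-size density under per-synapse weight heterogeneity.

    p(w) = Σ_k p_count(k) · q^(*k)(w), the count-pmf-weighted mixture of
    k-fold convolutions of the single-synapse weight density q (given on a
    uniform grid of spacing dx with Σ q·dx = 1).  Returns (w_grid, density)
    on the extended grid holding the K-fold support.
    """
    q = np.asarray(q, dtype=float)
    if dx <= 0:
        raise ValueError("dx must be > 0")
    if np.any(q < 0):
        raise ValueError("q must be nonnegative")
    if abs(q.sum() * dx - 1.0) > 1e-9:
        raise ValueError("q must be normalized on its grid (sum(q)·dx = 1)")
    K = p_count.K
    n_out = K * (q.size - 1) + 1
    if n_out > 5e7:
        raise ValueError("grid too coarse/large to hold the K-fold support")
    out = np.zeros(n_out)
    conv = q.copy()
    for j, pk in enumerate(p_count.probs):
        if pk > 0:
            out[: conv.size] += pk * conv
        if j < K - 1:
            conv = np.convolve(conv, q) * dx
    norm = out.sum() * dx
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("convolution grid too coarse: mass not conserved")
    out = out / norm
    return np.arange(n_out) * dx, out


# ---------------------------------------------------------------------------
# sampling, jittering, empirical correlation


def sample_drive(
    joint: JointJumpDistribution, T: float, seed: int | np.random.SeedSequence
) -> DriveRealization:
    """Sample one compound-Poisson drive path on [0, T].

    Event times are a homogeneous Poisson process of rate b; jump pairs are
    i.i.d. draws from the joint table via an inverse-CDF lookup.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(joint.b * T)
    times = np.sort(rng.random(n)) * T
    # exact ties are measure-zero but guard the strict-increase invariant
    while times.size > 1 and np.any(np.diff(times) <= 0):
        keep = np.concatenate(([True], np.diff(times) > 0))
        times = times[keep]
        n = times.size
    cdf = np.cumsum(joint.p)
    idx = np.searchsorted(cdf, rng.random(n) * cdf[-1], side="right")
    idx = np.minimum(idx, joint.p.size - 1)
    ke = joint.k[idx]
    ki = joint.l[idx]
    return DriveRealization(
        times=times, We=ke * joint.we, Wi=ki * joint.wi, T=T,
        counts_e=ke, counts_i=ki,
    )


def expand_and_jitter(
    drive: DriveRealization,
    Ke: int,
    sigma_J: float,
    seed: int | np.random.SeedSequence,
    population: str = "e",
) -> SpikeTrains:
    """Expand synchronous events into per-synapse spikes, optionally jittered.

    Each event of count k assigns spikes to k distinct synapses chosen
    uniformly at random; each spike time is then shifted by an independent
    centered Gaussian of s.d. ``sigma_J`` and margins of width 4·sigma_J are
    trimmed from both ends of the horizon.
    """
    if sigma_J < 0:
        raise ValueError("sigma_J must be >= 0")
    if population == "e":
        counts = drive.counts_e
        if counts is None:
            if drive.We.size and not drive.We.max() > 0:
                raise ValueError("drive has no excitatory component")
            w_unit = drive.We[drive.We > 0].min() if drive.We.size else 1.0
            counts = np.rint(drive.We / w_unit).astype(np.int64)
    else:
        counts = drive.counts_i
        if counts is None:
            raise ValueError("inhibitory counts unavailable on this drive")
    counts = np.asarray(counts, dtype=np.int64)
    active = counts > 0
    counts = counts[active]
    if counts.size and counts.max() > Ke:
        raise ValueError("event count exceeds the number of synapses")
    base_times = np.repeat(drive.times[active], counts)
    rng = np.random.default_rng(seed)
    from ._kernels import assign_distinct_synapses

    ids = assign_distinct_synapses(counts, Ke, int(rng.integers(2**31)))
    if sigma_J > 0:
        times = base_times + rng.normal(0.0, sigma_J, size=base_times.size)
    else:
        times = base_times.copy()
    t_start, t_stop = 4.0 * sigma_J, drive.T - 4.0 * sigma_J
    if t_stop <= t_start:
        raise ValueError("horizon too short for the jitter margins")
    keep = (times >= t_start) & (times < t_stop)
    times, ids = times[keep], ids[keep]
    order = np.argsort(times, kind="stable")
    return SpikeTrains(
        ids=ids[order], times=times[order], K=Ke, population=population,
        t_start=t_start, t_stop=t_stop,
    )


def empirical_count_correlation(trains: SpikeTrains, dt: float) -> float:
    """Mean pairwise Pearson correlation of binned spike counts.

    Computed through the population identity
    ρ̂ = (V[pooled] − Σk V[ck]) / ((Σk sd_k)² − Σk sd_k²),
    which equals the sd-weighted average pairwise Pearson correlation and
    avoids the O(K²) pair loop.  Per-synapse count moments are accumulated
    sparsely, so fine bin widths do not require a dense K×n_bins matrix.
    """
    if trains.K < 2:
        raise ValueError("need at least 2 synapses")
    n_bins = int(np.floor(trains.horizon / dt))
    if n_bins < 2:
        raise ValueError("horizon must cover at least 2 bins")
    t_max = trains.t_start + n_bins * dt
    sel = trains.times < t_max
    ids = trains.ids[sel]
    bins = ((trains.times[sel] - trains.t_start) / dt).astype(np.int64)
    K = trains.K
    # occupied (synapse, bin) cells and their multiplicities
    keys = ids * n_bins + bins
    cells, mult = np.unique(keys, return_counts=True)
    cell_ids = cells // n_bins
    n_k = np.bincount(ids, minlength=K).astype(float)
    sumsq_k = np.bincount(cell_ids, weights=mult.astype(float) ** 2, minlength=K)
    mean_k = n_k / n_bins
    var_k = sumsq_k / n_bins - mean_k**2
    pooled = np.bincount(bins, minlength=n_bins).astype(float)
    var_pooled = pooled.var()
    sd = np.sqrt(np.maximum(var_k, 0.0))
    denom = sd.sum() ** 2 - var_k.sum()
    if denom <= 0:
        raise ValueError("undefined correlation: zero-variance spike counts")
    return float((var_pooled - var_k.sum()) / denom)
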