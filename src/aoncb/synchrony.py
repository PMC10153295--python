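"""Discrete-time exchangeable spiking model and synchrony measures.

Synaptic inputs are modeled as exchangeable binary spiking indicators: within
each time bin of width ``dt``, every synapse of a population fires with a
common, randomly drawn probability θ (the de Finetti directing measure).  A
dispersed directing measure induces positive pairwise spiking correlations;
a point mass recovers independent Poissonian spiking.  With beta-distributed
θ ~ Beta(α, β) the per-bin coactivation count is beta-binomial and the
pairwise correlation is ρ = 1/(1 + α + β).

This discrete model is the conceptual ground truth that the continuous-time
jump processes in :mod:`aoncb.jumps` must match as dt → 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "DirectingMeasure",
    "CountDistribution",
    "JointCountDistribution",
    "SpikeRaster",
    "beta_binomial_count_pmf",
    "bivariate_count_pmf",
    "correlation_from_directing_measure",
    "correlation_from_counts",
    "cross_correlation_from_counts",
    "sample_discrete_raster",
    "discrete_params_from_rate_corr",
]

_PMF_TOL = 1e-12

Coupling = Literal["independent", "maximal", "point_mass"]


@dataclass(frozen=True)
class DirectingMeasure:
    """De Finetti directing measure with beta marginals.

    Parameters
    ----------
    alpha_e, beta_e, alpha_i, beta_i
        Positive shape parameters of the excitatory and inhibitory beta
        marginals.  The implied per-bin spike probability is
        r·dt = α/(α+β) and must lie in (0, 1).
    coupling
        ``"independent"``: θe ⟂ θi (zero cross-correlation).
        ``"maximal"``: θe = θi almost surely (requires equal shapes).
        ``"point_mass"``: degenerate θ ≡ α/(α+β) for both populations
        (independent Poissonian spiking, all correlations zero).
    dt
        Bin width in seconds.
    """

    alpha_e: float
    beta_e: float
    alpha_i: float
    beta_i: float
    coupling: Coupling = "independent"
    dt: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("alpha_e", "beta_e", "alpha_i", "beta_i"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.coupling not in ("independent", "maximal", "point_mass"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "maximal" and not (
            self.alpha_e == self.alpha_i and self.beta_e == self.beta_i
        ):
            raise ValueError("maximal coupling requires a common Beta(α, β)")

    @property
    def spike_prob_e(self) -> float:
        """Per-bin excitatory spike probability E[θe] = αe/(αe+βe)."""
        return self.alpha_e / (self.alpha_e + self.beta_e)

    @property
    def spike_prob_i(self) -> float:
        return self.alpha_i / (self.alpha_i + self.beta_i)

    @property
    def rate_e(self) -> float:
        """Implied single-synapse excitatory rate in Hz."""
        return self.spike_prob_e / self.dt

    @property
    def rate_i(self) -> float:
        return self.spike_prob_i / self.dt


@dataclass(frozen=True)
class CountDistribution:
    """Probability vector over coactivation counts 0..K."""

    pmf: np.ndarray
    K: int

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if pmf.shape != (self.K + 1,):
            raise ValueError("pmf must have length K+1")
        if np.any(pmf < 0):
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > _PMF_TOL:
            raise ValueError("pmf must sum to 1 within 1e-12")

    @property
    def counts(self) -> np.ndarray:
        return np.arange(self.K + 1)

    def mean(self) -> float:
        return float(self.counts @ self.pmf)


@dataclass(frozen=True)
class JointCountDistribution:
    """Probability matrix over (0..Ke) × (0..Ki) coactivation counts."""

    pmf: np.ndarray
    Ke: int
    Ki: int

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        if pmf.shape != (self.Ke + 1, self.Ki + 1):
            raise ValueError("pmf must have shape (Ke+1, Ki+1)")
        if np.any(pmf < 0):
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > _PMF_TOL:
            raise ValueError("pmf must sum to 1 within 1e-12")


@dataclass(frozen=True)
class SpikeRaster:
    """Binary activity matrix: rows = synapses, columns = time bins."""

    activity: np.ndarray
    dt: float
    population: Literal["e", "i"] = "e"
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.activity)
        if a.ndim != 2:
            raise ValueError("activity must be a 2-d array")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("activity entries must be in {0, 1}")
        object.__setattr__(self, "activity", a.astype(np.uint8))

    @property
    def K(self) -> int:
        return self.activity.shape[0]

    @property
    def n_bins(self) -> int:
        return self.activity.shape[1]

    def empirical_rate(self) -> float:
        """Mean per-synapse spiking rate in Hz."""
        return float(self.activity.mean() / self.dt)

    def empirical_correlation(self) -> float:
        """Population estimate of the mean pairwise spiking correlation.

        Uses the identity V[pooled] = Σk V[Xk] + Σ_{k≠l} C[Xk, Xl], so the
        sd-weighted average pairwise Pearson correlation is computed without
        an O(K²) loop.
        """
        counts = self.activity.sum(axis=0)
        v_pooled = counts.var()
        v_each = self.activity.var(axis=1)
        sd = np.sqrt(v_each)
        denom = sd.sum() ** 2 - (v_each).sum()
        if denom <= 0:
            raise ValueError("undefined correlation: zero-variance raster")
        return float((v_pooled - v_each.sum()) / denom)


def beta_binomial_count_pmf(K: int, alpha: float, beta: float) -> CountDistribution:
    """Beta-binomial law of the number of coactive synapses per bin.

    P[k] = C(K, k) B(α+k, β+K−k) / B(α, β) for k = 0..K; the mean is
    K·α/(α+β).  Evaluated in log-space (log-gamma) for numerical stability.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be > 0")
    k = np.arange(K + 1)
    pmf = stats.betabinom.pmf(k, K, alpha, beta)
    pmf = pmf / pmf.sum()
    return CountDistribution(pmf=pmf, K=K)


def bivariate_count_pmf(
    Ke: int, Ki: int, alpha: float, beta: float
) -> JointCountDistribution:
    """Joint count law under maximal coupling: k ~ Bin(Ke, θ), l ~ Bin(Ki, θ)
    conditionally independent given a common θ ~ Beta(α, β).

    P[k, l] = C(Ke,k) C(Ki,l) B(α+k+l, β+Ke+Ki−k−l) / B(α, β).
    """
    if Ke < 1 or Ki < 1:
        raise ValueError("Ke and Ki must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be > 0")
    from scipy.special import betaln, gammaln

    k = np.arange(Ke + 1)[:, None]
    l = np.arange(Ki + 1)[None, :]
    log_choose = (
        gammaln(Ke + 1) - gammaln(k + 1) - gammaln(Ke - k + 1)
        + gammaln(Ki + 1) - gammaln(l + 1) - gammaln(Ki - l + 1)
    )
    logp = log_choose + betaln(alpha + k + l, beta + Ke + Ki - k - l) - betaln(alpha, beta)
    pmf = np.exp(logp)
    pmf = pmf / pmf.sum()
    return JointCountDistribution(pmf=pmf, Ke=Ke, Ki=Ki)


def correlation_from_directing_measure(
    F: DirectingMeasure,
) -> tuple[float, float, float]:
    """Spiking correlations (ρe, ρi, ρei) implied by a directing measure.

    ρ = V[θ] / (E[θ](1−E[θ])) within a population, and
    ρei = C[θe, θi] / sqrt(E[θe](1−E[θe]) E[θi](1−E[θi])) across populations.
    For beta marginals these reduce to ρ = 1/(1+α+β); maximal coupling
    saturates the bound ρei = sqrt(ρe ρi).
    """
    if F.coupling == "point_mass":
        return 0.0, 0.0, 0.0
    rho_e = 1.0 / (1.0 + F.alpha_e + F.beta_e)
    rho_i = 1.0 / (1.0 + F.alpha_i + F.beta_i)
    if F.coupling == "independent":
        rho_ei = 0.0
    else:  # maximal: C[θe, θi] = V[θ] with common shapes
        rho_ei = float(np.sqrt(rho_e * rho_i))
    return rho_e, rho_i, rho_ei


def correlation_from_counts(p, K: int | None = None) -> float:
    """Within-population spiking correlation from a count pmf.

    ρ = E[k(k−1)] / (E[k] (K−1)).  Accepts a :class:`CountDistribution`
    (applied to its pmf as given, e.g. a jump-conditioned pmf on 1..K
    represented over 0..K) or a bare probability vector with explicit ``K``.
    """
    if isinstance(p, CountDistribution):
        pmf, K = p.pmf, p.K
    else:
        pmf = np.asarray(p, dtype=float)
        if K is None:
            K = len(pmf) - 1
    if K < 2:
        raise ValueError("undefined correlation: need K >= 2")
    k = np.arange(len(pmf))
    mean_k = float(k @ pmf)
    if mean_k <= 0:
        raise ValueError("undefined correlation: zero-mean count law")
    fact2 = float((k * (k - 1)) @ pmf)
    return fact2 / (mean_k * (K - 1))


def cross_correlation_from_counts(p: JointCountDistribution) -> float:
    """Cross-population spiking correlation ρei from a joint jump-count law.

    ρei = E[ke·ki] / sqrt(Ke·E[ke] · Ki·E[ki]); the pmf is understood to be
    conditioned on at least one activation (no mass at (0,0) required).
    """
    pmf, Ke, Ki = p.pmf, p.Ke, p.Ki
    k = np.arange(Ke + 1)[:, None]
    l = np.arange(Ki + 1)[None, :]
    mean_e = float((k * pmf).sum())
    mean_i = float((l * pmf).sum())
    if mean_e <= 0 or mean_i <= 0:
        raise ValueError("undefined cross-correlation: degenerate marginal")
    cross = float((k * l * pmf).sum())
    return cross / np.sqrt(Ke * mean_e * Ki * mean_i)


def sample_discrete_raster(
    F: DirectingMeasure, K_e: int, K_i: int, n_bins: int, seed: int | np.random.SeedSequence
) -> tuple[SpikeRaster, SpikeRaster]:
    """Sample exchangeable spike rasters for both populations.

    Per bin, (θe, θi) is drawn from the directing measure (shared θ for
    maximal coupling, independent draws otherwise, constants for point
    mass), then each synapse fires i.i.d. Bernoulli(θ).  θ draws are
    independent across bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    if F.coupling == "point_mass":
        theta_e = np.full(n_bins, F.spike_prob_e)
        theta_i = np.full(n_bins, F.spike_prob_i)
    elif F.coupling == "maximal":
        theta_e = rng.beta(F.alpha_e, F.beta_e, size=n_bins)
        theta_i = theta_e
    else:
        theta_e = rng.beta(F.alpha_e, F.beta_e, size=n_bins)
        theta_i = rng.beta(F.alpha_i, F.beta_i, size=n_bins)
    x = (rng.random((K_e, n_bins)) < theta_e[None, :]).astype(np.uint8)
    y = (rng.random((K_i, n_bins)) < theta_i[None, :]).astype(np.uint8)
    return (
        SpikeRaster(activity=x, dt=F.dt, population="e"),
        SpikeRaster(activity=y, dt=F.dt, population="i"),
    )


def discrete_params_from_rate_corr(r: float, rho: float, dt: float) -> tuple[float, float]:
    """Invert (rate, correlation) → beta shapes (α, β) at bin width dt.

    Solves α/(α+β) = r·dt and 1/(1+α+β) = ρ, i.e. α+β = 1/ρ − 1.
    ρ = 0 has no finite-shape representation (use the structural
    singleton-jump / Poisson limit instead) and is rejected.
    """
    p = r * dt
    if not 0 < p < 1:
        raise ValueError("need 0 < r·dt < 1")
    if not 0 < rho < 1:
        raise ValueError(
            "need 0 < rho < 1 (rho=0 has no finite shapes: use the Poisson limit)"
        )
    s = 1.0 / rho - 1.0
    return s * p, s * (1.0 - p)
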