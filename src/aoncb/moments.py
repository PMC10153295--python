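"""Closed-form stationary voltage moments of the AONCB neuron.

In the instantaneous-synapse limit the stationary mean and variance are
exact expectations over the jump distribution, expressed through
dimensionless synaptic efficacies:

    ae,1 = bτ  E[We/(We+Wi) (1 − e^{−(We+Wi)})]
    ae,2 = bτ/2 E[We/(We+Wi) (1 − e^{−2(We+Wi)})]
    ae,12 = ae,1 − ae,2 = bτ/2 E[We/(We+Wi) (1 − e^{−(We+Wi)})²]
    cei  = bτ/2 E[We·Wi/(We+Wi)² (1 − e^{−(We+Wi)})²]

(and symmetrically for inhibition), giving

    E[V] = (ae,1·Ve + ai,1·Vi + I/G) / (1 + ae,1 + ai,1)
    V[V] = (ae,12(Ve−E[V])² + ai,12(Vi−E[V])² − cei(Ve−Vi)²)
           / (1 + ae,2 + ai,2).

The module also provides the small-weight (effective-time-constant)
approximation with its synchrony corrections, the unitary-PSP calibration
response, and the variability-preserving scaling limit where the jump law
converges to a degenerate beta (Lévy) measure ν(dw) = (rβ/w)(1−w/Ω)^{β−1}dw.
Expectations over jump tables are always exact sparse sums, never sampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .jumps import JointJumpDistribution
from .neuron import MembraneParams

__all__ = [
    "Efficacies",
    "StationaryMoments",
    "LimitMeasure",
    "efficacies",
    "stationary_mean",
    "stationary_variance",
    "stationary_moments",
    "small_weight_moments",
    "synchrony_deltas",
    "psp_response",
    "limit_measure",
    "limit_moments",
    "small_weight_error_report",
]


@dataclass(frozen=True)
class Efficacies:
    """Dimensionless synaptic efficacies: sufficient statistics for the
    stationary moment formulas."""

    ae1: float
    ai1: float
    ae2: float
    ai2: float
    ae12: float
    ai12: float
    cei: float
    b: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("ae1", "ai1", "ae2", "ai2", "ae12", "ai12", "cei"):
            if getattr(self, name) < -1e-15:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.ae12 - (self.ae1 - self.ae2)) > 1e-12:
            raise ValueError("identity ae12 = ae1 - ae2 violated")
        if abs(self.ai12 - (self.ai1 - self.ai2)) > 1e-12:
            raise ValueError("identity ai12 = ai1 - ai2 violated")


@dataclass(frozen=True)
class StationaryMoments:
    mean: float  # mV
    variance: float  # mV^2

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


def efficacies(joint: JointJumpDistribution, tau: float) -> Efficacies:
    """Exact synaptic efficacies of a joint jump law (sparse sums)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    We, Wi, p, b = joint.We, joint.Wi, joint.p, joint.b
    wtot = We + Wi
    fe = We / wtot
    fi = Wi / wtot
    g1 = 1.0 - np.exp(-wtot)
    g2 = 1.0 - np.exp(-2.0 * wtot)
    bt = b * tau
    ae1 = bt * float(p @ (fe * g1))
    ai1 = bt * float(p @ (fi * g1))
    ae2 = 0.5 * bt * float(p @ (fe * g2))
    ai2 = 0.5 * bt * float(p @ (fi * g2))
    cei = 0.5 * bt * float(p @ (fe * fi * g1 * g1))
    return Efficacies(
        ae1=ae1, ai1=ai1, ae2=ae2, ai2=ai2,
        ae12=ae1 - ae2, ai12=ai1 - ai2, cei=cei, b=b, tau=tau,
    )


def stationary_mean(e: Efficacies, m: MembraneParams) -> float:
    """E[V] = (ae,1·Ve + ai,1·Vi + I/G) / (1 + ae,1 + ai,1)."""
    return (e.ae1 * m.Ve + e.ai1 * m.Vi + m.I_over_G) / (1.0 + e.ae1 + e.ai1)


def stationary_variance(e: Efficacies, m: MembraneParams) -> float:
    """Exact stationary voltage variance (mV²); nonnegative by construction,
    clipped against roundoff."""
    mu = stationary_mean(e, m)
    num = (
        e.ae12 * (m.Ve - mu) ** 2
        + e.ai12 * (m.Vi - mu) ** 2
        - e.cei * (m.Ve - m.Vi) ** 2
    )
    var = num / (1.0 + e.ae2 + e.ai2)
    if var < -1e-12:
        raise AssertionError(f"negative variance {var}: invalid jump table")
    return max(var, 0.0)


def stationary_moments(joint: JointJumpDistribution, m: MembraneParams) -> StationaryMoments:
    """Exact stationary mean and variance for a joint jump law."""
    e = efficacies(joint, m.tau)
    return StationaryMoments(mean=stationary_mean(e, m), variance=stationary_variance(e, m))


def _small_weight_mean(Ke, Ki, re, ri, we, wi, m: MembraneParams) -> float:
    ae1 = Ke * re * m.tau * we
    ai1 = Ki * ri * m.tau * wi
    return (ae1 * m.Ve + ai1 * m.Vi + m.I_over_G) / (1.0 + ae1 + ai1)


def synchrony_deltas(
    Ke: int, Ki: int, re: float, ri: float, we: float, wi: float,
    rho_e: float, rho_i: float, rho_ei: float, m: MembraneParams,
) -> tuple[float, float, float]:
    """Small-weight synchrony corrections (Δρe, Δρi, Δρei) to the variance.

    Δρe = ρe(Ke−1)·Ke re we²(Ve−E[V])² / (2(1/τ + Ke re we + Ki ri wi)) ≥ 0,
    symmetrically for Δρi, and
    Δρei = −ρei·sqrt(re·ri)·Ke we·Ki wi·(Ve−E[V])(E[V]−Vi)
           / (1/τ + Ke re we + Ki ri wi) ≤ 0.
    """
    mu = _small_weight_mean(Ke, Ki, re, ri, we, wi, m)
    denom = 1.0 / m.tau + Ke * re * we + Ki * ri * wi
    d_e = rho_e * max(Ke - 1, 0) * Ke * re * we**2 * (m.Ve - mu) ** 2 / (2.0 * denom)
    d_i = rho_i * max(Ki - 1, 0) * Ki * ri * wi**2 * (m.Vi - mu) ** 2 / (2.0 * denom)
    d_ei = (
        -rho_ei * math.sqrt(re * ri) * Ke * we * Ki * wi
        * (m.Ve - mu) * (mu - m.Vi) / denom
        if rho_ei > 0
        else 0.0
    )
    return d_e, d_i, d_ei


def small_weight_moments(
    Ke: int, Ki: int, re: float, ri: float, we: float, wi: float,
    rho_e: float, rho_i: float, rho_ei: float, m: MembraneParams,
) -> StationaryMoments:
    """Small-weight (effective-time-constant) stationary moments.

    The mean uses ae,1 ≈ Ke re τ we (synchrony-independent); the variance is
    the asynchronous diffusion-type estimate

        V[V] ≈ (Ke re we²(Ve−E[V])² + Ki ri wi²(Vi−E[V])²)
               / (2(1/τ + Ke re we + Ki ri wi))

    plus the synchrony corrections of :func:`synchrony_deltas`.  Warns when
    a weight exceeds 0.05, where neglected exponential corrections grow.
    """
    if max(we, wi) > 0.05:
        warnings.warn("small-weight approximation dubious for weights > 0.05")
    mu = _small_weight_mean(Ke, Ki, re, ri, we, wi, m)
    denom = 1.0 / m.tau + Ke * re * we + Ki * ri * wi
    v_async = (
        Ke * re * we**2 * (m.Ve - mu) ** 2 + Ki * ri * wi**2 * (m.Vi - mu) ** 2
    ) / (2.0 * denom)
    d_e, d_i, d_ei = synchrony_deltas(Ke, Ki, re, ri, we, wi, rho_e, rho_i, rho_ei, m)
    return StationaryMoments(mean=mu, variance=max(v_async + d_e + d_i + d_ei, 0.0))


def psp_response(w: float, epsilon: float, m: MembraneParams) -> tuple[float, float]:
    """Peak deflection and peak time of a unitary PSP from rest.

    A single all-or-none activation holds h·τ = w/ε for a duration τs = ετ,
    during which V relaxes toward Ve·(w/ε)/(1 + w/ε) with shortened time
    constant τ/(1 + w/ε); the deflection peaks at the end of the activation:

        peak = Ve·(w/ε)/(1 + w/ε)·(1 − exp(−ε(1 + w/ε))),  t_peak = ε·τ.

    Used to calibrate dimensionless weights from measured somatic PSPs.
    """
    if w <= 0 or epsilon <= 0:
        raise ValueError("w and epsilon must be > 0")
    x = w / epsilon
    peak = m.Ve * x / (1.0 + x) * (1.0 - math.exp(-epsilon * (1.0 + x)))
    return peak, epsilon * m.tau


@dataclass(frozen=True)
class LimitMeasure:
    """Degenerate-beta Lévy measure ν(dw) = (r·β/w)(1 − w/Ω)^{β−1} dw on (0, Ω].

    The total mass is infinite (the density diverges at 0), but integrals of
    functions vanishing at 0 — such as 1 − e^{−w} — are finite.  This is the
    weak limit of be·pe,k under the scaling we = Ω/Ke, Ke → ∞, and defines a
    beta-process drive with infinitely many vanishing jumps.
    """

    Omega: float
    beta: float
    r: float

    def __post_init__(self) -> None:
        if self.Omega <= 0 or self.beta <= 0 or self.r <= 0:
            raise ValueError("Omega, beta, r must be > 0")

    def integrate(self, f: Callable[[float], float]) -> float:
        """∫ f dν with the 1/w singularity removed by u = w/Ω substitution.

        Rejects integrands with f(0) ≠ 0 (the integral would be infinite).
        """
        if abs(f(0.0)) > 0:
            raise ValueError("integrand must vanish at 0 (measure has infinite mass)")
        Om, be, r = self.Omega, self.beta, self.r

        def g(u: float) -> float:
            if u <= 0.0:
                return 0.0
            return f(Om * u) * r * be * (1.0 - u) ** (be - 1.0) / u

        val, _ = quad(g, 0.0, 1.0, epsrel=1e-8, epsabs=1e-12, limit=200)
        return val


def limit_measure(Omega_e: float, beta_e: float, r_e: float) -> LimitMeasure:
    return LimitMeasure(Omega=Omega_e, beta=beta_e, r=r_e)


def limit_moments(nu: LimitMeasure, m: MembraneParams) -> StationaryMoments:
    """Stationary moments of an excitation-only beta-process drive.

    E[V] = Ve·A1/(1/τ + A1) with A1 = ∫(1−e^{−w})ν(dw), and
    V[V] = (Ve−E[V])²·∫(1−e^{−w})²ν(dw) / (2/τ + ∫(1−e^{−2w})ν(dw)).
    Variance vanishes as β → ∞ (ρ → 0): no synchrony, no variability.
    """
    a1 = nu.integrate(lambda w: 1.0 - math.exp(-w))
    a12 = nu.integrate(lambda w: (1.0 - math.exp(-w)) ** 2)
    a2 = nu.integrate(lambda w: 1.0 - math.exp(-2.0 * w))
    mean = m.Ve * a1 / (1.0 / m.tau + a1)
    var = (m.Ve - mean) ** 2 * a12 / (2.0 / m.tau + a2)
    return StationaryMoments(mean=mean, variance=max(var, 0.0))


def small_weight_error_report(
    joint: JointJumpDistribution,
    Ke: int, Ki: int, re: float, ri: float, we: float, wi: float,
    rho_e: float, rho_i: float, rho_ei: float, m: MembraneParams,
) -> dict:
    """Relative discrepancies between exact and small-weight quantities.

    Utility for judging where the exponential corrections matter; reports
    efficacy-level and moment-level relative errors.  No hard accuracy
    claim is attached to these numbers.
    """
    e = efficacies(joint, m.tau)
    sw = small_weight_moments(Ke, Ki, re, ri, we, wi, rho_e, rho_i, rho_ei, m)
    exact = stationary_moments(joint, m)
    ae1_sw = Ke * re * m.tau * we
    ai1_sw = Ki * ri * m.tau * wi
    out = {
        "mean_exact": exact.mean,
        "mean_small_weight": sw.mean,
        "var_exact": exact.variance,
        "var_small_weight": sw.variance,
        "rel_err_mean": abs(sw.mean - exact.mean) / max(abs(exact.mean), 1e-300),
        "rel_err_var": abs(sw.variance - exact.variance) / max(exact.variance, 1e-300),
        "rel_err_ae1": abs(ae1_sw - e.ae1) / max(e.ae1, 1e-300),
    }
    if ai1_sw > 0:
        out["rel_err_ai1"] = abs(ai1_sw - e.ai1) / max(e.ai1, 1e-300)
    return out
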