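"""Numba kernels for the sequential event loops.

The Marcus event-driven scheme, the integrate-and-fire variant and the
per-event synapse assignment are inherently sequential recursions over
millions of events, so they are compiled with numba; everything around them
stays vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "assign_distinct_synapses",
    "marcus_path",
    "marcus_integrate",
    "integrate_and_fire_path",
    "euler_voltage",
]


@njit(cache=False)
def assign_distinct_synapses(counts, K, seed):
    """For each event with count k, pick k distinct synapse ids uniformly.

    Partial Fisher-Yates on a persistent permutation: each event reshuffles
    the first k slots against the whole array, which yields a uniform
    k-subset independent of the permutation state left by previous events.
    """
    np.random.seed(seed)
    total = 0
    for n in range(counts.size):
        total += counts[n]
    out = np.empty(total, dtype=np.int64)
    perm = np.arange(K)
    pos = 0
    for n in range(counts.size):
        k = counts[n]
        for j in range(k):
            i = j + np.random.randint(0, K - j)
            tmp = perm[j]
            perm[j] = perm[i]
            perm[i] = tmp
            out[pos] = perm[j]
            pos += 1
    return out


@njit(cache=False, fastmath=False)
def marcus_path(times, We, Wi, tau, Ve, Vi, v_inf, v0, t_begin):
    """Exact event-anchored voltage path: pre- and post-jump voltages.

    Between events V relaxes exponentially toward v_inf with constant tau;
    at each event the Marcus rule V -> target + (V - target)·exp(-Wtot)
    with target = (We·Ve + Wi·Vi)/Wtot is applied.
    """
    n = times.size
    v_pre = np.empty(n)
    v_post = np.empty(n)
    v = v0
    t = t_begin
    for i in range(n):
        v = v_inf + (v - v_inf) * np.exp(-(times[i] - t) / tau)
        v_pre[i] = v
        wtot = We[i] + Wi[i]
        target = (We[i] * Ve + Wi[i] * Vi) / wtot
        v = target + (v - target) * np.exp(-wtot)
        v_post[i] = v
        t = times[i]
    return v_pre, v_post


@njit(cache=False, fastmath=False)
def marcus_integrate(times, We, Wi, tau, Ve, Vi, v_inf, v0, t_begin, t_end, t_acc):
    """Stream the Marcus path and accumulate exact segment integrals.

    Returns (v_end, acc_T, acc_v, acc_v2) where the integrals of V and V²
    are accumulated in closed form over all exponential segments lying in
    [t_acc, t_end] (segments straddling t_acc are clipped exactly).
    Memory-free: nothing per-event is stored, so arbitrarily long horizons
    can be processed in chunks by feeding v_end back in as v0.
    """
    v = v0
    t = t_begin
    acc_T = 0.0
    acc_v = 0.0
    acc_v2 = 0.0
    n = times.size
    for i in range(n + 1):
        t_next = times[i] if i < n else t_end
        if t_next > t:
            a = t if t >= t_acc else t_acc
            if t_next > a:
                # voltage at the (possibly clipped) segment start
                va = v_inf + (v - v_inf) * np.exp(-(a - t) / tau)
                d = t_next - a
                e1 = np.exp(-d / tau)
                dv = va - v_inf
                acc_T += d
                acc_v += v_inf * d + dv * tau * (1.0 - e1)
                acc_v2 += (
                    v_inf * v_inf * d
                    + 2.0 * v_inf * dv * tau * (1.0 - e1)
                    + dv * dv * 0.5 * tau * (1.0 - e1 * e1)
                )
            v = v_inf + (v - v_inf) * np.exp(-(t_next - t) / tau)
            t = t_next
        if i < n:
            wtot = We[i] + Wi[i]
            target = (We[i] * Ve + Wi[i] * Vi) / wtot
            v = target + (v - target) * np.exp(-wtot)
    return v, acc_T, acc_v, acc_v2


@njit(cache=False, fastmath=False)
def integrate_and_fire_path(
    times, We, Wi, tau, Ve, Vi, v_inf, v0, t_begin, t_end, VT, VR, max_spikes
):
    """Marcus path with an integrate-and-fire mechanism (no refractoriness).

    Spikes are registered whenever a jump carries V across VT (reset to VR);
    if v_inf >= VT the deterministic upward crossing between events is solved
    in closed form.  Returns (v_pre, v_post, spike_times, n_spikes).
    """
    n = times.size
    v_pre = np.empty(n)
    v_post = np.empty(n)
    spikes = np.empty(max_spikes)
    ns = 0
    v = v0
    t = t_begin
    for i in range(n + 1):
        t_next = times[i] if i < n else t_end
        # between events, an upward crossing is only possible if v_inf >= VT
        if v_inf >= VT and v < VT:
            # crossing time: v_inf + (v - v_inf) exp(-d/tau) = VT
            if v_inf > VT:
                d_cross = tau * np.log((v_inf - v) / (v_inf - VT))
                while t + d_cross < t_next and ns < max_spikes:
                    spikes[ns] = t + d_cross
                    ns += 1
                    t = t + d_cross
                    v = VR
                    d_cross = tau * np.log((v_inf - v) / (v_inf - VT))
        v = v_inf + (v - v_inf) * np.exp(-(t_next - t) / tau)
        t = t_next
        if i < n:
            v_pre[i] = v
            wtot = We[i] + Wi[i]
            target = (We[i] * Ve + Wi[i] * Vi) / wtot
            v = target + (v - target) * np.exp(-wtot)
            if v >= VT and ns < max_spikes:
                spikes[ns] = times[i]
                ns += 1
                v = VR
            v_post[i] = v
    return v_pre, v_post, spikes, ns


@njit(cache=False, fastmath=False)
def euler_voltage(he, hi, dt, tau, Ve, Vi, i_term, v0):
    """Forward-Euler integration of V' = -V/τ + he(Ve-V) + hi(Vi-V) + i_term
    over a uniform grid with piecewise-constant reduced conductances."""
    n = he.size
    v = np.empty(n + 1)
    v[0] = v0
    x = v0
    for i in range(n):
        x = x + dt * (-x / tau + he[i] * (Ve - x) + hi[i] * (Vi - x) + i_term)
        v[i + 1] = x
    return v
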