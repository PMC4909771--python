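"""Exact finite-size retrieval-error and capacity analysis of the diluted
Willshaw network.

The retrieval channel is analyzed for i.i.d. Bernoulli memory patterns
(activation probabilities ``p = k/m``, ``q = l/n``), noiseless queries, and a
network whose memory-relevant connectivity is ``P_eff`` (each required
synapse is present independently with probability ``P_eff``).  For a high
(member) output unit all ``k`` active address synapses are potentiated, so
its dendritic potential is ``Binomial(k, P_eff)``.  For a low unit the
analysis conditions on the unit usage ``B ~ Binomial(M-1, q)`` — the number
of other memories containing the unit — under which each active address unit
is potentiated onto it independently with probability
``pi1(B) = 1 - (1 - k/m)^B``.

Pattern capacity ``M_eps`` is the largest ``M`` whose threshold-optimized
output noise stays below ``eps``; monotonicity of the noise in ``M`` is
asserted, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from ._util import transinfo_binary
from .patterns import ParameterError, p1_expected

#: cumulative tail mass below which the unit-usage sum is truncated
TAIL_MASS = 1e-14


@dataclass
class ErrorRates:
    """Component error probabilities of one-step retrieval at threshold theta."""

    q01: float  # add-error probability per low unit
    q10: float  # miss-error probability per high unit
    theta: int
    eps_hat: float  # q10 + (1/q - 1) q01


@dataclass
class CapacityResult:
    """Threshold-optimized capacity point of the Willshaw network."""

    M_eps: int
    theta: int
    q01: float
    q10: float
    eps_hat: float
    p1: float  # fraction of potentiated synapses at M_eps
    P_1: float  # minimal anatomical connectivity p1 * P_eff
    C_abs: float  # total stored bits
    C_wp: float  # bit per synapse at connectivity P_eff (weight plasticity)
    C_tot: float  # bit per non-silent synapse (structural plasticity)


def _usage_support(M: int, q: float):
    """Truncated support and weights of the unit usage B ~ Binomial(M-1, q)."""
    dist = stats.binom(M - 1, q)
    lo = int(dist.ppf(TAIL_MASS))
    hi = int(dist.isf(TAIL_MASS))
    b = np.arange(lo, hi + 1)
    w = dist.pmf(b)
    return b, w


def _eps_curve(M: int, k: int, l: int, m: int, n: int, P_eff: float):
    """(q10, q01, eps_hat) for every threshold theta = 0..k."""
    q = l / n
    theta = np.arange(0, k + 1)
    # high units: all k member synapses required, present w.p. P_eff
    q10 = stats.binom.cdf(theta - 1, k, P_eff)
    # low units: condition on unit usage
    if M <= 1:
        q01 = np.where(theta == 0, 1.0, 0.0)
    else:
        b, w = _usage_support(M, q)
        pi1 = -np.expm1(b * np.log1p(-k / m))  # 1 - (1 - k/m)^B
        # tail Pr[X >= theta | B] for X ~ Binomial(k, P_eff * pi1(B))
        tail = stats.binom.sf(theta[None, :] - 1, k, (P_eff * pi1)[:, None])
        q01 = w @ tail
    eps = q10 + (1.0 / q - 1.0) * q01
    return q10, q01, eps


def error_rates_exact(M: int, k: int, l: int, m: int, n: int, P_eff: float,
                      theta: int) -> ErrorRates:
    """Exact component error rates at a fixed firing threshold."""
    if not 0 < P_eff <= 1:
        raise ParameterError("P_eff must be in (0, 1]")
    if not 0 <= theta <= k:
        raise ParameterError("theta must be in 0..k")
    q10, q01, eps = _eps_curve(M, k, l, m, n, P_eff)
    return ErrorRates(q01=float(q01[theta]), q10=float(q10[theta]),
                      theta=int(theta), eps_hat=float(eps[theta]))


def min_noise_over_theta(M: int, k: int, l: int, m: int, n: int,
                         P_eff: float) -> ErrorRates:
    """Scan all thresholds and return the rates minimizing the output noise
    (ties resolved toward the smallest threshold)."""
    q10, q01, eps = _eps_curve(M, k, l, m, n, P_eff)
    th = int(np.argmin(eps))  # argmin returns the first (smallest) theta on ties
    return ErrorRates(q01=float(q01[th]), q10=float(q10[th]),
                      theta=th, eps_hat=float(eps[th]))


def pattern_capacity(k: int, l: int, m: int, n: int, P_eff: float,
                     eps: float = 0.01) -> CapacityResult:
    """Largest number of storable memories at output-noise level ``eps``.

    Exponential bracketing then integer bisection on ``M``; the minimized
    noise is checked to be non-decreasing along the way.  Capacities are
    evaluated at the returned ``M_eps``:  ``C_abs = M n T(q, q01, q10)``,
    ``C_wp = C_abs / (P_eff m n)``, ``C_tot = C_abs / (P_1 m n)`` with
    ``P_1 = p1 P_eff``.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    q = l / n

    cache: dict[int, ErrorRates] = {}

    def noise(M: int) -> ErrorRates:
        if M not in cache:
            cache[M] = min_noise_over_theta(M, k, l, m, n, P_eff)
        return cache[M]

    if noise(1).eps_hat > eps:
        return CapacityResult(M_eps=0, theta=0, q01=0.0, q10=0.0, eps_hat=np.nan,
                              p1=0.0, P_1=0.0, C_abs=0.0, C_wp=0.0, C_tot=0.0)
    # exponential bracketing: find infeasible M_hi
    lo, hi = 1, 2
    prev = noise(1).eps_hat
    while noise(hi).eps_hat <= eps:
        cur = noise(hi).eps_hat
        if cur < prev - 1e-9:
            raise AssertionError("output noise not non-decreasing in M")
        prev = cur
        lo, hi = hi, hi * 2
        if hi > 2**40:
            raise ParameterError("capacity search did not terminate")
    # integer bisection on [lo feasible, hi infeasible)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        e_mid = noise(mid).eps_hat
        if e_mid + 1e-9 < noise(lo).eps_hat or e_mid > noise(hi).eps_hat + 1e-9:
            raise AssertionError("output noise not non-decreasing in M")
        if e_mid <= eps:
            lo = mid
        else:
            hi = mid
    M_eps = lo
    best = noise(M_eps)
    p1 = p1_expected(k, l, m, n, M_eps)
    P_1 = p1 * P_eff
    T = transinfo_binary(q, best.q01, best.q10)
    C_abs = M_eps * n * T
    C_wp = C_abs / (P_eff * m * n)
    C_tot = C_abs / (P_1 * m * n) if P_1 > 0 else 0.0
    return CapacityResult(M_eps=M_eps, theta=best.theta, q01=best.q01, q10=best.q10,
                          eps_hat=best.eps_hat, p1=p1, P_1=P_1, C_abs=C_abs,
                          C_wp=C_wp, C_tot=C_tot)


def weight_capacity_curve(p1):
    """Asymptotic high-fidelity weight capacity ``C(p1) = ln(p1) ln(1-p1) / ln 2``
    of the fully connected Willshaw net, in bit/synapse (symmetric in
    ``p1 <-> 1-p1``, maximal at ``p1 = 1/2``)."""
    p1 = np.asarray(p1, dtype=float)
    c = np.log(p1) * np.log1p(-p1) / np.log(2.0)
    return c if c.ndim else float(c)


def total_capacity_curve(p1):
    """Asymptotic capacity per non-silent synapse, ``C(p1)/p1``; diverges like
    ``-ld p1`` for sparse potentiation, the structural-plasticity advantage."""
    p1 = np.asarray(p1, dtype=float)
    c = weight_capacity_curve(p1) / p1
    return c if c.ndim else float(c)


def asymptotic_weight_capacity():
    """Maximize the asymptotic weight capacity over the potentiation fraction.

    Returns ``(C_max, p1_opt)``; the closed-form optimum is ``ln 2`` bit per
    synapse at ``p1 = 1/2``, which the numerical maximization confirms.
    """
    res = optimize.minimize_scalar(lambda p: -weight_capacity_curve(p),
                                   bounds=(1e-6, 1 - 1e-6), method="bounded",
                                   options={"xatol": 1e-12})
    return float(-res.fun), float(res.x)
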