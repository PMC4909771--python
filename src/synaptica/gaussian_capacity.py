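"""Gaussian signal-to-noise capacity analysis: optimal (covariance/Bayesian)
networks and binary zip nets with structural plasticity.

For the covariance learning rule the dendritic-potential distributions of
high and low output units are approximated by Gaussians separated by a
signal-to-noise ratio ``r`` with ``r^2 = m P (1-p) / ((M-1) q (1-q))``.  A
firing threshold placed at the fraction ``gamma`` of the separation gives
error rates ``q10 = Phi(-(1-gamma) r)`` and ``q01 = Phi(-gamma r)``; the
split is optimized to minimize the output noise.

A zip net binarizes the learned weights at the ``p1``-quantile under
homeostatic synaptic thresholds.  Binarization retains a fraction

    zeta(p1) = phi(Phi^-1(1-p1))^2 / (p1 (1-p1))

of the squared SNR (``2/pi ~ 0.64`` at ``p1 = 1/2``), so the zip net reaches
``zeta`` times the Gaussian pattern capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._util import transinfo_binary
from .patterns import ParameterError, p1_expected


@dataclass
class GaussianCapacityResult:
    """Capacity point from the Gaussian signal-to-noise theory."""

    M_eps: int
    snr: float  # SNR r at M_eps (after any zip reduction)
    gamma: float  # optimal threshold split in (0, 1)
    zeta: float  # binarization factor applied (1 for the Gaussian/Bayesian net)
    q01: float
    q10: float
    eps_hat: float
    C_abs: float
    C_wp: float = float("nan")  # bit/synapse at anatomical connectivity (Bayesian)
    C_tot: float = float("nan")  # bit per 1-synapse (zip net)
    degenerate: bool = False


def zip_factor(p1: float) -> float:
    """SNR-retention factor of thresholding a Gaussian weight at its
    ``p1``-quantile; symmetric in ``p1 <-> 1 - p1`` with maximum ``2/pi``."""
    if not 0.0 <= p1 <= 1.0:
        raise ParameterError("p1 must be in [0, 1]")
    if p1 in (0.0, 1.0):
        return 0.0  # boundary limit
    z = ndtri(1.0 - p1)
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    return float(phi * phi / (p1 * (1.0 - p1)))


def _min_eps_over_gamma(r: float, q: float):
    """Minimize ``eps(gamma) = Phi(-(1-gamma) r) + (1/q - 1) Phi(-gamma r)``
    over the threshold split gamma in (0, 1)."""

    def eps(gamma):
        return ndtr(-(1.0 - gamma) * r) + (1.0 / q - 1.0) * ndtr(-gamma * r)

    res = optimize.minimize_scalar(eps, bounds=(1e-9, 1 - 1e-9), method="bounded",
                                   options={"xatol": 1e-12})
    gamma = float(res.x)
    q10 = float(ndtr(-(1.0 - gamma) * r))
    q01 = float(ndtr(-gamma * r))
    return float(res.fun), gamma, q10, q01


def _snr(M: int, m: int, P: float, p: float, q: float) -> float:
    if M < 2:
        return float("inf")
    return float(np.sqrt(m * P * (1.0 - p) / ((M - 1) * q * (1.0 - q))))


def bayesian_capacity(k: int, l: int, m: int, n: int, P: float,
                      eps: float = 0.01) -> GaussianCapacityResult:
    """Pattern capacity of the optimal (covariance-rule) network with
    real-valued synapses at anatomical connectivity ``P``.

    Searches the largest ``M`` whose split-optimized output noise stays below
    ``eps`` (the noise is checked to be increasing in ``M``) and reports
    ``C_wp = M n T(q, q01, q10) / (P m n)``.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    p, q = k / m, l / n

    def noise(M: int):
        return _min_eps_over_gamma(_snr(M, m, P, p, q), q)

    if noise(2)[0] > eps:
        return GaussianCapacityResult(M_eps=0, snr=float("inf"), gamma=0.5, zeta=1.0,
                                      q01=0.0, q10=0.0, eps_hat=float("nan"),
                                      C_abs=0.0, C_wp=0.0)
    lo, hi = 2, 4
    prev = noise(2)[0]
    while noise(hi)[0] <= eps:
        cur = noise(hi)[0]
        if cur < prev - 1e-12:
            raise AssertionError("output noise not increasing in M")
        prev = cur
        lo, hi = hi, hi * 2
        if hi > 2**42:
            raise ParameterError("capacity search did not terminate")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if noise(mid)[0] <= eps:
            lo = mid
        else:
            hi = mid
    M_eps = lo
    e, gamma, q10, q01 = noise(M_eps)
    r = _snr(M_eps, m, P, p, q)
    C_abs = M_eps * n * transinfo_binary(q, q01, q10)
    return GaussianCapacityResult(M_eps=M_eps, snr=r, gamma=gamma, zeta=1.0,
                                  q01=q01, q10=q10, eps_hat=e, C_abs=C_abs,
                                  C_wp=C_abs / (P * m * n))


def zipnet_capacity(k: int, l: int, m: int, n: int, P1: float, P_pot: float,
                    eps: float = 0.01) -> GaussianCapacityResult:
    """Capacity of a binary zip net whose ``P1 m n`` potentiated synapses are
    moved by structural plasticity within potential connectivity ``P_pot``.

    The zip net reaches ``zeta(P1/P_pot)`` times the Gaussian capacity at
    connectivity ``P_pot``; error rates are re-evaluated at the reduced SNR
    ``r sqrt(zeta)`` and ``C_tot = C_abs / (P1 m n)`` counts bits per
    (non-silent) 1-synapse.
    """
    if P1 > P_pot:
        raise ParameterError("P1 must not exceed P_pot")
    p1 = P1 / P_pot
    zeta = zip_factor(p1)
    if zeta == 0.0:
        return GaussianCapacityResult(M_eps=0, snr=0.0, gamma=0.5, zeta=zeta,
                                      q01=0.0, q10=0.0, eps_hat=float("nan"),
                                      C_abs=0.0, C_tot=0.0, degenerate=True)
    base = bayesian_capacity(k, l, m, n, P_pot, eps)
    M = int(round(zeta * base.M_eps))
    p, q = k / m, l / n
    r_zip = np.sqrt(zeta) * _snr(M, m, P_pot, p, q)
    e, gamma, q10, q01 = _min_eps_over_gamma(r_zip, q)
    C_abs = M * n * transinfo_binary(q, q01, q10)
    return GaussianCapacityResult(M_eps=M, snr=float(r_zip), gamma=gamma, zeta=zeta,
                                  q01=q01, q10=q10, eps_hat=e, C_abs=C_abs,
                                  C_tot=C_abs / (P1 * m * n))
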