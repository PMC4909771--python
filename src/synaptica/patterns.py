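"""Binary memory patterns, Willshaw / zip-net storage, and one-step retrieval.

The network associates sparse binary address patterns ``u`` (population of
``m`` neurons, on average ``k`` active) with content patterns ``v``
(``n`` neurons, ``l`` active).  Storage clips a Hebbian synaptic potential
``omega_ij = sum_mu u_i v_j`` at a synaptic threshold; retrieval propagates a
query through the binary weight matrix and applies a firing threshold to the
dendritic potentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from ._util import as_rng


class ParameterError(ValueError):
    """Invalid model or generator parameters."""


@dataclass
class PatternSet:
    """A set of ``M`` binary memory pairs stored as sorted active-index lists.

    For auto-association use ``m == n`` and pass the same list for both sides.
    """

    m: int
    n: int
    u: list  # list of sorted int arrays, indices in [0, m)
    v: list  # list of sorted int arrays, indices in [0, n)
    k: float  # nominal mean number of active address units
    l: float  # nominal mean number of active content units

    def __post_init__(self):
        if len(self.u) != len(self.v):
            raise ParameterError("u and v must hold the same number of patterns")
        for a in self.u:
            if len(a) and (a[0] < 0 or a[-1] >= self.m):
                raise ParameterError("address index out of range")
        for a in self.v:
            if len(a) and (a[0] < 0 or a[-1] >= self.n):
                raise ParameterError("content index out of range")

    @property
    def M(self) -> int:
        return len(self.u)

    @property
    def p(self) -> float:
        return self.k / self.m

    @property
    def q(self) -> float:
        return self.l / self.n

    def u_dense(self) -> np.ndarray:
        out = np.zeros((self.M, self.m), dtype=np.uint8)
        for i, a in enumerate(self.u):
            out[i, a] = 1
        return out

    def v_dense(self) -> np.ndarray:
        out = np.zeros((self.M, self.n), dtype=np.uint8)
        for i, a in enumerate(self.v):
            out[i, a] = 1
        return out


@dataclass
class WeightMatrix:
    """Binary weights plus the anatomical mask and raw synaptic potentials."""

    W: np.ndarray  # (m, n) uint8
    mask: np.ndarray  # (m, n) uint8, W <= mask elementwise
    potentials: Optional[np.ndarray] = None  # (m, n) synaptic potentials omega
    thresholds: Optional[np.ndarray] = None  # scalar or per-column synaptic thresholds

    @property
    def shape(self):
        return self.W.shape


@dataclass
class RetrievalResult:
    """Output of one-step retrieval."""

    v_hat: np.ndarray  # (n,) uint8
    dendritic_potentials: np.ndarray  # (n,) float or int
    theta_used: np.ndarray | float  # scalar or per-unit firing threshold
    noise_draws: Optional[np.ndarray] = None
    warning: bool = False  # set when l-winner retrieval degenerates

    def active(self) -> np.ndarray:
        return np.flatnonzero(self.v_hat)


def generate_patterns(m, n, k, l, M, mode: Literal["fixed-size", "bernoulli"] = "fixed-size",
                      seed=None, auto: bool = False) -> PatternSet:
    """Draw ``M`` i.i.d. random memory pairs.

    ``fixed-size`` draws exactly ``k`` (resp. ``l``) active units uniformly
    without replacement; ``bernoulli`` activates each unit independently with
    probability ``p = k/m`` (``q = l/n``).  With ``auto=True`` the content side
    is the address side (requires ``m == n`` and ``k == l``).
    """
    if not (0 < k <= m and 0 < l <= n) or M < 0:
        raise ParameterError("need 0 < k <= m, 0 < l <= n, M >= 0")
    if auto and (m != n or k != l):
        raise ParameterError("auto-association needs m == n and k == l")
    rng = as_rng(seed)
    us, vs = [], []
    for _ in range(M):
        if mode == "fixed-size":
            uu = np.sort(rng.choice(m, size=int(k), replace=False))
            vv = uu if auto else np.sort(rng.choice(n, size=int(l), replace=False))
        elif mode == "bernoulli":
            uu = np.flatnonzero(rng.random(m) < k / m)
            vv = uu if auto else np.flatnonzero(rng.random(n) < l / n)
        else:
            raise ParameterError(f"unknown mode {mode!r}")
        us.append(uu.astype(np.int64))
        vs.append(vv.astype(np.int64))
    return PatternSet(m=m, n=n, u=us, v=vs, k=k, l=l)


def store_willshaw(patterns: PatternSet, mask: Optional[np.ndarray] = None) -> WeightMatrix:
    """Clipped-Hebbian storage: ``W_ij = 1`` iff ``omega_ij >= 1`` and masked in.

    The returned ``potentials`` hold the unclipped co-activation counts
    ``omega_ij``; thresholded at 1 on a full mask they double as the
    consolidation signal of the stored set.
    """
    m, n = patterns.m, patterns.n
    if mask is None:
        mask = np.ones((m, n), dtype=np.uint8)
    if mask.shape != (m, n):
        raise ParameterError(f"mask shape {mask.shape} != ({m}, {n})")
    omega = np.zeros((m, n), dtype=np.int64)
    for uu, vv in zip(patterns.u, patterns.v):
        omega[np.ix_(uu, vv)] += 1
    W = ((omega >= 1) & (mask > 0)).astype(np.uint8)
    return WeightMatrix(W=W, mask=np.asarray(mask, dtype=np.uint8),
                        potentials=omega, thresholds=np.float64(1.0))


def store_zipnet(patterns: PatternSet, potential_mask: np.ndarray, target_P1: float,
                 rule: Literal["covariance", "homosynaptic"] = "covariance") -> WeightMatrix:
    """Zip-net storage: homeostatic synaptic thresholds fix the 1-synapse fraction.

    Synaptic potentials follow the covariance rule
    ``omega_ij = sum_mu (u_i - p)(v_j - q)`` or the homosynaptic rule
    ``omega_ij = sum_mu u_i (v_j - q)`` on potential-mask entries.  For each
    content neuron ``j`` the synaptic threshold is set so that a fraction
    ``target_P1 / P_pot`` of its potential synapses is potentiated (top
    potentials first, ties broken by smaller presynaptic index).  The realized
    anatomical mask equals the chosen 1-synapses.
    """
    m, n = patterns.m, patterns.n
    potential_mask = np.asarray(potential_mask, dtype=np.uint8)
    if potential_mask.shape != (m, n):
        raise ParameterError("potential mask dimension mismatch")
    P_pot = potential_mask.sum() / (m * n)
    if not (0 < target_P1 <= P_pot):
        raise ParameterError(f"target_P1={target_P1} infeasible for P_pot={P_pot}")
    frac = target_P1 / P_pot

    U = patterns.u_dense().astype(np.float64)  # (M, m)
    V = patterns.v_dense().astype(np.float64)  # (M, n)
    p, q = patterns.p, patterns.q
    if rule == "covariance":
        omega = (U - p).T @ (V - q)
    elif rule == "homosynaptic":
        omega = U.T @ (V - q)
    else:
        raise ParameterError(f"unknown rule {rule!r}")

    W = np.zeros((m, n), dtype=np.uint8)
    thresholds = np.full(n, np.inf)
    for j in range(n):
        pot_rows = np.flatnonzero(potential_mask[:, j])
        if pot_rows.size == 0:
            continue
        c = int(np.ceil(frac * pot_rows.size))
        c = min(c, pot_rows.size)
        vals = omega[pot_rows, j]
        # stable order: value descending, presynaptic index ascending
        order = np.lexsort((pot_rows, -vals))
        chosen = pot_rows[order[:c]]
        W[chosen, j] = 1
        thresholds[j] = vals[order[c - 1]] if c > 0 else np.inf
    return WeightMatrix(W=W, mask=W.copy(), potentials=omega, thresholds=thresholds)


def retrieve(W: WeightMatrix, query: np.ndarray,
             strategy: Literal["fixed-theta", "l-winner", "pattern-part"] = "l-winner",
             theta: Optional[float] = None, l: Optional[int] = None,
             noise_max: float = 0.0, seed=None) -> RetrievalResult:
    """One-step retrieval of a content pattern from a (noisy) address query.

    Dendritic potentials are ``x_j = sum_i query_i W_ij`` plus optional
    intrinsic noise ``N_j ~ Uniform[0, noise_max]``.  Strategies:

    - ``fixed-theta``: scalar firing threshold ``theta``.
    - ``l-winner``: maximal integer threshold activating at least ``l`` units.
    - ``pattern-part``: per-unit threshold ``Theta_j = sum_i query_i mask_ij``
      (every anatomically connected active input must be potentiated), which
      yields zero miss errors for noiseless queries.
    """
    query = np.asarray(query)
    mq, n = W.W.shape
    if query.shape != (mq,):
        raise ParameterError("query length mismatch")
    x = query.astype(np.float64) @ W.W.astype(np.float64)
    noise = None
    if noise_max > 0:
        noise = as_rng(seed).uniform(0.0, noise_max, size=n)
        xn = x + noise
    else:
        xn = x

    warn = False
    if strategy == "fixed-theta":
        if theta is None:
            raise ParameterError("fixed-theta needs theta")
        theta_used = float(theta)
        v_hat = (xn >= theta_used).astype(np.uint8)
    elif strategy == "l-winner":
        if l is None or l < 1:
            raise ParameterError("l-winner needs l >= 1")
        if query.sum() == 0:
            warnings.warn("empty query in l-winner retrieval; returning empty output")
            return RetrievalResult(v_hat=np.zeros(n, dtype=np.uint8),
                                   dendritic_potentials=x, theta_used=np.inf,
                                   noise_draws=noise, warning=True)
        srt = np.sort(xn)[::-1]
        theta_used = float(np.floor(srt[min(l, n) - 1]))
        v_hat = (xn >= theta_used).astype(np.uint8)
    elif strategy == "pattern-part":
        theta_used = query.astype(np.float64) @ W.mask.astype(np.float64)
        v_hat = (xn >= theta_used).astype(np.uint8)
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    return RetrievalResult(v_hat=v_hat, dendritic_potentials=x,
                           theta_used=theta_used, noise_draws=noise, warning=warn)


def output_noise(v_hat: np.ndarray, v_true: np.ndarray, l: float):
    """Output noise ``eps_hat = Hamming(v_hat, v_true) / l`` plus error counts.

    Returns ``(eps_hat, q01_count, q10_count)`` where ``q01_count`` is the
    number of add errors (spurious ones) and ``q10_count`` the miss errors.
    """
    v_hat = np.asarray(v_hat).astype(bool)
    v_true = np.asarray(v_true).astype(bool)
    if v_hat.shape != v_true.shape:
        raise ParameterError("length mismatch")
    if l <= 0:
        raise ParameterError("l must be positive")
    adds = int(np.count_nonzero(v_hat & ~v_true))
    misses = int(np.count_nonzero(~v_hat & v_true))
    return (adds + misses) / l, adds, misses


def p1_expected(k, l, m, n, M) -> float:
    """Expected fraction of potentiated synapses after storing ``M`` memories.

    ``p1 = 1 - (1 - kl/(mn))^M`` for i.i.d. patterns with activities
    ``p = k/m``, ``q = l/n``; evaluated in log space so that very large ``M``
    and tiny ``kl/(mn)`` stay accurate.
    """
    if M < 0:
        raise ParameterError("M must be >= 0")
    pq = (k * l) / (m * n)
    if pq >= 1.0:
        return 1.0 if M >= 1 else 0.0
    return float(-np.expm1(M * np.log1p(-pq)))
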