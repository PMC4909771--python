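"""Transfer-entropy bounds on associative retrieval.

Viewing one-step retrieval as a memory channel transmitting i.i.d. memory
bits, the normalized transfer entropy TE between address and content
populations is bounded below by the normalized storage capacity
``CN = T(q, q01, q10)`` and above by the output entropy ``OE = H_b(q_hat)``.
Deterministic retrieval attains the upper bound; retrieval with independent
intrinsic noise attains the lower one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import as_rng, binary_entropy, transinfo_binary
from .patterns import ParameterError, PatternSet, WeightMatrix, output_noise, retrieve


@dataclass
class ChannelBounds:
    """Capacity/entropy bounds of the retrieval channel, per output unit.

    ``eps_hat`` uses the symmetric convention ``q q10 + (1-q) q01`` (for
    pure add noise this is ``(1-q) q01``).
    """

    q: float
    q01: float
    q10: float
    CN: float  # normalized capacity T(q, q01, q10), lower TE bound
    OE: float  # output entropy H_b(q_hat), upper TE bound
    eps_hat: float
    TE_estimate: Optional[float] = None


def channel_bounds(q: float, q01: float, q10: float) -> ChannelBounds:
    """Closed-form bounds for component error rates (q01, q10) at output
    activity q."""
    q_hat = q * (1.0 - q10) + (1.0 - q) * q01
    return ChannelBounds(
        q=q, q01=q01, q10=q10,
        CN=transinfo_binary(q, q01, q10),
        OE=binary_entropy(q_hat),
        eps_hat=q * q10 + (1.0 - q) * q01,
    )


def estimate_te_retrieval(W: WeightMatrix, patterns: PatternSet, trials: int,
                          noise_max: float = 0.0, seed=None,
                          strategy: str = "l-winner") -> ChannelBounds:
    """Plug-in transfer-entropy estimate from Monte-Carlo retrievals.

    Retrieves ``trials`` randomly chosen stored memories (noiseless queries,
    intrinsic noise ``N_j ~ Uniform[0, noise_max]``) and counts component
    errors against the true contents.  For deterministic retrieval
    (``noise_max = 0``) the estimate is the output entropy of the empirical
    output marginal; with intrinsic noise it is the normalized capacity from
    the empirical error rates.
    """
    if trials < 1:
        raise ParameterError("need at least one trial")
    rng = as_rng(seed)
    n = patterns.n
    l = int(round(patterns.l))
    tot_lo = tot_hi = 0
    n_add = n_miss = 0
    n_out_ones = 0
    for _ in range(trials):
        mu = int(rng.integers(patterns.M))
        query = np.zeros(patterns.m, dtype=np.uint8)
        query[patterns.u[mu]] = 1
        res = retrieve(W, query, strategy=strategy, l=l,
                       noise_max=noise_max, seed=rng)
        v_true = np.zeros(n, dtype=np.uint8)
        v_true[patterns.v[mu]] = 1
        _, adds, misses = output_noise(res.v_hat, v_true, l)
        n_add += adds
        n_miss += misses
        hi = len(patterns.v[mu])
        tot_hi += hi
        tot_lo += n - hi
        n_out_ones += int(res.v_hat.sum())
    q = tot_hi / (trials * n)
    q01 = n_add / tot_lo if tot_lo else 0.0
    q10 = n_miss / tot_hi if tot_hi else 0.0
    cb = channel_bounds(q, q01, q10)
    if noise_max == 0.0:
        q_hat_emp = n_out_ones / (trials * n)
        cb.TE_estimate = float(binary_entropy(q_hat_emp))
    else:
        cb.TE_estimate = cb.CN
    return cb
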