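"""Anatomical, potential, effectual connectivity and the consolidation load.

Four statistics summarize a structurally plastic network:

- ``P``      anatomical connectivity, the fraction of neuron pairs joined by
             an actual synapse;
- ``P_pot``  potential connectivity, pairs close enough to grow a synapse;
- ``P_eff``  effectual connectivity, the fraction of *required* synapses
             (those the memory set needs, marked by the consolidation signal
             ``S``) that are realized with nonzero weight;
- ``P_1S``   consolidation load, the fraction of pairs requiring a
             consolidated synapse.

Nonzero tests are exact (the Heaviside of ``S^2``); callers quantize
real-valued signals themselves.
"""

from __future__ import annotations

import numpy as np

from .patterns import PatternSet, ParameterError, p1_expected, store_willshaw


def willshaw_signal(patterns: PatternSet) -> np.ndarray:
    """Consolidation signal of a memory set: the full-connectivity clipped
    Hebbian weights (1 wherever any stored pair co-activates)."""
    return store_willshaw(patterns).W


def measure(actual_mask, potential_mask, W, S) -> dict:
    """Compute ``{P, P_pot, P_eff, P_1S}`` from masks, weights, and signal.

    Raises if ``S`` is identically zero (``P_eff`` would divide by zero).
    """
    actual_mask = np.asarray(actual_mask)
    potential_mask = np.asarray(potential_mask)
    W = np.asarray(W)
    S = np.asarray(S)
    if not (actual_mask.shape == potential_mask.shape == W.shape == S.shape):
        raise ParameterError("all matrices must share one shape")
    mn = W.size
    required = S != 0
    n_req = int(np.count_nonzero(required))
    if n_req == 0:
        raise ParameterError("consolidation signal is all-zero: P_eff undefined")
    return {
        "P": float(np.count_nonzero(actual_mask) / mn),
        "P_pot": float(np.count_nonzero(potential_mask) / mn),
        "P_eff": float(np.count_nonzero((W != 0) & required) / n_req),
        "P_1S": float(n_req / mn),
    }


def consolidation_load_expected(k, l, m, n, M) -> float:
    """Expected consolidation load ``P_1S = 1 - (1 - kl/(mn))^M`` for i.i.d.
    random memories (one minus the chance that no stored pair tags ``ij``)."""
    return p1_expected(k, l, m, n, M)
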