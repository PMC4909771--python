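"""Shared numerics: binary entropy, binary-channel transinformation, seeding."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.special import xlogy


def binary_entropy(x):
    """Entropy H_b(x) = -x ld x - (1-x) ld (1-x) in bits, with 0 log 0 := 0."""
    x = np.asarray(x, dtype=float)
    h = -(xlogy(x, x) + xlogy(1.0 - x, 1.0 - x)) / np.log(2.0)
    return h if h.ndim else float(h)


def transinfo_binary(q, q01, q10):
    """Transinformation of one bit sent through an asymmetric binary channel.

    The input bit is 1 with probability ``q``; ``q01`` is the probability of a
    0->1 error and ``q10`` of a 1->0 error.  Returns
    ``H_b(q_hat) - q H_b(q10) - (1-q) H_b(q01)`` in bits, where
    ``q_hat = q(1-q10) + (1-q) q01`` is the output marginal.
    """
    q = np.asarray(q, dtype=float)
    q01 = np.asarray(q01, dtype=float)
    q10 = np.asarray(q10, dtype=float)
    q_hat = q * (1.0 - q10) + (1.0 - q) * q01
    t = binary_entropy(q_hat) - q * binary_entropy(q10) - (1.0 - q) * binary_entropy(q01)
    # clip tiny negative round-off
    t = np.maximum(t, 0.0)
    return t if t.ndim else float(t)


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, Generator, or None) to a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rng(seed, stream: str) -> np.random.Generator:
    """Named substream derived from a master seed (reproducible per stage)."""
    if isinstance(seed, np.random.Generator):
        return seed
    key = zlib.crc32(stream.encode("utf8"))  # stable across processes
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)
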