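"""Shared plasticity parameters and rehearsal schedules.

A potential synapse is a three-state Markov chain: ``pi`` (potential, not
realized), ``0`` (realized but silent/unstable), ``1`` (potentiated and
consolidated).  Transition probabilities depend on a per-pair binary
consolidation signal ``s`` (the synaptic tag):

- consolidation ``0 -> 1`` with ``p_c|s``,
- elimination ``0 -> pi`` with ``p_e|s``,
- deconsolidation with ``p_d|s`` (model A: ``1 -> 0``; model B: ``1 -> pi``),
- synaptogenesis ``pi -> 0`` with ``p_g`` (usually homeostatic, balancing the
  elimination flux so anatomical connectivity stays constant).

Outside rehearsal the tags are inactive: every synapse uses the ``s = 0``
parameters and ``p_c = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

from .patterns import ParameterError


@dataclass
class PlasticityParams:
    """Transition probabilities for synapse models A and B.

    ``p_g=None`` requests homeostatic synaptogenesis (generation balances
    elimination); a float fixes the per-step pi->0 probability instead.
    """

    model: Literal["A", "B"] = "A"
    p_c: Tuple[float, float] = (0.0, 1.0)  # (p_c|0, p_c|1)
    p_e: Tuple[float, float] = (0.0, 0.0)  # (p_e|0, p_e|1)
    p_d: Tuple[float, float] = (0.0, 0.0)  # (p_d|0, p_d|1)
    p_g: Optional[float] = None  # None => homeostatic

    def __post_init__(self):
        if self.model not in ("A", "B"):
            raise ParameterError("model must be 'A' or 'B'")
        for name in ("p_c", "p_e", "p_d"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"{name} out of [0, 1]")
        if self.p_g is not None and not 0.0 <= self.p_g <= 1.0:
            raise ParameterError("p_g out of [0, 1]")
        for s in (0, 1):
            if self.p_c[s] + self.p_e[s] > 1.0 + 1e-12:
                raise ParameterError("state-0 exit probabilities exceed 1")

    def rates(self, s: int, rehearsing: bool) -> Tuple[float, float, float]:
        """Effective ``(p_c, p_e, p_d)`` for signal ``s``; outside rehearsal
        all synapses fall back to the untagged rates with ``p_c = 0``."""
        if not rehearsing:
            return 0.0, self.p_e[0], self.p_d[0]
        return self.p_c[s], self.p_e[s], self.p_d[s]


@dataclass
class RehearsalSchedule:
    """Sorted, disjoint ``[start, end]`` step intervals (inclusive) during
    which the memory set is rehearsed."""

    intervals: Sequence[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        iv = sorted((int(a), int(b)) for a, b in self.intervals)
        for a, b in iv:
            if a > b or a < 0:
                raise ParameterError(f"bad interval [{a}, {b}]")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 <= b0:
                raise ParameterError("intervals overlap")
        self.intervals = iv

    @classmethod
    def from_times(cls, times: Sequence[int]) -> "RehearsalSchedule":
        """Build from individual step indices, merging consecutive runs."""
        ts = sorted(set(int(t) for t in times))
        iv = []
        for t in ts:
            if iv and t == iv[-1][1] + 1:
                iv[-1][1] = t
            else:
                iv.append([t, t])
        return cls([(a, b) for a, b in iv])

    def rehearsing(self, t: int) -> bool:
        return any(a <= t <= b for a, b in self.intervals)

    @property
    def end(self) -> int:
        return self.intervals[-1][1] if self.intervals else -1

    def total_steps(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)
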