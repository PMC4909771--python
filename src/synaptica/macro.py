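"""Deterministic group-level solver for connectivity evolution.

Instead of tracking every potential synapse, the network is partitioned into
groups of synapses that receive the same consolidation signal ``s``.  Each
group evolves its per-synapse state probabilities ``(p_pi, p_0, p_1)`` by the
three-term Markov recursions of the synapse model; pair-level connectivity
fractions follow by mixing over the potential-synapse-count distribution
``nd`` (default: one potential synapse per pair).  The homeostatic
synaptogenesis rate ``p_g`` is recomputed each step from the pre-step state
so that the total elimination flux is balanced and anatomical connectivity
stays constant in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .patterns import ParameterError
from .plasticity import PlasticityParams, RehearsalSchedule


@dataclass
class GroupState:
    """Per-synapse state probabilities of one signal group."""

    P_pot: float  # fraction of neuron pairs in this group with >= 1 potential synapse
    p_pi: float
    p_0: float
    p_1: float

    def check(self):
        s = self.p_pi + self.p_0 + self.p_1
        if abs(s - 1.0) > 1e-9:
            raise ParameterError(f"group probabilities sum to {s}, not 1")


@dataclass
class MacroState:
    """Signal-group decomposition of a structurally plastic network."""

    groups: Dict[int, GroupState]  # signal value s -> group
    nd: Dict[int, float] = field(default_factory=lambda: {1: 1.0})  # p(n) synapse count dist
    P_1S: float = 0.0  # total consolidation load, incl. tagged pairs with no potential synapse

    def __post_init__(self):
        tot = sum(self.nd.values())
        if abs(tot - 1.0) > 1e-9:
            raise ParameterError("synapse-count distribution must sum to 1")
        for g in self.groups.values():
            g.check()


def _pair_level(g: GroupState, nd: Dict[int, float]):
    """Pair-level (P_1, P_pi, P_0) of a group: a pair is in state 1 iff it has
    at least one state-1 synapse, in state pi iff all synapses are pi."""
    P1 = g.P_pot * sum(w * (1.0 - (1.0 - g.p_1) ** n) for n, w in nd.items())
    Ppi = g.P_pot * sum(w * g.p_pi ** n for n, w in nd.items())
    P0 = g.P_pot - P1 - Ppi
    return P1, Ppi, P0


def init_macro(P: float, P_pot: float, P_1_init: float, P_1S: float,
               nd: Optional[Dict[int, float]] = None) -> MacroState:
    """Two-group initial state for a fixed binary consolidation signal.

    Tag placement is independent of potential-synapse placement, so the
    tagged group holds ``P_pot * P_1S`` of the pairs; within each group the
    initial consolidated and silent fractions are ``P_1_init / P_pot`` and
    ``(P - P_1_init) / P_pot``.
    """
    if not (0.0 <= P_1_init <= P <= P_pot <= 1.0):
        raise ParameterError("need 0 <= P_1_init <= P <= P_pot <= 1")
    if not 0.0 <= P_1S <= 1.0:
        raise ParameterError("P_1S must be in [0, 1]")
    nd = dict(nd) if nd else {1: 1.0}
    p1 = P_1_init / P_pot
    p0 = (P - P_1_init) / P_pot
    ppi = 1.0 - p1 - p0
    groups = {}
    if P_1S < 1.0:
        groups[0] = GroupState(P_pot=P_pot * (1.0 - P_1S), p_pi=ppi, p_0=p0, p_1=p1)
    if P_1S > 0.0:
        groups[1] = GroupState(P_pot=P_pot * P_1S, p_pi=ppi, p_0=p0, p_1=p1)
    return MacroState(groups=groups, nd=nd, P_1S=P_1S)


def homeostatic_pg(state: MacroState, params: PlasticityParams, rehearsing: bool) -> float:
    """Synaptogenesis rate balancing the expected elimination flux, computed
    from the pre-step state (explicit scheme); clipped to [0, 1]."""
    flux = 0.0
    pool = 0.0
    for s, g in state.groups.items():
        pc, pe, pd = params.rates(s, rehearsing)
        flux += pe * g.p_0 * g.P_pot
        if params.model == "B":
            flux += pd * g.p_1 * g.P_pot
        pool += g.p_pi * g.P_pot
    if pool <= 0.0:
        if flux > 0.0:
            warnings.warn("potential-synapse pool depleted; p_g set to 0")
        return 0.0
    return min(1.0, flux / pool)


def step_macro(state: MacroState, params: PlasticityParams, rehearsing: bool) -> MacroState:
    """One synchronous step of the group recursions.

    Model A routes the deconsolidation flux ``p_d p_1`` into state 0, model B
    into state pi.  Outside rehearsal every group uses the untagged rates
    with ``p_c = 0``.
    """
    pg = params.p_g if params.p_g is not None else homeostatic_pg(state, params, rehearsing)
    new_groups = {}
    for s, g in state.groups.items():
        pc, pe, pd = params.rates(s, rehearsing)
        p1 = (1.0 - pd) * g.p_1 + pc * g.p_0
        if params.model == "A":
            p0 = (1.0 - pc - pe) * g.p_0 + pd * g.p_1 + pg * g.p_pi
        else:
            p0 = (1.0 - pc - pe) * g.p_0 + pg * g.p_pi
        ppi = 1.0 - p1 - p0
        new_groups[s] = GroupState(P_pot=g.P_pot, p_pi=ppi, p_0=p0, p_1=p1)
    return MacroState(groups=new_groups, nd=state.nd, P_1S=state.P_1S)


def network_connectivities(state: MacroState) -> dict:
    """Network-level connectivities {P_pi, P_0, P_1, P, P_pot, P_1S, P_eff}.

    ``P_eff`` is the consolidated fraction of the tagged pairs,
    ``sum_{s != 0} P_1^(s) / P_1S``; the consolidation load in the
    denominator includes tagged pairs that lack a potential synapse.
    """
    P1 = Ppi = P0 = Ppot = Peff_num = 0.0
    for s, g in state.groups.items():
        g1, gpi, g0 = _pair_level(g, state.nd)
        P1 += g1
        Ppi += gpi
        P0 += g0
        Ppot += g.P_pot
        if s != 0:
            Peff_num += g1
    out = {"P_pi": Ppi, "P_0": P0, "P_1": P1, "P": P0 + P1, "P_pot": Ppot,
           "P_1S": state.P_1S}
    if state.P_1S <= 0.0:
        raise ParameterError("P_1S = 0: P_eff undefined")
    out["P_eff"] = Peff_num / state.P_1S
    return out


def run_protocol_macro(P: float, P_pot: float, P_1_init: float, P_1S: float,
                       params: PlasticityParams, schedule: RehearsalSchedule,
                       T: Optional[int] = None,
                       nd: Optional[Dict[int, float]] = None) -> pd.DataFrame:
    """Deterministic trajectory with the same schema as the micro runner
    (columns ``t, P, P_pot, P_1, P_eff, rehearsing``)."""
    if T is None:
        T = schedule.end + 1
    state = init_macro(P, P_pot, P_1_init, P_1S, nd=nd)
    rows = []

    def record(t, rehearsing):
        c = network_connectivities(state)
        rows.append({"t": t, "P": c["P"], "P_pot": c["P_pot"], "P_1": c["P_1"],
                     "P_eff": c["P_eff"], "rehearsing": rehearsing})

    record(0, schedule.rehearsing(0))
    for t in range(T):
        reh = schedule.rehearsing(t)
        state = step_macro(state, params, reh)
        record(t + 1, reh)
    return pd.DataFrame(rows)
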