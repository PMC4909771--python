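"""Stochastic per-potential-synapse simulation of structural plasticity.

Each potential synapse is simulated as an independent three-state Markov
chain (see :mod:`synaptica.plasticity`); updates are synchronous, all
transitions drawn from the start-of-step state snapshot.  Homeostatic
synaptogenesis regrows, in every step, as many synapses as were eliminated,
at uniformly random potential locations, keeping anatomical connectivity
constant until the pool of unrealized potential synapses depletes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from ._util import as_rng, spawn_rng
from .patterns import ParameterError
from .plasticity import PlasticityParams, RehearsalSchedule

# state codes
PI, SILENT, CONS = 0, 1, 2


@dataclass
class SynapsePopulation:
    """Per-potential-synapse state arrays for an m x n projection.

    One potential synapse per neuron pair; ``pair_index`` holds flat indices
    ``i * n + j`` of the potential locations, ``state`` their Markov state,
    and ``tag`` the binary consolidation signal at the pair.
    """

    m: int
    n: int
    pair_index: np.ndarray  # (n_pot,) int64 flat pair ids
    state: np.ndarray  # (n_pot,) int8 in {PI, SILENT, CONS}
    tag: np.ndarray  # (n_pot,) bool
    n_tag_total: Optional[int] = None  # tagged pairs incl. those without a potential synapse

    @property
    def n_pot(self) -> int:
        return self.pair_index.size

    @property
    def mn(self) -> int:
        return self.m * self.n

    def measure(self) -> dict:
        """Connectivity statistics {P, P_pot, P_1, P_1S, P_eff} of the
        current state.  P_eff divides the consolidated tagged pairs by the
        full consolidation load (tagged pairs that lack a potential synapse
        can never be realized but still count as required).
        """
        n_tag = self.n_tag_total
        if n_tag is None:
            n_tag = int(np.count_nonzero(self.tag))
        n_cons_tag = int(np.count_nonzero(self.tag & (self.state == CONS)))
        return {
            "P": float(np.count_nonzero(self.state != PI) / self.mn),
            "P_pot": float(self.n_pot / self.mn),
            "P_1": float(np.count_nonzero(self.state == CONS) / self.mn),
            "P_1S": float(n_tag / self.mn),
            "P_eff": (n_cons_tag / n_tag) if n_tag else float("nan"),
        }


def init_population(m: int, n: int, P: float, P_pot: float, P_1_init: float,
                    signal: np.ndarray, seed=None) -> SynapsePopulation:
    """Place potential synapses, actual synapses, and initial consolidated
    synapses uniformly at random (independent of the tags).

    ``signal`` is an (m, n) binary consolidation-signal matrix; exact counts
    ``round(P_pot*mn)`` etc. are used so small nets match their nominal
    connectivities.
    """
    if not (0.0 <= P_1_init <= P <= P_pot <= 1.0):
        raise ParameterError("need 0 <= P_1_init <= P <= P_pot <= 1")
    signal = np.asarray(signal)
    if signal.shape != (m, n):
        raise ParameterError("signal shape mismatch")
    rng = as_rng(seed)
    mn = m * n
    n_pot = int(round(P_pot * mn))
    pair_index = np.sort(rng.choice(mn, size=n_pot, replace=False))
    state = np.zeros(n_pot, dtype=np.int8)
    n_act = int(round(P * mn))
    actual = rng.choice(n_pot, size=n_act, replace=False)
    state[actual] = SILENT
    n_cons = int(round(P_1_init * mn))
    if n_cons:
        state[rng.choice(actual, size=n_cons, replace=False)] = CONS
    flat = signal.reshape(-1) != 0
    tag = flat[pair_index]
    return SynapsePopulation(m=m, n=n, pair_index=pair_index, state=state, tag=tag,
                             n_tag_total=int(np.count_nonzero(flat)))


def step_micro(pop: SynapsePopulation, params: PlasticityParams, rehearsing: bool,
               seed=None, rng: Optional[np.random.Generator] = None) -> int:
    """Advance the population one synchronous step (in place).

    Weight transitions (0<->1) and structural transitions are all drawn from
    the start-of-step snapshot.  Synaptogenesis is applied here only when
    ``params.p_g`` is a number; homeostatic regrowth is a separate call to
    :func:`homeostatic_generation`.  Returns the number of synapses
    eliminated in this step (0->pi, plus 1->pi for model B), the flux the
    homeostatic rule must balance.
    """
    rng = rng if rng is not None else as_rng(seed)
    # realized synapses: one uniform each drives the mutually exclusive exits
    act = np.flatnonzero(pop.state != PI)
    state0 = pop.state[act].copy()
    u = rng.random(act.size)

    if rehearsing:
        s_eff = pop.tag[act]
        pc_ = np.where(s_eff, params.p_c[1], params.p_c[0])
        pe_ = np.where(s_eff, params.p_e[1], params.p_e[0])
        pd_ = np.where(s_eff, params.p_d[1], params.p_d[0])
    else:
        pc_, pe_, pd_ = 0.0, params.p_e[0], params.p_d[0]

    silent = state0 == SILENT
    cons = state0 == CONS
    consolidate = silent & (u < pc_)
    eliminate = silent & ~consolidate & (u < np.asarray(pc_) + pe_)
    deconsolidate = cons & (u < pd_)

    pop.state[act[consolidate]] = CONS
    pop.state[act[eliminate]] = PI
    pop.state[act[deconsolidate]] = SILENT if params.model == "A" else PI

    n_elim = int(np.count_nonzero(eliminate))
    if params.model == "B":
        n_elim += int(np.count_nonzero(deconsolidate))

    if params.p_g is not None and params.p_g > 0:
        pi_idx = np.flatnonzero(pop.state == PI)
        # exclude synapses realized in this very step (synchronous update)
        pi_snapshot = np.setdiff1d(pi_idx, act, assume_unique=True)
        grow = pi_snapshot[rng.random(pi_snapshot.size) < params.p_g]
        pop.state[grow] = SILENT
    return n_elim


def homeostatic_generation(pop: SynapsePopulation, eliminated_count: int,
                           mode: Literal["exact", "probabilistic"] = "exact",
                           seed=None, rng: Optional[np.random.Generator] = None,
                           candidates: Optional[np.ndarray] = None) -> bool:
    """Regrow synapses at unrealized potential locations.

    ``exact`` regrows exactly ``min(eliminated_count, #pi)`` synapses chosen
    uniformly among state-pi locations, so network connectivity is constant
    up to pool depletion; ``probabilistic`` applies ``p_g =
    eliminated/#pi`` (clipped) independently per pi-synapse.  ``candidates``
    restricts the pool (e.g. to the start-of-step pi snapshot, matching the
    synchronous-update semantics).  Returns True if the pool was depleted
    (connectivity may drop).
    """
    if eliminated_count < 0:
        raise ParameterError("eliminated_count must be >= 0")
    if eliminated_count == 0:
        return False
    rng = rng if rng is not None else as_rng(seed)
    if candidates is not None:
        pi_idx = candidates[pop.state[candidates] == PI]
    else:
        pi_idx = np.flatnonzero(pop.state == PI)
    if pi_idx.size == 0:
        warnings.warn("potential-synapse pool depleted; connectivity may drop")
        return True
    if mode == "exact":
        grow = rng.choice(pi_idx, size=min(eliminated_count, pi_idx.size), replace=False)
        pop.state[grow] = SILENT
        return eliminated_count > pi_idx.size
    elif mode == "probabilistic":
        p_g = min(1.0, eliminated_count / pi_idx.size)
        grow = pi_idx[rng.random(pi_idx.size) < p_g]
        pop.state[grow] = SILENT
        return False
    raise ParameterError(f"unknown mode {mode!r}")


def run_protocol_micro(pop: SynapsePopulation, params: PlasticityParams,
                       schedule: RehearsalSchedule, T: Optional[int] = None,
                       seed=None,
                       homeostasis: Literal["exact", "probabilistic"] = "exact",
                       ) -> pd.DataFrame:
    """Iterate the stochastic dynamics for ``T`` steps, recording connectivity.

    The returned frame has one row per time 0..T with columns
    ``t, P, P_pot, P_1, P_eff, rehearsing``.  When ``params.p_g`` is None the
    eliminated synapses of each step are regrown homeostatically.
    """
    if T is None:
        T = schedule.end + 1
    rng = spawn_rng(seed, "micro")
    rows = []

    def record(t, rehearsing):
        mm = pop.measure()
        rows.append({"t": t, "P": mm["P"], "P_pot": mm["P_pot"], "P_1": mm["P_1"],
                     "P_eff": mm["P_eff"], "rehearsing": rehearsing})

    record(0, schedule.rehearsing(0))
    for t in range(T):
        reh = schedule.rehearsing(t)
        if params.p_g is None and homeostasis == "probabilistic":
            # expected elimination flux from the snapshot, like the macro rule
            n_pi = int(np.count_nonzero(pop.state == PI))
            flux = _expected_elimination(pop, params, reh)
            pg = min(1.0, flux / n_pi) if n_pi else 0.0
            local = PlasticityParams(model=params.model, p_c=params.p_c,
                                     p_e=params.p_e, p_d=params.p_d, p_g=pg)
            step_micro(pop, local, reh, rng=rng)
        else:
            pi_snapshot = np.flatnonzero(pop.state == PI) if params.p_g is None else None
            n_elim = step_micro(pop, params, reh, rng=rng)
            if params.p_g is None:
                homeostatic_generation(pop, n_elim, mode="exact", rng=rng,
                                       candidates=pi_snapshot)
        record(t + 1, reh)
    return pd.DataFrame(rows)


def _expected_elimination(pop: SynapsePopulation, params: PlasticityParams,
                          rehearsing: bool) -> float:
    pe0 = params.p_e[0]
    pd0 = params.p_d[0]
    silent = pop.state == SILENT
    cons = pop.state == CONS
    if rehearsing:
        flux = (pe0 * np.count_nonzero(silent & ~pop.tag)
                + params.p_e[1] * np.count_nonzero(silent & pop.tag))
        if params.model == "B":
            flux += (pd0 * np.count_nonzero(cons & ~pop.tag)
                     + params.p_d[1] * np.count_nonzero(cons & pop.tag))
    else:
        flux = pe0 * np.count_nonzero(silent)
        if params.model == "B":
            flux += pd0 * np.count_nonzero(cons)
    return float(flux)
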