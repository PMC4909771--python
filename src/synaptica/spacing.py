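"""Closed-form theory of the spacing effect and Cepeda-style protocol runs.

A set of new memories is studied until time ``t1`` (reaching effectual
connectivity ``Peff1``), restudied once after a gap ``dt``, and tested after
a further retention interval RI.  Between rehearsals the tags are inactive:
consolidated synapses deconsolidate at rate ``p_d|0`` and silent synapses
turn over at ``p_e|0`` while homeostatic synaptogenesis keeps anatomical
connectivity constant.  Under ``p_c|s = s`` and ``p_e|1 = p_d|1 = 0``
(synapse model B) the effectual connectivity reached by the second rehearsal
admits the closed form implemented in :func:`peff_after_gap`, and the
optimal gap solves a scalar equation in ``x = (1 - p_d|0)^dt`` that is
independent of the retention interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .macro import init_macro, network_connectivities, run_protocol_macro, step_macro
from .patterns import ParameterError
from .plasticity import PlasticityParams, RehearsalSchedule


@dataclass
class SpacingProtocol:
    """Timing of a two-session study protocol (in model steps)."""

    t1: int  # end of initial study
    gap: int  # dt between sessions
    ri: int  # retention interval between second session and test

    def __post_init__(self):
        if min(self.t1, self.gap, self.ri) < 0:
            raise ParameterError("protocol times must be non-negative")

    @property
    def t2(self) -> int:
        return self.t1 + self.gap

    @property
    def t3(self) -> int:
        return self.t2 + self.ri


@dataclass
class SpacingParams:
    """Network and plasticity parameters of the spacing-effect theory.

    ``peff1`` is the effectual connectivity reached at the end of the first
    study session; if None it is computed by running the macroscopic model
    for ``t1`` rehearsal steps.  The defaults are a cortical parameter set:
    potential connectivity 0.4, anatomical connectivity 0.1, a 20% initial
    up-state fraction ``P_1(t0) = 0.02``, and a small consolidation load
    ``P_1S = 0.001`` for the new facts.
    """

    P: float = 0.1
    P_pot: float = 0.4
    P1_t0: float = 0.02
    P_1S: float = 0.001
    p_e0: float = 0.01
    p_d0: float = 0.0002
    t1: int = 10
    peff1: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.P1_t0 <= self.P <= self.P_pot <= 1.0):
            raise ParameterError("need 0 <= P1_t0 <= P <= P_pot <= 1")
        if self.peff1 is None:
            self.peff1 = _peff_after_study(self)

    @property
    def alpha(self) -> float:
        """Turnover/deconsolidation rate ratio ln(1-p_e0)/ln(1-p_d0)."""
        return math.log1p(-self.p_e0) / math.log1p(-self.p_d0)

    def plasticity(self, model: str = "B") -> PlasticityParams:
        return PlasticityParams(model=model, p_c=(0.0, 1.0),
                                p_e=(self.p_e0, 0.0), p_d=(self.p_d0, 0.0))


def _peff_after_study(params: SpacingParams, model: str = "B") -> float:
    """Effectual connectivity after ``t1`` rehearsal steps of the macro model."""
    state = init_macro(params.P, params.P_pot, params.P1_t0, params.P_1S)
    pl = params.plasticity(model)
    for _ in range(params.t1):
        state = step_macro(state, pl, rehearsing=True)
    return network_connectivities(state)["P_eff"]


def p1_at_t1(params: SpacingParams) -> float:
    """Consolidated fraction at the end of the first study session:
    ``P_1(t0)(1 - P_1S)(1 - p_d0)^t1 + P_1S Peff1`` (untagged up-state
    synapses decay; tagged ones track the achieved performance)."""
    return (params.P1_t0 * (1.0 - params.P_1S) * (1.0 - params.p_d0) ** params.t1
            + params.P_1S * params.peff1)


def peff_after_gap(params: SpacingParams, dt):
    """Effectual connectivity right after the second rehearsal for gap ``dt``.

    Closed form valid for ``p_c|s = s``, ``p_e|1 = p_d|1 = 0``, synapse
    model B with homeostatic synaptogenesis.
    """
    dt = np.asarray(dt, dtype=float)
    P, Ppot = params.P, params.P_pot
    peff1 = params.peff1
    p1t1 = p1_at_t1(params)
    xd = (1.0 - params.p_d0) ** dt
    xe = (1.0 - params.p_e0) ** dt
    num = (P * Ppot
           + ((Ppot - P) * peff1 - Ppot * p1t1) * xd
           - Ppot * (P - p1t1) * xe)
    den = Ppot - p1t1 * xd - (P - p1t1) * xe
    if np.any(den <= 0):
        raise ParameterError("vanishing denominator in the gap formula "
                             f"(P={P}, Ppot={Ppot}, p1t1={p1t1})")
    out = num / den
    return out if out.ndim else float(out)


def peff_at_test(params: SpacingParams, dt, ri):
    """Performance at test: the post-rehearsal level decays exponentially by
    ``(1 - p_d0)`` per retention step, so the optimal gap is RI-independent."""
    return peff_after_gap(params, dt) * (1.0 - params.p_d0) ** np.asarray(ri, dtype=float)


@dataclass
class OptimalGap:
    """Solution of the optimal-gap criterion."""

    dt: float  # continuous argmax
    dt_int: int  # best integer neighbor under peff_after_gap
    x: float  # (1 - p_d0)^dt at the optimum
    alpha: float
    boundary: bool = False  # True when no interior optimum exists


def optimal_gap(params: SpacingParams) -> OptimalGap:
    """Solve the optimality criterion for the study gap.

    The stationarity condition in ``x = (1-p_d0)^dt`` reads::

        (Peff1 - P1(t1))/(P - P1(t1)) + (alpha-1) (Peff1/Ppot) x^alpha
            - alpha x^(alpha-1) = 0

    with ``alpha = ln(1-p_e0)/ln(1-p_d0)``.  Solved by safeguarded root
    finding (Brent) on (0, 1) to 1e-12; a finite interior optimum requires
    ``alpha > 1`` (turnover faster than deconsolidation).
    """
    if not (0.0 < params.p_d0 < 1.0 and 0.0 < params.p_e0 < 1.0):
        raise ParameterError("need 0 < p_d0 < 1 and 0 < p_e0 < 1")
    a = params.alpha
    peff1 = params.peff1
    p1t1 = p1_at_t1(params)
    c0 = (peff1 - p1t1) / (params.P - p1t1)

    def f(x):
        return c0 + (a - 1.0) * (peff1 / params.P_pot) * x ** a - a * x ** (a - 1.0)

    lo, hi = 1e-12, 1.0 - 1e-12
    if f(lo) * f(hi) > 0:
        # monotone case: optimum at a boundary (gap 0 or infinite)
        dt = 0.0 if f(hi) > 0 else float("inf")
        return OptimalGap(dt=dt, dt_int=0 if dt == 0.0 else np.iinfo(np.int64).max,
                          x=float("nan"), alpha=a, boundary=True)
    x_opt = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    dt = math.log(x_opt) / math.log1p(-params.p_d0)
    # best integer neighbor under the objective
    cands = sorted({max(0, math.floor(dt)), math.ceil(dt)})
    dt_int = max(cands, key=lambda d: peff_after_gap(params, d))
    return OptimalGap(dt=dt, dt_int=int(dt_int), x=float(x_opt), alpha=a)


def run_cepeda_protocol(params: SpacingParams, gaps: Sequence[int],
                        retention_intervals: Sequence[int], model: str = "B",
                        tr2: int = 1) -> pd.DataFrame:
    """Simulate the two-session protocol on a grid of gaps and RIs.

    For each gap: ``t1`` rehearsal steps, the gap, ``tr2`` rehearsal steps,
    then decay through the longest retention interval; the macroscopic
    engine (model A or B) integrates the whole trajectory.  Returns a frame
    with columns ``gap, ri, peff2, peff3``.
    """
    if len(gaps) == 0 or len(retention_intervals) == 0:
        raise ParameterError("grids must be non-empty")
    pl = params.plasticity(model)
    rows = []
    ris = sorted(int(r) for r in retention_intervals)
    for gap in gaps:
        gap = int(gap)
        t2_start = params.t1 + gap
        schedule = RehearsalSchedule(
            [(0, params.t1 - 1), (t2_start, t2_start + tr2 - 1)]
            if params.t1 > 0 else [(t2_start, t2_start + tr2 - 1)])
        T = t2_start + tr2 + ris[-1]
        traj = run_protocol_macro(params.P, params.P_pot, params.P1_t0,
                                  params.P_1S, pl, schedule, T=T)
        peff = traj["P_eff"].to_numpy()
        t2_end = t2_start + tr2
        for ri in ris:
            rows.append({"gap": gap, "ri": ri, "peff2": peff[t2_end],
                         "peff3": peff[t2_end + ri]})
    return pd.DataFrame(rows)
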