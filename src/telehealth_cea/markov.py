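"""Three-state Markov cohort engine: in-person, telehealth, dead.

A closed cohort starts 100% in one live delivery-mode state and is advanced
through yearly cycles by a row-stochastic transition matrix. Within a
cycle, death is applied first and modality switching only among survivors,
so the supplied annual mortality is the actual probability of dying that
year. Costs and caregiver-burden effectiveness accrue per cycle for the
states occupied at cycle start (cycle 0 undiscounted) and are discounted at
a fixed per-cycle rate; an optional half-cycle correction averages adjacent
occupancies instead.

Rewards can be attributed two ways:

* ``"state"`` — each live state accrues its own cost/effect; the totals
  reflect the mixed delivery experience of the cohort (the textbook cohort
  accrual).
* ``"strategy"`` — all alive members accrue the starting modality's
  cost/effect; the background transitions then only shape survival and the
  per-alive-year outcome equals the per-cycle reward exactly. This is the
  attribution under which the incremental comparison reduces to the
  per-person-year incremental ratio (see :mod:`telehealth_cea.cea`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

STATES = ("in_person", "telehealth", "dead")
STRATEGIES = ("in_person_start", "telehealth_start")
_START_STATE = {"in_person_start": 0, "telehealth_start": 1}
_STRATEGY_MODALITY = {"in_person_start": "in_person", "telehealth_start": "telehealth"}


@dataclass
class MarkovParameters:
    """Inputs of one scenario; probabilities and rates are per one-year cycle."""

    p_switch_in_to_tele: float
    p_switch_tele_to_in: float
    m_in: float
    m_tele: float
    c_delivery_in: float
    c_delivery_tele: float
    e_in: float
    e_tele: float
    ed_rate_in: float = 0.0
    ed_rate_tele: float = 0.0
    hosp_rate_in: float = 0.0
    hosp_rate_tele: float = 0.0
    c_ed: float = 0.0
    c_hosp: float = 0.0
    discount_rate: float = 0.03
    horizon: int = 10
    include_utilization_costs: bool = False
    half_cycle_correction: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("p_switch_in_to_tele", "p_switch_tele_to_in", "m_in", "m_tele"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in ("c_delivery_in", "c_delivery_tele", "ed_rate_in", "ed_rate_tele",
                     "hosp_rate_in", "hosp_rate_tele", "c_ed", "c_hosp", "discount_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("e_in", "e_tele"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ParameterError(f"{name} must lie in [0, 100]")
        if self.horizon < 1:
            raise ParameterError("horizon must be >= 1")

    def with_overrides(self, **kwargs) -> "MarkovParameters":
        return replace(self, **kwargs)

    def state_cost(self, state: str) -> float:
        """Per-cycle cost of occupying a live state."""
        if state == "in_person":
            c = self.c_delivery_in
            if self.include_utilization_costs:
                c += self.ed_rate_in * self.c_ed + self.hosp_rate_in * self.c_hosp
        elif state == "telehealth":
            c = self.c_delivery_tele
            if self.include_utilization_costs:
                c += self.ed_rate_tele * self.c_ed + self.hosp_rate_tele * self.c_hosp
        else:
            raise ParameterError(f"unknown live state {state!r}")
        return c

    def state_effect(self, state: str) -> float:
        if state == "in_person":
            return self.e_in
        if state == "telehealth":
            return self.e_tele
        raise ParameterError(f"unknown live state {state!r}")


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle; row t is occupancy at time t."""

    occupancy: np.ndarray  # (horizon + 1, 3) over STATES

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ParameterError("occupancy must have shape (cycles + 1, 3)")
        if (occ < -1e-12).any():
            raise ParameterError("occupancy fractions must be nonnegative")
        if np.abs(occ.sum(axis=1) - 1.0).max() > 1e-12:
            raise ParameterError("occupancy rows must sum to 1")
        if (np.diff(occ[:, 2]) < -1e-12).any():
            raise ParameterError("dead-state occupancy must be non-decreasing")
        self.occupancy = occ

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        return self.occupancy[:, 0] + self.occupancy[:, 1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        return df


@dataclass
class StrategyOutcome:
    """Discounted and undiscounted totals for one strategy."""

    strategy: str
    discounted_cost: float
    discounted_effect: float
    undiscounted_cost: float
    undiscounted_effect: float
    discounted_alive_years: float
    trace: CohortTrace
    attribution: str = "state"
    scenario: str | None = None

    @property
    def cost_per_alive_year(self) -> float:
        return self.discounted_cost / self.discounted_alive_years

    @property
    def effect_per_alive_year(self) -> float:
        return self.discounted_effect / self.discounted_alive_years


def build_transition_matrix(params: MarkovParameters) -> np.ndarray:
    """Row-stochastic 3x3 matrix over (in_person, telehealth, dead).

    Death first, switching among survivors: P(i -> dead) = m_i,
    P(i -> other live) = s_i (1 - m_i), P(i -> i) takes the remainder so
    each row sums to 1 exactly. Dead is absorbing.
    """
    mat = np.zeros((3, 3))
    for i, (s, m) in enumerate([(params.p_switch_in_to_tele, params.m_in),
                                (params.p_switch_tele_to_in, params.m_tele)]):
        mat[i, 2] = m
        mat[i, 1 - i] = s * (1.0 - m)
        mat[i, i] = 1.0 - mat[i, 2] - mat[i, 1 - i]
    mat[2, 2] = 1.0
    return mat


def run_cohort(params: MarkovParameters, start_state: str) -> CohortTrace:
    """Advance a cohort starting 100% in ``start_state`` over the horizon."""
    if start_state not in STATES[:2]:
        raise ParameterError(f"start_state must be a live state, got {start_state!r}")
    mat = build_transition_matrix(params)
    occ = np.zeros((params.horizon + 1, 3))
    occ[0, STATES.index(start_state)] = 1.0
    for t in range(params.horizon):
        occ[t + 1] = occ[t] @ mat
    return CohortTrace(occ)


def accrue(trace: CohortTrace, params: MarkovParameters, strategy: str | None = None,
           attribution: Literal["state", "strategy"] = "state") -> StrategyOutcome:
    """Sum per-cycle discounted rewards over a trace.

    For cycle t = 0..horizon-1 the states occupied at cycle start earn one
    cycle of reward, discounted by (1 + r)^-t; with the half-cycle
    correction the mean of occupancies at t and t+1 earns the reward at
    discount (1 + r)^-(t + 1/2). Dead earns nothing.
    """
    if trace.horizon != params.horizon:
        raise ParameterError(
            f"trace horizon {trace.horizon} does not match params horizon {params.horizon}")
    if attribution not in ("state", "strategy"):
        raise ParameterError("attribution must be 'state' or 'strategy'")
    if attribution == "strategy" and strategy not in STRATEGIES:
        raise ParameterError("strategy attribution requires a valid strategy name")
    if strategy is not None and strategy not in STRATEGIES:
        raise ParameterError(f"unknown strategy {strategy!r}")

    occ = trace.occupancy
    if params.half_cycle_correction:
        exposure = 0.5 * (occ[:-1] + occ[1:])            # (horizon, 3)
        times = np.arange(params.horizon) + 0.5
    else:
        exposure = occ[:-1]
        times = np.arange(params.horizon, dtype=float)
    disc = (1.0 + params.discount_rate) ** -times

    if attribution == "state":
        cost_vec = np.array([params.state_cost("in_person"), params.state_cost("telehealth"), 0.0])
        eff_vec = np.array([params.state_effect("in_person"), params.state_effect("telehealth"), 0.0])
        cost_per_cycle = exposure @ cost_vec
        eff_per_cycle = exposure @ eff_vec
    else:
        modality = _STRATEGY_MODALITY[strategy]
        alive = exposure[:, 0] + exposure[:, 1]
        cost_per_cycle = alive * params.state_cost(modality)
        eff_per_cycle = alive * params.state_effect(modality)

    alive_exposure = exposure[:, 0] + exposure[:, 1]
    return StrategyOutcome(
        strategy=strategy or "unspecified",
        discounted_cost=float(disc @ cost_per_cycle),
        discounted_effect=float(disc @ eff_per_cycle),
        undiscounted_cost=float(cost_per_cycle.sum()),
        undiscounted_effect=float(eff_per_cycle.sum()),
        discounted_alive_years=float(disc @ alive_exposure),
        trace=trace,
        attribution=attribution,
        scenario=params.label,
    )


def run_strategy(params: MarkovParameters, strategy: str,
                 attribution: Literal["state", "strategy"] = "state") -> StrategyOutcome:
    """Run the cohort for a strategy (its starting state) and accrue rewards."""
    if strategy not in STRATEGIES:
        raise ParameterError(f"strategy must be one of {STRATEGIES}")
    trace = run_cohort(params, _STRATEGY_MODALITY[strategy])
    return accrue(trace, params, strategy=strategy, attribution=attribution)


def annuity_factor(rate: float, cycles: int) -> float:
    """Sum_{t=0}^{cycles-1} (1 + rate)^-t, the no-event discounted exposure."""
    return float(sum((1.0 + rate) ** -t for t in range(cycles)))
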