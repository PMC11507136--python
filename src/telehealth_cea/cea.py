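"""Incremental cost-effectiveness analysis of telehealth vs. in-person care.

Differences are always telehealth minus in-person. Two ratio conventions
are emitted side by side:

* ``icer_standard`` — the textbook delta-cost over delta-effect;
* ``icer_reported`` — the sign convention of the source results
  (= -icer_standard), under which a negative value reads "cost saving with
  telehealth" per modified ZBI-12 point.

The headline scenario comparison is made *per discounted alive
person-year*: each strategy's discounted totals are normalized by its
discounted alive-time before differencing. With strategy-attributed
rewards this reduces exactly to the per-cycle incremental ratio
-(c_te - c_in)/(e_te - e_in), which is the only construction consistent
with the published scenario ICERs (the trace-total ratio under either
reward attribution is far from them; it is still computed and logged as a
secondary result).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .markov import MarkovParameters, StrategyOutcome, run_strategy

logger = logging.getLogger(__name__)

#: Below this absolute incremental effect (point-years) the ratio is
#: declared undefined rather than reported as floating-point noise.
ZERO_EFFECT_THRESHOLD = 1e-9

DOMINANCE_LABELS = ("telehealth_dominates", "in_person_dominates",
                    "tradeoff_NE", "tradeoff_SW", "undefined")


@dataclass
class CEAResult:
    delta_cost: float
    delta_effect: float
    icer_standard: float
    icer_reported: float
    icer_defined: bool
    dominance: str
    scenario: str | None = None
    per_alive_year: bool = False


def _dominance(delta_cost: float, delta_effect: float) -> str:
    if delta_cost == 0.0 and delta_effect == 0.0:
        return "undefined"
    if delta_cost <= 0.0 and delta_effect >= 0.0:
        return "telehealth_dominates"
    if delta_cost >= 0.0 and delta_effect <= 0.0:
        return "in_person_dominates"
    if delta_cost > 0.0 and delta_effect > 0.0:
        return "tradeoff_NE"
    return "tradeoff_SW"


def compute_icer(outcome_tele: StrategyOutcome, outcome_in: StrategyOutcome,
                 per_alive_year: bool = False) -> CEAResult:
    """Incremental comparison of the two strategies of one scenario.

    With ``per_alive_year`` the comparison uses cost and effect per
    discounted alive person-year instead of cohort totals.
    """
    if outcome_tele.trace.horizon != outcome_in.trace.horizon:
        raise ParameterError("outcomes come from different horizons")
    if outcome_tele.attribution != outcome_in.attribution:
        raise ParameterError("outcomes use different reward attributions")
    if outcome_tele.scenario != outcome_in.scenario:
        raise ParameterError("outcomes come from different scenarios")

    if per_alive_year:
        dc = outcome_tele.cost_per_alive_year - outcome_in.cost_per_alive_year
        de = outcome_tele.effect_per_alive_year - outcome_in.effect_per_alive_year
    else:
        dc = outcome_tele.discounted_cost - outcome_in.discounted_cost
        de = outcome_tele.discounted_effect - outcome_in.discounted_effect

    defined = abs(de) >= ZERO_EFFECT_THRESHOLD
    if defined:
        icer = dc / de
        reported = -icer
    else:
        icer = float("nan")
        reported = float("nan")
    return CEAResult(
        delta_cost=dc,
        delta_effect=de,
        icer_standard=icer,
        icer_reported=reported,
        icer_defined=defined,
        dominance=_dominance(dc, de),
        scenario=outcome_tele.scenario,
        per_alive_year=per_alive_year,
    )


@dataclass
class ScenarioEvaluation:
    """Both strategies of one scenario plus the two ICER readings."""

    params: MarkovParameters
    outcome_in: StrategyOutcome
    outcome_tele: StrategyOutcome
    result: CEAResult            # headline: per-alive-year, strategy-attributed
    result_trace_totals: CEAResult  # secondary: trace totals, state-attributed


def evaluate_scenario(params: MarkovParameters) -> ScenarioEvaluation:
    """Run both strategies and compute headline and trace-total ICERs."""
    out_in_s = run_strategy(params, "in_person_start", attribution="strategy")
    out_te_s = run_strategy(params, "telehealth_start", attribution="strategy")
    headline = compute_icer(out_te_s, out_in_s, per_alive_year=True)

    out_in_t = run_strategy(params, "in_person_start", attribution="state")
    out_te_t = run_strategy(params, "telehealth_start", attribution="state")
    secondary = compute_icer(out_te_t, out_in_t, per_alive_year=False)
    logger.debug("scenario %s: headline ICER (reported) %.4f, trace-total ICER (reported) %.4f",
                 params.label, headline.icer_reported, secondary.icer_reported)
    return ScenarioEvaluation(params, out_in_s, out_te_s, headline, secondary)


def reproduce_paper_models(models: Mapping[str, MarkovParameters] | None = None,
                           reference_icers: Mapping[str, float] | None = None,
                           ) -> tuple[pd.DataFrame, dict[str, ScenarioEvaluation]]:
    """Evaluate the packaged scenarios and lay the results out table-style.

    Returns a results table with one row per delivery type per model
    (transition probability, mortality, utilization rates, unit costs,
    annual delivery cost, effectiveness, and the reported ICER on the
    telehealth row) plus the full evaluations. When reference ICERs are
    supplied, deviations are logged, never corrected.
    """
    from . import fixtures  # deferred: fixtures imports this module's types

    if models is None:
        models = fixtures.MODELS
    if reference_icers is None:
        reference_icers = fixtures.PUBLISHED_ICERS

    rows = []
    evaluations: dict[str, ScenarioEvaluation] = {}
    for name, params in models.items():
        ev = evaluate_scenario(params)
        evaluations[name] = ev
        for delivery, switch, mort, ed, hosp, cdel, eff in (
            ("in_person", params.p_switch_in_to_tele, params.m_in,
             params.ed_rate_in, params.hosp_rate_in, params.c_delivery_in, params.e_in),
            ("telehealth", params.p_switch_tele_to_in, params.m_tele,
             params.ed_rate_tele, params.hosp_rate_tele, params.c_delivery_tele, params.e_tele),
        ):
            rows.append({
                "model": name,
                "delivery_type": delivery,
                "transition_to_other_pct_per_year": 100.0 * switch,
                "mortality_pct_per_year": 100.0 * mort,
                "ed_visits_per_year": ed,
                "hospitalizations_per_year": hosp,
                "ed_cost_usd_per_event": params.c_ed,
                "hosp_cost_usd_per_event": params.c_hosp,
                "incremental_cost_usd_per_year": cdel,
                "modified_zbi12_mean": eff,
                "icer_reported_usd_per_point": (
                    ev.result.icer_reported if delivery == "telehealth" else float("nan")),
            })
        ref = (reference_icers or {}).get(name)
        if ref is not None:
            dev = ev.result.icer_reported - ref
            logger.info("%s: reported ICER %.3f vs reference %.2f (deviation %+.3f, %+.2f%%)",
                        name, ev.result.icer_reported, ref, dev, 100.0 * dev / abs(ref))
    return pd.DataFrame(rows), evaluations


def one_way_sensitivity(params: MarkovParameters, parameter_name: str,
                        low: float, high: float, steps: int) -> pd.DataFrame:
    """Re-evaluate the scenario over a grid of one parameter, all else fixed."""
    if not hasattr(params, parameter_name) or parameter_name in ("label",):
        raise ParameterError(f"unknown parameter {parameter_name!r}")
    if low > high:
        raise ParameterError("low must not exceed high")
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    grid = np.linspace(low, high, steps)
    cast = type(getattr(params, parameter_name))  # keep int fields (e.g. horizon) int
    rows = []
    for value in grid:
        trial = replace(params, **{parameter_name: cast(value)})
        ev = evaluate_scenario(trial)
        rows.append({
            "parameter": parameter_name,
            "value": float(value),
            "delta_cost": ev.result.delta_cost,
            "delta_effect": ev.result.delta_effect,
            "icer_reported": ev.result.icer_reported,
            "dominance": ev.result.dominance,
        })
    return pd.DataFrame(rows)
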