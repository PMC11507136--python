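"""Estimation of Markov model inputs from person-level records.

Turns person-year observation records and discharge abstracts into the
inputs the cohort model consumes: annual transition and mortality
probabilities (with Wilson 95% intervals), ED/hospitalization rates,
per-event costs standardized over age x gender cells, annual delivery-mode
costs (telehealth training labor vs. travel + caregiver productivity
loss), inflation adjustment to a common price year, and the caregiver
burden effectiveness measure (ZBI-12 rescaled from the raw 0-48 burden
scale to a 0-100 "lower burden is better" scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConfigurationError, EstimationError, ParameterError
from .synthetic import MODALITIES

logger = logging.getLogger(__name__)

AGE_BANDS = ("<=79", "80+")
WEIGHT_GENDERS = ("male", "female")


@dataclass
class CostingWeights:
    """Fixed population shares over (age_band, gender) cells for direct standardization."""

    weights: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        w = {(str(a), str(g)): float(v) for (a, g), v in dict(self.weights).items()}
        if any(v < 0 for v in w.values()):
            raise ParameterError("weights must be nonnegative")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(f"weights sum to {total:.6f}, not 1")
        self.weights = w

    @classmethod
    def from_marginals(cls, p_age_le79: float, p_male: float) -> "CostingWeights":
        """Joint cell weights as the product of age and gender marginals."""
        w = {}
        for band, pa in ((AGE_BANDS[0], p_age_le79), (AGE_BANDS[1], 1.0 - p_age_le79)):
            for gender, pg in (("male", p_male), ("female", 1.0 - p_male)):
                w[(band, gender)] = pa * pg
        return cls(w)


@dataclass
class DeliveryCostInputs:
    """Ingredients of the annual per-person delivery-mode costs."""

    trainer_wage: float                  # USD/hour
    training_hours_per_conversion: float
    conversion_probability: float        # in-person -> telehealth, per year
    roundtrip_drive_time: float          # minutes
    in_person_visit_time: float          # minutes
    telehealth_visit_time: float         # minutes
    wage_rate: float                     # USD/hour, caregiver opportunity cost
    distance_roundtrip: float            # miles
    mileage_rate: float                  # USD/mile
    visits_per_year: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be nonnegative")
        if self.conversion_probability > 1:
            raise ParameterError("conversion_probability must lie in [0, 1]")


@dataclass
class ProbabilityEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    events: int
    person_years: int


@dataclass
class RateEstimate:
    rate: float
    se: float
    events: int
    person_years: int


@dataclass
class EstimatedParameters:
    """All per-scenario model inputs, probabilities as decimals (not percent)."""

    p_switch_in_to_tele: float
    p_switch_tele_to_in: float
    m_in: float
    m_tele: float
    ed_rate_in: float
    ed_rate_tele: float
    hosp_rate_in: float
    hosp_rate_tele: float
    c_ed: float
    c_hosp: float
    c_delivery_in: float
    c_delivery_tele: float
    e_in: float
    e_tele: float

    def __post_init__(self) -> None:
        for name in ("p_switch_in_to_tele", "p_switch_tele_to_in", "m_in", "m_tele"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for name in ("ed_rate_in", "ed_rate_tele", "hosp_rate_in", "hosp_rate_tele",
                     "c_ed", "c_hosp", "c_delivery_in", "c_delivery_tele"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("e_in", "e_tele"):
            if not 0.0 <= getattr(self, name) <= 100.0:
                raise ParameterError(f"{name} must lie in [0, 100]")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({f.name: float(getattr(self, f.name)) for f in fields(self)}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EstimatedParameters":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**{f.name: float(data[f.name]) for f in fields(cls)})


_EVENT_COLUMNS = {"switch": "switched_this_year", "death": "died_this_year"}
_RATE_COLUMNS = {"ed": "ed_visit_count", "hosp": "hospitalization_count"}


def _at_risk(records: pd.DataFrame, modality: str) -> pd.DataFrame:
    if modality not in MODALITIES:
        raise ParameterError(f"unknown modality {modality!r}")
    return records[records["modality_at_start"] == modality]


def estimate_annual_probability(records: pd.DataFrame, event: str, modality: str) -> ProbabilityEstimate:
    """Annual event probability: events / person-years at risk in the modality.

    Person-years at risk are attributed to the modality at the start of the
    year (a switcher's year counts toward the origin modality). Because the
    cohort model applies death first and switching only among survivors,
    the switch probability is estimated conditionally on surviving the
    year: decedents are excluded from the switch denominator. The 95%
    interval is the Wilson score interval.
    """
    if event not in _EVENT_COLUMNS:
        raise ParameterError(f"event must be one of {sorted(_EVENT_COLUMNS)}")
    at_risk = _at_risk(records, modality)
    if event == "switch":
        at_risk = at_risk[~at_risk["died_this_year"].astype(bool)]
    n = len(at_risk)
    if n == 0:
        raise EstimationError(f"no person-years at risk in modality {modality!r}")
    k = int(at_risk[_EVENT_COLUMNS[event]].astype(bool).sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    est = ProbabilityEstimate(k / n, float(lo), float(hi), k, n)
    logger.debug("p(%s | %s) = %.4f [%.4f, %.4f] (%d/%d)",
                 event, modality, est.estimate, est.ci_low, est.ci_high, k, n)
    return est


def estimate_event_rate(records: pd.DataFrame, event: str, modality: str) -> RateEstimate:
    """Mean annual event count: total events / person-years observed."""
    if event not in _RATE_COLUMNS:
        raise ParameterError(f"event must be one of {sorted(_RATE_COLUMNS)}")
    at_risk = _at_risk(records, modality)
    n = len(at_risk)
    if n == 0:
        raise EstimationError(f"no person-years observed in modality {modality!r}")
    total = int(at_risk[_RATE_COLUMNS[event]].sum())
    rate = total / n
    se = math.sqrt(rate / n) if rate > 0 else 0.0  # Poisson SE of the mean
    logger.debug("rate(%s | %s) = %.4f +- %.4f (%d events / %d py)", event, modality, rate, se, total, n)
    return RateEstimate(rate, se, total, n)


def estimate_event_cost(discharges: pd.DataFrame, setting: str, weights: CostingWeights) -> float:
    """Per-event cost, directly standardized over (age_band, gender) cells.

    Each event is priced as its length of stay times the mean daily charge
    of its cell x principal-diagnosis group; cell means over events are then
    combined with the supplied population weights. Weight mass on cells with
    no data is renormalized away with a warning. The "other" gender is
    pooled with the majority gender of the discharge set for weighting.
    """
    sub = discharges[discharges["setting"] == setting].copy()
    if sub.empty:
        raise EstimationError(f"no discharges in setting {setting!r}")

    known = sub["gender"].isin(WEIGHT_GENDERS)
    if (~known).any():
        majority = sub.loc[known, "gender"].mode()
        fill = majority.iloc[0] if not majority.empty else "female"
        sub.loc[~known, "gender"] = fill

    mean_daily = sub.groupby(["age_band", "gender", "principal_dx"])["daily_charge"].transform("mean")
    sub["event_cost"] = sub["los_days"] * mean_daily
    cell_means = sub.groupby(["age_band", "gender"])["event_cost"].mean()

    total_weight = 0.0
    acc = 0.0
    dropped = 0.0
    for cell, w in weights.weights.items():
        if cell in cell_means.index:
            acc += w * float(cell_means.loc[cell])
            total_weight += w
        else:
            dropped += w
    if total_weight == 0:
        raise EstimationError("no discharge falls in any positively weighted cell")
    if dropped > 0:
        logger.warning("renormalizing: weight %.3f lies on cells with no %s discharges",
                       dropped, setting)
    return acc / total_weight


def rescale_zbi(raw):
    """Map a raw ZBI-12 burden score (0-48, higher = more burden) to the
    modified 0-100 effectiveness scale (higher = less burden): 100*(1 - raw/48)."""
    arr = np.asarray(raw, dtype=float)
    if ((arr < 0) | (arr > 48)).any():
        raise ParameterError("raw ZBI-12 scores must lie in [0, 48]")
    out = 100.0 * (1.0 - arr / 48.0)
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def inverse_rescale_zbi(modified):
    """Inverse of :func:`rescale_zbi`: modified 0-100 back to raw 0-48."""
    arr = np.asarray(modified, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ParameterError("modified scores must lie in [0, 100]")
    out = 48.0 * (1.0 - arr / 100.0)
    return float(out) if np.isscalar(modified) or arr.ndim == 0 else out


def time_savings(roundtrip_drive: float, in_person_visit: float, telehealth_visit: float) -> float:
    """Caregiver time saved per telehealth visit, in minutes:
    roundtrip drive time + (in-person visit time - telehealth visit time).
    Negative when the telehealth visit outlasts drive plus in-person visit."""
    for name, v in (("roundtrip_drive", roundtrip_drive),
                    ("in_person_visit", in_person_visit),
                    ("telehealth_visit", telehealth_visit)):
        if v < 0:
            raise ParameterError(f"{name} must be nonnegative")
    return roundtrip_drive + (in_person_visit - telehealth_visit)


def delivery_costs(inputs: DeliveryCostInputs) -> tuple[float, float]:
    """Annual delivery-mode costs (c_delivery_in, c_delivery_tele) in USD/year.

    Telehealth carries the training labor cost (trainer wage x training
    hours x annual conversion probability); in-person carries travel plus
    caregiver productivity loss per visit, scaled by visits per year.
    """
    c_tele = inputs.trainer_wage * inputs.training_hours_per_conversion * inputs.conversion_probability
    saved_hours = time_savings(inputs.roundtrip_drive_time, inputs.in_person_visit_time,
                               inputs.telehealth_visit_time) / 60.0
    c_in = inputs.visits_per_year * (
        inputs.distance_roundtrip * inputs.mileage_rate + saved_hours * inputs.wage_rate
    )
    return c_in, c_tele


def adjust_inflation(cost: float, from_year: int, to_year: int = 2022,
                     rates: Mapping[int, float] | None = None) -> float:
    """Compound a cost from ``from_year`` prices to ``to_year`` prices.

    ``rates`` maps year y to the healthcare inflation rate from y to y+1 and
    must cover every year in [from_year, to_year).
    """
    if from_year > to_year:
        raise ParameterError("from_year must not exceed to_year")
    if from_year == to_year:
        return float(cost)
    rates = rates or {}
    out = float(cost)
    for year in range(from_year, to_year):
        if year not in rates:
            raise ConfigurationError(f"missing inflation rate for {year}")
        out *= 1.0 + rates[year]
    return out


def estimate_all(records: pd.DataFrame, discharges: pd.DataFrame, weights: CostingWeights,
                 delivery_inputs: DeliveryCostInputs, stratum: str | None = None) -> EstimatedParameters:
    """Assemble every model input for one scenario from person-level data."""
    if stratum is not None:
        records = records[records["stratum"] == stratum]
        if records.empty:
            raise EstimationError(f"no person-years in stratum {stratum!r}")
        discharges = discharges[discharges["person_id"].isin(records["person_id"])]
    if records.empty:
        raise EstimationError("no person-year records supplied")

    p_in = estimate_annual_probability(records, "switch", "in_person")
    p_te = estimate_annual_probability(records, "switch", "telehealth")
    m_in = estimate_annual_probability(records, "death", "in_person")
    m_te = estimate_annual_probability(records, "death", "telehealth")
    ed_in = estimate_event_rate(records, "ed", "in_person")
    ed_te = estimate_event_rate(records, "ed", "telehealth")
    ho_in = estimate_event_rate(records, "hosp", "in_person")
    ho_te = estimate_event_rate(records, "hosp", "telehealth")
    c_ed = estimate_event_cost(discharges, "ED", weights)
    c_hosp = estimate_event_cost(discharges, "inpatient", weights)
    c_in, c_tele = delivery_costs(delivery_inputs)

    e_by_mod = {}
    for mod in MODALITIES:
        sub = _at_risk(records, mod)
        if sub.empty:
            raise EstimationError(f"no person-years in modality {mod!r}")
        e_by_mod[mod] = rescale_zbi(float(sub["zbi12_raw"].mean()))

    params = EstimatedParameters(
        p_switch_in_to_tele=p_in.estimate,
        p_switch_tele_to_in=p_te.estimate,
        m_in=m_in.estimate,
        m_tele=m_te.estimate,
        ed_rate_in=ed_in.rate,
        ed_rate_tele=ed_te.rate,
        hosp_rate_in=ho_in.rate,
        hosp_rate_tele=ho_te.rate,
        c_ed=c_ed,
        c_hosp=c_hosp,
        c_delivery_in=c_in,
        c_delivery_tele=c_tele,
        e_in=e_by_mod["in_person"],
        e_tele=e_by_mod["telehealth"],
    )
    logger.info("estimated parameters%s: %s", f" for {stratum}" if stratum else "", params)
    return params
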