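"""Synthetic person-year and hospital-discharge data generator.

The cost-effectiveness pipeline was designed around payor administrative
records (person-level primary-care delivery history) and statewide
ED/inpatient discharge abstracts. Neither source is publicly releasable,
so this module generates records with the same statistical structure:

* a cohort of people living with ADRD, with age/gender/race drawn from a
  demographic profile (age as a truncated normal whose *truncated* moments
  match the profile's mean/SD);
* annual modality switching (in-person <-> telehealth) and death as
  Bernoulli events, death evaluated first and switching among survivors —
  the same within-cycle ordering the Markov engine uses;
* annual ED-visit and hospitalization counts as Poisson draws with
  modality-specific means;
* caregiver burden as integer ZBI-12 raw scores (0-48 scale) from a
  truncated normal;
* one discharge record per counted event, with length of stay, a lognormal
  daily charge, and an ICD-10-CM principal diagnosis drawn from the ADRD
  code family (F01/F02/F03), optionally contaminated with non-ADRD codes
  so the diagnostic filter has something to remove.

All draws flow from a single mandatory seed; a fixed seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

GENDERS = ("male", "female", "other")
RACES = ("nh_white", "nh_black", "hispanic_latino", "nh_asian", "other_mixed")
MODALITIES = ("in_person", "telehealth")

#: ADRD diagnostic code family: vascular dementia, dementia in other
#: diseases, unspecified dementia.
ADRD_PREFIXES = ("F01", "F02", "F03")

# Representative billable sub-codes per family, used for synthetic records.
_ADRD_SUBCODES = {"F01": "F01.50", "F02": "F02.80", "F03": "F03.90"}

# Non-ADRD principal diagnoses for contamination. G30.9 (Alzheimer's
# disease) is deliberately included: it is outside the F01/F02/F03 filter.
_CONTAMINANT_CODES = ("I10", "E11.9", "J18.9", "N39.0", "G30.9", "I50.9")

PERSON_YEAR_COLUMNS = [
    "person_id", "year_index", "stratum", "age", "gender", "race",
    "modality_at_start", "switched_this_year", "died_this_year",
    "ed_visit_count", "hospitalization_count", "zbi12_raw",
]

DISCHARGE_COLUMNS = [
    "record_id", "person_id", "setting", "principal_dx",
    "los_days", "daily_charge", "age_band", "gender",
]


def _check_probs(name: str, probs: Mapping[str, float], keys: tuple[str, ...]) -> dict[str, float]:
    probs = dict(probs)
    if set(probs) - set(keys):
        raise ParameterError(f"{name}: unknown categories {set(probs) - set(keys)}")
    vals = np.array([probs.get(k, 0.0) for k in keys], dtype=float)
    if (vals < 0).any() or vals.max() > 1:
        raise ParameterError(f"{name}: probabilities must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ParameterError(f"{name}: probabilities sum to {vals.sum():.6f}, not 1")
    return {k: float(v) for k, v in zip(keys, vals)}


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name}={value} outside [0, 1]")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        raise ParameterError(f"{name}={value} must be nonnegative")
    return float(value)


@dataclass
class DemographicProfile:
    """Age/gender/race distribution of one cohort stratum."""

    stratum: str
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    gender_probs: Mapping[str, float]
    race_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ParameterError("age_min must not exceed age_max")
        if self.age_sd <= 0:
            raise ParameterError("age_sd must be positive")
        self.gender_probs = _check_probs("gender_probs", self.gender_probs, GENDERS)
        self.race_probs = _check_probs("race_probs", self.race_probs, RACES)


@dataclass
class GenerationConfig:
    """Stochastic settings for one synthetic-cohort run.

    ``p_switch``, ``p_death``, ``ed_mean``, ``hosp_mean`` and
    ``zbi_raw_mean`` are per-modality mappings keyed by ``in_person`` /
    ``telehealth``; burden differs by delivery mode in the source tables,
    so the generator carries a modality-specific burden mean.
    """

    n_persons: int
    seed: int
    n_years: int = 1
    p_switch: Mapping[str, float] = field(default_factory=lambda: {"in_person": 0.0, "telehealth": 0.0})
    p_death: Mapping[str, float] = field(default_factory=lambda: {"in_person": 0.0, "telehealth": 0.0})
    ed_mean: Mapping[str, float] = field(default_factory=lambda: {"in_person": 0.0, "telehealth": 0.0})
    hosp_mean: Mapping[str, float] = field(default_factory=lambda: {"in_person": 0.0, "telehealth": 0.0})
    zbi_raw_mean: Mapping[str, float] = field(default_factory=lambda: {"in_person": 24.0, "telehealth": 24.0})
    zbi_raw_sd: float = 8.0
    los_mean: float = 5.0
    daily_charge_mean: float = 6000.0
    daily_charge_sd: float = 1800.0
    adrd_code_probs: Mapping[str, float] = field(default_factory=lambda: {"F01": 0.20, "F02": 0.15, "F03": 0.65})
    contamination_frac: float = 0.0
    p_start_telehealth: float = 0.5

    def __post_init__(self) -> None:
        if self.n_persons < 0:
            raise ParameterError("n_persons must be >= 0")
        if self.n_years < 1:
            raise ParameterError("n_years must be >= 1")
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        for name in ("p_switch", "p_death"):
            mapping = dict(getattr(self, name))
            for mod in MODALITIES:
                _check_prob(f"{name}[{mod}]", mapping.get(mod, 0.0))
            setattr(self, name, {m: float(mapping.get(m, 0.0)) for m in MODALITIES})
        for name in ("ed_mean", "hosp_mean"):
            mapping = dict(getattr(self, name))
            for mod in MODALITIES:
                _check_nonneg(f"{name}[{mod}]", mapping.get(mod, 0.0))
            setattr(self, name, {m: float(mapping.get(m, 0.0)) for m in MODALITIES})
        zbi = dict(self.zbi_raw_mean)
        for mod in MODALITIES:
            if not 0.0 <= zbi.get(mod, 24.0) <= 48.0:
                raise ParameterError(f"zbi_raw_mean[{mod}] must lie in [0, 48]")
        self.zbi_raw_mean = {m: float(zbi.get(m, 24.0)) for m in MODALITIES}
        _check_nonneg("zbi_raw_sd", self.zbi_raw_sd)
        if self.los_mean < 1:
            raise ParameterError("los_mean must be >= 1 day")
        if self.daily_charge_mean <= 0:
            raise ParameterError("daily_charge_mean must be positive")
        _check_nonneg("daily_charge_sd", self.daily_charge_sd)
        self.adrd_code_probs = _check_probs("adrd_code_probs", self.adrd_code_probs, ADRD_PREFIXES)
        if not 0.0 <= self.contamination_frac < 1.0:
            raise ParameterError("contamination_frac must lie in [0, 1)")
        _check_prob("p_start_telehealth", self.p_start_telehealth)


@lru_cache(maxsize=64)
def matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated normal whose truncated moments are (mean, sd).

    Published cohort summaries describe the observed (range-limited) ages,
    so the sampler matches the truncated distribution's moments rather than
    naively truncating N(mean, sd). Solved by least squares; when the target
    pair is outside the truncated-normal family's reachable set (possible
    for tight ranges), the closest attainable pair is used and a warning is
    logged.
    """

    def residual(x: np.ndarray) -> list[float]:
        mu, sigma = x[0], math.exp(x[1])
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(residual, [mean, math.log(sd)], xtol=1e-13, ftol=1e-13)
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    err = residual(sol.x)
    if max(abs(e) for e in err) > 0.05:
        logger.warning(
            "truncated normal cannot attain mean=%.2f sd=%.2f on [%.1f, %.1f]; "
            "closest fit deviates by (%.2f, %.2f)", mean, sd, lo, hi, err[0], err[1]
        )
    return mu, sigma


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    mu, sigma = matched_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _sample_zbi_raw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Integer ZBI-12 raw scores from a moment-matched normal truncated to [0, 48]."""
    if sd == 0:
        return np.full(size, round(mean))
    raw = _sample_truncnorm(rng, mean, sd, 0.0, 48.0, size)
    return np.clip(np.rint(raw), 0, 48).astype(int)


def generate_cohort(profile: DemographicProfile, config: GenerationConfig) -> pd.DataFrame:
    """Simulate ``n_persons`` forward for up to ``n_years`` person-years.

    Within each year, death is evaluated first and modality switching only
    among survivors; ED/hospitalization counts accrue regardless of
    same-year death (events can precede death within the year). A person
    contributes no further rows after the year they die.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    ages0 = _sample_truncnorm(rng, profile.age_mean, profile.age_sd,
                              profile.age_min, profile.age_max, n)
    genders = rng.choice(GENDERS, size=n, p=[profile.gender_probs[g] for g in GENDERS])
    races = rng.choice(RACES, size=n, p=[profile.race_probs[r] for r in RACES])
    modality = np.where(rng.random(n) < config.p_start_telehealth, "telehealth", "in_person")

    rows: list[dict] = []
    alive = np.ones(n, dtype=bool)
    for year in range(config.n_years):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        mods = modality[idx]
        p_death = np.array([config.p_death[m] for m in mods])
        p_switch = np.array([config.p_switch[m] for m in mods])
        ed_mu = np.array([config.ed_mean[m] for m in mods])
        hosp_mu = np.array([config.hosp_mean[m] for m in mods])

        died = rng.random(idx.size) < p_death
        switched = (rng.random(idx.size) < p_switch) & ~died
        ed_counts = rng.poisson(ed_mu)
        hosp_counts = rng.poisson(hosp_mu)
        zbi = np.empty(idx.size, dtype=int)
        for mod in MODALITIES:
            sel = mods == mod
            if sel.any():
                zbi[sel] = _sample_zbi_raw(rng, config.zbi_raw_mean[mod], config.zbi_raw_sd,
                                           int(sel.sum()))

        for j, i in enumerate(idx):
            rows.append({
                "person_id": int(i),
                "year_index": year,
                "stratum": profile.stratum,
                "age": float(ages0[i] + year),
                "gender": genders[i],
                "race": races[i],
                "modality_at_start": mods[j],
                "switched_this_year": bool(switched[j]),
                "died_this_year": bool(died[j]),
                "ed_visit_count": int(ed_counts[j]),
                "hospitalization_count": int(hosp_counts[j]),
                "zbi12_raw": int(zbi[j]),
            })
        alive[idx[died]] = False
        flip = idx[switched]
        modality[flip] = np.where(modality[flip] == "telehealth", "in_person", "telehealth")

    df = pd.DataFrame(rows, columns=PERSON_YEAR_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=PERSON_YEAR_COLUMNS)
    return df


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (mu, sigma) of a lognormal with the given mean/SD."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def age_band(age: float) -> str:
    """Two-band age split used for cost standardization: <=79 vs 80+."""
    return "<=79" if age <= 79 else "80+"


def generate_discharges(person_years: pd.DataFrame, config: GenerationConfig) -> pd.DataFrame:
    """One discharge record per counted ED visit / hospitalization.

    ED discharges have a 1-day stay (priced per event); inpatient stays are
    1 + Poisson(los_mean - 1) days. Daily charges are lognormal (hospital
    charges are right-skewed). A ``contamination_frac`` share of records
    receives non-ADRD principal diagnoses.
    """
    if person_years.empty:
        return pd.DataFrame(columns=DISCHARGE_COLUMNS)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    mu, sigma = _lognormal_params(config.daily_charge_mean, config.daily_charge_sd)

    settings, persons, ages, genders = [], [], [], []
    for row in person_years.itertuples(index=False):
        for _ in range(int(row.ed_visit_count)):
            settings.append("ED")
            persons.append(row.person_id)
            ages.append(row.age)
            genders.append(row.gender)
        for _ in range(int(row.hospitalization_count)):
            settings.append("inpatient")
            persons.append(row.person_id)
            ages.append(row.age)
            genders.append(row.gender)
    n = len(settings)
    if n == 0:
        return pd.DataFrame(columns=DISCHARGE_COLUMNS)

    settings_arr = np.array(settings)
    los = np.ones(n, dtype=int)
    inpat = settings_arr == "inpatient"
    los[inpat] = 1 + rng.poisson(max(config.los_mean - 1.0, 0.0), size=int(inpat.sum()))

    charges = rng.lognormal(mu, sigma, size=n) if sigma > 0 else np.full(n, config.daily_charge_mean)

    families = rng.choice(ADRD_PREFIXES, size=n,
                          p=[config.adrd_code_probs[k] for k in ADRD_PREFIXES])
    codes = np.array([_ADRD_SUBCODES[f] for f in families], dtype=object)
    contaminated = rng.random(n) < config.contamination_frac
    if contaminated.any():
        codes[contaminated] = rng.choice(_CONTAMINANT_CODES, size=int(contaminated.sum()))

    return pd.DataFrame({
        "record_id": np.arange(n),
        "person_id": persons,
        "setting": settings_arr,
        "principal_dx": codes,
        "los_days": los,
        "daily_charge": np.round(charges, 2),
        "age_band": [age_band(a) for a in ages],
        "gender": genders,
    }, columns=DISCHARGE_COLUMNS)


def select_adrd_records(records: pd.DataFrame, code_column: str = "principal_dx") -> pd.DataFrame:
    """Keep records whose principal diagnosis is in the ADRD family.

    A code qualifies when, after trimming whitespace, it case-insensitively
    starts with F01, F02 or F03 (any sub-code digits allowed). Malformed or
    empty codes are dropped and logged, never fatal.
    """
    if code_column not in records.columns:
        raise ParameterError(f"records lack a {code_column!r} column")
    codes = records[code_column]
    valid = codes.map(lambda c: isinstance(c, str) and c.strip() != "")
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("dropping %d records with malformed or empty %s", n_bad, code_column)
    trimmed = codes.where(valid, "").astype(str).str.strip().str.upper()
    keep = valid & trimmed.str.startswith(ADRD_PREFIXES)
    return records.loc[keep].copy()


def sample_size(confidence: float, margin: float, population: int) -> int:
    """Required sample size for a proportion, with finite-population correction.

    Uses the conservative p=0.5 variance: n0 = z^2 * 0.25 / margin^2 with z
    the two-sided normal quantile, corrected as n0 / (1 + (n0-1)/N) and
    rounded up.
    """
    if not 0.0 < confidence < 1.0:
        raise ParameterError("confidence must lie in (0, 1)")
    if not 0.0 < margin < 1.0:
        raise ParameterError("margin must lie in (0, 1)")
    if population < 1:
        raise ParameterError("population must be >= 1")
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    n0 = z * z * 0.25 / (margin * margin)
    corrected = n0 / (1.0 + (n0 - 1.0) / population)
    return max(1, math.ceil(corrected))
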