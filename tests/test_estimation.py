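"""Parameter estimation: probabilities, rates, costs, burden rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telehealth_cea import fixtures
from telehealth_cea.estimation import (
    CostingWeights,
    DeliveryCostInputs,
    adjust_inflation,
    delivery_costs,
    estimate_all,
    estimate_annual_probability,
    estimate_event_cost,
    estimate_event_rate,
    inverse_rescale_zbi,
    rescale_zbi,
    time_savings,
)
from telehealth_cea.exceptions import ConfigurationError, EstimationError, ParameterError
from telehealth_cea.synthetic import generate_cohort, generate_discharges


def _person_years(modality, switched, died, ed=None, hosp=None, zbi=None):
    n = len(modality)
    return pd.DataFrame({
        "person_id": range(n),
        "year_index": 0,
        "stratum": "urban",
        "age": 80.0,
        "gender": "female",
        "race": "nh_white",
        "modality_at_start": modality,
        "switched_this_year": switched,
        "died_this_year": died,
        "ed_visit_count": ed if ed is not None else [0] * n,
        "hospitalization_count": hosp if hosp is not None else [0] * n,
        "zbi12_raw": zbi if zbi is not None else [24] * n,
    })


class TestAnnualProbability:
    def test_direct_count_ratio(self):
        df = _person_years(["telehealth"] * 50, [True] * 8 + [False] * 42, [False] * 50)
        est = estimate_annual_probability(df, "switch", "telehealth")
        assert est.estimate == pytest.approx(0.16)
        assert est.ci_low < 0.16 < est.ci_high

    def test_no_events_gives_zero(self):
        df = _person_years(["in_person"] * 10, [False] * 10, [False] * 10)
        assert estimate_annual_probability(df, "death", "in_person").estimate == 0.0

    def test_switch_denominator_excludes_decedents(self):
        df = _person_years(["telehealth"] * 10, [True] * 2 + [False] * 8,
                           [False] * 5 + [True] * 5)
        est = estimate_annual_probability(df, "switch", "telehealth")
        assert est.person_years == 5
        assert est.estimate == pytest.approx(2 / 5)

    def test_zero_person_years_is_an_error(self):
        df = _person_years(["in_person"] * 3, [False] * 3, [False] * 3)
        with pytest.raises(EstimationError):
            estimate_annual_probability(df, "death", "telehealth")


class TestEventRate:
    def test_arithmetic_mean(self):
        df = _person_years(["in_person"] * 4, [False] * 4, [False] * 4, ed=[0, 1, 2, 3])
        assert estimate_event_rate(df, "ed", "in_person").rate == pytest.approx(1.5)

    def test_all_zero_counts(self):
        df = _person_years(["in_person"] * 4, [False] * 4, [False] * 4)
        assert estimate_event_rate(df, "hosp", "in_person").rate == 0.0


def _discharges(rows):
    return pd.DataFrame(rows, columns=["record_id", "person_id", "setting", "principal_dx",
                                       "los_days", "daily_charge", "age_band", "gender"])


class TestEventCost:
    def test_single_cell_hand_arithmetic(self):
        dis = _discharges([
            (0, 0, "inpatient", "F03.90", 2, 500.0, "80+", "female"),
            (1, 1, "inpatient", "F03.90", 4, 500.0, "80+", "female"),
        ])
        weights = CostingWeights({("80+", "female"): 1.0})
        assert estimate_event_cost(dis, "inpatient", weights) == pytest.approx(1500.0)

    def test_two_cells_midpoint(self):
        dis = _discharges([
            (0, 0, "inpatient", "F03.90", 2, 500.0, "<=79", "male"),
            (1, 1, "inpatient", "F03.90", 6, 500.0, "80+", "female"),
        ])
        weights = CostingWeights({("<=79", "male"): 0.5, ("80+", "female"): 0.5})
        assert estimate_event_cost(dis, "inpatient", weights) == pytest.approx(2000.0)

    def test_degenerate_weights_equal_cell_mean(self):
        dis = _discharges([
            (0, 0, "ED", "F01.50", 1, 800.0, "80+", "male"),
            (1, 1, "ED", "F01.50", 1, 1200.0, "80+", "male"),
            (2, 2, "ED", "F02.80", 1, 999.0, "<=79", "female"),
        ])
        weights = CostingWeights({("80+", "male"): 1.0, ("<=79", "female"): 0.0})
        assert estimate_event_cost(dis, "ED", weights) == pytest.approx(1000.0)

    def test_weight_on_empty_cell_renormalized(self, caplog):
        dis = _discharges([(0, 0, "ED", "F01.50", 1, 700.0, "80+", "male")])
        weights = CostingWeights({("80+", "male"): 0.6, ("<=79", "female"): 0.4})
        with caplog.at_level("WARNING"):
            cost = estimate_event_cost(dis, "ED", weights)
        assert cost == pytest.approx(700.0)
        assert any("renormalizing" in r.message for r in caplog.records)

    def test_order_and_batching_invariance(self):
        rng = np.random.default_rng(5)
        rows = [(i, i, "inpatient", rng.choice(["F01.50", "F03.90"]),
                 int(rng.integers(1, 10)), float(rng.uniform(300, 900)),
                 rng.choice(["<=79", "80+"]), rng.choice(["male", "female"]))
                for i in range(60)]
        dis = _discharges(rows)
        weights = CostingWeights.from_marginals(0.4, 0.45)
        base = estimate_event_cost(dis, "inpatient", weights)
        shuffled = dis.sample(frac=1.0, random_state=1)
        assert estimate_event_cost(shuffled, "inpatient", weights) == pytest.approx(base)

    def test_no_discharges_in_setting_is_an_error(self):
        dis = _discharges([(0, 0, "ED", "F01.50", 1, 700.0, "80+", "male")])
        with pytest.raises(EstimationError):
            estimate_event_cost(dis, "inpatient", CostingWeights({("80+", "male"): 1.0}))


class TestZbiRescale:
    @pytest.mark.parametrize("raw,expected", [(0, 100.0), (48, 0.0), (24, 50.0)])
    def test_endpoints_and_midpoint(self, raw, expected):
        assert rescale_zbi(raw) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=48, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_bijection_roundtrip(self, raw):
        assert inverse_rescale_zbi(rescale_zbi(raw)) == pytest.approx(raw, abs=1e-9)

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 48, 97)
        assert (np.diff(rescale_zbi(grid)) < 0).all()

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            rescale_zbi(-1)
        with pytest.raises(ParameterError):
            rescale_zbi(48.5)


class TestDeliveryCosts:
    def test_time_savings_formula(self):
        assert time_savings(60, 30, 15) == 75
        assert time_savings(0, 20, 20) == 0
        assert time_savings(0, 10, 40) == -30
        with pytest.raises(ParameterError):
            time_savings(-1, 10, 10)

    def _inputs(self, **kw):
        base = dict(trainer_wage=50.0, training_hours_per_conversion=4.0,
                    conversion_probability=1.0, roundtrip_drive_time=60.0,
                    in_person_visit_time=30.0, telehealth_visit_time=15.0,
                    wage_rate=20.0, distance_roundtrip=10.0, mileage_rate=0.5,
                    visits_per_year=4.0)
        base.update(kw)
        return DeliveryCostInputs(**base)

    def test_training_cost_hand_arithmetic(self):
        _, c_tele = delivery_costs(self._inputs())
        assert c_tele == pytest.approx(200.0)

    def test_zero_conversion_and_zero_visits(self):
        assert delivery_costs(self._inputs(conversion_probability=0.0))[1] == 0.0
        assert delivery_costs(self._inputs(visits_per_year=0.0))[0] == 0.0

    def test_in_person_cost_hand_arithmetic(self):
        c_in, _ = delivery_costs(self._inputs())
        # 4 * (10 * 0.5 + (75/60) * 20) = 4 * (5 + 25) = 120
        assert c_in == pytest.approx(120.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=25)
    def test_homogeneous_in_wage_and_mileage_rates(self, scale):
        base_in, base_tele = delivery_costs(self._inputs())
        scaled_in, scaled_tele = delivery_costs(self._inputs(
            trainer_wage=50.0 * scale, wage_rate=20.0 * scale, mileage_rate=0.5 * scale))
        assert scaled_in == pytest.approx(scale * base_in)
        assert scaled_tele == pytest.approx(scale * base_tele)


class TestInflation:
    def test_identity_same_year(self):
        assert adjust_inflation(100.0, 2022, 2022) == 100.0

    def test_single_and_compound_steps(self):
        assert adjust_inflation(100.0, 2021, 2022, {2021: 0.05}) == pytest.approx(105.0)
        assert adjust_inflation(100.0, 2020, 2022, {2020: 0.03, 2021: 0.04}) == pytest.approx(107.12)

    def test_missing_rate_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            adjust_inflation(100.0, 2020, 2022, {2020: 0.03})


@pytest.fixture(scope="module")
def generated():
    cfg = fixtures.generation_config("model_a", n_persons=5000, seed=31)
    cohort = generate_cohort(fixtures.URBAN_PROFILE, cfg)
    discharges = generate_discharges(cohort, cfg)
    return cfg, cohort, discharges


class TestEstimateAll:
    def test_recovers_generator_settings_within_three_se(self, generated, model_a):
        cfg, cohort, discharges = generated
        est = estimate_all(cohort, discharges, fixtures.URBAN_WEIGHTS,
                           fixtures.DELIVERY_INPUTS_DEFAULT)
        checks = [
            (est.p_switch_tele_to_in, model_a.p_switch_tele_to_in, "switch", "telehealth"),
            (est.p_switch_in_to_tele, model_a.p_switch_in_to_tele, "switch", "in_person"),
            (est.m_tele, model_a.m_tele, "death", "telehealth"),
            (est.m_in, model_a.m_in, "death", "in_person"),
        ]
        for got, target, event, modality in checks:
            n = estimate_annual_probability(cohort, event, modality).person_years
            se = np.sqrt(target * (1 - target) / n)
            assert abs(got - target) < 3 * se, (event, modality)
        for got, target, event, modality in [
            (est.ed_rate_tele, model_a.ed_rate_tele, "ed", "telehealth"),
            (est.hosp_rate_in, model_a.hosp_rate_in, "hosp", "in_person"),
        ]:
            n = estimate_event_rate(cohort, event, modality).person_years
            assert abs(got - target) < 3 * np.sqrt(target / n), (event, modality)
        # burden means on the modified 0-100 scale; raw SD is the generator's 8 points
        for got, target, modality in [(est.e_in, model_a.e_in, "in_person"),
                                      (est.e_tele, model_a.e_tele, "telehealth")]:
            n = (cohort.modality_at_start == modality).sum()
            se_modified = (100.0 / 48.0) * 8.0 / np.sqrt(n)
            assert abs(got - target) < 3 * se_modified, modality

    def test_split_half_estimates_agree(self, generated):
        _, cohort, discharges = generated
        half = cohort.person_id < cohort.person_id.median()
        d_half = discharges.person_id < cohort.person_id.median()
        a = estimate_all(cohort[half], discharges[d_half], fixtures.URBAN_WEIGHTS,
                         fixtures.DELIVERY_INPUTS_DEFAULT)
        b = estimate_all(cohort[~half], discharges[~d_half], fixtures.URBAN_WEIGHTS,
                         fixtures.DELIVERY_INPUTS_DEFAULT)
        # joint 3-SE agreement on the headline probability
        pa = estimate_annual_probability(cohort[half], "switch", "telehealth")
        pb = estimate_annual_probability(cohort[~half], "switch", "telehealth")
        se = np.sqrt(pa.estimate * (1 - pa.estimate) / pa.person_years
                     + pb.estimate * (1 - pb.estimate) / pb.person_years)
        assert abs(a.p_switch_tele_to_in - b.p_switch_tele_to_in) < 3 * max(se, 1e-3)

    def test_empty_stratum_is_an_error(self, generated):
        _, cohort, discharges = generated
        with pytest.raises(EstimationError):
            estimate_all(cohort, discharges, fixtures.URBAN_WEIGHTS,
                         fixtures.DELIVERY_INPUTS_DEFAULT, stratum="rural")
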