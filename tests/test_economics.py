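"""Discounting, utilities, cost accumulation and ICER logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crcscreen as cs
from crcscreen import Individual, State
from crcscreen.economics import ArmResult, SimHistory, event_unit_cost


def _history(n=1, horizon=1, events=None, state=None, survivor=None, ages=None):
    state_trace = (np.full((n, horizon), int(State.FREE), dtype=np.int8)
                   if state is None else state)
    survivor_trace = (np.zeros((n, horizon), dtype=bool)
                      if survivor is None else survivor)
    return SimHistory(
        n=n, horizon=horizon, seed=0, group="arabic",
        entry_ages=np.full(n, 55) if ages is None else ages,
        events=events or {}, state_trace=state_trace,
        survivor_trace=survivor_trace)


def _ev(year=0, person=0, stage=None):
    rec = {"year": np.array([year]), "person": np.array([person])}
    if stage is not None:
        rec["stage"] = np.array([stage])
    return rec


class TestDiscount:
    def test_one_year_at_five_percent(self):
        assert cs.discount(100, 1, 0.05) == pytest.approx(95.2381, abs=1e-4)

    def test_rate_zero_is_identity(self):
        assert cs.discount(123.45, 17, 0.0) == 123.45

    def test_fifty_years(self):
        assert cs.discount(1.0, 50, 0.05) == pytest.approx(0.087204, abs=1e-6)

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            cs.discount(1.0, -1, 0.05)


class TestAnnualUtility:
    @pytest.mark.parametrize("age,state,survivor,expected", [
        (60, State.FREE, False, 0.80),
        (72, State.FREE, False, 0.76),
        (82, State.CRC_B, True, 0.70),   # five-year survivor: population norm
        (60, State.CRC_D, False, 0.68),
        (60, State.CRC_A, False, 0.74),
    ])
    def test_examples(self, utilities, age, state, survivor, expected):
        ind = Individual(id=0, age=age, health_state=state, survivor=survivor)
        assert cs.annual_utility(ind, utilities) == expected

    def test_dead_contributes_zero(self, utilities):
        ind = Individual(id=0, age=70, health_state=State.DEAD, alive=False)
        assert cs.annual_utility(ind, utilities) == 0.0

    def test_vectorized_matches_scalar(self, utilities, rng):
        states = rng.integers(0, 8, size=500)
        ages = rng.integers(50, 100, size=500)
        survivors = rng.random(500) < 0.2
        vec = cs.economics.annual_utility_vector(states, ages, survivors, utilities)
        for i in range(500):
            ind = Individual(id=i, age=int(ages[i]), health_state=State(states[i]),
                             survivor=bool(survivors[i]),
                             alive=states[i] != int(State.DEAD))
            assert vec[i] == cs.annual_utility(ind, utilities)


class TestAccumulate:
    def test_single_negative_kit_round(self, costs, utilities):
        events = {"kit_sent": _ev(), "kit_returned_negative": _ev()}
        h = _history(events=events)
        res = cs.accumulate(h, costs, utilities, rate=0.0)
        assert res.cost_per_person == pytest.approx(8.00 + 2.40 + 17.85)

    def test_alive_one_cycle_at_55(self, costs, utilities):
        res = cs.accumulate(_history(), costs, utilities, rate=0.0)
        assert res.qalys_per_person == pytest.approx(0.80)
        assert res.cost_per_person == 0.0

    def test_stage_b_diagnosis_adds_treatment_cost(self, costs, utilities):
        h = _history(events={"diagnosis": _ev(stage=1)})
        res = cs.accumulate(h, costs, utilities, rate=0.0)
        assert res.cost_per_person == pytest.approx(52_594)
        assert res.crc_cases == 1

    def test_unknown_event_kind_errors(self, costs, utilities):
        h = _history(events={"teleportation": _ev()})
        with pytest.raises(KeyError, match="teleportation"):
            cs.accumulate(h, costs, utilities, rate=0.0)

    def test_zero_rate_equals_undiscounted(self, costs, utilities):
        events = {"kit_sent": _ev(year=0), "gp_visit": _ev(year=0),
                  "colonoscopy": _ev(year=0)}
        h = _history(horizon=3, events=events)
        res = cs.accumulate(h, costs, utilities, rate=0.0)
        assert res.cost_per_person == res.cost_per_person_undiscounted
        assert res.qalys_per_person == res.qalys_per_person_undiscounted

    def test_discounted_below_undiscounted(self, costs, utilities):
        h = _history(horizon=10, events={"colonoscopy": _ev(year=7)})
        res = cs.accumulate(h, costs, utilities, rate=0.05)
        assert res.cost_per_person < res.cost_per_person_undiscounted
        assert res.qalys_per_person < res.qalys_per_person_undiscounted

    def test_annuity_closed_form(self, costs, utilities):
        # unit utilities, no mortality: discounted QALYs are the annuity sum
        T, r = 12, 0.05
        import dataclasses
        u1 = dataclasses.replace(
            utilities, utility_norm_bands=((0, 200, 1.0),))
        res = cs.accumulate(_history(horizon=T), costs, u1, rate=r)
        assert res.qalys_per_person == pytest.approx(
            sum((1 + r) ** -t for t in range(T)), rel=1e-12)

    def test_intervention_cost_accrues_at_year_zero(self, costs, utilities):
        res = cs.accumulate(_history(), costs, utilities, rate=0.05,
                            intervention_cost_pp=6.90)
        assert res.cost_per_person == pytest.approx(6.90)


class TestInterventionCostPerPerson:
    def test_arabic_program(self):
        assert cs.intervention_cost_per_person(120_863, 17_522) == 6.90

    def test_mandarin_program(self):
        # computed 3.11; the published rounding prints 3.10
        assert cs.intervention_cost_per_person(120_337, 38_660) == 3.11

    def test_zero_cost(self):
        assert cs.intervention_cost_per_person(0, 1000) == 0.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            cs.intervention_cost_per_person(100, 0)


def _arm(cost, qaly):
    return ArmResult(cost_per_person=cost, qalys_per_person=qaly,
                     cost_per_person_undiscounted=cost,
                     qalys_per_person_undiscounted=qaly,
                     cases_detected=0, crc_cases=0, crc_deaths=0, n_patients=1)


class TestComputeIcer:
    def test_simple_ratio(self):
        res = cs.compute_icer(_arm(0, 0), _arm(10, 0.01))
        assert res.icer == pytest.approx(1000.0)
        assert res.below_threshold

    def test_published_increment_pair(self):
        res = cs.compute_icer(_arm(0, 0), _arm(9.94, 0.010))
        assert res.icer == pytest.approx(994.0)

    def test_dominant_flagged(self):
        res = cs.compute_icer(_arm(10, 0.0), _arm(5, 0.01))
        assert res.dominance == "dominant" and res.below_threshold

    def test_zero_qaly_difference_undefined_not_infinite(self):
        res = cs.compute_icer(_arm(0, 1.0), _arm(10, 1.0))
        assert res.icer is None and res.dominance is None

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-100, 100), st.floats(-1, 1))
    def test_quadrant_logic_matches_brute_force(self, d_cost, d_qaly):
        res = cs.compute_icer(_arm(0, 0), _arm(d_cost, d_qaly), wtp=50_000)
        if d_qaly == 0:
            assert res.icer is None
        else:
            assert res.icer == pytest.approx(d_cost / d_qaly)
            # brute-force four-quadrant classification
            if d_qaly > 0 and d_cost < 0:
                assert res.dominance == "dominant"
            elif d_qaly < 0 and d_cost > 0:
                assert res.dominance == "dominated"
            else:
                assert res.dominance is None
            expected_ce = (d_qaly > 0) and (d_cost < 0 or d_cost / d_qaly <= 50_000)
            assert res.below_threshold == expected_ce


class TestEventCosts:
    @pytest.mark.parametrize("kind,expected", [
        ("kit_sent", 10.40), ("kit_returned_positive", 17.85),
        ("gp_visit", 37.60), ("colonoscopy", 2258.0),
        ("colonoscopy_polypectomy", 4203.0), ("surveillance_gp", 37.60),
        ("adenoma_detected", 0.0),
    ])
    def test_mapping(self, costs, kind, expected):
        assert event_unit_cost(kind, costs) == pytest.approx(expected)

    def test_diagnosis_uses_stage(self, costs):
        assert event_unit_cost("diagnosis", costs, "d") == 90_272
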