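"""Engine orchestration: reproducibility, CRN pairing, oracle equivalence."""

from dataclasses import replace

import numpy as np
import pytest

import crcscreen as cs
from crcscreen import RunSpec, State, Track
from crcscreen.engine import burn_in_cohort, simulate_arm
from crcscreen.screening import Scenario

import _oracle
from conftest import make_cohort


def _zeroed(params):
    """Parameters with no disease and no death."""
    zero_bands = {b: 0.0 for b in params.progressive_adenoma_incidence_by_band}
    return replace(
        params,
        progressive_adenoma_incidence_by_band=dict(zero_bands),
        all_adenoma_incidence_by_band=dict(zero_bands),
        low_risk_adenoma_incidence_by_band=dict(zero_bands),
        background_mortality_by_age=np.zeros_like(params.background_mortality_by_age),
    )


class TestRunSpec:
    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            RunSpec(group="arabic", horizon_years=0)
        with pytest.raises(ValueError):
            RunSpec(group="arabic", n_patients=0)


class TestDeterminism:
    def test_same_runspec_bit_identical(self, params, costs, utilities):
        rs = RunSpec(group="arabic", n_patients=500, horizon_years=20, seed=5)
        base = cs.base_scenario("arabic", params)
        a = cs.run_arm(rs, base, params, costs, utilities)
        b = cs.run_arm(rs, base, params, costs, utilities)
        assert a.cost_per_person == b.cost_per_person
        assert a.qalys_per_person == b.qalys_per_person
        assert a.crc_cases == b.crc_cases

    def test_identical_scenarios_identical_arms(self, params, costs, utilities):
        # common random numbers: a paired comparison of two identical
        # scenarios yields exactly zero increments
        rs = RunSpec(group="arabic", n_patients=2000, horizon_years=30, seed=2)
        base = cs.base_scenario("arabic", params)
        same = replace(base, name="copy")
        cua, _ = cs.run_cua(rs, base, same, params, costs, utilities)
        assert cua.incremental_cost == 0.0
        assert cua.incremental_qalys == 0.0
        assert cua.icer is None


class TestDegenerateDynamics:
    def test_zero_incidence_no_cases_annuity_qalys(self, params, costs, utilities):
        p = _zeroed(params)
        rs = RunSpec(group="arabic", n_patients=300, horizon_years=15, seed=1,
                     discount_rate=0.05)
        res = cs.run_arm(rs, cs.base_scenario("arabic", p), p, costs, utilities)
        assert res.crc_cases == 0 and res.crc_deaths == 0
        # everyone survives the horizon: QALYs are a norm-utility annuity,
        # bracketed by the lowest and highest age-band norms
        annuity = sum(1.05 ** -t for t in range(15))
        assert res.qalys_per_person <= 0.80 * annuity + 1e-9
        assert res.qalys_per_person >= 0.70 * annuity - 1e-9

    def test_burn_in_zero_incidence_keeps_everyone_free(self, params):
        cohort = make_cohort(500, age=74)
        out = burn_in_cohort(cohort, _zeroed(params), seed=3)
        assert np.all(out.state == int(State.FREE))

    def test_burn_in_seeds_latent_disease(self, params):
        cohort = make_cohort(5000, age=70)
        out = burn_in_cohort(cohort, params, seed=3)
        assert (out.state != int(State.FREE)).mean() > 0.02
        assert not out.diagnosed.any()


class TestScreeningPathwayInvariants:
    def test_no_events_after_death_and_gp_before_colonoscopy(self, params):
        scn = cs.base_scenario("mandarin", params)
        cohort = make_cohort(2000, age=60)
        h = simulate_arm(cohort, scn, params, horizon=30, seed=9)
        death_year = np.full(h.n, np.iinfo(np.int32).max)
        for kind in ("crc_death", "background_death"):
            ev = h.events.get(kind)
            if ev is not None:
                np.minimum.at(death_year, ev["person"], ev["year"])
        for kind, ev in h.events.items():
            if kind in ("crc_death", "background_death"):
                continue
            assert np.all(ev["year"] <= death_year[ev["person"]]), kind
        # every diagnostic colonoscopy in a cycle is preceded by a GP visit
        gp = {(y, p) for y, p in zip(h.events["gp_visit"]["year"],
                                     h.events["gp_visit"]["person"])}
        for kind in ("colonoscopy", "colonoscopy_polypectomy"):
            ev = h.events.get(kind)
            if ev is None:
                continue
            for y, p in zip(ev["year"], ev["person"]):
                assert (y, p) in gp

    def test_full_rates_mean_colonoscopy_for_every_invitee(self, params):
        p = replace(params, positivity_rate_by_group={"lote": 1.0, "english": 1.0})
        scn = Scenario(name="all", group="arabic", participation_rate=1.0,
                       colonoscopy_followup_rate=1.0, uplift_duration=1)
        cohort = make_cohort(1000, age=60)  # invitation due at 60
        h = simulate_arm(cohort, scn, p, horizon=1, seed=4)
        n_colo = sum(len(h.events.get(k, {"year": []})["year"])
                     for k in ("colonoscopy", "colonoscopy_polypectomy"))
        n_alive_invited = 1000 - h.count("background_death")
        assert n_colo == n_alive_invited

    def test_detected_cancers_nondecreasing_in_participation(self, params):
        counts = []
        for part in (0.2, 0.8):
            scn = Scenario(name=f"p{part}", group="arabic",
                           participation_rate=part,
                           colonoscopy_followup_rate=0.631, uplift_duration=50)
            detected = 0
            for seed in range(8):
                cohort = make_cohort(3000, age=58)
                cohort = burn_in_cohort(cohort, params, seed=100 + seed)
                h = simulate_arm(cohort, scn, params, horizon=17, seed=seed)
                detected += h.count("cancer_detected") + h.count("adenoma_detected")
            counts.append(detected)
        assert counts[1] > counts[0]


class TestOracleEquivalence:
    def test_toy_three_state_chain(self, params):
        # free -> high-risk adenoma -> CRC A only; no death, no diagnosis
        p = replace(
            _zeroed(params),
            progressive_adenoma_incidence_by_band={
                b: 0.05 for b in params.progressive_adenoma_incidence_by_band},
            all_adenoma_incidence_by_band={
                b: 0.05 for b in params.progressive_adenoma_incidence_by_band},
            low_risk_adenoma_incidence_by_band={
                b: 0.0 for b in params.progressive_adenoma_incidence_by_band},
            transition_probs={**params.transition_probs, "high_to_crc": 0.1},
            symptomatic_diagnosis_prob_by_stage={"A": 0.0, "B": 0.0, "C": 0.0,
                                                 "D": 0.0},
        )
        n, T = 40_000, 20
        cohort = make_cohort(n, age=60, track=Track.NATURAL_HISTORY)
        h = simulate_arm(cohort, cs.base_scenario("arabic", p), p, horizon=T,
                         seed=12)
        sim = _oracle.classify_history(h)
        exp = _oracle.occupancy(p, entry_age=60, horizon=T)
        se = np.sqrt(exp * (1 - exp) / n)
        assert np.all(np.abs(sim - exp) <= 3 * se + 1e-12)

    def test_full_natural_history_occupancy(self, params):
        # all states, age-varying mortality and incidence, diagnosis
        # absorbing; 225 simultaneous cells, so the bound is multiplicity
        # aware: every cell within 4.5 SE and 99% of cells within 3 SE
        n, T = 60_000, 25
        cohort = make_cohort(n, age=58, track=Track.NATURAL_HISTORY)
        h = simulate_arm(cohort, cs.base_scenario("mandarin", params), params,
                         horizon=T, seed=21)
        sim = _oracle.classify_history(h)
        exp = _oracle.occupancy(params, entry_age=58, horizon=T)
        se = np.sqrt(exp * (1 - exp) / n)
        z = np.abs(sim - exp) / np.where(se > 0, se, np.inf)
        assert np.all((se > 0) | (np.abs(sim - exp) < 1e-12))
        assert z.max() <= 4.5
        assert (z <= 3.0).mean() >= 0.99


class TestPSA:
    def test_collapsed_ranges_zero_width_interval(self, params, costs, utilities):
        spec = cs.PSASpec(entries={"transition_low_to_high": (0.02, 0.02)},
                          n_trials=4, n_patients_per_trial=800)
        rs = RunSpec(group="arabic", n_patients=800, horizon_years=15, seed=3)
        base = cs.base_scenario("arabic", params)
        intv = cs.uplift_scenario("arabic", 5.0, params, costs=costs)
        summary, trials = cs.run_psa(rs, base, intv, params, costs, utilities,
                                     spec, share_simulation_seed=True)
        assert trials["d_cost"].nunique() == 1
        assert trials["d_qaly"].nunique() == 1
        if summary.icer_low is not None:
            assert summary.icer_low == summary.icer_high

    def test_interval_brackets_point_under_variation(self, params, costs, utilities):
        spec = cs.default_psa_spec(params, costs, n_trials=30, n_patients=1500)
        rs = RunSpec(group="mandarin", n_patients=1500, horizon_years=25, seed=8)
        base = cs.base_scenario("mandarin", params)
        # persistent large uplift so every trial shows a QALY difference
        intv = Scenario(name="big", group="mandarin", participation_rate=0.9,
                        colonoscopy_followup_rate=0.631, uplift_duration=25,
                        intervention_cost_total=120_337.0)
        summary, trials = cs.run_psa(rs, base, intv, params, costs, utilities, spec)
        assert summary.n_trials == 30
        valid = trials[trials["d_qaly"] != 0]
        icers = valid["d_cost"] / valid["d_qaly"]
        assert summary.icer_low <= np.median(icers) <= summary.icer_high


class TestValidateModel:
    def test_zero_incidence_fails_benchmark_and_reports(self, params, costs,
                                                        utilities):
        p = _zeroed(params)
        rs = RunSpec(group="mandarin", n_patients=400, horizon_years=10, seed=1)
        res = cs.run_arm(rs, cs.base_scenario("mandarin", p), p, costs, utilities)
        report = cs.validate_model(res, population=38_660, horizon_years=10,
                                   benchmarks={"crc_cases_per_year": 46.5})
        assert report["crc_cases_per_year"]["simulated"] == 0.0
        assert not report["crc_cases_per_year"]["pass"]

    def test_unknown_metric_rejected(self, params, costs, utilities):
        res = cs.economics.ArmResult(0, 0, 0, 0, 0, 0, 0, n_patients=10)
        with pytest.raises(KeyError):
            cs.validate_model(res, 1000, 10, {"nonsense": 1.0})
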