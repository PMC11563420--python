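"""Screening pathway, colonoscopy outcomes and surveillance (scalar ops)."""

from dataclasses import replace

import numpy as np
import pytest

import crcscreen as cs
from crcscreen import Individual, State, Track
from crcscreen.screening import Scenario, colonoscopy_outcome


def _ind(state=State.FREE, age=60, track=Track.SCREENING, **kw):
    return Individual(id=0, age=age, health_state=state, screening_track=track, **kw)


def _scenario(params, group="arabic", part=None, fu=None, dur=1):
    return Scenario(
        name="t", group=group,
        participation_rate=part if part is not None
        else params.participation_baseline_by_group[group],
        colonoscopy_followup_rate=fu if fu is not None
        else params.colonoscopy_followup_by_group["lote"],
        uplift_duration=dur)


class TestInvitationDue:
    @pytest.mark.parametrize("age,due", [
        (50, True), (62, True), (74, True),   # program ages
        (51, False), (75, False), (49, False),  # odd / outside program
    ])
    def test_biennial_even_ages_50_to_74(self, age, due):
        assert cs.invitation_due(age) is due


class TestScenario:
    def test_rates_validated(self):
        with pytest.raises(ValueError, match="participation_rate"):
            Scenario(name="x", group="arabic", participation_rate=1.5,
                     colonoscopy_followup_rate=0.5)

    def test_uplift_reverts_to_baseline(self, params):
        s = cs.uplift_scenario("arabic", 1.3, params, intervention_cost_total=0)
        assert s.participation(params, 0) == pytest.approx(0.307 + 0.013)
        assert s.participation(params, 1) == 0.307
        assert s.followup(params, 0) == 0.631
        assert s.followup(params, 1) == 0.543

    def test_base_scenario_is_constant(self, params):
        s = cs.base_scenario("mandarin", params)
        assert s.participation(params, 0) == s.participation(params, 30) == 0.40
        assert s.intervention_cost_total == 0.0


class TestStepScreening:
    def test_zero_participation_only_kit_sent(self, params, rng):
        s = _scenario(params, part=0.0)
        for _ in range(200):
            out, events = cs.step_screening(_ind(age=62), s, params, 0, rng)
            assert [e.kind for e in events] == ["kit_sent"]
            assert out.screening_track is Track.SCREENING

    def test_no_invitation_outside_program_ages(self, params, rng):
        s = _scenario(params, part=1.0)
        _, events = cs.step_screening(_ind(age=61), s, params, 0, rng)
        assert events == []

    def test_positivity_rate_within_three_se(self, params, rng):
        s = _scenario(params, part=1.0)
        n = 100_000
        pos = 0
        for _ in range(n):
            _, events = cs.step_screening(_ind(age=62), s, params, 0, rng)
            pos += any(e.kind == "kit_returned_positive" for e in events)
        se = np.sqrt(0.064 * 0.936 / n)
        assert abs(pos / n - 0.064) < 3 * se

    def test_decliners_switch_to_natural_history(self, params, rng):
        # force positivity; follow-up 0 -> everyone declines colonoscopy
        p = replace(params, positivity_rate_by_group={"lote": 1.0, "english": 1.0})
        s = _scenario(p, part=1.0, fu=0.0)
        out, events = cs.step_screening(_ind(age=62), s, p, 0, rng)
        kinds = [e.kind for e in events]
        assert "declined_colonoscopy" in kinds and "gp_visit" in kinds
        assert out.screening_track is Track.NATURAL_HISTORY

    def test_full_rates_everyone_gets_colonoscopy(self, params, rng):
        p = replace(params, positivity_rate_by_group={"lote": 1.0, "english": 1.0})
        s = _scenario(p, part=1.0, fu=1.0)
        for _ in range(100):
            _, events = cs.step_screening(_ind(age=62), s, p, 0, rng)
            assert any(e.kind.startswith("colonoscopy") for e in events)

    def test_events_carry_costs_when_schedule_given(self, params, costs, rng):
        s = _scenario(params, part=0.0)
        _, events = cs.step_screening(_ind(age=62), s, params, 0, rng, costs=costs)
        assert events[0].costs_attached == pytest.approx(8.00 + 2.40)


class TestColonoscopyOutcome:
    def test_latent_mode_reveals_latent_state(self, params, rng):
        out, ind, _ = colonoscopy_outcome(_ind(State.LOW_RISK), params, rng)
        assert out == "adenoma_low_risk"
        assert ind.health_state is State.FREE
        assert ind.screening_track is Track.SURVEILLANCE
        out, ind, _ = colonoscopy_outcome(_ind(State.FREE), params, rng)
        assert out == "no_disease"

    def test_latent_cancer_staged_from_screened_mix(self, params, rng):
        n = 100_000
        stages = np.zeros(4)
        for _ in range(n):
            out, ind, _ = colonoscopy_outcome(_ind(State.CRC_C), params, rng)
            assert out == "cancer" and ind.diagnosed
            stages[ind.dx_stage - int(State.CRC_A)] += 1
        frac = stages / n
        target = params.stage_distribution_screened
        se = np.sqrt(target * (1 - target) / n)
        assert np.all(np.abs(frac - target) < 3 * se)

    def test_prevalence_mode_matches_renormalized_table(self, params, rng):
        n = 100_000
        crc = 0
        for _ in range(n):
            out, _, _ = colonoscopy_outcome(_ind(State.FREE), params, rng,
                                            mode="prevalence")
            crc += out == "cancer"
        target = 0.0313 / 1.0227
        se = np.sqrt(target * (1 - target) / n)
        assert abs(crc / n - target) < 3 * se

    def test_prevalence_mode_all_free_degenerate(self, params, rng):
        p = replace(params,
                    colonoscopy_prevalence_raw=np.array([1.0, 0.0, 0.0, 0.0]))
        for _ in range(200):
            out, ind, events = colonoscopy_outcome(_ind(State.FREE), p, rng,
                                                   mode="prevalence")
            assert out == "no_disease"
            assert all(e.kind != "colonoscopy_polypectomy" for e in events)


class TestSurveillance:
    def test_due_after_five_years(self, params, rng):
        ind = _ind(age=70, track=Track.SURVEILLANCE, years_since_last_surveillance=5)
        _, events = cs.step_surveillance(ind, params, rng)
        assert any("colonoscopy" in e.kind for e in events)

    def test_not_due_before_interval(self, params, rng):
        ind = _ind(age=70, track=Track.SURVEILLANCE, years_since_last_surveillance=3)
        out, events = cs.step_surveillance(ind, params, rng)
        assert events == []
        assert out.years_since_last_surveillance == 4

    def test_exits_at_age_75(self, params, rng):
        ind = _ind(age=76, track=Track.SURVEILLANCE, years_since_last_surveillance=5)
        out, events = cs.step_surveillance(ind, params, rng)
        assert events == []
        assert out.screening_track is Track.NATURAL_HISTORY

    def test_adenoma_removed_at_surveillance(self, params, rng):
        ind = _ind(State.HIGH_RISK, age=70, track=Track.SURVEILLANCE,
                   years_since_last_surveillance=5)
        out, events = cs.step_surveillance(ind, params, rng)
        assert out.health_state is State.FREE
        assert any(e.kind == "surveillance_colonoscopy_polypectomy" for e in events)

    def test_latent_cancer_detected_at_surveillance(self, params, rng):
        ind = _ind(State.CRC_B, age=70, track=Track.SURVEILLANCE,
                   years_since_last_surveillance=5)
        out, events = cs.step_surveillance(ind, params, rng)
        assert out.diagnosed and out.dx_stage == int(State.CRC_B)
        assert out.screening_track is Track.NATURAL_HISTORY
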