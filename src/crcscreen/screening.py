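"""National bowel-screening pathway and colonoscopy surveillance.

The program mails an immunochemical FOBT kit to everyone at the even ages
50, 52, ..., 74.  A returned positive kit leads to a GP visit and, with the
group's colonoscopy-assessment rate, a diagnostic colonoscopy.  Colonoscopy
outcomes are sampled from the observed outcome prevalence of the program
(free of disease / low-risk adenoma / high-risk adenoma / CRC) rather than
from test sensitivity and specificity; the sampled outcome overwrites the
individual's latent state (the latent state is retained in the event log for
diagnostics).  Detected adenomas are removed and the individual enters
5-yearly colonoscopy surveillance until age 75; detected cancers are staged
from the screen-detected stage distribution.  Decliners of colonoscopy move
permanently to the natural-history part of the model, where cancer can only
present symptomatically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._states import ADENOMA_STATES, CRC_STATES, State, Track, stage_label
from .cohort import Individual
from .parameters import (DEFAULT_SCREENING_AGES, CostSchedule, ModelParameters)

__all__ = ["ScreeningEvent", "Scenario", "invitation_due", "step_screening",
           "colonoscopy_outcome", "step_surveillance", "base_scenario",
           "uplift_scenario"]

# colonoscopy outcome codes, in prevalence-vector order
OUTCOME_FREE, OUTCOME_LOW, OUTCOME_HIGH, OUTCOME_CRC = range(4)
OUTCOME_NAMES = ("no_disease", "adenoma_low_risk", "adenoma_high_risk", "cancer")


@dataclass(frozen=True)
class ScreeningEvent:
    kind: str
    age: int
    costs_attached: float = 0.0
    detail: str = ""


@dataclass
class Scenario:
    """One arm: participation and follow-up rates plus program cost.

    ``participation_rate`` and ``colonoscopy_followup_rate`` apply while
    ``year_index < uplift_duration``; afterwards rates revert to the group
    baselines from the parameter set.
    """

    name: str
    group: str  # "arabic" | "mandarin"
    participation_rate: float
    colonoscopy_followup_rate: float
    uplift_duration: int = 1
    intervention_cost_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("participation_rate", "colonoscopy_followup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")

    def participation(self, params: ModelParameters, year_index: int) -> float:
        if year_index < self.uplift_duration:
            return self.participation_rate
        return params.participation_baseline_by_group[self.group]

    def followup(self, params: ModelParameters, year_index: int) -> float:
        if year_index < self.uplift_duration:
            return self.colonoscopy_followup_rate
        return params.colonoscopy_followup_by_group["lote"]


def base_scenario(group: str, params: ModelParameters) -> Scenario:
    """Usual practice: baseline participation, LOTE follow-up, no program cost."""
    return Scenario(
        name=f"{group}_base", group=group,
        participation_rate=params.participation_baseline_by_group[group],
        colonoscopy_followup_rate=params.colonoscopy_followup_by_group["lote"],
        uplift_duration=0, intervention_cost_total=0.0,
    )


def uplift_scenario(group: str, uplift_pp: float, params: ModelParameters,
                    costs: CostSchedule | None = None,
                    intervention_cost_total: float | None = None,
                    uplift_duration: int = 1, name: str | None = None) -> Scenario:
    """Tailored-recruitment arm: participation raised by ``uplift_pp``
    percentage points and colonoscopy follow-up raised to the
    English-speaking rate, both for ``uplift_duration`` years."""
    if intervention_cost_total is None:
        if costs is None:
            raise ValueError("supply costs or intervention_cost_total")
        intervention_cost_total = costs.intervention_total_by_group[group]
    return Scenario(
        name=name or f"{group}_uplift_{uplift_pp:g}pp", group=group,
        participation_rate=(params.participation_baseline_by_group[group]
                            + uplift_pp / 100.0),
        colonoscopy_followup_rate=params.colonoscopy_followup_by_group["english"],
        uplift_duration=uplift_duration,
        intervention_cost_total=intervention_cost_total,
    )


def invitation_due(age: int, screening_ages=DEFAULT_SCREENING_AGES) -> bool:
    """Whether a screening kit is mailed at this age (50, 52, ..., 74)."""
    return int(age) in screening_ages


def _event(kind: str, age: int, costs: CostSchedule | None, detail: str = "") -> ScreeningEvent:
    from .economics import event_unit_cost  # local import avoids a cycle

    dollars = event_unit_cost(kind, costs, detail) if costs is not None else 0.0
    return ScreeningEvent(kind=kind, age=age, costs_attached=dollars, detail=detail)


def colonoscopy_outcome(
    ind: Individual, params: ModelParameters, rng: np.random.Generator,
    costs: CostSchedule | None = None, mode: str = "latent",
) -> tuple[str, Individual, list[ScreeningEvent]]:
    """Diagnostic colonoscopy after a positive kit and GP referral.

    In the default ``"latent"`` mode the colonoscopy reveals the
    individual's latent natural-history state: adenomas are removed
    (polypectomy) and the individual enters surveillance, and a latent
    cancer is diagnosed with its stage drawn from the screen-detected stage
    distribution (the stage shift that distinguishes screen detection from
    symptomatic presentation).  In ``"prevalence"`` mode the outcome is
    instead drawn from the renormalized observed outcome prevalence of the
    program and imposed on the individual, overwriting the latent state;
    this reproduces the observed outcome mix exactly but makes detected
    disease independent of individual risk, so the default keeps outcomes
    tied to the latent state and treats the observed prevalence as a
    validation benchmark.
    """
    events: list[ScreeningEvent] = []
    latent = ind.health_state.name
    if mode == "latent":
        if ind.health_state in ADENOMA_STATES:
            outcome = (OUTCOME_LOW if ind.health_state is State.LOW_RISK
                       else OUTCOME_HIGH)
        elif ind.health_state in CRC_STATES:
            outcome = OUTCOME_CRC
        else:
            outcome = OUTCOME_FREE
    elif mode == "prevalence":
        cum = np.cumsum(params.colonoscopy_prevalence)
        outcome = int(np.searchsorted(cum, rng.random(), side="right"))
        outcome = min(outcome, OUTCOME_CRC)
    else:
        raise ValueError(f"unknown colonoscopy outcome mode {mode!r}")
    if outcome == OUTCOME_FREE:
        events.append(_event("colonoscopy", ind.age, costs, latent))
        events.append(_event("no_disease", ind.age, costs))
        ind = replace(ind, health_state=State.FREE)
    elif outcome in (OUTCOME_LOW, OUTCOME_HIGH):
        events.append(_event("colonoscopy_polypectomy", ind.age, costs, latent))
        events.append(_event("adenoma_detected", ind.age, costs))
        ind = replace(ind, health_state=State.FREE,
                      screening_track=Track.SURVEILLANCE,
                      years_since_last_surveillance=0)
    else:
        stage_idx = int(np.searchsorted(
            np.cumsum(params.stage_distribution_screened), rng.random(), side="right"))
        stage_idx = min(stage_idx, 3)
        new_state = State(int(State.CRC_A) + stage_idx)
        events.append(_event("colonoscopy", ind.age, costs, latent))
        events.append(_event("cancer_detected", ind.age, costs, stage_label(new_state)))
        events.append(_event("diagnosis", ind.age, costs, stage_label(new_state)))
        ind = replace(ind, health_state=new_state, diagnosed=True,
                      dx_stage=int(new_state), years_since_diagnosis=0,
                      screening_track=Track.NATURAL_HISTORY)
    return OUTCOME_NAMES[outcome], ind, events


def step_screening(
    ind: Individual, scenario: Scenario, params: ModelParameters,
    year_index: int, rng: np.random.Generator, costs: CostSchedule | None = None,
) -> tuple[Individual, list[ScreeningEvent]]:
    """One screening-program round for one individual, if an invitation is due."""
    if not ind.alive or ind.screening_track is not Track.SCREENING:
        return ind, []
    if not invitation_due(ind.age, params.screening_ages):
        return ind, []
    events = [_event("kit_sent", ind.age, costs)]
    if rng.random() >= scenario.participation(params, year_index):
        return ind, events
    positivity = params.positivity_rate_by_group["lote"]
    if rng.random() < positivity:
        events.append(_event("kit_returned_positive", ind.age, costs))
        events.append(_event("gp_visit", ind.age, costs))
        if rng.random() < scenario.followup(params, year_index):
            _, ind, colo_events = colonoscopy_outcome(ind, params, rng, costs)
            events.extend(colo_events)
        else:
            events.append(_event("declined_colonoscopy", ind.age, costs))
            ind = replace(ind, screening_track=Track.NATURAL_HISTORY)
    else:
        events.append(_event("kit_returned_negative", ind.age, costs))
    return ind, events


def step_surveillance(
    ind: Individual, params: ModelParameters, rng: np.random.Generator,
    costs: CostSchedule | None = None,
) -> tuple[Individual, list[ScreeningEvent]]:
    """Five-yearly colonoscopy surveillance after adenoma removal.

    Each fifth year a GP referral and a colonoscopy occur; any adenoma found
    is removed.  Latent cancer found at a surveillance colonoscopy is
    diagnosed at its latent stage.  At age 75 the individual leaves
    surveillance for the natural-history track (no further colonoscopies).
    """
    if not ind.alive or ind.screening_track is not Track.SURVEILLANCE:
        return ind, []
    if ind.age >= params.surveillance_max_age:
        return replace(ind, screening_track=Track.NATURAL_HISTORY), []
    if ind.years_since_last_surveillance < params.surveillance_interval:
        return replace(ind,
                       years_since_last_surveillance=ind.years_since_last_surveillance + 1), []
    events = [_event("surveillance_gp", ind.age, costs)]
    state = ind.health_state
    if state in ADENOMA_STATES:
        events.append(_event("surveillance_colonoscopy_polypectomy", ind.age, costs))
        events.append(_event("adenoma_detected", ind.age, costs, "surveillance"))
        ind = replace(ind, health_state=State.FREE)
    elif state in CRC_STATES:
        events.append(_event("surveillance_colonoscopy", ind.age, costs))
        events.append(_event("cancer_detected", ind.age, costs, stage_label(state)))
        events.append(_event("diagnosis", ind.age, costs, stage_label(state)))
        ind = replace(ind, diagnosed=True, dx_stage=int(state),
                      years_since_diagnosis=0,
                      screening_track=Track.NATURAL_HISTORY)
    else:
        events.append(_event("surveillance_colonoscopy", ind.age, costs))
    if ind.screening_track is Track.SURVEILLANCE:
        ind = replace(ind, years_since_last_surveillance=1)
    return ind, events
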