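"""Annual-cycle natural history: progression, diagnosis, survival, mortality.

Colorectal cancer develops along the adenoma-carcinoma pathway: free of
disease -> low-risk adenoma -> high-risk adenoma -> CRC stage A -> B -> C ->
D.  Progressive-adenoma incidence seeds the high-risk state directly (the
schedule is constructed as CRC incidence 20 years later); low-risk adenoma
incidence seeds the low-risk state.  Undiagnosed cancer may present
symptomatically with a stage-specific annual probability; the stage
recorded at presentation is drawn from the not-screened registry stage
distribution, from which those probabilities were themselves derived.
After diagnosis the stage is frozen and mortality
follows the stage- and year-specific survival table for five years; patients
alive after five years are cancer survivors with general-population
mortality and no recurrence.

Within one annual cycle events are applied in a fixed order: mortality,
then symptomatic diagnosis, then at most one progression step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._states import State, stage_label
from .cohort import Individual
from .parameters import ModelParameters

__all__ = ["TransitionEvent", "step_natural_history", "symptomatic_diagnosis",
           "survival_step"]

_ALLOWED_EDGES = {
    (State.FREE, State.LOW_RISK), (State.FREE, State.HIGH_RISK),
    (State.LOW_RISK, State.HIGH_RISK), (State.HIGH_RISK, State.CRC_A),
    (State.CRC_A, State.CRC_B), (State.CRC_B, State.CRC_C),
    (State.CRC_C, State.CRC_D),
}


@dataclass(frozen=True)
class TransitionEvent:
    from_state: State
    to_state: State
    cause: str  # progression | symptomatic_diagnosis | crc_death | background_death | adenoma_incidence

    def __post_init__(self) -> None:
        if self.to_state is State.DEAD or self.from_state is self.to_state:
            return
        if (self.from_state, self.to_state) not in _ALLOWED_EDGES:
            raise ValueError(
                f"transition {self.from_state.name} -> {self.to_state.name} not allowed"
            )


def symptomatic_diagnosis(stage: str | State, params: ModelParameters,
                          rng: np.random.Generator) -> bool:
    """Whether an undiagnosed cancer of the given stage presents this cycle."""
    label = stage if isinstance(stage, str) else stage_label(stage)
    if label not in params.symptomatic_diagnosis_prob_by_stage:
        raise ValueError(f"{stage!r} is not a CRC stage")
    return bool(rng.random() < params.symptomatic_diagnosis_prob_by_stage[label])


def survival_step(ind: Individual, params: ModelParameters,
                  rng: np.random.Generator) -> Individual:
    """One post-diagnosis annual cycle.

    Years 1-5 since diagnosis apply the stage-specific conditional annual
    survival (all-cause for those years); afterwards the individual is a
    survivor subject to background mortality only.
    """
    if not ind.diagnosed:
        raise ValueError("survival_step requires a diagnosed individual")
    if not ind.alive:
        return ind
    ysd = ind.years_since_diagnosis
    if ysd >= 5:
        q = params.background_mortality_by_age[min(ind.age, params.max_age)]
        survivor = True
    else:
        stage = stage_label(ind.dx_stage)
        surv = params.survival_by_stage_year[stage]
        if ysd >= len(surv):
            raise ValueError(f"no survival entry for stage {stage}, year {ysd + 1}")
        q = 1.0 - surv[ysd]
        survivor = False
    if rng.random() < q:
        return replace(ind, alive=False, health_state=State.DEAD, survivor=survivor)
    return replace(ind, age=ind.age + 1, years_since_diagnosis=ysd + 1,
                   survivor=survivor or ysd + 1 >= 5)


def _progression(ind: Individual, params: ModelParameters,
                 rng: np.random.Generator) -> tuple[Individual, list[TransitionEvent]]:
    state = ind.health_state
    t = params.transition_probs
    if state is State.FREE:
        age = min(ind.age, params.max_age)
        p_high = params.progressive_incidence_by_age()[age] if age >= 50 else 0.0
        p_low = params.low_risk_incidence_by_age()[age] if age >= 50 else 0.0
        u = rng.random()
        if u < p_high:
            new = State.HIGH_RISK
        elif u < p_high + p_low:
            new = State.LOW_RISK
        else:
            return ind, []
        return (replace(ind, health_state=new),
                [TransitionEvent(state, new, "adenoma_incidence")])
    edges = {
        State.LOW_RISK: (State.HIGH_RISK, t["low_to_high"]),
        State.HIGH_RISK: (State.CRC_A, t["high_to_crc"]),
        State.CRC_A: (State.CRC_B, t["a_to_b"]),
        State.CRC_B: (State.CRC_C, t["b_to_c"]),
        State.CRC_C: (State.CRC_D, t["c_to_d"]),
    }
    if state not in edges:
        return ind, []
    new, p = edges[state]
    if rng.random() < p:
        return replace(ind, health_state=new), [TransitionEvent(state, new, "progression")]
    return ind, []


def step_natural_history(
    ind: Individual, params: ModelParameters, rng: np.random.Generator
) -> tuple[Individual, list[TransitionEvent]]:
    """Apply one annual natural-history cycle to one individual.

    Order within the cycle: mortality first, then symptomatic diagnosis for
    undiagnosed cancer, then at most one progression / incidence step.  A
    dead individual is returned unchanged.
    """
    if not ind.alive:
        return ind, []
    events: list[TransitionEvent] = []

    if ind.diagnosed:
        out = survival_step(ind, params, rng)
        if not out.alive:
            cause = "background_death"
            if ind.years_since_diagnosis < 5:
                # only the excess hazard over background is CRC-attributed
                stage = stage_label(ind.dx_stage)
                q_stage = 1.0 - params.survival_by_stage_year[stage][ind.years_since_diagnosis]
                q_bg = params.background_mortality_by_age[min(ind.age, params.max_age)]
                p_crc = max(q_stage - q_bg, 0.0) / q_stage if q_stage > 0 else 0.0
                if rng.random() < p_crc:
                    cause = "crc_death"
            events.append(TransitionEvent(ind.health_state, State.DEAD, cause))
        return out, events

    q = params.background_mortality_by_age[min(ind.age, params.max_age)]
    if rng.random() < q:
        return (replace(ind, alive=False, health_state=State.DEAD),
                [TransitionEvent(ind.health_state, State.DEAD, "background_death")])

    state = ind.health_state
    if state in (State.CRC_A, State.CRC_B, State.CRC_C, State.CRC_D):
        if symptomatic_diagnosis(state, params, rng):
            # stage at presentation drawn from the not-screened distribution,
            # which the per-stage presentation probabilities were derived from
            cum = np.cumsum(params.stage_distribution_not_screened)
            k = min(int(np.searchsorted(cum, rng.random(), side="right")), 3)
            dx_state = State(int(State.CRC_A) + k)
            events.append(TransitionEvent(state, state, "symptomatic_diagnosis"))
            return (replace(ind, age=ind.age + 1, health_state=dx_state,
                            diagnosed=True, dx_stage=int(dx_state),
                            years_since_diagnosis=0),
                    events)

    ind, prog_events = _progression(ind, params, rng)
    events.extend(prog_events)
    return replace(ind, age=ind.age + 1), events
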