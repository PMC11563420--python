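"""Deterministic cohort-model oracle for the natural-history microsimulation.

Expected state occupancy is propagated by exact matrix products over the
same per-cycle kernel order the microsimulation uses (mortality, then
symptomatic diagnosis, then one progression step).  Diagnosis is absorbing
here: the oracle tracks "ever diagnosed" rather than post-diagnosis
survival, and the microsimulation side classifies individuals the same way.

Written independently of the engine's implementation: kernels are built as
explicit stochastic matrices and composed by matrix multiplication.
"""

from __future__ import annotations

import numpy as np

# oracle state order
FREE, LOW, HIGH, A, B, C, D, DX, DEAD = range(9)
N_STATES = 9
_UNDIAG = [FREE, LOW, HIGH, A, B, C, D]


def _mort_kernel(q: float) -> np.ndarray:
    m = np.eye(N_STATES)
    for s in _UNDIAG:
        m[s, s] = 1.0 - q
        m[s, DEAD] = q
    return m


def _diag_kernel(dx_probs: dict[str, float]) -> np.ndarray:
    m = np.eye(N_STATES)
    for s, stage in ((A, "A"), (B, "B"), (C, "C"), (D, "D")):
        d = dx_probs[stage]
        m[s, s] = 1.0 - d
        m[s, DX] = d
    return m


def _prog_kernel(p_high: float, p_low: float, t: dict[str, float]) -> np.ndarray:
    m = np.eye(N_STATES)
    m[FREE, HIGH] = p_high
    m[FREE, LOW] = p_low
    m[FREE, FREE] = 1.0 - p_high - p_low
    for s, nxt, key in ((LOW, HIGH, "low_to_high"), (HIGH, A, "high_to_crc"),
                        (A, B, "a_to_b"), (B, C, "b_to_c"), (C, D, "c_to_d")):
        m[s, nxt] = t[key]
        m[s, s] = 1.0 - t[key]
    return m


def occupancy(params, entry_age: int, horizon: int) -> np.ndarray:
    """Expected occupancy (horizon x 9) for a cohort entering free of
    disease at ``entry_age``, natural history only."""
    prog_inc = params.progressive_incidence_by_age()
    low_inc = params.low_risk_incidence_by_age()
    q_bg = params.background_mortality_by_age

    v = np.zeros(N_STATES)
    v[FREE] = 1.0
    out = np.zeros((horizon, N_STATES))
    for cycle in range(horizon):
        age = min(entry_age + cycle, params.max_age)
        q = 1.0 if age >= params.max_age else q_bg[age]
        kernel = (_mort_kernel(q)
                  @ _diag_kernel(params.symptomatic_diagnosis_prob_by_stage)
                  @ _prog_kernel(prog_inc[age], low_inc[age],
                                 params.transition_probs))
        v = v @ kernel
        out[cycle] = v
    return out


def classify_history(history) -> np.ndarray:
    """Per-cycle occupancy fractions of a simulated arm in oracle classes.

    Ever-diagnosed individuals are absorbed into DX; the dead-without-
    diagnosis go to DEAD; everyone else keeps their traced state.
    """
    n, T = history.n, history.horizon
    dx_year = np.full(n, np.iinfo(np.int32).max)
    ev = history.events.get("diagnosis")
    if ev is not None:
        np.minimum.at(dx_year, ev["person"], ev["year"])
    out = np.zeros((T, N_STATES))
    for t in range(T):
        states = history.state_trace[:, t].astype(int)
        cls = states.copy()  # package codes 0..6 match oracle order
        cls[states == 7] = DEAD
        cls[dx_year <= t] = DX
        out[t] = np.bincount(cls, minlength=N_STATES) / n
    return out
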