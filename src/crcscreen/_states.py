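"""Shared health-state and track codes for the microsimulation.

Integer codes are used throughout so cohorts can be stored as flat numpy
arrays; the enums exist for readable scalar code and event logs.
"""

from __future__ import annotations

from enum import IntEnum


class State(IntEnum):
    """Markov health states of the natural-history model."""

    FREE = 0            # free of disease
    LOW_RISK = 1        # low-risk adenoma
    HIGH_RISK = 2       # high-risk (progressive) adenoma
    CRC_A = 3           # colorectal cancer, ACPS stage A
    CRC_B = 4
    CRC_C = 5
    CRC_D = 6
    DEAD = 7


class Track(IntEnum):
    """Which part of the model an individual currently moves through."""

    SCREENING = 0
    NATURAL_HISTORY = 1
    SURVEILLANCE = 2


CRC_STATES = (State.CRC_A, State.CRC_B, State.CRC_C, State.CRC_D)
ADENOMA_STATES = (State.LOW_RISK, State.HIGH_RISK)

STAGES = ("A", "B", "C", "D")


def stage_label(state: int) -> str:
    """Map a CRC state code to its ACPS stage letter."""
    idx = int(state) - int(State.CRC_A)
    if not 0 <= idx < 4:
        raise ValueError(f"state {state!r} is not a CRC state")
    return STAGES[idx]


def stage_state(label: str) -> State:
    """Map an ACPS stage letter to its state code."""
    try:
        return State(int(State.CRC_A) + STAGES.index(label.upper()))
    except ValueError as exc:
        raise ValueError(f"unknown ACPS stage {label!r}") from exc
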