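"""Eligible population and simulated cohort construction.

The eligible population is everyone in the language group aged 50-74 in the
target year; counts per single year of age come from two census years and
are linearly interpolated.  Individuals are sampled with ages proportional
to the interpolated counts and enter the model free of disease, undiagnosed
and in the screening track.  The cohort is closed: no migration and no
replenishment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._states import State, Track

__all__ = ["PopulationTable", "Individual", "Cohort",
           "interpolate_population", "sample_cohort"]


@dataclass
class PopulationTable:
    """Single-year-of-age counts at two census years and the target year."""

    ages: np.ndarray
    counts_2016: np.ndarray
    counts_2021: np.ndarray
    counts_target: np.ndarray
    target_year: float
    group: str = ""

    @property
    def total(self) -> float:
        return float(self.counts_target.sum())

    def validate(self) -> None:
        for name, c in (("counts_2016", self.counts_2016),
                        ("counts_2021", self.counts_2021),
                        ("counts_target", self.counts_target)):
            if np.any(np.asarray(c) < 0):
                raise ValueError(f"{name} contains negative counts")
        lo = np.minimum(self.counts_2016, self.counts_2021)
        hi = np.maximum(self.counts_2016, self.counts_2021)
        if np.any(self.counts_target < lo - 1e-9) or np.any(self.counts_target > hi + 1e-9):
            raise ValueError("interpolated counts fall outside the census envelope")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "count_2016": self.counts_2016,
            "count_2021": self.counts_2021,
            f"count_{self.target_year:g}": self.counts_target,
        })


@dataclass
class Individual:
    """One simulated person; scalar mirror of a :class:`Cohort` row."""

    id: int
    age: int
    health_state: State = State.FREE
    diagnosed: bool = False
    dx_stage: int = -1
    years_since_diagnosis: int = 0
    screening_track: Track = Track.SCREENING
    years_since_last_surveillance: int = 0
    alive: bool = True
    survivor: bool = False


@dataclass
class Cohort:
    """Struct-of-arrays container for the simulated population."""

    age: np.ndarray
    state: np.ndarray
    diagnosed: np.ndarray
    dx_stage: np.ndarray
    years_since_dx: np.ndarray
    track: np.ndarray
    years_since_surveillance: np.ndarray
    alive: np.ndarray
    survivor: np.ndarray
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.age)

    @classmethod
    def of_ages(cls, ages: np.ndarray, seed: int | None = None) -> "Cohort":
        n = len(ages)
        return cls(
            age=np.asarray(ages, dtype=np.int64).copy(),
            state=np.full(n, int(State.FREE), dtype=np.int8),
            diagnosed=np.zeros(n, dtype=bool),
            dx_stage=np.full(n, -1, dtype=np.int8),
            years_since_dx=np.zeros(n, dtype=np.int64),
            track=np.full(n, int(Track.SCREENING), dtype=np.int8),
            years_since_surveillance=np.zeros(n, dtype=np.int64),
            alive=np.ones(n, dtype=bool),
            survivor=np.zeros(n, dtype=bool),
            seed=seed,
        )

    def copy(self) -> "Cohort":
        return Cohort(*(np.copy(getattr(self, f)) for f in (
            "age", "state", "diagnosed", "dx_stage", "years_since_dx",
            "track", "years_since_surveillance", "alive", "survivor")),
            seed=self.seed)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n),
            "age": self.age,
            "state": [State(s).name for s in self.state],
            "diagnosed": self.diagnosed,
            "track": [Track(t).name for t in self.track],
            "alive": self.alive,
        })

    def individual(self, i: int) -> Individual:
        return Individual(
            id=i, age=int(self.age[i]), health_state=State(self.state[i]),
            diagnosed=bool(self.diagnosed[i]), dx_stage=int(self.dx_stage[i]),
            years_since_diagnosis=int(self.years_since_dx[i]),
            screening_track=Track(self.track[i]),
            years_since_last_surveillance=int(self.years_since_surveillance[i]),
            alive=bool(self.alive[i]), survivor=bool(self.survivor[i]),
        )


def interpolate_population(
    counts_2016: pd.Series, counts_2021: pd.Series, target_year: float,
    group: str = "", year_lo: int = 2016, year_hi: int = 2021,
) -> PopulationTable:
    """Linearly interpolate census counts to the target year, per age.

    Exact at both census endpoints; per-age counts vary monotonically
    between them.
    """
    if not (year_lo <= target_year <= year_hi):
        raise ValueError(f"target_year {target_year} outside [{year_lo}, {year_hi}]")
    a16 = np.asarray(counts_2016.index, dtype=int)
    a21 = np.asarray(counts_2021.index, dtype=int)
    if not np.array_equal(a16, a21):
        raise ValueError("census tables cover different ages")
    w = (target_year - year_lo) / (year_hi - year_lo)
    c16 = counts_2016.to_numpy(dtype=float)
    c21 = counts_2021.to_numpy(dtype=float)
    table = PopulationTable(
        ages=a16, counts_2016=c16, counts_2021=c21,
        counts_target=(1.0 - w) * c16 + w * c21,
        target_year=target_year, group=group,
    )
    table.validate()
    return table


def sample_cohort(pop_table: PopulationTable, n: int,
                  seed: int | np.random.Generator = 0) -> Cohort:
    """Sample ``n`` individuals with ages proportional to the target counts."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    counts = np.asarray(pop_table.counts_target, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("population table has no positive counts")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ages = rng.choice(pop_table.ages, size=n, p=counts / total)
    return Cohort.of_ages(np.sort(ages))
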