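"""Synthetic stand-ins for the unavailable raw inputs, with known truth.

Three generators emulate the data the analysis would otherwise load:

* census-like single-year-of-age counts for 2016 and 2021 whose linear
  interpolation to 2019 hits the published eligible-population totals
  exactly (17,522 Arabic / 38,660 Mandarin speakers aged 50-74);
* monthly kit-return series for a control and an intervention period with
  negative-binomial dispersion around a known true rate ratio, for
  effect-recovery tests;
* stage-graded five-year survival curves and an age-increasing background
  life table (Gompertz-Makeham shape).  These are documented approximations
  of the unpublished survival and mortality inputs, not reconstructions,
  and every downstream result that depends on them is approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effectiveness import MonthlySeries

__all__ = ["GeneratorSpec", "gen_census_tables", "gen_monthly_kit_series",
           "gen_survival_and_life_tables"]

_POPULATION_TARGETS = {"arabic": 17_522.0, "mandarin": 38_660.0}


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic-data generators; defaults are the study
    conditions."""

    seed: int = 0
    group: str = "arabic"
    target_total_2019: float | None = None   # None: published total for group
    census_growth: float = 1.15              # 2021 total / 2016 total
    age_decay_2016: float = 0.045            # exponential age-profile slope
    age_decay_2021: float = 0.040
    ages: tuple[int, int] = (50, 74)
    # kit-return series
    baseline_return_rate: float | None = None  # None: group baseline
    true_rate_ratio: float = 1.18
    dispersion: float = 60.0                 # NB size parameter; larger -> Poisson
    monthly_kits_sent: float | None = None   # None: population / 24
    months: tuple[int, ...] = tuple(range(3, 12))  # March-November
    # survival / mortality fixtures
    survival_5y_targets: tuple[float, float, float, float] = (0.95, 0.85, 0.65, 0.15)
    makeham_a: float = 0.0005
    gompertz_b: float = 0.0025
    gompertz_c: float = 0.092
    max_age: int = 100

    def resolved_total(self) -> float:
        if self.target_total_2019 is not None:
            return float(self.target_total_2019)
        try:
            return _POPULATION_TARGETS[self.group]
        except KeyError:
            raise ValueError(f"no default population total for group {self.group!r}")

    def resolved_return_rate(self) -> float:
        if self.baseline_return_rate is not None:
            return float(self.baseline_return_rate)
        return {"arabic": 0.307, "mandarin": 0.40}[self.group]


def gen_census_tables(spec: GeneratorSpec) -> tuple[pd.Series, pd.Series]:
    """Smooth census-year age profiles whose 2019 interpolation is exact.

    The 2019 interpolation weight between the 2016 and 2021 censuses is 0.6;
    endpoint totals are solved so that 0.4*T2016 + 0.6*T2021 equals the
    requested total, with the stated inter-census growth.
    """
    target = spec.resolved_total()
    if target <= 0:
        raise ValueError("target total must be positive")
    g = spec.census_growth
    t2016 = target / (0.4 + 0.6 * g)
    t2021 = g * t2016

    ages = np.arange(spec.ages[0], spec.ages[1] + 1)
    w16 = np.exp(-spec.age_decay_2016 * (ages - ages[0]))
    w21 = np.exp(-spec.age_decay_2021 * (ages - ages[0]))
    c2016 = pd.Series(w16 / w16.sum() * t2016, index=ages, name="count_2016")
    c2021 = pd.Series(w21 / w21.sum() * t2021, index=ages, name="count_2021")
    return c2016, c2021


def gen_monthly_kit_series(spec: GeneratorSpec) -> tuple[MonthlySeries, MonthlySeries]:
    """Control- and intervention-period kit-return series.

    Monthly returns are negative-binomial around rate x kits-sent, with the
    intervention-period rate equal to the control rate times
    ``spec.true_rate_ratio`` (the recorded ground truth for recovery tests).
    """
    if spec.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(spec.seed)
    months = np.asarray(spec.months)
    sent_level = spec.monthly_kits_sent
    if sent_level is None:
        sent_level = spec.resolved_total() / 24.0
    base_rate = spec.resolved_return_rate()

    def _one(period: str, rate: float) -> MonthlySeries:
        # mild seasonal variation in mail-out volume
        sent = np.round(sent_level * (1.0 + 0.1 * np.sin(2 * np.pi * months / 12.0)))
        mu = rate * sent
        k = spec.dispersion
        returned = rng.negative_binomial(k, k / (k + mu))
        returned = np.minimum(returned, sent).astype(float)
        series = MonthlySeries(area=spec.group, period=period, months=months,
                               kits_sent=sent, kits_returned=returned)
        series.validate(window=(int(months.min()), int(months.max())))
        return series

    control = _one("control", base_rate)
    intervention = _one("intervention", min(base_rate * spec.true_rate_ratio, 1.0))
    return control, intervention


def gen_survival_and_life_tables(
    spec: GeneratorSpec,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Survival-by-stage fixture and background life table.

    Returns a mapping of ACPS stage to conditional annual survival for years
    1-5 after diagnosis (constant conditional survival whose five-year
    product hits the stage's cumulative target exactly) and a vector of
    annual death probabilities q(age) for ages 0..max_age with a
    Gompertz-Makeham shape, forced to 1 at the maximum age.
    """
    targets = spec.survival_5y_targets
    if any(a < b for a, b in zip(targets, targets[1:])):
        raise ValueError(
            "five-year survival targets must be non-increasing from stage A to D")
    survival = {}
    for stage, s5 in zip("ABCD", targets):
        annual = s5 ** (1.0 / 5.0) if s5 > 0 else 0.0
        survival[stage] = np.full(5, annual)

    ages = np.arange(spec.max_age + 1)
    q = spec.makeham_a + spec.gompertz_b * np.exp(spec.gompertz_c * (ages - 50.0))
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0  # maximum attainable age
    return survival, q
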