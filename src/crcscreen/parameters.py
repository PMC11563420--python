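"""Model parameters: loading, validation, derivations and PSA sampling.

The packaged defaults mirror the published parameter tables for the
microsimulation: age-banded colorectal-cancer (CRC) and adenoma incidence,
annual transition probabilities along the adenoma-carcinoma pathway,
screening-pathway rates, stage distributions at diagnosis, the cost schedule
and the utility schedule.  Survival-by-stage and background-mortality tables
are not published; documented synthetic fixtures from
:mod:`crcscreen.synthetic_data` stand in and can be replaced by the user.

Probabilistic sensitivity analysis (PSA) draws every parameter with a printed
uncertainty range from a uniform distribution over that range; parameters
without a range stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from ._states import STAGES

__all__ = [
    "ParameterError",
    "ModelParameters",
    "CostSchedule",
    "UtilitySchedule",
    "PSASpec",
    "load_parameters",
    "save_parameters",
    "derive_adenoma_incidence",
    "default_psa_spec",
    "build_psa_sampler",
]

CRC_BANDS = ("50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+")
ADENOMA_BANDS = ("50-54", "55-59", "60-64", "65+")
# band label -> (age_lo, age_hi) ; hi is inclusive
_CRC_BAND_EDGES = {
    "50-54": (50, 54), "55-59": (55, 59), "60-64": (60, 64), "65-69": (65, 69),
    "70-74": (70, 74), "75-79": (75, 79), "80-84": (80, 84), "85+": (85, 200),
}
_ADENOMA_BAND_EDGES = {
    "50-54": (50, 54), "55-59": (55, 59), "60-64": (60, 64), "65+": (65, 200),
}
TRANSITION_KEYS = ("low_to_high", "high_to_crc", "a_to_b", "b_to_c", "c_to_d")
GROUPS = ("arabic", "mandarin")
LANGUAGE_STRATA = ("lote", "english")

DEFAULT_SCREENING_AGES = frozenset(range(50, 75, 2))


class ParameterError(ValueError):
    """A parameter failed validation; the message names the offending field."""


def _check_prob(name: str, value: float, errors: list[str]) -> None:
    if not (0.0 <= value <= 1.0):
        errors.append(f"{name}={value!r} outside [0, 1]")


@dataclass
class ModelParameters:
    """Full natural-history and screening-pathway parameter set."""

    crc_incidence_by_band: dict[str, float]
    progressive_adenoma_incidence_by_band: dict[str, float]
    progressive_fraction: float
    transition_probs: dict[str, float]
    transition_ranges: dict[str, tuple[float, float]]
    symptomatic_diagnosis_prob_by_stage: dict[str, float]
    symptomatic_diagnosis_ranges: dict[str, tuple[float, float]]
    stage_distribution_screened: np.ndarray
    stage_distribution_not_screened: np.ndarray
    colonoscopy_prevalence_raw: np.ndarray  # free / low-risk / high-risk / CRC
    positivity_rate_by_group: dict[str, float]
    colonoscopy_followup_by_group: dict[str, float]
    participation_baseline_by_group: dict[str, float]
    survival_by_stage_year: dict[str, np.ndarray]  # conditional annual survival, years 1-5
    background_mortality_by_age: np.ndarray  # q(age), indexed 0..max_age
    max_age: int = 100
    surveillance_interval: int = 5
    surveillance_max_age: int = 75
    screening_ages: frozenset = DEFAULT_SCREENING_AGES
    # derived in __post_init__ / load
    all_adenoma_incidence_by_band: dict[str, float] = field(default_factory=dict)
    low_risk_adenoma_incidence_by_band: dict[str, float] = field(default_factory=dict)
    # printed table rows retained for reference (unused by default)
    progressive_adenoma_incidence_printed: dict[str, float] = field(default_factory=dict)
    all_adenoma_incidence_printed: dict[str, float] = field(default_factory=dict)
    low_risk_adenoma_incidence_printed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage_distribution_screened = np.asarray(
            self.stage_distribution_screened, dtype=float
        )
        self.stage_distribution_not_screened = np.asarray(
            self.stage_distribution_not_screened, dtype=float
        )
        self.colonoscopy_prevalence_raw = np.asarray(
            self.colonoscopy_prevalence_raw, dtype=float
        )
        self.background_mortality_by_age = np.asarray(
            self.background_mortality_by_age, dtype=float
        )
        self.survival_by_stage_year = {
            s: np.asarray(v, dtype=float) for s, v in self.survival_by_stage_year.items()
        }
        if not self.all_adenoma_incidence_by_band:
            prog = self.progressive_adenoma_incidence_by_band
            self.all_adenoma_incidence_by_band = {
                b: v / self.progressive_fraction for b, v in prog.items()
            }
            self.low_risk_adenoma_incidence_by_band = {
                b: self.all_adenoma_incidence_by_band[b] - v for b, v in prog.items()
            }

    @property
    def colonoscopy_prevalence(self) -> np.ndarray:
        """Colonoscopy-outcome probabilities renormalized to sum to 1.

        The printed values sum to 1.0227; the four outcomes are exhaustive,
        so ratios are preserved and the vector rescaled.
        """
        raw = self.colonoscopy_prevalence_raw
        return raw / raw.sum()

    # -- age-indexed lookups ------------------------------------------------
    def _band_array(self, by_band: Mapping[str, float], edges: Mapping[str, tuple]) -> np.ndarray:
        out = np.zeros(self.max_age + 1)
        for band, value in by_band.items():
            lo, hi = edges[band]
            out[lo: min(hi, self.max_age) + 1] = value
        return out

    def crc_incidence_by_age(self) -> np.ndarray:
        return self._band_array(self.crc_incidence_by_band, _CRC_BAND_EDGES)

    def progressive_incidence_by_age(self) -> np.ndarray:
        return self._band_array(self.progressive_adenoma_incidence_by_band, _ADENOMA_BAND_EDGES)

    def low_risk_incidence_by_age(self) -> np.ndarray:
        return self._band_array(self.low_risk_adenoma_incidence_by_band, _ADENOMA_BAND_EDGES)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        for band, v in self.crc_incidence_by_band.items():
            _check_prob(f"crc_incidence[{band}]", v, errors)
        for band, v in self.progressive_adenoma_incidence_by_band.items():
            _check_prob(f"progressive_adenoma_incidence[{band}]", v, errors)
        for band, v in self.all_adenoma_incidence_by_band.items():
            _check_prob(f"all_adenoma_incidence[{band}]", v, errors)
            low = self.low_risk_adenoma_incidence_by_band[band]
            _check_prob(f"low_risk_adenoma_incidence[{band}]", low, errors)
        if not (0.0 < self.progressive_fraction <= 1.0):
            errors.append(f"progressive_fraction={self.progressive_fraction!r} outside (0, 1]")
        for key in TRANSITION_KEYS:
            if key not in self.transition_probs:
                errors.append(f"transition_probs missing {key}")
                continue
            _check_prob(f"transition_probs[{key}]", self.transition_probs[key], errors)
        for stage in STAGES:
            if stage not in self.symptomatic_diagnosis_prob_by_stage:
                errors.append(f"symptomatic_diagnosis_prob missing stage {stage}")
                continue
            _check_prob(
                f"symptomatic_diagnosis_prob[{stage}]",
                self.symptomatic_diagnosis_prob_by_stage[stage], errors,
            )
        for name, vec in (
            ("stage_distribution_screened", self.stage_distribution_screened),
            ("stage_distribution_not_screened", self.stage_distribution_not_screened),
        ):
            if vec.shape != (4,):
                errors.append(f"{name} must have 4 entries")
            elif not np.isclose(vec.sum(), 1.0, atol=1e-9):
                errors.append(f"{name} sums to {vec.sum():.6f}, expected 1")
        if self.colonoscopy_prevalence_raw.shape != (4,):
            errors.append("colonoscopy_prevalence must have 4 entries")
        if np.any(self.colonoscopy_prevalence_raw < 0):
            errors.append("colonoscopy_prevalence has negative entries")
        for name, d in (
            ("positivity_rate", self.positivity_rate_by_group),
            ("colonoscopy_followup", self.colonoscopy_followup_by_group),
            ("participation_baseline", self.participation_baseline_by_group),
        ):
            for g, v in d.items():
                _check_prob(f"{name}[{g}]", v, errors)
        for stage in STAGES:
            surv = self.survival_by_stage_year.get(stage)
            if surv is None or len(surv) != 5:
                errors.append(f"survival_by_stage_year[{stage}] must cover years 1-5")
            elif np.any((surv < 0) | (surv > 1)):
                errors.append(f"survival_by_stage_year[{stage}] outside [0, 1]")
        q = self.background_mortality_by_age
        if len(q) < self.max_age + 1:
            errors.append("background_mortality_by_age must cover ages 0..max_age")
        elif np.any((q < 0) | (q > 1)):
            errors.append("background_mortality_by_age outside [0, 1]")
        if errors:
            raise ParameterError("; ".join(errors))


@dataclass
class CostSchedule:
    """Unit costs (2019 Australian dollars) of screening and treatment."""

    fobt_kit: float
    packaging_postage: float
    lab_analysis: float
    gp_consult: float
    colonoscopy_no_polypectomy: float
    colonoscopy_polypectomy: float
    treatment_by_stage: dict[str, float]
    treatment_ranges: dict[str, tuple[float, float]]
    intervention_total_by_group: dict[str, float]
    eligible_population_by_group: dict[str, float]
    reference_year: int = 2019

    def validate(self) -> None:
        errors: list[str] = []
        for name in (
            "fobt_kit", "packaging_postage", "lab_analysis", "gp_consult",
            "colonoscopy_no_polypectomy", "colonoscopy_polypectomy",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} is negative")
        for stage in STAGES:
            v = self.treatment_by_stage.get(stage)
            if v is None:
                errors.append(f"treatment_by_stage missing stage {stage}")
                continue
            if v < 0:
                errors.append(f"treatment_by_stage[{stage}] is negative")
            lo, hi = self.treatment_ranges.get(stage, (v, v))
            if not (lo <= v <= hi):
                errors.append(f"treatment_ranges[{stage}]=({lo}, {hi}) does not bracket {v}")
        if errors:
            raise ParameterError("; ".join(errors))


@dataclass
class UtilitySchedule:
    """Health-state utility weights, discounting and the WTP threshold."""

    utility_crc_stage: dict[str, float]
    utility_norm_bands: tuple[tuple[int, int, float], ...] = (
        (50, 69, 0.80), (70, 79, 0.76), (80, 200, 0.70),
    )
    discount_rate: float = 0.05
    wtp_threshold: float = 50_000.0

    def norm_for_age(self, age: int) -> float:
        for lo, hi, u in self.utility_norm_bands:
            if lo <= age <= hi:
                return u
        # below the first band (cohort enters at 50+): use the first band
        return self.utility_norm_bands[0][2]

    def norm_by_age(self, max_age: int = 150) -> np.ndarray:
        ages = np.arange(max_age + 1)
        out = np.full(max_age + 1, self.utility_norm_bands[0][2])
        for lo, hi, u in self.utility_norm_bands:
            out[(ages >= lo) & (ages <= hi)] = u
        return out

    def validate(self) -> None:
        errors: list[str] = []
        for stage, u in self.utility_crc_stage.items():
            _check_prob(f"utility_crc_stage[{stage}]", u, errors)
        for lo, hi, u in self.utility_norm_bands:
            _check_prob(f"utility_norm[{lo}-{hi}]", u, errors)
        if not (0.0 <= self.discount_rate < 1.0):
            errors.append(f"discount_rate={self.discount_rate!r} outside [0, 1)")
        if errors:
            raise ParameterError("; ".join(errors))


@dataclass
class PSASpec:
    """Which parameters vary in the PSA, and the trial dimensions.

    ``entries`` maps a parameter name (matching the packaged CSV naming) to a
    (low, high) bound pair sampled uniformly.
    """

    entries: dict[str, tuple[float, float]]
    n_trials: int = 2000
    n_patients_per_trial: int = 10_000


# ---------------------------------------------------------------------------
# loading


def _read_table(path, package_file: str) -> pd.DataFrame:
    if path is not None:
        return pd.read_csv(path)
    with resources.files("crcscreen.data").joinpath(package_file).open() as fh:
        return pd.read_csv(fh)


def _rows(df: pd.DataFrame, overrides: Mapping[str, float] | None) -> dict[str, dict]:
    table: dict[str, dict] = {}
    for rec in df.to_dict("records"):
        table[rec["name"]] = rec
    if overrides:
        for name, value in overrides.items():
            if name not in table:
                raise ParameterError(f"unknown parameter {name!r} in config overrides")
            table[name] = {**table[name], "value": value}
    return table


def _val(table: dict, name: str) -> float:
    try:
        return float(table[name]["value"])
    except KeyError as exc:
        raise ParameterError(f"missing required parameter {name!r}") from exc


def _rng_pair(table: dict, name: str) -> tuple[float, float] | None:
    rec = table.get(name)
    if rec is None:
        return None
    lo, hi = rec.get("low"), rec.get("high")
    if lo is None or hi is None or pd.isna(lo) or pd.isna(hi):
        return None
    return float(lo), float(hi)


_BAND_SUFFIX = {"50-54": "50_54", "55-59": "55_59", "60-64": "60_64",
                "65-69": "65_69", "70-74": "70_74", "75-79": "75_79",
                "80-84": "80_84", "85+": "85p", "65+": "65p"}


def load_parameters(
    config: Mapping[str, float] | None = None,
    *,
    parameters_path=None,
    costs_path=None,
    utilities_path=None,
    survival_by_stage_year: Mapping[str, np.ndarray] | None = None,
    background_mortality_by_age: np.ndarray | None = None,
    incidence_preset: str = "derived",
    low_risk_preset: str = "derived",
) -> tuple[ModelParameters, CostSchedule, UtilitySchedule]:
    """Load and validate the full parameter set.

    Parameters
    ----------
    config
        Optional mapping of parameter names (as in the packaged CSVs) to
        override values.  Unknown names raise :class:`ParameterError`.
    survival_by_stage_year, background_mortality_by_age
        User-supplied replacements for the synthetic fixtures.
    incidence_preset
        ``"derived"`` (default) computes progressive-adenoma incidence from
        the CRC incidence schedule by the 20-year-shift rule, which keeps
        the model's long-run cancer incidence consistent with the registry
        rates it was built from.  ``"printed"`` uses the published
        progressive-incidence rows, which are roughly twice the values the
        stated rule yields (a documented source inconsistency).
    low_risk_preset
        ``"derived"`` (default) computes low-risk adenoma incidence from the
        progressive incidence and the progressive fraction; ``"printed"``
        uses the printed (internally inconsistent) table rows instead.
    """
    ptab = _rows(_read_table(parameters_path, "model_parameters.csv"), config)
    ctab = _rows(_read_table(costs_path, "costs.csv"), None)
    utab = _rows(_read_table(utilities_path, "utilities.csv"), None)

    crc = {b: _val(ptab, f"crc_incidence_{_BAND_SUFFIX[b]}") for b in CRC_BANDS}
    fraction_pre = _val(ptab, "progressive_fraction")
    if incidence_preset == "derived":
        prog, _, _ = derive_adenoma_incidence(crc, fraction_pre)
    elif incidence_preset == "printed":
        prog = {b: _val(ptab, f"progressive_adenoma_incidence_{_BAND_SUFFIX[b]}")
                for b in ADENOMA_BANDS}
    else:
        raise ParameterError(f"unknown incidence_preset {incidence_preset!r}")
    prog_printed = {b: _val(ptab, f"progressive_adenoma_incidence_{_BAND_SUFFIX[b]}")
                    for b in ADENOMA_BANDS}
    all_printed = {b: _val(ptab, f"all_adenoma_incidence_printed_{_BAND_SUFFIX[b]}")
                   for b in ADENOMA_BANDS}
    low_printed = {b: _val(ptab, f"low_risk_adenoma_incidence_printed_{_BAND_SUFFIX[b]}")
                   for b in ADENOMA_BANDS}
    fraction = _val(ptab, "progressive_fraction")

    transitions = {k: _val(ptab, f"transition_{k}") for k in TRANSITION_KEYS}
    t_ranges = {k: r for k in TRANSITION_KEYS
                if (r := _rng_pair(ptab, f"transition_{k}")) is not None}
    sympt = {s: _val(ptab, f"symptomatic_dx_{s.lower()}") for s in STAGES}
    s_ranges = {s: r for s in STAGES
                if (r := _rng_pair(ptab, f"symptomatic_dx_{s.lower()}")) is not None}

    def _stagevec(prefix: str) -> np.ndarray:
        return np.array([_val(ptab, f"{prefix}_{s.lower()}") for s in STAGES])

    prev = np.array([_val(ptab, f"colonoscopy_prevalence_{k}")
                     for k in ("free", "low", "high", "crc")])

    max_age = int(_val(ptab, "max_age"))
    if survival_by_stage_year is None or background_mortality_by_age is None:
        from .synthetic_data import GeneratorSpec, gen_survival_and_life_tables

        surv_fix, mort_fix = gen_survival_and_life_tables(GeneratorSpec(max_age=max_age))
        if survival_by_stage_year is None:
            survival_by_stage_year = surv_fix
        if background_mortality_by_age is None:
            background_mortality_by_age = mort_fix

    params = ModelParameters(
        crc_incidence_by_band=crc,
        progressive_adenoma_incidence_by_band=prog,
        progressive_fraction=fraction,
        transition_probs=transitions,
        transition_ranges=t_ranges,
        symptomatic_diagnosis_prob_by_stage=sympt,
        symptomatic_diagnosis_ranges=s_ranges,
        stage_distribution_screened=_stagevec("stage_screened"),
        stage_distribution_not_screened=_stagevec("stage_not_screened"),
        colonoscopy_prevalence_raw=prev,
        positivity_rate_by_group={g: _val(ptab, f"positivity_{g}") for g in LANGUAGE_STRATA},
        colonoscopy_followup_by_group={g: _val(ptab, f"followup_{g}") for g in LANGUAGE_STRATA},
        participation_baseline_by_group={g: _val(ptab, f"participation_{g}") for g in GROUPS},
        survival_by_stage_year=dict(survival_by_stage_year),
        background_mortality_by_age=np.asarray(background_mortality_by_age, dtype=float),
        max_age=max_age,
        surveillance_interval=int(_val(ptab, "surveillance_interval")),
        surveillance_max_age=int(_val(ptab, "surveillance_max_age")),
        progressive_adenoma_incidence_printed=prog_printed,
        all_adenoma_incidence_printed=all_printed,
        low_risk_adenoma_incidence_printed=low_printed,
    )
    if low_risk_preset == "printed":
        params.low_risk_adenoma_incidence_by_band = dict(low_printed)
    elif low_risk_preset != "derived":
        raise ParameterError(f"unknown low_risk_preset {low_risk_preset!r}")

    costs = CostSchedule(
        fobt_kit=_val(ctab, "fobt_kit"),
        packaging_postage=_val(ctab, "packaging_postage"),
        lab_analysis=_val(ctab, "lab_analysis"),
        gp_consult=_val(ctab, "gp_consult"),
        colonoscopy_no_polypectomy=_val(ctab, "colonoscopy_no_polypectomy"),
        colonoscopy_polypectomy=_val(ctab, "colonoscopy_polypectomy"),
        treatment_by_stage={s: _val(ctab, f"treatment_{s.lower()}") for s in STAGES},
        treatment_ranges={s: r for s in STAGES
                          if (r := _rng_pair(ctab, f"treatment_{s.lower()}")) is not None},
        intervention_total_by_group={g: _val(ctab, f"intervention_total_{g}") for g in GROUPS},
        eligible_population_by_group={g: _val(ctab, f"eligible_population_{g}") for g in GROUPS},
        reference_year=int(_val(ctab, "reference_year")),
    )
    utilities = UtilitySchedule(
        utility_crc_stage={s: _val(utab, f"utility_stage_{s.lower()}") for s in STAGES},
        utility_norm_bands=(
            (50, 69, _val(utab, "utility_norm_50_69")),
            (70, 79, _val(utab, "utility_norm_70_79")),
            (80, 200, _val(utab, "utility_norm_80p")),
        ),
        discount_rate=_val(utab, "discount_rate"),
        wtp_threshold=_val(utab, "wtp_threshold"),
    )
    params.validate()
    costs.validate()
    utilities.validate()
    return params, costs, utilities


def save_parameters(params: ModelParameters, costs: CostSchedule,
                    utilities: UtilitySchedule, directory) -> None:
    """Write the parameter set back to the three-CSV on-disk schema.

    A reload of the written files reproduces the in-memory values exactly
    (floats are serialized with full repr precision).
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = []
    for b in CRC_BANDS:
        rows.append((f"crc_incidence_{_BAND_SUFFIX[b]}", params.crc_incidence_by_band[b], "", ""))
    for b in ADENOMA_BANDS:
        rows.append((f"progressive_adenoma_incidence_{_BAND_SUFFIX[b]}",
                     params.progressive_adenoma_incidence_printed.get(
                         b, params.progressive_adenoma_incidence_by_band[b]), "", ""))
    for b in ADENOMA_BANDS:
        rows.append((f"all_adenoma_incidence_printed_{_BAND_SUFFIX[b]}",
                     params.all_adenoma_incidence_printed.get(b, ""), "", ""))
    for b in ADENOMA_BANDS:
        rows.append((f"low_risk_adenoma_incidence_printed_{_BAND_SUFFIX[b]}",
                     params.low_risk_adenoma_incidence_printed.get(b, ""), "", ""))
    rows.append(("progressive_fraction", params.progressive_fraction, "", ""))
    for k in TRANSITION_KEYS:
        lo, hi = params.transition_ranges.get(k, ("", ""))
        rows.append((f"transition_{k}", params.transition_probs[k], lo, hi))
    for s in STAGES:
        lo, hi = params.symptomatic_diagnosis_ranges.get(s, ("", ""))
        rows.append((f"symptomatic_dx_{s.lower()}",
                     params.symptomatic_diagnosis_prob_by_stage[s], lo, hi))
    for s, v in zip(STAGES, params.stage_distribution_screened):
        rows.append((f"stage_screened_{s.lower()}", v, "", ""))
    for s, v in zip(STAGES, params.stage_distribution_not_screened):
        rows.append((f"stage_not_screened_{s.lower()}", v, "", ""))
    for k, v in zip(("free", "low", "high", "crc"), params.colonoscopy_prevalence_raw):
        rows.append((f"colonoscopy_prevalence_{k}", v, "", ""))
    for g in LANGUAGE_STRATA:
        rows.append((f"positivity_{g}", params.positivity_rate_by_group[g], "", ""))
        rows.append((f"followup_{g}", params.colonoscopy_followup_by_group[g], "", ""))
    for g in GROUPS:
        rows.append((f"participation_{g}", params.participation_baseline_by_group[g], "", ""))
    rows.append(("max_age", params.max_age, "", ""))
    rows.append(("surveillance_interval", params.surveillance_interval, "", ""))
    rows.append(("surveillance_max_age", params.surveillance_max_age, "", ""))
    pd.DataFrame(rows, columns=["name", "value", "low", "high"]).assign(
        units="", source=""
    ).to_csv(directory / "model_parameters.csv", index=False)

    crows = [
        ("fobt_kit", costs.fobt_kit, "", ""),
        ("packaging_postage", costs.packaging_postage, "", ""),
        ("lab_analysis", costs.lab_analysis, "", ""),
        ("gp_consult", costs.gp_consult, "", ""),
        ("colonoscopy_no_polypectomy", costs.colonoscopy_no_polypectomy, "", ""),
        ("colonoscopy_polypectomy", costs.colonoscopy_polypectomy, "", ""),
    ]
    for s in STAGES:
        lo, hi = costs.treatment_ranges.get(s, ("", ""))
        crows.append((f"treatment_{s.lower()}", costs.treatment_by_stage[s], lo, hi))
    for g in GROUPS:
        crows.append((f"intervention_total_{g}", costs.intervention_total_by_group[g], "", ""))
        crows.append((f"eligible_population_{g}", costs.eligible_population_by_group[g], "", ""))
    crows.append(("reference_year", costs.reference_year, "", ""))
    pd.DataFrame(crows, columns=["name", "value", "low", "high"]).assign(
        units="", source=""
    ).to_csv(directory / "costs.csv", index=False)

    urows = [(f"utility_stage_{s.lower()}", utilities.utility_crc_stage[s], "", "")
             for s in STAGES]
    urows += [
        ("utility_norm_50_69", utilities.utility_norm_bands[0][2], "", ""),
        ("utility_norm_70_79", utilities.utility_norm_bands[1][2], "", ""),
        ("utility_norm_80p", utilities.utility_norm_bands[2][2], "", ""),
        ("discount_rate", utilities.discount_rate, "", ""),
        ("wtp_threshold", utilities.wtp_threshold, "", ""),
    ]
    pd.DataFrame(urows, columns=["name", "value", "low", "high"]).assign(
        units="", source=""
    ).to_csv(directory / "utilities.csv", index=False)


# ---------------------------------------------------------------------------
# derivations


_SHIFT_20Y = {"50-54": "70-74", "55-59": "75-79", "60-64": "80-84", "65+": "85+"}


def derive_adenoma_incidence(
    crc_incidence_by_band: Mapping[str, float], progressive_fraction: float
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Derive adenoma incidence schedules from CRC incidence.

    Progressive-adenoma incidence at band *b* equals CRC incidence 20 years
    later (band *b* + 20y); all-adenoma incidence is progressive divided by
    the progressive fraction, and low-risk incidence is the difference.

    Returns ``(progressive, all_adenomas, low_risk)`` keyed by adenoma band.
    """
    if not (0.0 < progressive_fraction <= 1.0):
        raise ParameterError(
            f"progressive_fraction={progressive_fraction!r} outside (0, 1]"
        )
    progressive: dict[str, float] = {}
    for band, src in _SHIFT_20Y.items():
        if src not in crc_incidence_by_band:
            raise ParameterError(
                f"CRC incidence band {src!r} (20-year shift of {band!r}) is missing"
            )
        progressive[band] = float(crc_incidence_by_band[src])
    all_adenomas = {b: v / progressive_fraction for b, v in progressive.items()}
    low_risk = {b: all_adenomas[b] - v for b, v in progressive.items()}
    return progressive, all_adenomas, low_risk


# ---------------------------------------------------------------------------
# PSA


def default_psa_spec(params: ModelParameters, costs: CostSchedule,
                     n_trials: int = 2000, n_patients: int = 10_000) -> PSASpec:
    """Uniform sampling bounds for every parameter with a printed range."""
    entries: dict[str, tuple[float, float]] = {}
    for k, r in params.transition_ranges.items():
        entries[f"transition_{k}"] = r
    for s, r in params.symptomatic_diagnosis_ranges.items():
        entries[f"symptomatic_dx_{s.lower()}"] = r
    for s, r in costs.treatment_ranges.items():
        entries[f"treatment_{s.lower()}"] = r
    return PSASpec(entries=entries, n_trials=n_trials, n_patients_per_trial=n_patients)


def psa_draw(params: ModelParameters, costs: CostSchedule, spec: PSASpec,
             rng: np.random.Generator) -> tuple[ModelParameters, CostSchedule]:
    """One complete, validated parameter draw; unranged parameters stay fixed."""
    transitions = dict(params.transition_probs)
    sympt = dict(params.symptomatic_diagnosis_prob_by_stage)
    treat = dict(costs.treatment_by_stage)
    for name, (lo, hi) in spec.entries.items():
        value = float(rng.uniform(lo, hi))
        if name.startswith("transition_"):
            transitions[name.removeprefix("transition_")] = value
        elif name.startswith("symptomatic_dx_"):
            sympt[name.removeprefix("symptomatic_dx_").upper()] = value
        elif name.startswith("treatment_"):
            treat[name.removeprefix("treatment_").upper()] = value
        else:
            raise ParameterError(f"PSA entry {name!r} does not map to a parameter")
    new_params = replace(
        params,
        transition_probs=transitions,
        symptomatic_diagnosis_prob_by_stage=sympt,
    )
    # drawn treatment costs always lie inside the stated ranges
    new_costs = replace(costs, treatment_by_stage=treat)
    new_params.validate()
    new_costs.validate()
    return new_params, new_costs


def build_psa_sampler(params: ModelParameters, costs: CostSchedule, spec: PSASpec,
                      seed: int) -> Iterator[tuple[ModelParameters, CostSchedule]]:
    """Reproducible stream of ``spec.n_trials`` validated parameter draws."""
    rng = np.random.default_rng(seed)
    for _ in range(spec.n_trials):
        yield psa_draw(params, costs, spec, rng)
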