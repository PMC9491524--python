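"""Synthetic inputs with known ground truth for the whole pipeline.

No survey microdata or epidemiology extracts ship with the package; this
module generates every input the analysis needs — paired pre/post survey
cohorts, a population table by single year of age and sex, per-disease
epidemiology bundles and cost-item tables — from explicit parameters, so
every downstream stage can be tested against a known truth.

The defaults emulate the study conditions: a cohort of ~1 500 respondents
aged 25-49 surveyed before and after a campaign, an adult state population
with Gompertz-shaped all-cause mortality, and nine obesity-related diseases
whose incidence responds log-linearly to BMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DISEASES",
    "FEMALE_ONLY_DISEASES",
    "SurveyGenParams",
    "PopulationGenParams",
    "DiseaseGenParams",
    "PopulationBundle",
    "DiseaseEpiBundle",
    "generate_survey_cohort",
    "generate_population",
    "generate_disease_epi",
    "write_bundle_csvs",
]

#: the nine obesity-related diseases carried by the lifetable model
DISEASES = (
    "ischaemic_heart_disease",
    "hypertensive_heart_disease",
    "ischaemic_stroke",
    "diabetes",
    "osteoarthritis",
    "kidney_cancer",
    "colorectal_cancer",
    "endometrial_cancer",
    "breast_cancer",
)
#: diseases modelled in females only (incidence zeroed for males)
FEMALE_ONLY_DISEASES = ("endometrial_cancer", "breast_cancer")

_CANCERS = ("kidney_cancer", "colorectal_cancer", "endometrial_cancer",
            "breast_cancer")


# ---------------------------------------------------------------------------
# Survey cohort


@dataclass
class SurveyGenParams:
    """Ground-truth parameters of a paired-cohort consumption survey.

    ``true_change`` maps category -> serves/week change (negative =
    reduction).  pre and post serves are bivariate normal with the stated
    correlation, then clipped at zero (nobody reports negative consumption);
    at the default pre_mean/pre_sd the clipping bias on the paired mean is
    about +0.01 serves/week.
    """

    n_respondents: int = 1504
    food_categories: tuple[str, ...] = ("sugary_drinks", "sweet_food", "fast_food")
    true_change: dict = field(default_factory=lambda: {
        "sugary_drinks": -0.78, "sweet_food": -0.28, "fast_food": 0.0})
    pre_mean: float = 7.0
    pre_sd: float = 3.0
    pre_post_correlation: float = 0.7
    retention: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.n_respondents < 2:
            raise ValueError("n_respondents must be >= 2")
        if not self.pre_sd > 0:
            raise ValueError("pre_sd must be positive")
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if not -1 <= self.pre_post_correlation <= 1:
            raise ValueError("pre_post_correlation must be in [-1, 1]")


def generate_survey_cohort(params: SurveyGenParams) -> pd.DataFrame:
    """Generate retained paired records, long format.

    Returns columns (respondent_id, category, pre, post) in serves/week.
    Retention is binomial per respondent; only retained respondents (both
    waves complete) appear, matching a paired-t analysis of completers.
    """
    rng = np.random.default_rng(params.seed)
    retained = rng.random(params.n_respondents) < params.retention
    ids = np.flatnonzero(retained)
    n = ids.size
    rho = params.pre_post_correlation
    frames = []
    for cat in params.food_categories:
        delta = params.true_change.get(cat, 0.0)
        pre = rng.normal(params.pre_mean, params.pre_sd, size=n)
        noise = rng.normal(0.0, 1.0, size=n)
        post = (params.pre_mean + delta
                + rho * (pre - params.pre_mean)
                + np.sqrt(1 - rho**2) * params.pre_sd * noise)
        frames.append(pd.DataFrame({
            "respondent_id": ids,
            "category": cat,
            "pre": np.clip(pre, 0.0, None),
            "post": np.clip(post, 0.0, None),
        }))
    return pd.concat(frames, ignore_index=True)


def survey_to_csv_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Decompose serves/week into the survey CSV dialect (days x times).

    Serves are rounded to integers; up to 7 serves map to (serves, 1), more
    frequent consumption maps to 7 days at the nearest integer times/day
    (a small discretisation of heavy consumers, documented in the methods
    note).
    """
    def decompose(s):
        s = int(round(s))
        if s <= 0:
            return 0, 0
        if s <= 7:
            return s, 1
        return 7, int(round(s / 7))

    rows = {"respondent_id": [], "category": [], "days_pre": [],
            "times_pre": [], "days_post": [], "times_post": []}
    for row in cohort.itertuples():
        dp, tp = decompose(row.pre)
        da, ta = decompose(row.post)
        rows["respondent_id"].append(row.respondent_id)
        rows["category"].append(row.category)
        rows["days_pre"].append(dp)
        rows["times_pre"].append(tp)
        rows["days_post"].append(da)
        rows["times_post"].append(ta)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Population


@dataclass
class PopulationGenParams:
    """Parameters of the synthetic adult population table.

    Mortality follows a Gompertz law acm = level * exp(slope * age), sex
    ratio applied to females; heights taper slightly with age.  Counts are
    persons per single-year stratum (default ~18 000, i.e. an adult state
    population of order 10^6).
    """

    age_min: int = 18
    age_max: int = 100
    count_per_stratum: float = 18_000.0
    height_male: float = 1.78
    height_female: float = 1.64
    height_age_slope: float = -0.0005  # m per year of age past 30
    bmi_mean: float = 27.5
    bmi_sd: float = 5.0
    gompertz_level: float = 3.0e-5
    gompertz_slope: float = 0.095
    female_mortality_ratio: float = 0.6
    yld_base: float = 0.05
    yld_age_slope: float = 0.0015  # per year of age past 18
    seed: int = 0

    def __post_init__(self):
        if self.age_max < self.age_min:
            raise ValueError("empty age range")
        if not self.bmi_sd > 0:
            raise ValueError("bmi_sd must be positive")
        if self.count_per_stratum < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PopulationBundle:
    """Population table: one row per (sex, age) stratum.

    Columns: sex ('male'/'female'), age, count, height_m, bmi_mean, bmi_sd,
    acm_rate (all-cause mortality per person-year), yld_rate (baseline
    years-lived-with-disability rate in [0, 1)).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if (t["count"] < 0).any():
            raise ValueError("negative population count")
        if not t["height_m"].between(1.0, 2.2, inclusive="neither").all():
            raise ValueError("heights must be in (1.0, 2.2) m")
        if not (t["acm_rate"] > 0).all():
            raise ValueError("mortality rates must be positive")
        if not t["yld_rate"].between(0, 1, inclusive="left").all():
            raise ValueError("yld_rate must be in [0, 1)")
        if not (t["bmi_sd"] > 0).all():
            raise ValueError("bmi_sd must be positive")

    def stratum(self, sex: str, age: int) -> pd.Series:
        hit = self.table[(self.table["sex"] == sex) & (self.table["age"] == age)]
        if hit.empty:
            raise KeyError(f"no stratum ({sex}, {age})")
        return hit.iloc[0]


def generate_population(params: PopulationGenParams | None = None) -> PopulationBundle:
    """Deterministic synthetic population over the requested age range."""
    p = params or PopulationGenParams()
    ages = np.arange(p.age_min, p.age_max + 1)
    rows = []
    for sex in ("male", "female"):
        base_h = p.height_male if sex == "male" else p.height_female
        mort_scale = 1.0 if sex == "male" else p.female_mortality_ratio
        height = base_h + p.height_age_slope * np.clip(ages - 30, 0, None)
        acm = mort_scale * p.gompertz_level * np.exp(p.gompertz_slope * ages)
        yld = np.clip(p.yld_base + p.yld_age_slope * (ages - p.age_min), 0, 0.95)
        rows.append(pd.DataFrame({
            "sex": sex,
            "age": ages,
            "count": p.count_per_stratum,
            "height_m": height,
            "bmi_mean": p.bmi_mean,
            "bmi_sd": p.bmi_sd,
            "acm_rate": acm,
            "yld_rate": yld,
        }))
    return PopulationBundle(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Disease epidemiology


@dataclass
class DiseaseGenParams:
    """Shape parameters for one disease's synthetic epidemiology.

    Incidence is exponential in age around a reference rate at age 60:
    i(a) = incidence_60 * exp(age_slope * (a - 60)).  Case fatality and
    remission are constant excess rates among prevalent cases; cancers have
    nonzero remission by default, chronic diseases zero.  ``rr_per_bmi_unit``
    is the relative risk of incidence per one kg/m^2 of BMI.
    """

    incidence_60: float
    age_slope: float
    case_fatality: float
    remission: float
    disability_weight: float
    annual_cost: float
    rr_per_bmi_unit: float

    def __post_init__(self):
        for name in ("incidence_60", "case_fatality", "remission"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.disability_weight < 1:
            raise ValueError("disability_weight must be in [0, 1)")
        if not self.rr_per_bmi_unit > 0:
            raise ValueError("rr_per_bmi_unit must be positive")


#: default epidemiology shapes, magnitudes in line with burden-of-disease
#: rates for an Australian adult population (per person-year; A$/year)
DEFAULT_DISEASE_PARAMS: dict[str, DiseaseGenParams] = {
    "ischaemic_heart_disease": DiseaseGenParams(8.0e-3, 0.085, 0.040, 0.0, 0.08, 6_000.0, 1.10),
    "hypertensive_heart_disease": DiseaseGenParams(8.0e-4, 0.080, 0.050, 0.0, 0.10, 4_000.0, 1.15),
    "ischaemic_stroke": DiseaseGenParams(3.0e-3, 0.090, 0.060, 0.0, 0.18, 7_000.0, 1.08),
    "diabetes": DiseaseGenParams(8.0e-3, 0.030, 0.015, 0.0, 0.05, 3_500.0, 1.20),
    "osteoarthritis": DiseaseGenParams(1.0e-2, 0.020, 0.0, 0.0, 0.10, 2_500.0, 1.06),
    "kidney_cancer": DiseaseGenParams(2.0e-4, 0.060, 0.080, 0.08, 0.15, 12_000.0, 1.06),
    "colorectal_cancer": DiseaseGenParams(1.2e-3, 0.070, 0.100, 0.08, 0.15, 15_000.0, 1.03),
    "endometrial_cancer": DiseaseGenParams(5.0e-4, 0.040, 0.050, 0.10, 0.12, 12_000.0, 1.10),
    "breast_cancer": DiseaseGenParams(2.0e-3, 0.020, 0.050, 0.10, 0.12, 12_000.0, 1.03),
}


@dataclass
class DiseaseEpiBundle:
    """Disease epidemiology table: one row per disease x sex x age.

    Columns: disease, sex, age, incidence, case_fatality, remission,
    disability_weight, annual_cost, rr_per_bmi_unit.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        for col in ("incidence", "case_fatality", "remission"):
            if (t[col] < 0).any():
                raise ValueError(f"negative {col}")
        if not t["disability_weight"].between(0, 1, inclusive="left").all():
            raise ValueError("disability_weight must be in [0, 1)")
        if not (t["rr_per_bmi_unit"] > 0).all():
            raise ValueError("rr_per_bmi_unit must be positive")

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.table["disease"].unique())


def generate_disease_epi(disease_params: dict[str, DiseaseGenParams] | None = None,
                         age_min: int = 18, age_max: int = 100) -> DiseaseEpiBundle:
    """Deterministic synthetic epidemiology bundle over an age range."""
    params = dict(DEFAULT_DISEASE_PARAMS) if disease_params is None else disease_params
    ages = np.arange(age_min, age_max + 1)
    rows = []
    for disease, dp in params.items():
        inc = dp.incidence_60 * np.exp(dp.age_slope * (ages - 60.0))
        inc = np.clip(inc, 0.0, 0.5)  # keep annual cycles stable
        for sex in ("male", "female"):
            sex_inc = inc if not (sex == "male" and disease in FEMALE_ONLY_DISEASES) else np.zeros_like(inc)
            rows.append(pd.DataFrame({
                "disease": disease,
                "sex": sex,
                "age": ages,
                "incidence": sex_inc,
                "case_fatality": dp.case_fatality,
                "remission": dp.remission,
                "disability_weight": dp.disability_weight,
                "annual_cost": dp.annual_cost,
                "rr_per_bmi_unit": dp.rr_per_bmi_unit,
            }))
    return DiseaseEpiBundle(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Writers


def write_bundle_csvs(outdir, survey_params: SurveyGenParams | None = None,
                      population_params: PopulationGenParams | None = None) -> dict:
    """Write the pipeline's CSV inputs plus a YAML manifest of true values.

    Emits survey.csv (days/times dialect), population.csv, disease_epi.csv
    and manifest.yaml; returns the manifest dict.
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sp = survey_params or SurveyGenParams()
    pp = population_params or PopulationGenParams()
    cohort = generate_survey_cohort(sp)
    survey_to_csv_records(cohort).to_csv(outdir / "survey.csv", index=False)
    generate_population(pp).table.to_csv(outdir / "population.csv", index=False)
    generate_disease_epi(age_min=pp.age_min, age_max=pp.age_max).table.to_csv(
        outdir / "disease_epi.csv", index=False)

    manifest = {
        "survey": {
            "n_respondents": sp.n_respondents,
            "retention": sp.retention,
            "true_change": dict(sp.true_change),
            "pre_mean": sp.pre_mean,
            "pre_sd": sp.pre_sd,
            "pre_post_correlation": sp.pre_post_correlation,
            "seed": sp.seed,
        },
        "population": {
            "ages": [pp.age_min, pp.age_max],
            "count_per_stratum": pp.count_per_stratum,
            "bmi_mean": pp.bmi_mean,
            "bmi_sd": pp.bmi_sd,
            "gompertz": [pp.gompertz_level, pp.gompertz_slope],
        },
        "diseases": list(DEFAULT_DISEASE_PARAMS),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
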