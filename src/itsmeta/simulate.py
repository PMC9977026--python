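"""Synthetic aggregated school-level studies with known ground truth.

Generates the three tables the analysis consumes — per-cell test results
(one row per school x domain x grade x year, with the mean score and its
standard error), yearly school profiles, and the regional reference means
used for centring — from a generating model that mirrors the inference
model: a long-term trend, exposure-group ITS terms (level shift at the
event year plus a post-event slope change), confounder effects, school and
student-cohort random intercepts, a per-cell residual, and sampling noise
whose SD is exactly the reported standard error.

The default configuration emulates the Latrobe Valley / Wellington study
region: 69 schools split 34 / 28 / 7 across no-low, moderate and high
smoke-exposure groups, NAPLAN years 2008-2018 with the mine-fire event in
2014, grades 3/5/7/9 and five testing domains. Covariate laws are matched
to the published per-group medians and IQRs (ICSEA, enrolments, proportion
of girls) and school type / sector counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DOMAINS = ["reading", "writing", "spelling", "grammar", "numeracy"]
GRADES = (3, 5, 7, 9)
EXPOSURE_GROUPS = ("no_low", "moderate", "high")

#: grades taught by each school type (combined schools teach all four)
GRADES_BY_TYPE = {
    "primary": (3, 5),
    "secondary": (7, 9),
    "combined": (3, 5, 7, 9),
}

# Per-group school type and sector counts for the default 34/28/7 study,
# taken from the published 2014 school-profile table.
_TYPE_COUNTS = {
    "no_low": {"primary": 29, "secondary": 4, "combined": 1},
    "moderate": {"primary": 25, "secondary": 3, "combined": 0},
    "high": {"primary": 6, "secondary": 1, "combined": 0},
}
_GOVERNMENT_COUNTS = {"no_low": 26, "moderate": 22, "high": 5}

# Covariate laws per exposure group: ICSEA normal means (sd 40) match the
# published medians; enrolment lognormals match each group's median and IQR.
_ICSEA_MEAN = {"no_low": 974.0, "moderate": 962.0, "high": 922.0}
_ICSEA_SD = 40.0
_ENROL_LOG_MEDIAN = {
    "no_low": math.log(108.0),
    "moderate": math.log(165.0),
    "high": math.log(204.0),
}
_ENROL_LOG_SD = {
    "no_low": math.log(254.0 / 47.0) / 1.349,
    "moderate": math.log(340.0 / 118.0) / 1.349,
    "high": math.log(280.0 / 142.0) / 1.349,
}
_PROP_GIRLS_MEAN = 0.49
_PROP_GIRLS_CONCENTRATION = 120.0


class ConfigError(ValueError):
    """A simulation configuration violates an invariant."""


@dataclass
class SimulationTruth:
    """Generating parameter values of a synthetic study.

    ITS coefficients are in centred-score points; ``beta_t`` is points per
    year, the trend differences are points per post-event year. Confounder
    coefficients apply to standardized covariates (see ``generate_study``).
    """

    beta_t: float = -0.5
    beta_m_pre: float = -2.0
    beta_h_pre: float = -10.0
    beta_m_int: float = -2.0
    beta_h_int: float = -10.0
    beta_m_trend: float = 0.5
    beta_h_trend: float = 2.0
    confounder_betas: dict = field(
        default_factory=lambda: {
            "icsea": 15.0,        # per ICSEA sd (40 points)
            "enrolments": 1.0,    # per log-enrolment sd
            "prop_girls": 2.0,    # per 0.05 of proportion girls
            "sector_non_government": 3.0,
            "grade_5": 0.0, "grade_7": 0.0, "grade_9": 0.0,
        }
    )
    sigma_cohort: float = 5.0
    sigma_school: float = 5.0
    sigma_e: float = 5.0
    event_year: int = 2014

    def validate(self) -> None:
        for name in ("sigma_cohort", "sigma_school", "sigma_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulationConfig:
    """Study layout and sampling laws for one synthetic study."""

    n_schools_by_group: dict = field(
        default_factory=lambda: {"no_low": 34, "moderate": 28, "high": 7}
    )
    first_year: int = 2008
    last_year: int = 2018
    grades: tuple = GRADES
    domains: tuple = tuple(DOMAINS)
    within_school_sd: float = 70.0
    missingness_rate: float = 0.0
    reference_base_grade3: float = 420.0
    reference_per_grade_step: float = (580.0 - 420.0) / 3.0
    reference_per_year_drift: float = 0.0
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    seed: int = 0

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def validate(self) -> None:
        for group, n in self.n_schools_by_group.items():
            if group not in EXPOSURE_GROUPS:
                raise ConfigError(f"unknown exposure group {group!r}")
            if n < 1:
                raise ConfigError(f"n_schools_by_group[{group!r}] must be >= 1")
        if self.within_school_sd <= 0:
            raise ConfigError("within_school_sd must be > 0")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ConfigError("missingness_rate must be in [0, 1)")
        if self.first_year > self.last_year:
            raise ConfigError("first_year must not exceed last_year")
        ev = self.truth.event_year
        if not (self.first_year < ev <= self.last_year):
            raise ConfigError(
                "event_year must lie inside the study span with at least "
                "one pre-event year"
            )
        if not set(self.grades) <= set(GRADES):
            raise ConfigError(f"grades must be a subset of {set(GRADES)}")
        if not self.domains:
            raise ConfigError("domains must be non-empty")
        self.truth.validate()


def generate_reference_means(
    years: Sequence[int],
    grades: Sequence[int],
    domains: Sequence[str],
    base_grade3: float = 420.0,
    per_grade_step: float = (580.0 - 420.0) / 3.0,
    per_year_drift: float = 0.0,
) -> pd.DataFrame:
    """Regional average score per (year, grade, domain).

    The mean rises linearly with grade — ``base_grade3`` at Grade 3 plus
    ``per_grade_step`` for each two-grade step — so with the defaults Grade 3
    sits at 420 and Grade 9 at 580, the span national testing reports.
    ``per_year_drift`` adds a linear calendar-year drift.
    """
    years, grades, domains = list(years), sorted(grades), list(domains)
    if not years or not grades or not domains:
        raise ConfigError("years, grades and domains must all be non-empty")
    first_year = min(years)
    rows = [
        {
            "year": year,
            "grade": grade,
            "domain": domain,
            "reference_mean": base_grade3
            + per_grade_step * (grade - 3) / 2.0
            + per_year_drift * (year - first_year),
        }
        for year in years
        for grade in grades
        for domain in domains
    ]
    return pd.DataFrame(rows)


def _assign_school_attribute(counts: dict, n: int, labels: Sequence[str]) -> list:
    """Deterministic label vector with given counts, padded proportionally."""
    out: list = []
    for label in labels:
        out.extend([label] * counts.get(label, 0))
    if len(out) < n:  # non-default group size: extend with the modal label
        modal = max(labels, key=lambda l: counts.get(l, 0))
        out.extend([modal] * (n - len(out)))
    return out[:n]


def _school_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per school: static identity, group, type, sector."""
    rows = []
    for group in EXPOSURE_GROUPS:
        n = config.n_schools_by_group.get(group, 0)
        if n == 0:
            continue
        types = _assign_school_attribute(
            _TYPE_COUNTS[group], n, ("primary", "secondary", "combined")
        )
        n_gov = _GOVERNMENT_COUNTS.get(group, round(0.77 * n))
        n_gov = min(n_gov, n) if n >= 7 else round(0.77 * n)
        sectors = ["government"] * n_gov + ["non-government"] * (n - n_gov)
        for i in range(n):
            rows.append(
                {
                    "school_id": f"{group[:1].upper()}{i + 1:03d}",
                    "exposure_group": group,
                    "school_type": types[i],
                    "sector": sectors[i],
                }
            )
    schools = pd.DataFrame(rows)
    # static per-school covariate anchors; yearly profiles jitter around them
    schools["icsea_base"] = np.array(
        [rng.normal(_ICSEA_MEAN[g], _ICSEA_SD) for g in schools["exposure_group"]]
    ).clip(500, 1300)
    schools["enrolments_base"] = np.array(
        [
            rng.lognormal(_ENROL_LOG_MEDIAN[g], _ENROL_LOG_SD[g])
            for g in schools["exposure_group"]
        ]
    ).round().clip(10, None)
    a = _PROP_GIRLS_MEAN * _PROP_GIRLS_CONCENTRATION
    b = (1 - _PROP_GIRLS_MEAN) * _PROP_GIRLS_CONCENTRATION
    schools["prop_girls_base"] = rng.beta(a, b, size=len(schools))
    return schools


def _profile_table(
    schools: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Yearly school profiles: small AR-free jitter around the school anchors."""
    years = list(config.years)
    reps = len(years)
    prof = schools.loc[schools.index.repeat(reps)].reset_index(drop=True)
    prof["year"] = np.tile(years, len(schools))
    prof["icsea"] = (
        prof["icsea_base"] + rng.normal(0.0, 5.0, len(prof))
    ).round().clip(500, 1300)
    prof["enrolments"] = (
        prof["enrolments_base"] * rng.lognormal(0.0, 0.05, len(prof))
    ).round().clip(10, None).astype(int)
    prof["prop_girls"] = (
        prof["prop_girls_base"] + rng.normal(0.0, 0.01, len(prof))
    ).clip(0.0, 1.0)
    return prof[
        ["school_id", "year", "icsea", "enrolments", "prop_girls",
         "sector", "school_type", "exposure_group"]
    ]


def _its_value(truth: SimulationTruth, group: str, year: int, first_year: int) -> float:
    t = year - first_year
    i_post = 1.0 if year >= truth.event_year else 0.0
    t_post = max(0, year - truth.event_year)
    val = truth.beta_t * t
    if group == "moderate":
        val += truth.beta_m_pre + truth.beta_m_int * i_post + truth.beta_m_trend * i_post * t_post
    elif group == "high":
        val += truth.beta_h_pre + truth.beta_h_int * i_post + truth.beta_h_trend * i_post * t_post
    return val


def generate_study(config: SimulationConfig):
    """Draw one synthetic study.

    Returns ``(observations, profiles, reference, truth)``: observations has
    one row per school x taught grade x year x domain with columns
    (school_id, domain, grade, year, cohort_id, mean, se, n); profiles is the
    yearly school-profile table; reference the centring table. The emitted SE
    is exactly ``within_school_sd / sqrt(n)`` and the sampling noise added to
    each cell mean has that same SD, so the reported SE is the true sampling
    SD of the cell mean. Deterministic given ``config.seed``.
    """
    config.validate()
    truth = config.truth
    rng = np.random.default_rng(config.seed)

    schools = _school_table(config, rng)
    profiles = _profile_table(schools, config, rng)
    reference = generate_reference_means(
        config.years,
        config.grades,
        config.domains,
        config.reference_base_grade3,
        config.reference_per_grade_step,
        config.reference_per_year_drift,
    )
    ref_lookup = reference.set_index(["year", "grade", "domain"])["reference_mean"]

    cb = truth.confounder_betas
    prof_idx = profiles.set_index(["school_id", "year"])

    theta_school = {
        sid: rng.normal(0.0, truth.sigma_school) for sid in schools["school_id"]
    }
    theta_cohort: dict = {}

    rows = []
    for school in schools.itertuples(index=False):
        taught = [g for g in GRADES_BY_TYPE[school.school_type] if g in config.grades]
        if not taught:
            continue
        n_grades = max(len(GRADES_BY_TYPE[school.school_type]), 1)
        for year in config.years:
            prof = prof_idx.loc[(school.school_id, year)]
            # standardized confounder contributions (anchored at the default
            # study's typical values so truth is seed-independent)
            conf = (
                cb.get("icsea", 0.0) * (prof["icsea"] - 960.0) / 40.0
                + cb.get("enrolments", 0.0)
                * (math.log(prof["enrolments"]) - math.log(150.0))
                + cb.get("prop_girls", 0.0) * (prof["prop_girls"] - 0.49) / 0.05
                + cb.get("sector_non_government", 0.0)
                * (1.0 if school.sector == "non-government" else 0.0)
            )
            its = _its_value(truth, school.exposure_group, year, config.first_year)
            for grade in taught:
                cohort_id = year - (grade - 3)
                key = (school.school_id, cohort_id)
                if key not in theta_cohort:
                    theta_cohort[key] = rng.normal(0.0, truth.sigma_cohort)
                grade_eff = cb.get(f"grade_{grade}", 0.0)
                n_students = max(
                    5,
                    int(round(rng.lognormal(
                        math.log(max(prof["enrolments"] / n_grades, 5.0)), 0.3
                    ))),
                )
                se = config.within_school_sd / math.sqrt(n_students)
                for domain in config.domains:
                    if config.missingness_rate > 0 and rng.random() < config.missingness_rate:
                        continue
                    theta_e = rng.normal(0.0, truth.sigma_e)
                    mean = (
                        ref_lookup.loc[(year, grade, domain)]
                        + its + conf + grade_eff
                        + theta_school[school.school_id]
                        + theta_cohort[key]
                        + theta_e
                        + rng.normal(0.0, se)
                    )
                    rows.append(
                        {
                            "school_id": school.school_id,
                            "domain": domain,
                            "grade": grade,
                            "year": year,
                            "cohort_id": cohort_id,
                            "mean": mean,
                            "se": se,
                            "n": n_students,
                        }
                    )
    observations = pd.DataFrame(rows)
    return observations, profiles, reference, truth


def write_study(
    out_dir: str | Path,
    observations: pd.DataFrame,
    profiles: pd.DataFrame,
    reference: pd.DataFrame,
    truth: SimulationTruth,
) -> dict:
    """Write the four study artifacts as CSV/JSON; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out / "observations.csv",
        "profiles": out / "profiles.csv",
        "reference_means": out / "reference_means.csv",
        "truth": out / "truth.json",
    }
    observations.to_csv(paths["observations"], index=False)
    profiles.to_csv(paths["profiles"], index=False)
    reference.to_csv(paths["reference_means"], index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
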