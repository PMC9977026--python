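"""Validation, cohort assignment and centring of aggregated test results.

Observations are long-format DataFrames with one row per
school x domain x grade x year cell, carrying the cell's mean score, the
standard error of that mean (the known sampling SD used as the
meta-analytic weight) and the student count. Profiles carry the yearly
school covariates. Both schemas are produced by :mod:`itsmeta.simulate`
and mirror publicly released aggregated school data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TESTED_GRADES = (3, 5, 7, 9)

OBSERVATION_COLUMNS = [
    "school_id", "domain", "grade", "year", "cohort_id", "mean", "se", "n",
]
PROFILE_COLUMNS = [
    "school_id", "year", "icsea", "enrolments", "prop_girls",
    "sector", "school_type", "exposure_group",
]


class ValidationError(ValueError):
    """A table violates a schema invariant (strict mode only)."""


def assign_cohort(year: int, grade: int) -> int:
    """Student-cohort id for a (year, grade) cell.

    A cohort is the set of students progressing together through the
    biennial test grades, so the cell tested at Grade 5 in 2016 holds the
    same students as the Grade 3 cell of 2014. The id is the calendar year
    in which the cohort sat (or would have sat) Grade 3:
    ``cohort_id = year - (grade - 3)``.
    """
    if grade not in TESTED_GRADES:
        raise ValueError(f"grade must be one of {TESTED_GRADES}, got {grade}")
    return year - (grade - 3)


def add_cohorts(observations: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the cohort_id column (re)derived from year and grade."""
    bad = set(observations["grade"].unique()) - set(TESTED_GRADES)
    if bad:
        raise ValueError(f"grades outside tested set {TESTED_GRADES}: {sorted(bad)}")
    out = observations.copy()
    out["cohort_id"] = out["year"] - (out["grade"] - 3)
    return out


def center_scores(observations: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Centre cell means against the regional reference means.

    Subtracts the reference mean for the matching (year, grade, domain)
    from each cell mean. The reference is treated as a known constant (its
    pool is far larger than any one cell), so the SE is unchanged. The
    returned frame carries ``centred=True``.
    """
    keys = ["year", "grade", "domain"]
    ref = reference[keys + ["reference_mean"]]
    merged = observations.merge(ref, on=keys, how="left", validate="many_to_one")
    missing = merged["reference_mean"].isna()
    if missing.any():
        missing_keys = (
            merged.loc[missing, keys].drop_duplicates().to_records(index=False).tolist()
        )
        raise KeyError(
            f"no reference mean for {len(missing_keys)} (year, grade, domain) "
            f"key(s): {missing_keys[:10]}"
        )
    out = observations.copy()
    out["mean"] = merged["mean"].to_numpy() - merged["reference_mean"].to_numpy()
    out.attrs["centred"] = True
    return out


def uncenter_scores(observations: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`center_scores` (adds the reference back)."""
    keys = ["year", "grade", "domain"]
    merged = observations.merge(
        reference[keys + ["reference_mean"]], on=keys, how="left", validate="many_to_one"
    )
    out = observations.copy()
    out["mean"] = merged["mean"].to_numpy() + merged["reference_mean"].to_numpy()
    out.attrs["centred"] = False
    return out


@dataclass
class ValidationReport:
    """Counts of violations per rule, plus the cleaned tables."""

    counts: dict = field(default_factory=dict)
    observations: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None

    @property
    def total_violations(self) -> int:
        return sum(self.counts.values())


def validate_tables(
    observations: pd.DataFrame,
    profiles: pd.DataFrame,
    study_years: tuple[int, int] | None = None,
    drop: bool = False,
    strict: bool = False,
) -> ValidationReport:
    """Check the observation and profile tables against schema invariants.

    Rules: ``nonpositive_se`` (se <= 0 or missing; these cells carry no
    meta-analytic weight and are dropped rather than imputed when
    ``drop=True``), ``bad_grade``, ``orphan_school`` (observation school_id
    with no profile row at all), ``profile_year_out_of_range``,
    ``bad_prop_girls``, ``icsea_out_of_range``. Report-only unless
    ``strict``, in which case the first violated rule raises
    :class:`ValidationError`.
    """
    counts: dict[str, int] = {}
    obs, prof = observations, profiles

    bad_se = ~(obs["se"] > 0)
    counts["nonpositive_se"] = int(bad_se.sum())
    bad_grade = ~obs["grade"].isin(TESTED_GRADES)
    counts["bad_grade"] = int(bad_grade.sum())
    orphan = ~obs["school_id"].isin(prof["school_id"])
    counts["orphan_school"] = int(orphan.sum())

    if study_years is not None:
        lo, hi = study_years
        out_of_range = ~prof["year"].between(lo, hi)
    else:
        out_of_range = ~prof["year"].isin(obs["year"].unique())
    counts["profile_year_out_of_range"] = int(out_of_range.sum())
    bad_girls = ~prof["prop_girls"].between(0.0, 1.0)
    counts["bad_prop_girls"] = int(bad_girls.sum())
    bad_icsea = ~prof["icsea"].between(500, 1300)
    counts["icsea_out_of_range"] = int(bad_icsea.sum())

    if strict:
        for rule, n in counts.items():
            if n:
                raise ValidationError(f"rule {rule!r} violated by {n} row(s)")

    report = ValidationReport(counts=counts)
    if drop:
        report.observations = obs.loc[~(bad_se | bad_grade | orphan)].copy()
        report.profiles = prof.loc[~(out_of_range | bad_girls | bad_icsea)].copy()
    else:
        report.observations = obs
        report.profiles = prof
    return report
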