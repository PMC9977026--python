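"""Fixed-effects design matrix and random-effect grouping for the ITS model.

The fixed-effects block is the interrupted-time-series parameterization
for two exposed groups against a control:

    beta_t*T + beta_m_pre*E_m + beta_m_int*E_m*I_post + beta_m_trend*E_m*I_post*T_post
             + beta_h_pre*E_h + beta_h_int*E_h*I_post + beta_h_trend*E_h*I_post*T_post

where T counts years from the study start (0 for the first year), I_post
switches on in the event year, and T_post counts years elapsed since the
event year (0 in the event year itself, 1 the year after, ...). E_m / E_h
indicate moderate / high exposure with the no-low group as reference, so
the pre-coefficients are pre-event group offsets, the int-coefficients the
immediate level shift at the event, and the trend-coefficients the
post-event slope change. Confounders (ICSEA, log-scale-free enrolments,
proportion of girls, sector, grade level) complete the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ITS_COLUMNS = [
    "trend",
    "moderate_pre",
    "high_pre",
    "moderate_interruption",
    "high_interruption",
    "moderate_post_trend",
    "high_post_trend",
]
CONTINUOUS_COVARIATES = ["icsea", "enrolments", "prop_girls"]

_GROUPS = ("no_low", "moderate", "high")


def its_terms(
    year: int, exposure_group: str, event_year: int, first_year: int = 2008
) -> dict[str, float]:
    """The seven ITS design values for one cell.

    Returns a dict keyed by :data:`ITS_COLUMNS`. The no-low group is the
    reference: all six exposure columns are zero for it.
    """
    if exposure_group not in _GROUPS:
        raise ValueError(
            f"unknown exposure group {exposure_group!r}; expected one of {_GROUPS}"
        )
    t = float(year - first_year)
    i_post = 1.0 if year >= event_year else 0.0
    t_post = float(max(0, year - event_year))
    e_m = 1.0 if exposure_group == "moderate" else 0.0
    e_h = 1.0 if exposure_group == "high" else 0.0
    return {
        "trend": t,
        "moderate_pre": e_m,
        "high_pre": e_h,
        "moderate_interruption": e_m * i_post,
        "high_interruption": e_h * i_post,
        "moderate_post_trend": e_m * i_post * t_post,
        "high_post_trend": e_h * i_post * t_post,
    }


@dataclass
class ItsDesign:
    """Design matrix plus aligned response, SEs and grouping indices."""

    X: np.ndarray
    column_names: list
    y: np.ndarray
    se: np.ndarray
    school_index: np.ndarray        # per-row code into school_labels
    cohort_index: np.ndarray        # per-row code into cohort_labels
    school_labels: list
    cohort_labels: list             # (school_id, cohort_id) pairs
    scaling_metadata: dict = field(default_factory=dict)  # col -> (center, scale)
    event_year: int = 2014
    first_year: int = 2008
    domain: str | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_schools(self) -> int:
        return len(self.school_labels)

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_labels)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.column_names.index(name)]

    def validate(self) -> None:
        n = len(self.y)
        if not (self.X.shape == (n, len(self.column_names)) and len(self.se) == n):
            raise ValueError("X, y and se are not aligned")
        em, eh = self.column("moderate_pre"), self.column("high_pre")
        if np.any(em * eh != 0):
            raise ValueError("a row is flagged both moderate and high exposure")
        if np.any((self.column("moderate_interruption") == 0)
                  & (self.column("moderate_post_trend") != 0)):
            raise ValueError("moderate post-trend nonzero before the event")
        if np.any((self.column("high_interruption") == 0)
                  & (self.column("high_post_trend") != 0)):
            raise ValueError("high post-trend nonzero before the event")


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        suspect = [names[j] for j in np.where(diag < tol)[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns include: {suspect or names}"
        )


def build_design(
    observations: pd.DataFrame,
    profiles: pd.DataFrame,
    domain: str,
    event_year: int,
    first_year: int | None = None,
    scale_continuous: bool = True,
    check_rank: bool = True,
) -> ItsDesign:
    """Assemble the per-domain design from centred observations and profiles.

    Profiles join on (school_id, year); missing profile years are filled by
    carrying the school's last earlier profile forward (then backward for
    leading gaps). Continuous covariates are centred at their sample means
    and scaled by sample SDs for sampler efficiency; the per-column
    (center, scale) pairs are kept so reports can back-transform to natural
    units. Grade enters as indicators with Grade 3 as reference, sector as
    a non-government indicator.
    """
    obs = observations.loc[observations["domain"] == domain].reset_index(drop=True)
    if obs.empty:
        raise ValueError(f"no observations for domain {domain!r}")
    if first_year is None:
        first_year = int(obs["year"].min())

    unmatched = set(obs["school_id"]) - set(profiles["school_id"])
    if unmatched:
        raise KeyError(
            f"{len(unmatched)} school_id(s) have no profile rows: "
            f"{sorted(unmatched)[:10]}"
        )

    # (school, year) join with LOCF across each school's profile years
    years = np.sort(obs["year"].unique())
    grid = (
        pd.MultiIndex.from_product(
            [profiles["school_id"].unique(), years], names=["school_id", "year"]
        ).to_frame(index=False)
    )
    prof_full = grid.merge(profiles, on=["school_id", "year"], how="left")
    prof_cols = ["icsea", "enrolments", "prop_girls", "sector", "exposure_group"]
    prof_full[prof_cols] = (
        prof_full.sort_values(["school_id", "year"])
        .groupby("school_id")[prof_cols]
        .transform(lambda s: s.ffill().bfill())
    )
    merged = obs.merge(prof_full, on=["school_id", "year"], how="left", validate="many_to_one")
    if merged["exposure_group"].isna().any():
        bad = merged.loc[merged["exposure_group"].isna(), ["school_id", "year"]]
        raise KeyError(f"profile join failed for: {bad.drop_duplicates().values.tolist()[:10]}")

    n = len(merged)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    its = np.array(
        [
            list(its_terms(int(y), g, event_year, first_year).values())
            for y, g in zip(merged["year"], merged["exposure_group"])
        ]
    )
    for j, name in enumerate(ITS_COLUMNS):
        cols[name] = its[:, j]

    scaling: dict[str, tuple[float, float]] = {}
    for name in CONTINUOUS_COVARIATES:
        raw = merged[name].to_numpy(dtype=float)
        if scale_continuous:
            center, scale = float(raw.mean()), float(raw.std(ddof=0))
            if scale == 0.0:
                center, scale = 0.0, 1.0
            cols[name] = (raw - center) / scale
            scaling[name] = (center, scale)
        else:
            cols[name] = raw
    cols["sector_non_government"] = (merged["sector"] == "non-government").to_numpy(float)
    for grade in (5, 7, 9):
        if (merged["grade"] == grade).any():
            cols[f"grade_{grade}"] = (merged["grade"] == grade).to_numpy(float)

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if check_rank:  # single-group fixtures are legitimately deficient
        _check_rank(X, names)

    school_codes, school_labels = pd.factorize(merged["school_id"], sort=True)
    cohort_key = list(zip(merged["school_id"], merged["cohort_id"]))
    cohort_codes, cohort_labels = pd.factorize(pd.Series(cohort_key), sort=True)

    design = ItsDesign(
        X=X,
        column_names=names,
        y=merged["mean"].to_numpy(dtype=float),
        se=merged["se"].to_numpy(dtype=float),
        school_index=school_codes.astype(np.int64),
        cohort_index=cohort_codes.astype(np.int64),
        school_labels=list(school_labels),
        cohort_labels=list(cohort_labels),
        scaling_metadata=scaling,
        event_year=event_year,
        first_year=first_year,
        domain=domain,
    )
    design.validate()
    return design
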