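"""Sensitivity analyses: configured re-fits with one modification each.

Three families of variant mirror the robustness checks standard for this
model: alternative priors on the random-effect SDs, dropping the cohort
random effect (school-level clustering only), and excluding named schools
(e.g. schools relocated during the event). Variants re-use the base MCMC
seed by default so differences reflect the modification rather than
Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .design import ITS_COLUMNS, build_design
from .model import McmcConfig, PosteriorFit, PriorSpec, SdPrior, fit_model, summarize

#: default alternative priors on the three SDs, applied to all of them
DEFAULT_PRIOR_VARIANTS = {
    "tn_0_5": SdPrior(mean=0.0, sd=5.0),
    "tn_10_10": SdPrior(mean=10.0, sd=10.0),
    "tn_10_50_diffuse": SdPrior(mean=10.0, sd=50.0),
}


@dataclass
class SensitivityVariant:
    name: str
    prior_override: PriorSpec | None = None
    drop_cohort_random_effect: bool = False
    exclude_school_ids: tuple = ()

    def is_null(self) -> bool:
        return (
            self.prior_override is None
            and not self.drop_cohort_random_effect
            and not self.exclude_school_ids
        )


@dataclass
class BaseStudy:
    """Everything needed to rebuild the design from scratch for a variant."""

    observations: pd.DataFrame  # centred
    profiles: pd.DataFrame
    domain: str
    event_year: int
    first_year: int | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)


def run_variant(
    base: BaseStudy,
    variant: SensitivityVariant,
    mcmc: McmcConfig,
) -> tuple[pd.DataFrame, PosteriorFit]:
    """Re-fit with the variant's modification; returns (coefficient table, fit).

    School exclusions are applied before the design is rebuilt; dropping
    the cohort random effect fixes its SD at zero (the component then
    vanishes from the likelihood).
    """
    obs, prof = base.observations, base.profiles
    if variant.exclude_school_ids:
        known = set(obs["school_id"])
        unknown = set(variant.exclude_school_ids) - known
        if unknown:
            raise ValueError(f"excluded school_ids not in study: {sorted(unknown)}")
        keep_prof = prof.loc[~prof["school_id"].isin(variant.exclude_school_ids)]
        lost_groups = set(prof["exposure_group"].unique()) - set(
            keep_prof["exposure_group"].unique()
        )
        if lost_groups:
            raise ValueError(
                f"exclusion removes every school of group(s) {sorted(lost_groups)}; "
                "exposure coefficients would be unidentifiable"
            )
        obs = obs.loc[~obs["school_id"].isin(variant.exclude_school_ids)]
        prof = keep_prof

    priors = variant.prior_override or base.priors
    if variant.drop_cohort_random_effect:
        priors = replace(priors, sd_cohort=SdPrior(fixed=0.0))

    design = build_design(obs, prof, base.domain, base.event_year, base.first_year)
    fit = fit_model(design, priors, mcmc)
    table = summarize(fit)
    table.attrs["variant"] = variant.name
    return table, fit


def compare_variants(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side coefficient comparison across >= 2 variants.

    Rows are the ITS coefficients; per variant a (mean, ci_2.5, ci_97.5)
    column block, plus a ``sign_agrees_<name>`` flag marking whether the
    posterior-mean sign matches the first (base) variant.
    """
    if len(tables) < 2:
        raise ValueError("need at least two variant tables to compare")
    names = list(tables)
    base_idx = set(tables[names[0]].index)
    for name in names[1:]:
        diff = base_idx.symmetric_difference(tables[name].index)
        if diff:
            raise ValueError(
                f"variant {name!r} coefficient set differs from base: {sorted(diff)}"
            )
    its_rows = [c for c in tables[names[0]].index if c in ITS_COLUMNS]
    out = pd.DataFrame(index=its_rows)
    base_sign = tables[names[0]].loc[its_rows, "mean"].apply(lambda v: v >= 0)
    for name in names:
        t = tables[name].loc[its_rows]
        out[f"mean_{name}"] = t["mean"]
        out[f"ci_2.5_{name}"] = t["ci_2.5"]
        out[f"ci_97.5_{name}"] = t["ci_97.5"]
        out[f"sign_agrees_{name}"] = (t["mean"] >= 0) == base_sign
    return out
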