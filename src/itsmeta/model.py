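"""Bayesian hierarchical meta-regression with known sampling variances.

The observation model for cell *i* (a school x grade x year x domain mean)
with centred mean ``y_i`` and known standard error ``tau_i`` is

    y_i ~ Normal( X_i beta + theta_school(i) + theta_cohort(i),
                  tau_i^2 + sigma_e^2 )

with school random intercepts ``theta_s ~ N(0, sigma_s^2)``, school-cohort
random intercepts ``theta_sc ~ N(0, sigma_sc^2)`` nested in schools, and a
per-cell residual whose variance ``sigma_e^2`` is folded analytically into
the observation variance (an exact marginalization — the residual is
additive Gaussian at observation level, so integrating it out just
inflates the known sampling variance).

Priors follow the weakly-informative scheme standard for this model:
Normal(0, 50^2) on every fixed effect and truncated-normal TN(10, 5^2)
restricted to (0, inf) on each of the three SDs. The TN location of 10
(rather than 0) reflects that between-school spread in centred scores in
a disadvantaged region is expected to be of that order.

Inference is by Markov chain Monte Carlo. Conditional on the three SDs the
model is jointly Gaussian, so ``beta``, ``theta_s`` and ``theta_sc`` are
drawn exactly from their Gaussian full conditionals (a blocked Gibbs
sweep); the SDs, whose conditionals are non-standard because of the TN
priors and the variance-inflation role of ``sigma_e``, are updated by
univariate slice sampling. Each SD prior can instead be fixed at a value;
fixing it at 0 removes that variance component from the model entirely,
which is how the GLS limit and the "no cohort random effect" sensitivity
variant are expressed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import ITS_COLUMNS, ItsDesign, its_terms

__all__ = [
    "SdPrior", "PriorSpec", "McmcConfig", "PosteriorFit",
    "fit_model", "summarize", "predicted_margins", "effect_to_months",
]


@dataclass(frozen=True)
class SdPrior:
    """Truncated-normal prior TN(mean, sd^2) on (0, inf) for one SD.

    ``fixed`` pins the SD at a constant instead (0 removes the component).
    """

    mean: float = 10.0
    sd: float = 5.0
    fixed: float | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior sd must be > 0")
        if self.fixed is not None and self.fixed < 0:
            raise ValueError("fixed SD value must be >= 0")

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return -0.5 * ((x - self.mean) / self.sd) ** 2


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the fixed effects and the three SD parameters."""

    fixed_effect_sd: float = 50.0
    sd_cohort: SdPrior = field(default_factory=SdPrior)
    sd_school: SdPrior = field(default_factory=SdPrior)
    sd_error: SdPrior = field(default_factory=SdPrior)

    def __post_init__(self):
        if self.fixed_effect_sd <= 0:
            raise ValueError("fixed_effect_sd must be > 0")

    def with_all_sds_fixed(self, value: float = 0.0) -> "PriorSpec":
        fixed = SdPrior(fixed=value)
        return replace(self, sd_cohort=fixed, sd_school=fixed, sd_error=fixed)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: ``iterations`` per chain includes warmup (half)."""

    chains: int = 4
    iterations: int = 2000
    warmup: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least 1 chain")
        if self.kept <= 0:
            raise ValueError("iterations must exceed warmup")

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup

    @property
    def kept(self) -> int:
        return self.iterations - self.n_warmup


def _slice_sample(x0, log_target, rng, width=2.0, max_steps=64):
    """One univariate slice-sampling update on (0, inf) (Neal stepping-out)."""
    log_y = log_target(x0) - rng.exponential()
    u = rng.uniform(0.0, width)
    left, right = x0 - u, x0 + (width - u)
    steps = max_steps
    while left > 0 and log_target(left) > log_y and steps > 0:
        left -= width
        steps -= 1
    left = max(left, 1e-12)
    steps = max_steps
    while log_target(right) > log_y and steps > 0:
        right += width
        steps -= 1
    while True:
        x1 = rng.uniform(left, right)
        if log_target(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _group_gaussian_update(resid, w, index, n_groups, sigma, rng):
    """Exact draw of group intercepts from their Gaussian full conditional."""
    sw = np.bincount(index, weights=w, minlength=n_groups)
    sm = np.bincount(index, weights=w * resid, minlength=n_groups)
    prec = sw + 1.0 / sigma**2
    return sm / prec + rng.standard_normal(n_groups) / np.sqrt(prec)


def _group_means(X, index, n_groups):
    """Per-group column means Xbar (n_groups x p) and deviations X - Xbar."""
    counts = np.bincount(index, minlength=n_groups).astype(float)
    xbar = np.empty((n_groups, X.shape[1]))
    for j in range(X.shape[1]):
        xbar[:, j] = np.bincount(index, weights=X[:, j], minlength=n_groups) / counts
    return xbar, X - xbar[index]


def _interweave(beta, theta, index, xbar, G, X, w, resid, sigma,
                prior_prec_beta, fitted, rng):
    """Exact Gibbs draws along the directions beta_j += d, theta -= d*xbar_j.

    For a column constant within groups this translation leaves the
    likelihood invariant and re-draws the split between the fixed effect
    and the random-intercept means it competes with (ancillarity-
    sufficiency interweaving); for a column with within-group variation
    the residual term enters through the deviations G and the draw is
    still an exact 1-D conditional. Breaks the slow-mixing posterior
    correlation between school-level covariates and the school intercepts.
    ``resid``, ``theta``, ``beta`` and ``fitted`` are updated in place.
    """
    sigma2 = sigma**2
    for j in range(X.shape[1]):
        g = G[:, j]
        xb = xbar[:, j]
        prec = prior_prec_beta + float(w @ (g * g)) + float(xb @ xb) / sigma2
        lin = (float((w * resid) @ g) + float(theta @ xb) / sigma2
               - beta[j] * prior_prec_beta)
        d = lin / prec + rng.standard_normal() / np.sqrt(prec)
        beta[j] += d
        theta -= d * xb
        fitted += d * X[:, j]
        resid -= d * g


def _collapsed_sd_update(sigma, prior, resid, w, index, n_groups, rng):
    """Slice update of a random-intercept SD with its intercepts integrated out.

    Conditional on everything else, the groups are independent and each
    contributes a rank-1 term sigma^2 * 11' to its residual covariance, so
    by the Woodbury/matrix-determinant identities the marginal log-likelihood
    needs only the per-group weight sums a_g and weighted residual sums b_g:

        -1/2 * sum_g [ log(1 + sigma^2 a_g) - sigma^2 b_g^2 / (1 + sigma^2 a_g) ]

    Sampling sigma against this marginal (then redrawing the intercepts)
    removes the funnel coupling that makes the conditional update mix slowly.
    """
    a = np.bincount(index, weights=w, minlength=n_groups)
    b2 = np.bincount(index, weights=w * resid, minlength=n_groups) ** 2

    def log_target(s):
        if s <= 0:
            return -np.inf
        denom = 1.0 + s * s * a
        return float(-0.5 * np.sum(np.log(denom)) + 0.5 * s * s * np.sum(b2 / denom)
                     + prior.logpdf(s))

    return _slice_sample(sigma, log_target, rng)


def _run_chain(design: ItsDesign, priors: PriorSpec, mcmc: McmcConfig, rng):
    X, y, tau2 = design.X, design.y, design.se**2
    si, ci = design.school_index, design.cohort_index
    n, p = X.shape
    n_s, n_c = design.n_schools, design.n_cohorts
    xbar_s, G_s = _group_means(X, si, n_s)
    xbar_c, G_c = _group_means(X, ci, n_c)

    use_school = priors.sd_school.fixed != 0.0
    use_cohort = priors.sd_cohort.fixed != 0.0

    def init_sd(prior: SdPrior) -> float:
        if prior.fixed is not None:
            return prior.fixed
        return max(0.1, prior.mean * rng.uniform(0.5, 1.5))

    sigma_s, sigma_c, sigma_e = (
        init_sd(priors.sd_school), init_sd(priors.sd_cohort), init_sd(priors.sd_error)
    )
    theta_s, theta_c = np.zeros(n_s), np.zeros(n_c)
    prior_prec_beta = 1.0 / priors.fixed_effect_sd**2
    eye_p = np.eye(p)

    kept = mcmc.kept
    out = {
        "beta": np.empty((kept, p)),
        "sigma_school": np.empty(kept),
        "sigma_cohort": np.empty(kept),
        "sigma_e": np.empty(kept),
        "theta_school": np.empty((kept, n_s)),
        "theta_cohort": np.empty((kept, n_c)),
    }

    for it in range(mcmc.iterations):
        w = 1.0 / (tau2 + sigma_e**2)

        # --- beta | rest: Gaussian with precision X'WX + I/sd^2
        part = y - theta_s[si] - theta_c[ci]
        Xw = X * w[:, None]
        A = X.T @ Xw + prior_prec_beta * eye_p
        b = Xw.T @ part
        c_and_lower = cho_factor(A, lower=True)
        mean = cho_solve(c_and_lower, b)
        z = rng.standard_normal(p)
        beta = mean + solve_triangular(c_and_lower[0].T, z, lower=False)
        fitted = X @ beta

        # --- random intercepts | rest
        if use_school:
            theta_s = _group_gaussian_update(
                y - fitted - theta_c[ci], w, si, n_s, sigma_s, rng
            )
        if use_cohort:
            theta_c = _group_gaussian_update(
                y - fitted - theta_s[si], w, ci, n_c, sigma_c, rng
            )

        # --- interweaving: re-draw the split between each fixed effect and
        # the random-intercept means it competes with
        if (use_school and sigma_s > 0) or (use_cohort and sigma_c > 0):
            resid = y - fitted - theta_s[si] - theta_c[ci]
            if use_school and sigma_s > 0:
                _interweave(beta, theta_s, si, xbar_s, G_s, X, w, resid,
                            sigma_s, prior_prec_beta, fitted, rng)
            if use_cohort and sigma_c > 0:
                _interweave(beta, theta_c, ci, xbar_c, G_c, X, w, resid,
                            sigma_c, prior_prec_beta, fitted, rng)

        # --- SDs | rest: collapsed slice updates under the TN priors,
        # each followed by an exact redraw of its intercepts
        if use_school and priors.sd_school.fixed is None:
            r = y - fitted - theta_c[ci]
            sigma_s = _collapsed_sd_update(
                sigma_s, priors.sd_school, r, w, si, n_s, rng
            )
            theta_s = _group_gaussian_update(r, w, si, n_s, sigma_s, rng)
        if use_cohort and priors.sd_cohort.fixed is None:
            r = y - fitted - theta_s[si]
            sigma_c = _collapsed_sd_update(
                sigma_c, priors.sd_cohort, r, w, ci, n_c, rng
            )
            theta_c = _group_gaussian_update(r, w, ci, n_c, sigma_c, rng)
        if priors.sd_error.fixed is None:
            resid = y - fitted - theta_s[si] - theta_c[ci]
            r2 = resid**2

            def log_target_e(s):
                if s <= 0:
                    return -np.inf
                v = tau2 + s**2
                return float(-0.5 * np.sum(np.log(v)) - 0.5 * np.sum(r2 / v)
                             + priors.sd_error.logpdf(s))

            sigma_e = _slice_sample(sigma_e, log_target_e, rng)

        k = it - mcmc.n_warmup
        if k >= 0:
            out["beta"][k] = beta
            out["sigma_school"][k] = sigma_s
            out["sigma_cohort"][k] = sigma_c
            out["sigma_e"][k] = sigma_e
            out["theta_school"][k] = theta_s
            out["theta_cohort"][k] = theta_c
    return out


@dataclass
class PosteriorFit:
    """Posterior draws (chains x kept iterations x parameter) plus metadata."""

    beta: np.ndarray
    sigma_school: np.ndarray
    sigma_cohort: np.ndarray
    sigma_e: np.ndarray
    theta_school: np.ndarray
    theta_cohort: np.ndarray
    column_names: list
    scaling_metadata: dict
    event_year: int
    first_year: int
    domain: str | None
    priors: PriorSpec
    mcmc: McmcConfig
    design_hash: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_draws(self, name: str) -> np.ndarray:
        """Flattened draws for one coefficient (scaled/model units)."""
        return self.beta[:, :, self.column_names.index(name)].ravel()

    def to_inference_data(self) -> az.InferenceData:
        coords = {"coefficient": self.column_names}
        return az.from_dict(
            posterior={
                "beta": self.beta,
                "sigma_school": self.sigma_school,
                "sigma_cohort": self.sigma_cohort,
                "sigma_e": self.sigma_e,
            },
            coords=coords,
            dims={"beta": ["coefficient"]},
        )


def _design_hash(design: ItsDesign) -> str:
    h = hashlib.sha256()
    for arr in (design.X, design.y, design.se, design.school_index, design.cohort_index):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _compute_diagnostics(fit: PosteriorFit) -> dict:
    idata = fit.to_inference_data()
    names, rhats, esss = [], [], []
    varying = ["beta"]
    for sd_name, prior in (
        ("sigma_school", fit.priors.sd_school),
        ("sigma_cohort", fit.priors.sd_cohort),
        ("sigma_e", fit.priors.sd_error),
    ):
        if prior.fixed is None:
            varying.append(sd_name)
    rhat = az.rhat(idata, var_names=varying)
    ess = az.ess(idata, var_names=varying)
    for v in varying:
        r = np.atleast_1d(rhat[v].values)
        e = np.atleast_1d(ess[v].values)
        if v == "beta":
            names.extend(fit.column_names)
        else:
            names.append(v)
        rhats.extend(r.tolist())
        esss.extend(e.tolist())
    multichain = fit.beta.shape[0] >= 2
    return {
        "rhat": dict(zip(names, rhats)),
        "ess": dict(zip(names, esss)),
        "max_rhat": float(np.nanmax(rhats)) if multichain else float("nan"),
        "min_ess": float(np.nanmin(esss)),
        "divergences": 0,  # Gibbs/slice updates cannot diverge
        "warnings": (
            ["max R-hat exceeds 1.01"]
            if multichain and np.nanmax(rhats) > 1.01
            else []
        ),
    }


def fit_model(
    design: ItsDesign,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    diagnostics: bool = True,
) -> PosteriorFit:
    """Fit the hierarchical meta-regression by blocked Gibbs/slice MCMC.

    Reproducible given ``mcmc.seed`` (per-chain streams are spawned from
    it). Convergence problems are reported in ``fit.diagnostics`` as
    warnings, never silently discarded.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    if np.any(design.se <= 0):
        raise ValueError("all standard errors must be > 0")

    chain_rngs = [np.random.default_rng(s) for s in
                  np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)]
    chains = [_run_chain(design, priors, mcmc, rng) for rng in chain_rngs]

    stacked = {k: np.stack([c[k] for c in chains], axis=0) for k in chains[0]}
    fit = PosteriorFit(
        beta=stacked["beta"],
        sigma_school=stacked["sigma_school"],
        sigma_cohort=stacked["sigma_cohort"],
        sigma_e=stacked["sigma_e"],
        theta_school=stacked["theta_school"],
        theta_cohort=stacked["theta_cohort"],
        column_names=list(design.column_names),
        scaling_metadata=dict(design.scaling_metadata),
        event_year=design.event_year,
        first_year=design.first_year,
        domain=design.domain,
        priors=priors,
        mcmc=mcmc,
        design_hash=_design_hash(design),
    )
    if diagnostics:
        fit.diagnostics = _compute_diagnostics(fit)
    return fit


def _tail_probs(draws: np.ndarray) -> tuple[float, float]:
    p_lt = float(np.mean(draws < 0))
    return p_lt, 1.0 - p_lt


def summarize(fit: PosteriorFit, natural_units: bool = True) -> pd.DataFrame:
    """Coefficient table: posterior mean, SD, 95% CI, P(beta<0), P(beta>0).

    Continuous covariates are reported per natural unit (the scaled-column
    coefficient divided by the column's scale) when ``natural_units``.
    """
    n_total = fit.beta.shape[0] * fit.beta.shape[1]
    if n_total < 100:
        raise ValueError(f"need >= 100 kept draws to summarize, have {n_total}")
    rows = []
    for j, name in enumerate(fit.column_names):
        draws = fit.beta[:, :, j].ravel()
        if natural_units and name in fit.scaling_metadata:
            draws = draws / fit.scaling_metadata[name][1]
        p_lt, p_gt = _tail_probs(draws)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "coefficient": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "p_lt_0": p_lt,
                "p_gt_0": p_gt,
            }
        )
    return pd.DataFrame(rows).set_index("coefficient")


def default_reference_covariates(fit: PosteriorFit) -> dict[str, float]:
    """Covariates held fixed for predicted margins.

    Continuous columns sit at their sample means (0 on the scaled scale);
    indicator columns at their modal category (here: the default zero
    level, i.e. government sector and Grade 3).
    """
    ref: dict[str, float] = {}
    for name in fit.column_names:
        if name == "intercept" or name in ITS_COLUMNS:
            continue
        ref[name] = 0.0
    return ref


def predicted_margins(
    fit: PosteriorFit,
    years,
    exposure_groups=("no_low", "moderate", "high"),
    reference_covariates: dict | None = None,
) -> pd.DataFrame:
    """Predicted centred score per (year, exposure group), with 95% CI.

    For each draw the linear predictor is evaluated with the ITS terms for
    the requested year/group, every other covariate fixed at its reference
    value, and random effects at 0 (a typical school). Columns: year,
    exposure_group, mean, sd, ci_2.5, ci_97.5.
    """
    years = list(years)
    span_max = fit.first_year + 50
    for y in years:
        if not (fit.first_year <= y <= span_max):
            raise ValueError(f"year {y} outside the study span starting {fit.first_year}")
    ref = (default_reference_covariates(fit) if reference_covariates is None
           else dict(reference_covariates))
    missing = [
        c for c in fit.column_names
        if c != "intercept" and c not in ITS_COLUMNS and c not in ref
    ]
    if missing:
        raise ValueError(f"reference covariates missing for columns: {missing}")

    beta_flat = fit.beta.reshape(-1, fit.beta.shape[-1])
    rows = []
    for year in years:
        for group in exposure_groups:
            terms = its_terms(year, group, fit.event_year, fit.first_year)
            x = np.array([
                1.0 if c == "intercept" else terms.get(c, ref.get(c, 0.0))
                for c in fit.column_names
            ])
            draws = beta_flat @ x
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "year": year,
                    "exposure_group": group,
                    "mean": float(draws.mean()),
                    "sd": float(draws.std(ddof=1)),
                    "ci_2.5": float(lo),
                    "ci_97.5": float(hi),
                }
            )
    return pd.DataFrame(rows)


def margin_draws(fit: PosteriorFit, year: int, group: str,
                 reference_covariates: dict | None = None) -> np.ndarray:
    """Per-draw predicted margin for one (year, group); used for identities."""
    ref = (default_reference_covariates(fit) if reference_covariates is None
           else dict(reference_covariates))
    terms = its_terms(year, group, fit.event_year, fit.first_year)
    x = np.array([
        1.0 if c == "intercept" else terms.get(c, ref.get(c, 0.0))
        for c in fit.column_names
    ])
    return fit.beta.reshape(-1, fit.beta.shape[-1]) @ x


def effect_to_months(effect: float, points_per_year: float = 27.0) -> float:
    """Convert a score-point effect into months of typical learning.

    National test scores grow by about 27 points per school year, so an
    11-point deficit corresponds to roughly five months of progression.
    """
    if points_per_year <= 0:
        raise ValueError("points_per_year must be > 0")
    return effect / points_per_year * 12.0
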