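"""Sampler correctness: conjugate oracle, recovery, margins algebra, summaries."""

import dataclasses

import numpy as np
import pytest

from itsmeta import (
    ItsDesign,
    McmcConfig,
    PosteriorFit,
    PriorSpec,
    SdPrior,
    effect_to_months,
    fit_model,
    predicted_margins,
    summarize,
)
from itsmeta.design import ITS_COLUMNS
from itsmeta.model import margin_draws


def intercept_only_design(y, se):
    n = len(y)
    return ItsDesign(
        X=np.ones((n, 1)),
        column_names=["intercept"],
        y=np.asarray(y, float),
        se=np.asarray(se, float),
        school_index=np.zeros(n, dtype=np.int64),
        cohort_index=np.zeros(n, dtype=np.int64),
        school_labels=["A"],
        cohort_labels=[("A", 0)],
        event_year=2014,
        first_year=2008,
    )


def fit_with_draws(draws_by_coef, scaling=None):
    """Wrap fixed draw vectors in a PosteriorFit for summary-level tests."""
    names = list(draws_by_coef)
    beta = np.stack([np.asarray(draws_by_coef[c], float) for c in names], axis=-1)
    beta = beta[None, :, :]  # one chain
    kept = beta.shape[1]
    zeros = np.zeros((1, kept))
    return PosteriorFit(
        beta=beta, sigma_school=zeros, sigma_cohort=zeros, sigma_e=zeros,
        theta_school=np.zeros((1, kept, 1)), theta_cohort=np.zeros((1, kept, 1)),
        column_names=names, scaling_metadata=scaling or {}, event_year=2014,
        first_year=2008, domain=None, priors=PriorSpec(),
        mcmc=McmcConfig(chains=1, iterations=2 * kept), design_hash="test",
    )


class TestConjugateOracle:
    def test_intercept_only_matches_closed_form(self, rng):
        """With SDs pinned at zero the posterior for the intercept is the
        textbook normal-normal posterior with known variances."""
        n = 30
        se = rng.uniform(2.0, 8.0, n)
        y = rng.normal(-4.0, 6.0, n)
        design = intercept_only_design(y, se)
        prior_sd = 50.0
        priors = PriorSpec(fixed_effect_sd=prior_sd).with_all_sds_fixed(0.0)
        fit = fit_model(design, priors, McmcConfig(chains=2, iterations=2000, seed=4),
                        diagnostics=False)

        w = 1.0 / se**2
        post_prec = w.sum() + 1.0 / prior_sd**2
        post_mean = (w * y).sum() / post_prec
        post_sd = 1.0 / np.sqrt(post_prec)

        draws = fit.beta_draws("intercept")
        m = len(draws)  # draws are iid here (direct conditional sampling)
        mcse_mean = post_sd / np.sqrt(m)
        mcse_sd = post_sd * np.sqrt(1.0 / (2.0 * m))
        assert abs(draws.mean() - post_mean) < 3 * mcse_mean
        assert abs(draws.std(ddof=1) - post_sd) < 3 * mcse_sd

    def test_no_signal_shrinks_to_zero(self):
        n = 40
        design = intercept_only_design(np.zeros(n), np.full(n, 5.0))
        priors = PriorSpec().with_all_sds_fixed(0.0)
        fit = fit_model(design, priors, McmcConfig(chains=2, iterations=600, seed=1),
                        diagnostics=False)
        assert abs(fit.beta_draws("intercept").mean()) < 0.5 * priors.fixed_effect_sd
        assert abs(fit.beta_draws("intercept").mean()) < 1.0

    def test_nonpositive_se_rejected(self):
        design = intercept_only_design([1.0, 2.0], [1.0, 0.0])
        with pytest.raises(ValueError, match="standard errors"):
            fit_model(design)


class TestRecoveryOnDefaultStudy:
    def test_its_coefficients_within_two_posterior_sds(self, default_fit, centred_study):
        truth = centred_study[3]
        table = summarize(default_fit)
        expected = {
            "trend": truth.beta_t,
            "moderate_pre": truth.beta_m_pre,
            "high_pre": truth.beta_h_pre,
            "moderate_interruption": truth.beta_m_int,
            "high_interruption": truth.beta_h_int,
            "moderate_post_trend": truth.beta_m_trend,
            "high_post_trend": truth.beta_h_trend,
        }
        for coef, true_value in expected.items():
            row = table.loc[coef]
            assert abs(row["mean"] - true_value) < 2 * row["sd"], coef

    def test_diagnostics_attached(self, default_fit):
        diag = default_fit.diagnostics
        assert diag["divergences"] == 0
        assert np.isfinite(diag["max_rhat"])
        assert diag["min_ess"] > 0

    def test_doubling_iterations_is_stable(self, default_design, default_fit):
        """Posterior means are already converged at the default length."""
        import arviz as az

        longer = fit_model(default_design,
                           mcmc=McmcConfig(chains=2, iterations=2000, seed=7),
                           diagnostics=False)
        short_ess = az.ess(default_fit.to_inference_data(), var_names=["beta"])
        long_ess = az.ess(longer.to_inference_data(), var_names=["beta"])
        for coef in ITS_COLUMNS:
            j = default_fit.column_names.index(coef)
            a, b = default_fit.beta[:, :, j].ravel(), longer.beta[:, :, j].ravel()
            mcse = np.sqrt(
                a.var(ddof=1) / float(short_ess["beta"][j])
                + b.var(ddof=1) / float(long_ess["beta"][j])
            )
            assert abs(a.mean() - b.mean()) < 2.5 * mcse, coef


class TestSummaries:
    def test_fixed_draw_set(self):
        # 100 draws cycling {-1, -2, 3, 4}: mean 1.0, half below zero
        draws = np.tile([-1.0, -2.0, 3.0, 4.0], 25)
        table = summarize(fit_with_draws({"x": draws}))
        assert table.loc["x", "mean"] == pytest.approx(1.0)
        assert table.loc["x", "p_lt_0"] == pytest.approx(0.5)
        assert table.loc["x", "p_gt_0"] == pytest.approx(0.5)

    def test_all_positive_draws(self):
        table = summarize(fit_with_draws({"x": np.linspace(0.5, 2.0, 120)}))
        assert table.loc["x", "p_gt_0"] == 1.0
        assert table.loc["x", "p_lt_0"] == 0.0

    def test_tail_probabilities_sum_to_one(self, default_fit):
        table = summarize(default_fit)
        np.testing.assert_allclose(table["p_lt_0"] + table["p_gt_0"], 1.0)

    def test_interval_contains_mean(self, default_fit):
        table = summarize(default_fit)
        assert ((table["ci_2.5"] <= table["mean"])
                & (table["mean"] <= table["ci_97.5"])).all()

    def test_natural_units_rescaling(self):
        draws = np.linspace(-1.0, 1.0, 200)
        scaled = summarize(
            fit_with_draws({"icsea": draws}, scaling={"icsea": (960.0, 40.0)})
        )
        model_units = summarize(fit_with_draws({"icsea": draws}))
        assert scaled.loc["icsea", "mean"] == pytest.approx(
            model_units.loc["icsea", "mean"] / 40.0
        )

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(fit_with_draws({"x": np.ones(40)}))


class TestPredictedMargins:
    def test_pre_event_group_gap_is_pre_coefficient(self, default_fit):
        """margin(high) - margin(no_low) before the event equals beta_h_pre
        draw by draw (exact linear identity)."""
        gap = (margin_draws(default_fit, 2010, "high")
               - margin_draws(default_fit, 2010, "no_low"))
        np.testing.assert_allclose(gap, default_fit.beta_draws("high_pre"))

    def test_event_year_jump_is_trend_plus_interruption(self, default_fit):
        jump = (margin_draws(default_fit, 2014, "high")
                - margin_draws(default_fit, 2013, "high"))
        expected = (default_fit.beta_draws("trend")
                    + default_fit.beta_draws("high_interruption"))
        np.testing.assert_allclose(jump, expected)

    def test_control_margin_is_trend_line(self, default_fit):
        """No-low margins move by beta_t per year with no exposure terms."""
        step = (margin_draws(default_fit, 2012, "no_low")
                - margin_draws(default_fit, 2011, "no_low"))
        np.testing.assert_allclose(step, default_fit.beta_draws("trend"))

    def test_margins_table_layout(self, default_fit):
        years = range(2008, 2019)
        table = predicted_margins(default_fit, years)
        assert len(table) == 11 * 3
        assert ((table["ci_2.5"] <= table["mean"])
                & (table["mean"] <= table["ci_97.5"])).all()

    def test_year_outside_span_rejected(self, default_fit):
        with pytest.raises(ValueError, match="span"):
            predicted_margins(default_fit, [1990])


class TestEffectToMonths:
    @pytest.mark.parametrize(
        "effect, expected",
        [(27.0, 12.0), (0.0, 0.0), (11.09, 4.93), (10.31, 4.58)],
    )
    def test_conversion(self, effect, expected):
        assert round(effect_to_months(effect), 2) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            effect_to_months(10.0, points_per_year=0.0)


class TestConfigs:
    def test_mcmc_warmup_default_is_half(self):
        mcmc = McmcConfig(iterations=2000)
        assert mcmc.n_warmup == 1000 and mcmc.kept == 1000

    def test_bad_mcmc_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, warmup=100)

    def test_bad_priors_rejected(self):
        with pytest.raises(ValueError):
            SdPrior(sd=0.0)
        with pytest.raises(ValueError):
            PriorSpec(fixed_effect_sd=-1.0)
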