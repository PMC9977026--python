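"""ITS codings, design-matrix assembly, and scaling back-transformation."""

import numpy as np
import pandas as pd
import pytest

from itsmeta import ITS_COLUMNS, build_design, center_scores, its_terms
from itsmeta.simulate import SimulationConfig, generate_study

# Hand-computed ITS codings for one school over 2008-2018, event year 2014:
# T counts from 0 in 2008; the interruption indicator switches on in 2014;
# the post-event clock T_post is 0 through 2014 and then 1, 2, ... Values
# are (T, interruption, post_trend) shared by the school's exposure block.
HAND_TABLE = {
    2008: (0, 0, 0), 2009: (1, 0, 0), 2010: (2, 0, 0), 2011: (3, 0, 0),
    2012: (4, 0, 0), 2013: (5, 0, 0), 2014: (6, 1, 0), 2015: (7, 1, 1),
    2016: (8, 1, 2), 2017: (9, 1, 3), 2018: (10, 1, 4),
}


class TestItsTerms:
    def test_first_year_control_school(self):
        terms = its_terms(2008, "no_low", 2014)
        assert terms["trend"] == 0
        assert all(terms[c] == 0 for c in ITS_COLUMNS if c != "trend")

    def test_post_event_high_school(self):
        terms = its_terms(2015, "high", 2014)
        assert terms["trend"] == 7
        assert terms["high_pre"] == 1
        assert terms["high_interruption"] == 1
        assert terms["high_post_trend"] == 1
        assert terms["moderate_pre"] == terms["moderate_interruption"] == 0

    def test_pre_event_moderate_school(self):
        terms = its_terms(2013, "moderate", 2014)
        assert terms["trend"] == 5
        assert terms["moderate_pre"] == 1
        assert terms["moderate_interruption"] == 0
        assert terms["moderate_post_trend"] == 0

    @pytest.mark.parametrize("group, prefix", [("high", "high"), ("moderate", "moderate")])
    def test_full_span_matches_hand_table(self, group, prefix):
        """Exact integer equality against the hand-computed 2008-2018 table."""
        other = "moderate" if group == "high" else "high"
        for year, (t, interruption, post_trend) in HAND_TABLE.items():
            terms = its_terms(year, group, event_year=2014, first_year=2008)
            assert terms["trend"] == t
            assert terms[f"{prefix}_pre"] == 1
            assert terms[f"{prefix}_interruption"] == interruption
            assert terms[f"{prefix}_post_trend"] == post_trend
            assert terms[f"{other}_pre"] == 0
            assert terms[f"{other}_interruption"] == 0
            assert terms[f"{other}_post_trend"] == 0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="exposure group"):
            its_terms(2014, "severe", 2014)


class TestBuildDesign:
    def test_shape_and_alignment(self, default_design):
        d = default_design
        assert d.X.shape == (len(d.y), len(d.column_names))
        assert len(d.se) == len(d.y)
        # 68 schools teach 2 grades, the 1 combined school all 4, over 11 years
        assert d.X.shape[0] == (68 * 2 + 1 * 4) * 11

    def test_row_invariants(self, default_design):
        d = default_design
        assert not np.any(d.column("moderate_pre") * d.column("high_pre"))
        for prefix in ("moderate", "high"):
            pre_event = d.column(f"{prefix}_interruption") == 0
            assert not d.column(f"{prefix}_post_trend")[pre_event].any()
        no_low = (d.column("moderate_pre") == 0) & (d.column("high_pre") == 0)
        exposure = [c for c in ITS_COLUMNS if c != "trend"]
        for c in exposure:
            assert not d.column(c)[no_low].any()

    def test_single_school_design_matches_hand_table(self):
        config = SimulationConfig(
            n_schools_by_group={"high": 1}, seed=0, domains=("reading",)
        )
        obs, profiles, reference, truth = generate_study(config)
        centred = center_scores(obs, reference)
        d = build_design(centred, profiles, "reading", truth.event_year,
                         check_rank=False)
        years = centred["year"].to_numpy()
        for year, (t, interruption, post_trend) in HAND_TABLE.items():
            rows = years == year
            assert (d.column("trend")[rows] == t).all()
            assert (d.column("high_pre")[rows] == 1).all()
            assert (d.column("high_interruption")[rows] == interruption).all()
            assert (d.column("high_post_trend")[rows] == post_trend).all()

    def test_identical_covariates_identical_rows(self, centred_study):
        """Duplicating a cell (new y, same covariates) duplicates its X row."""
        centred, profiles, _, truth = centred_study
        doubled = pd.concat(
            [centred, centred.iloc[[0]].assign(mean=centred["mean"].iloc[0] + 5)],
            ignore_index=True,
        )
        d = build_design(doubled, profiles, "reading", truth.event_year)
        first, last = d.X[0], d.X[-1]
        np.testing.assert_allclose(first, last)

    def test_row_order_invariance(self, centred_study):
        centred, profiles, _, truth = centred_study
        d1 = build_design(centred, profiles, "reading", truth.event_year)
        shuffled = centred.sample(frac=1.0, random_state=3)
        d2 = build_design(shuffled, profiles, "reading", truth.event_year)
        order1, order2 = np.argsort(d1.y), np.argsort(d2.y)  # y values are a.s. unique
        np.testing.assert_allclose(d1.X[order1], d2.X[order2])
        np.testing.assert_allclose(d1.y[order1], d2.y[order2])

    def test_scaling_metadata_recorded(self, default_design):
        for col in ("icsea", "enrolments", "prop_girls"):
            center, scale = default_design.scaling_metadata[col]
            assert scale > 0
            assert abs(default_design.column(col).mean()) < 1e-9

    def test_missing_profile_school_rejected(self, centred_study):
        centred, profiles, _, truth = centred_study
        with pytest.raises(KeyError, match="GHOST"):
            build_design(
                pd.concat([centred, centred.iloc[[0]].assign(school_id="GHOST")]),
                profiles, "reading", truth.event_year,
            )

    def test_constant_covariate_triggers_rank_error(self, centred_study):
        centred, profiles, _, truth = centred_study
        flat = profiles.assign(icsea=960.0)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(centred, flat, "reading", truth.event_year)

    def test_empty_domain_rejected(self, centred_study):
        centred, profiles, _, truth = centred_study
        with pytest.raises(ValueError, match="no observations"):
            build_design(centred, profiles, "latin", truth.event_year)


class TestBackTransform:
    def test_scaled_and_raw_wls_agree(self, centred_study):
        """coef(scaled column) / scale equals coef(raw column) under WLS."""
        import statsmodels.api as sm

        centred, profiles, _, truth = centred_study
        scaled = build_design(centred, profiles, "reading", truth.event_year)
        raw = build_design(centred, profiles, "reading", truth.event_year,
                           scale_continuous=False)
        w = 1.0 / scaled.se**2
        fit_scaled = sm.WLS(scaled.y, scaled.X, weights=w).fit()
        fit_raw = sm.WLS(raw.y, raw.X, weights=w).fit()
        for col, (_, scale) in scaled.scaling_metadata.items():
            j = scaled.column_names.index(col)
            assert fit_scaled.params[j] / scale == pytest.approx(
                fit_raw.params[j], rel=1e-8, abs=1e-10
            )
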