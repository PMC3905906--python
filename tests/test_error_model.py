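"""Analytic misclassification model: worked examples, study predictions,
theoretical curves, and the follow-up-duration inverse."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telogain import (
    IncompleteRecordError,
    curve_table,
    cv_to_sigma,
    gainer_probability,
    predict_study,
    required_followup,
    round_half_away,
    sigma_of_difference,
)


def phi_lower_tail(z: float) -> float:
    """Independent normal-CDF oracle via the C library's erfc."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


class TestCvToSigma:
    @pytest.mark.parametrize(
        "cv,mean_tl,expected",
        [(0.03, 7000.0, 210.0), (0.0, 7000.0, 0.0), (0.015, 7400.0, 111.0)],
    )
    def test_definitional_arithmetic(self, cv, mean_tl, expected):
        assert cv_to_sigma(cv, mean_tl) == pytest.approx(expected)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            cv_to_sigma(-0.01, 7000.0)


class TestSigmaOfDifference:
    @pytest.mark.parametrize(
        "sigma,r,expected",
        [
            (150.0, 1, 150.0 * math.sqrt(2)),  # single measurements: ~212 bp
            (150.0, 2, 150.0),                 # duplicates averaged: sigma itself
            (100.0, 8, 50.0),
        ],
    )
    def test_replicate_scaling(self, sigma, r, expected):
        assert sigma_of_difference(sigma, r) == pytest.approx(expected)

    def test_unequal_replicate_counts(self):
        got = sigma_of_difference(100.0, replicates=2, replicates_followup=4)
        assert got == pytest.approx(100.0 * math.sqrt(1 / 2 + 1 / 4))

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            sigma_of_difference(100.0, 0)


class TestGainerProbability:
    def test_worked_example_two_sigma_loss(self):
        # true loss 300 bp, sigma_d 150 bp -> lower tail at z = -2
        assert gainer_probability(300.0, 150.0) == pytest.approx(0.02275, abs=5e-6)

    def test_zero_loss_is_a_coin_flip(self):
        assert gainer_probability(0.0, 123.4) == pytest.approx(0.5)

    def test_against_erfc_oracle(self):
        # the CV-6.4-style chain: mu 210 bp, sigma_d 282.29 bp
        assert gainer_probability(210.0, 282.29) == pytest.approx(
            phi_lower_tail(210.0 / 282.29), rel=1e-12
        )
        assert gainer_probability(210.0, 282.29) == pytest.approx(0.2284, abs=1e-4)

    def test_degenerate_sigma_rejected_not_silently_zero(self):
        with pytest.raises(ValueError, match="sigma_d"):
            gainer_probability(300.0, 0.0)

    @given(
        mu=st.floats(-500, 500),
        sigma_d=st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_in_sign_of_loss(self, mu, sigma_d):
        p = gainer_probability(mu, sigma_d)
        q = gainer_probability(-mu, sigma_d)
        assert p + q == pytest.approx(1.0, abs=1e-12)

    @given(
        mu=st.floats(0.0, 500.0),
        sigma_d=st.floats(100.0, 500.0),
        bump=st.floats(1.0, 200.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_loss_and_noise(self, mu, sigma_d, bump):
        p = gainer_probability(mu, sigma_d)
        assert 0.0 < p <= 0.5
        assert gainer_probability(mu + bump, sigma_d) < p
        assert gainer_probability(mu, sigma_d + bump) >= p  # equality only at mu=0


# One-decimal predicted gainer percentages for every study with complete inputs.
EXPECTED_PREDICTIONS = {
    "gardner2005": 0.1,
    "aviv2009": 1.0,
    "ehrlenbach2009": 0.0,
    "farzanehfar2010": 22.8,
    "chen2011a": 14.8,
    "chen2011b": 9.6,
    "chen2011c": 1.0,
    "kark2012": 1.8,
    "steenstrup2013": 1.7,
}


class TestPredictStudy:
    @pytest.mark.parametrize("study_id,expected", sorted(EXPECTED_PREDICTIONS.items()))
    def test_published_predictions_reproduce(self, catalog_by_id, study_id, expected):
        pred = predict_study(catalog_by_id[study_id])
        assert pred.predicted_pct == expected

    def test_trace_is_internally_consistent(self, catalog_by_id):
        pred = predict_study(catalog_by_id["steenstrup2013"])
        assert pred.mu_total == pytest.approx(30.8 * 10.9)
        assert pred.sigma == pytest.approx(0.028 * 5675.0)
        assert pred.sigma_d == pred.sigma  # duplicates
        assert pred.z == pytest.approx(pred.mu_total / pred.sigma_d)
        assert pred.probability == pytest.approx(phi_lower_tail(pred.z), rel=1e-12)

    def test_cv_override_reevaluates_a_study(self, catalog_by_id):
        pred = predict_study(catalog_by_id["farzanehfar2010"], cv_override=0.064)
        assert pred.predicted_pct == 33.4

    def test_relative_units_study_predicts_in_ts_units(self, catalog_by_id):
        pred = predict_study(catalog_by_id["svenson2011"])
        # half-year follow-up with a tiny change: essentially a coin flip
        assert 0.49 < pred.probability < 0.5

    def test_incomplete_record_raises_naming_fields(self, catalog_by_id):
        with pytest.raises(IncompleteRecordError, match="attrition_rate"):
            predict_study(catalog_by_id["epel2009"])

    def test_mean_tl_conventions(self, catalog_by_id):
        rec = catalog_by_id["kark2012"]
        base = predict_study(rec, mean_tl="baseline")
        fixed = predict_study(rec, mean_tl=7330.0)
        assert base.sigma == pytest.approx(0.022 * 7330.0)
        assert base.probability == pytest.approx(fixed.probability)
        with pytest.raises(ValueError, match="convention"):
            predict_study(rec, mean_tl="median")


class TestCurveTable:
    def test_headline_cells_at_ten_years(self):
        tab = curve_table([0.03, 0.05], attrition_rate=30.0, replicates=2,
                          fu_grid=[10.0], mean_tl=7000.0)
        by_cv = tab.set_index("cv")["predicted_pct"]
        assert by_cv[0.03] == pytest.approx(7.656, abs=1e-3)
        assert by_cv[0.05] == pytest.approx(19.568, abs=1e-3)

    def test_monotone_along_both_axes(self):
        tab = curve_table([0.01, 0.03, 0.05], attrition_rate=30.0, replicates=2,
                          fu_grid=[2.0, 6.0, 10.0, 14.0])
        for _, traj in tab.groupby("cv"):
            assert traj.sort_values("followup_years")["predicted_pct"].is_monotonic_decreasing
        for _, col in tab.groupby("followup_years"):
            assert col.sort_values("cv")["predicted_pct"].is_monotonic_increasing

    def test_long_followup_limit_vanishes(self):
        tab = curve_table([0.05], attrition_rate=30.0, replicates=1, fu_grid=[1e4])
        assert tab["predicted_pct"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            curve_table([], fu_grid=[10.0])


class TestRequiredFollowup:
    def test_inverts_the_curve_to_high_precision(self):
        for target in (1.0, 7.65, 25.0):
            t = required_followup(0.03, 2, 30.0, target)
            cell = curve_table([0.03], 30.0, 2, fu_grid=[t])["predicted_pct"].iloc[0]
            assert cell == pytest.approx(target, abs=1e-9)

    def test_headline_target_needs_ten_years(self):
        assert required_followup(0.03, 2, 30.0, 7.65) == pytest.approx(10.0, abs=0.01)

    def test_halving_attrition_doubles_duration(self):
        t_fast = required_followup(0.04, 1, 30.0, 5.0)
        t_slow = required_followup(0.04, 1, 15.0, 5.0)
        assert t_slow == pytest.approx(2 * t_fast)

    @pytest.mark.parametrize("target", [50.0, 60.0, 0.0, -1.0])
    def test_unreachable_targets_rejected(self, target):
        with pytest.raises(ValueError):
            required_followup(0.03, 2, 30.0, target)

    def test_zero_attrition_rejected(self):
        with pytest.raises(ValueError):
            required_followup(0.03, 2, 0.0, 5.0)


@pytest.mark.parametrize(
    "x,ndigits,expected",
    [(22.85, 1, 22.9), (0.05, 1, 0.1), (-0.05, 1, -0.1), (2.2750132, 2, 2.28),
     (49.585, 1, 49.6), (7.65, 0, 8.0)],
)
def test_round_half_away_ties_go_outward(x, ndigits, expected):
    assert round_half_away(x, ndigits) == expected
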