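"""Stage-1/stage-2 estimation tests: covariate encoding, logistic MLE
against the closed-form 2x2 oracle and statsmodels, Firth fallback under
separation, and inverse-variance pooling algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_cohort, two_arm_study
from multitrial.estimation import (ANY_MED_VS_ETAU, MED_PN_VS_MED,
                                   StudyEstimate, encode_covariates,
                                   fit_study_logistic, get_contrast,
                                   pool_estimates)
from multitrial.exceptions import NonEstimableError, ValidationError


def crude_log_or(a, b, c, d):
    """log((a*d)/(b*c)) for treated pos/neg a,b and reference pos/neg c,d."""
    return math.log((a * d) / (b * c))


class TestEncoding:
    def test_reference_row_encoding(self):
        # target participant: age at the study mean, male, White, housed,
        # no stimulant use, control arm
        rows = [
            {"age": 39.0, "sex": "male", "race": "White"},
            {"age": 29.0, "sex": "female", "race": "Black", "arm": "MED",
             "unhoused": True, "stimulant_use": True},
            {"age": 49.0, "sex": "male", "race": "Other", "arm": "MED"},
        ]
        sd = encode_covariates(make_cohort(rows))
        assert sd.colnames == ["intercept", "treat", "age_c", "female",
                               "race_White", "race_Other", "unhoused",
                               "stimulant"]
        X = np.column_stack([np.ones(3), sd.treat, sd.Z])
        np.testing.assert_allclose(X[0], [1, 0, 0, 0, 1, 0, 0, 0])

    def test_single_level_covariate_dropped_with_warning(self):
        rows = [{"sex": "female"}, {"sex": "female", "arm": "MED"}]
        sd = encode_covariates(make_cohort(rows))
        assert "female" not in sd.colnames
        assert any("female" in w for w in sd.warnings)

    def test_race_other_dummy_coding(self):
        rows = [{"race": "Other"}, {"race": "Black", "arm": "MED"},
                {"race": "White"}]
        sd = encode_covariates(make_cohort(rows))
        i_w = sd.colnames.index("race_White") - 2
        i_o = sd.colnames.index("race_Other") - 2
        assert sd.Z[0, i_w] == 0 and sd.Z[0, i_o] == 1
        assert sd.Z[1, i_w] == 0 and sd.Z[1, i_o] == 0
        assert sd.Z[2, i_w] == 1 and sd.Z[2, i_o] == 0

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValidationError, match="covariate"):
            encode_covariates(make_cohort([{}]), covariates=("shoe_size",))


class TestStudyFit:
    def test_matches_crude_log_cross_ratio(self):
        df = two_arm_study(30, 10, 35, 5)
        est = fit_study_logistic(df, covariates=())
        assert est.theta_hat == pytest.approx(crude_log_or(30, 10, 35, 5), abs=1e-3)
        assert est.se == pytest.approx(
            math.sqrt(1 / 30 + 1 / 10 + 1 / 35 + 1 / 5), abs=1e-3)
        assert est.converged and not est.penalized
        assert est.n_treated == 40 and est.n_reference == 40

    def test_identical_arms_give_zero_effect(self):
        df = two_arm_study(12, 8, 12, 8)
        est = fit_study_logistic(df, covariates=())
        assert abs(est.theta_hat) < 1e-8

    def test_separation_triggers_penalized_fit(self):
        df = two_arm_study(15, 0, 8, 7)  # treated arm all positive
        est = fit_study_logistic(df, covariates=())
        assert est.penalized
        assert np.isfinite(est.theta_hat) and est.variance > 0

    def test_single_outcome_level_non_estimable(self):
        df = two_arm_study(10, 0, 10, 0)
        with pytest.raises(NonEstimableError, match="single level"):
            fit_study_logistic(df, covariates=())

    def test_missing_contrast_arm_non_estimable(self):
        df = make_cohort([{"arm": "MED", "outcome": "positive"},
                          {"arm": "MED"}])
        with pytest.raises(NonEstimableError):
            fit_study_logistic(df, covariates=())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_lone_binary_predictor_equals_closed_form(self, cells):
        a, b, c, d = cells
        df = two_arm_study(a, b, c, d)
        est = fit_study_logistic(df, covariates=())
        assert est.theta_hat == pytest.approx(crude_log_or(a, b, c, d), abs=1e-6)
        assert not est.penalized

    def test_adjusted_fit_matches_statsmodels(self, default_cohort):
        import statsmodels.api as sm

        study = default_cohort[default_cohort["study_id"] == "site1"]
        est = fit_study_logistic(study, ANY_MED_VS_ETAU)
        sd = encode_covariates(study, contrast=ANY_MED_VS_ETAU)
        X = np.column_stack([np.ones(len(sd.y)), sd.treat, sd.Z])
        ref = sm.GLM(sd.y, X, family=sm.families.Binomial()).fit()
        assert est.theta_hat == pytest.approx(ref.params[1], abs=1e-6)
        assert est.se == pytest.approx(ref.bse[1], rel=1e-4)

    def test_pn_contrast_uses_med_arms_only(self, default_cohort):
        study = default_cohort[default_cohort["study_id"] == "site3"]
        est = fit_study_logistic(study, MED_PN_VS_MED)
        assert est.n_treated == 54 and est.n_reference == 46


class TestPooling:
    def make(self, study_id, theta, var):
        return StudyEstimate(study_id=study_id, theta_hat=theta, variance=var,
                             se=math.sqrt(var), n_treated=1, n_reference=1,
                             converged=True, penalized=False)

    def test_single_study_reduction(self):
        pooled = pool_estimates([self.make("a", 0.7, 0.09)])
        assert pooled.theta_p == pytest.approx(0.7)
        assert pooled.se_p == pytest.approx(0.3)

    def test_hand_computed_two_study_average(self):
        pooled = pool_estimates([self.make("a", 0.5, 0.04),
                                 self.make("b", -0.3, 0.01)])
        assert pooled.weights == {"a": pytest.approx(25.0), "b": pytest.approx(100.0)}
        assert pooled.theta_p == pytest.approx(-0.14)
        assert pooled.se_p == pytest.approx(math.sqrt(1 / 125))

    def test_constant_estimates_pool_to_constant(self):
        ests = [self.make(s, -0.4, v) for s, v in (("a", 0.1), ("b", 0.5), ("c", 2.0))]
        assert pool_estimates(ests).theta_p == pytest.approx(-0.4)

    def test_order_invariance_and_convex_hull(self, rng):
        ests = [self.make(f"s{i}", rng.normal(), rng.uniform(0.01, 1.0))
                for i in range(6)]
        p1 = pool_estimates(ests)
        p2 = pool_estimates(list(reversed(ests)))
        assert p1.theta_p == pytest.approx(p2.theta_p)
        thetas = [e.theta_hat for e in ests]
        assert min(thetas) <= p1.theta_p <= max(thetas)

    def test_weight_rescaling_invariance(self):
        # scaling all variances by a constant rescales weights but not theta_p
        ests = [self.make("a", 0.5, 0.04), self.make("b", -0.3, 0.01)]
        scaled = [self.make("a", 0.5, 0.4), self.make("b", -0.3, 0.1)]
        assert pool_estimates(ests).theta_p == pytest.approx(
            pool_estimates(scaled).theta_p)

    def test_errors(self):
        with pytest.raises(ValidationError, match="empty"):
            pool_estimates([])
        with pytest.raises(ValidationError, match="bad_study"):
            pool_estimates([self.make("bad_study", 0.0, 0.0)])


def test_contrast_lookup_and_eligibility(default_cohort):
    assert get_contrast("any_med_vs_etau") is ANY_MED_VS_ETAU
    assert ANY_MED_VS_ETAU.eligible(default_cohort) == ["site1", "site2", "site3"]
    assert MED_PN_VS_MED.eligible(default_cohort) == ["site2", "site3"]
    with pytest.raises(ValidationError):
        get_contrast("nope")
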