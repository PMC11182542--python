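"""Generator tests: design registry, determinism, marginal and generative
consistency, follow-up/missingness processes, and the simulation-side
estimand."""

import math

import numpy as np
import pandas as pd
import pytest

from multitrial.exceptions import ValidationError
from multitrial.simulate import (CovariateDistributions, Missingness,
                                 SimulationConfig, StudyDesign,
                                 apply_followup_process, consort_flow_config,
                                 default_config, generate_cohort,
                                 three_site_designs, true_pooled_log_or)


def single_study_config(n_per_arm, theta=0.0, intercept=0.0, flat=True,
                        seed=0, missing_rate=0.0, mechanism="MCAR",
                        logit_shift=0.0, exclusions=None):
    from multitrial.simulate import DEFAULT_COVARIATE_EFFECTS

    cfg = SimulationConfig(
        designs=[StudyDesign("s1", {"MED": n_per_arm, "ETAU": n_per_arm},
                             "XR-NTX")],
        study_intercepts={"s1": intercept},
        theta_med={"s1": theta},
        covariate_effects={} if flat else dict(DEFAULT_COVARIATE_EFFECTS),
        missingness=Missingness(mechanism, missing_rate, logit_shift),
        seed=seed,
    )
    if exclusions:
        cfg.exclusion_rates = exclusions
    cfg.validate()
    return cfg


class TestRegistry:
    def test_three_site_design_counts(self):
        designs = three_site_designs()
        assert sum(d.n_total for d in designs) == 330
        by_id = {d.study_id: d for d in designs}
        assert by_id["site1"].arm_sizes == {"MED": 58, "ETAU": 52}
        assert by_id["site2"].arm_sizes == {"MED": 29, "MED_PN": 21, "ETAU": 19}
        assert by_id["site3"].arm_sizes == {"MED": 46, "MED_PN": 54, "ETAU": 51}
        assert by_id["site3"].n_total == 151
        assert not by_id["site1"].has_pn_arm
        assert by_id["site2"].has_pn_arm and by_id["site3"].has_pn_arm

    def test_generated_cohort_matches_registry(self):
        cohort = generate_cohort(default_config(seed=1))
        assert len(cohort) == 330
        counts = cohort.groupby(["study_id", "arm"]).size()
        assert counts[("site1", "MED")] == 58
        assert counts[("site2", "MED_PN")] == 21
        assert counts[("site3", "ETAU")] == 51
        # medication typing follows the design
        med = cohort[cohort["arm"] != "ETAU"]
        assert (med.loc[med["study_id"] == "site3", "medication_type"] == "IM").all()
        assert (cohort.loc[cohort["arm"] == "ETAU", "medication_type"] == "none").all()

    def test_validation_errors_name_the_field(self):
        with pytest.raises(ValidationError, match="designs"):
            SimulationConfig(designs=[], study_intercepts={}, theta_med={}).validate()
        with pytest.raises(ValidationError, match="race_probs"):
            CovariateDistributions(race_probs=(0.5, 0.4, 0.2)).validate()
        with pytest.raises(ValidationError, match="theta_med"):
            SimulationConfig(designs=three_site_designs(),
                             study_intercepts={d.study_id: 0.0 for d in three_site_designs()},
                             theta_med={}).validate()
        cfg = default_config()
        cfg.exclusion_rates = {"prison_transfer": 0.7,
                               "incarcerated_at_followup": 0.6, "deceased": 0.0}
        with pytest.raises(ValidationError, match="sum above 1"):
            cfg.validate()


class TestGeneration:
    def test_deterministic_given_seed(self):
        a = generate_cohort(default_config(seed=42))
        b = generate_cohort(default_config(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(default_config(seed=43))
        assert not a["outcome"].equals(c["outcome"])

    def test_null_symmetry_both_arms_half_positive(self):
        cfg = single_study_config(10_000, theta=0.0, intercept=0.0)
        cohort = generate_cohort(cfg)
        for arm in ("MED", "ETAU"):
            frac = (cohort.loc[cohort["arm"] == arm, "outcome"] == "positive").mean()
            assert abs(frac - 0.5) < 3 * 0.005  # 3 binomial SEs at n=1e4

    def test_large_sample_odds_ratio_recovery(self):
        cfg = single_study_config(50_000, theta=math.log(3.0), intercept=0.0)
        cohort = generate_cohort(cfg)
        p = {arm: (cohort.loc[cohort["arm"] == arm, "outcome"] == "positive").mean()
             for arm in ("MED", "ETAU")}
        emp_or = (p["MED"] / (1 - p["MED"])) / (p["ETAU"] / (1 - p["ETAU"]))
        assert abs(emp_or - 3.0) / 3.0 < 0.05

    def test_covariate_marginals_converge(self):
        cfg = single_study_config(5_000)
        cd = cfg.covariate_distributions
        cohort = generate_cohort(cfg)
        n = len(cohort)
        se = lambda p: math.sqrt(p * (1 - p) / n)
        assert abs((cohort["sex"] == "female").mean() - cd.p_female) < 3 * se(cd.p_female)
        assert abs((cohort["race"] == "White").mean() - cd.race_probs[1]) < 3 * se(cd.race_probs[1])
        assert abs(cohort["unhoused"].mean() - cd.p_unhoused) < 3 * se(cd.p_unhoused)
        assert abs(cohort["stimulant_use"].mean() - cd.p_stimulant_use) < 3 * se(cd.p_stimulant_use)
        assert abs(cohort["age"].mean() - cd.age_mean) < 3 * cd.age_sd / math.sqrt(n) + 0.2
        assert cohort["age"].between(*cd.age_bounds).all()


class TestFollowupProcess:
    def test_zero_rates_identity(self):
        cfg = single_study_config(200, seed=5)
        cohort = generate_cohort(cfg)
        out = apply_followup_process(cohort, cfg)
        assert (out["follow_up_status"] == "in_community").all()
        assert out["outcome"].equals(cohort["outcome"])

    def test_mcar_missingness_rate(self):
        cfg = single_study_config(5_000, missing_rate=0.2)
        out = apply_followup_process(generate_cohort(cfg), cfg)
        assert abs((out["outcome"] == "missing").mean() - 0.2) < 0.01

    def test_outcome_dependent_missingness_is_differential(self):
        cfg = single_study_config(10_000, missing_rate=0.15,
                                  mechanism="outcome_dependent", logit_shift=1.0)
        cohort = generate_cohort(cfg)
        out = apply_followup_process(cohort, cfg)
        was_positive = cohort["outcome"] == "positive"
        miss_pos = (out.loc[was_positive, "outcome"] == "missing").mean()
        miss_neg = (out.loc[~was_positive, "outcome"] == "missing").mean()
        assert miss_pos > miss_neg + 0.05

    def test_consort_scale_flow(self):
        cfg = consort_flow_config(seed=9)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 488
        out = apply_followup_process(cohort, cfg)
        counts = out["follow_up_status"].value_counts()
        # expected 48 prison transfers, 110 incarcerated at follow-up
        assert abs(counts.get("prison_transfer", 0) - 48) < 3 * math.sqrt(48 * (1 - 48 / 488))
        assert abs(counts.get("incarcerated_at_followup", 0) - 110) < 3 * math.sqrt(110 * (1 - 110 / 488))

    def test_rates_summing_above_one_rejected(self):
        cfg = single_study_config(10)
        with pytest.raises(ValidationError):
            apply_followup_process(generate_cohort(cfg), single_study_config(
                10, exclusions={"prison_transfer": 0.6,
                                "incarcerated_at_followup": 0.5,
                                "deceased": 0.0}))


class TestTrueParameters:
    def test_constant_thetas_pool_to_constant(self):
        cfg = default_config(theta_med=-0.4)
        assert true_pooled_log_or(cfg).theta_p_true == pytest.approx(-0.4)

    def test_hand_computed_weighted_average(self):
        cfg = SimulationConfig(
            designs=[StudyDesign("a", {"MED": 5, "ETAU": 5}, "XR-NTX"),
                     StudyDesign("b", {"MED": 5, "ETAU": 5}, "IM")],
            study_intercepts={"a": 0.0, "b": 0.0},
            theta_med={"a": 0.5, "b": -0.3})
        tp = true_pooled_log_or(cfg, weights={"a": 25, "b": 100})
        assert tp.theta_p_true == pytest.approx((12.5 - 30) / 125)  # -0.14

    def test_single_study_reduction(self):
        cfg = single_study_config(10, theta=0.7)
        assert true_pooled_log_or(cfg).theta_p_true == pytest.approx(0.7)

    def test_nonpositive_weight_rejected(self):
        cfg = single_study_config(10, theta=0.7)
        with pytest.raises(ValidationError, match="weights"):
            true_pooled_log_or(cfg, weights={"s1": 0.0})

    def test_pooled_within_convex_hull(self):
        cfg = SimulationConfig(
            designs=[StudyDesign("a", {"MED": 5, "ETAU": 5}, "XR-NTX"),
                     StudyDesign("b", {"MED": 9, "ETAU": 9}, "IM")],
            study_intercepts={"a": 0.0, "b": 0.0},
            theta_med={"a": -0.9, "b": 0.2})
        tp = true_pooled_log_or(cfg)
        assert -0.9 <= tp.theta_p_true <= 0.2


def test_config_roundtrip_yaml_json(tmp_path):
    cfg = default_config(seed=7)
    path = tmp_path / "config.json"
    cfg.to_json(path)
    back = SimulationConfig.from_file(path)
    assert back.to_dict() == cfg.to_dict()
    pd.testing.assert_frame_equal(generate_cohort(back), generate_cohort(cfg))
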