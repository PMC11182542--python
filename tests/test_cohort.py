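"""Cohort-stage tests: exclusion filters, missing-as-positive imputation,
baseline summarization and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from multitrial.cohort import (apply_exclusions, impute_missing_as_positive,
                               read_cohort_csv, summarize_baseline,
                               write_cohort_csv, frame_to_records,
                               records_to_frame)
from multitrial.exceptions import ContractViolationError, ValidationError
from multitrial.simulate import default_config, generate_cohort, apply_followup_process


class TestExclusions:
    def test_prison_transfer_excluded_with_reason(self):
        df = make_cohort([{"follow_up_status": "prison_transfer"},
                          {"follow_up_status": "in_community"}])
        kept, report = apply_exclusions(df)
        assert len(kept) == 1
        assert report.counts["s1"]["PRISON_TRANSFER"] == 1
        assert report.excluded_ids == ["p0000"]

    def test_all_in_community_is_identity(self):
        df = make_cohort([{} for _ in range(8)])
        kept, report = apply_exclusions(df)
        pd.testing.assert_frame_equal(kept, df)
        assert report.counts == {} and report.totals() == {}

    def test_mixed_statuses_counted_per_reason(self):
        statuses = (["in_community"] * 6 + ["prison_transfer"] * 2
                    + ["incarcerated_at_followup"] + ["deceased"])
        df = make_cohort([{"follow_up_status": s} for s in statuses])
        kept, report = apply_exclusions(df)
        assert len(kept) == 6
        assert report.totals() == {"PRISON_TRANSFER": 2, "INCARCERATED": 1,
                                   "DECEASED": 1}
        assert report.n_input == report.n_kept + len(report.excluded_ids)
        # input order preserved among kept records
        assert list(kept["participant_id"]) == [f"p{i:04d}" for i in range(6)]

    def test_unset_status_names_participant(self):
        df = make_cohort([{"follow_up_status": None}])
        with pytest.raises(ValidationError, match="p0000"):
            apply_exclusions(df)


class TestImputation:
    def test_missing_becomes_positive_with_flag(self):
        df = make_cohort([{"outcome": "missing"}, {"outcome": "negative"}])
        out = impute_missing_as_positive(df)
        assert list(out["outcome"]) == ["positive", "negative"]
        assert list(out["outcome_imputed"]) == [True, False]

    def test_positive_count_arithmetic(self):
        df = make_cohort([{"outcome": "positive"}] * 7
                         + [{"outcome": "missing"}] * 5
                         + [{"outcome": "negative"}] * 8)
        out = impute_missing_as_positive(df)
        assert (out["outcome"] == "positive").sum() == 12

    def test_excluded_record_reaching_imputation_is_contract_violation(self):
        df = make_cohort([{"follow_up_status": "deceased"}])
        with pytest.raises(ContractViolationError, match="p0000"):
            impute_missing_as_positive(df)

    def test_monotone_prevalence_and_fixed_order_idempotence(self):
        cfg = default_config(seed=21)
        cfg.exclusion_rates = {"prison_transfer": 0.08,
                               "incarcerated_at_followup": 0.2,
                               "deceased": 0.01}
        raw = apply_followup_process(generate_cohort(cfg), cfg)
        kept, _ = apply_exclusions(raw)
        complete_case = (kept["outcome"] == "positive").mean()
        imputed = impute_missing_as_positive(kept)
        post = (imputed["outcome"] == "positive").mean()
        n_missing = (kept["outcome"] == "missing").sum()
        assert post >= complete_case and n_missing > 0 and post > complete_case
        # second pass through the documented order is a no-op
        kept2, rep2 = apply_exclusions(imputed)
        again = impute_missing_as_positive(kept2)
        pd.testing.assert_frame_equal(again, imputed)
        assert rep2.totals() == {}

    def test_equality_iff_nothing_missing(self):
        df = make_cohort([{"outcome": "positive"}, {"outcome": "negative"}])
        out = impute_missing_as_positive(df)
        assert (out["outcome"] == "positive").mean() == 0.5
        assert not out["outcome_imputed"].any()


class TestBaselineSummary:
    def test_overall_female_percent_from_group_counts(self):
        rows = []
        rows += [{"arm": "ETAU", "sex": "female"}] * 28
        rows += [{"arm": "ETAU", "sex": "male"}] * 94
        rows += [{"arm": "MED", "sex": "female"}] * 42
        rows += [{"arm": "MED", "sex": "male"}] * 166
        summary = summarize_baseline(make_cohort(rows))
        cat = summary.categorical["sex"]
        assert summary.n == {"ETAU": 122, "any_treatment": 208, "overall": 330}
        assert cat["ETAU"]["female"] == {"count": 28, "percent": 23.0}
        assert cat["any_treatment"]["female"] == {"count": 42, "percent": 20.2}
        assert cat["overall"]["female"] == {"count": 70, "percent": 21.2}

    def test_single_record_degenerate_sd(self):
        summary = summarize_baseline(make_cohort([{"age": 40.0}]))
        assert summary.continuous["age"]["overall"] == {"mean": 40.0, "sd": 0.0}
        assert any("n<2" in w for w in summary.warnings)

    def test_saturated_category(self):
        rows = [{"arm": "ETAU", "sex": "female"},
                {"arm": "MED", "sex": "female", "study_id": "s2"}]
        summary = summarize_baseline(make_cohort(rows))
        assert summary.categorical["sex"]["overall"]["female"]["percent"] == 100.0

    def test_percentages_sum_to_100(self, default_cohort):
        summary = summarize_baseline(default_cohort)
        for var in ("sex", "race", "arm", "study_id"):
            for group, levels in summary.categorical[var].items():
                total = sum(v["percent"] for v in levels.values())
                assert abs(total - 100.0) < 0.1, (var, group)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_baseline(make_cohort([]))


class TestCsvRoundTrip:
    def test_synthetic_cohort_roundtrips(self, tmp_path, default_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort, path)
        back = read_cohort_csv(path)
        a = default_cohort.reset_index(drop=True)
        pd.testing.assert_frame_equal(back, a, check_dtype=False)

    def test_record_api_roundtrip(self):
        df = make_cohort([{"outcome": "missing"}, {"arm": "MED"}])
        records = frame_to_records(df)
        pd.testing.assert_frame_equal(records_to_frame(records), df)

    def test_inconsistent_medication_rejected(self, tmp_path):
        df = make_cohort([{}])
        df.loc[0, "medication_type"] = "XR-NTX"  # ETAU arm with a medication
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="medication_type"):
            read_cohort_csv(path)

    def test_unknown_column_strict_vs_lenient(self, tmp_path):
        df = make_cohort([{}])
        df["site_notes"] = "x"
        path = tmp_path / "extra.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="site_notes"):
            read_cohort_csv(path, strict=True)
        back = read_cohort_csv(path, strict=False)
        assert "site_notes" not in back.columns

    def test_unparseable_level_names_row_and_column(self, tmp_path):
        df = make_cohort([{}, {}])
        df.loc[1, "race"] = "Martian"
        path = tmp_path / "bad2.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 1"):
            read_cohort_csv(path)
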