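import numpy as np
import pandas as pd
import pytest

from multitrial.cohort import COHORT_COLUMNS
from multitrial.simulate import default_config, simulate_analytic_cohort


def make_cohort(rows) -> pd.DataFrame:
    """Build a cohort frame from compact row dicts (defaults filled in)."""
    defaults = dict(study_id="s1", arm="ETAU", medication_type="none",
                    age=40.0, sex="male", race="Black", hispanic=False,
                    unhoused=False, stimulant_use=False,
                    follow_up_status="in_community", outcome="negative",
                    outcome_imputed=False)
    full = []
    for i, row in enumerate(rows):
        rec = {**defaults, "participant_id": f"p{i:04d}", **row}
        if rec["arm"] != "ETAU" and rec["medication_type"] == "none":
            rec["medication_type"] = "XR-NTX"
        full.append(rec)
    return pd.DataFrame(full, columns=COHORT_COLUMNS)


def two_arm_study(n_treat_pos, n_treat_neg, n_ref_pos, n_ref_neg,
                  study_id="s1", rng=None) -> pd.DataFrame:
    """Covariate-free two-arm study from 2x2 cell counts (covariates are
    filled with constants, so adjusted fits reduce to the crude contrast)."""
    rows = []
    for arm, pos, neg in (("MED", n_treat_pos, n_treat_neg),
                          ("ETAU", n_ref_pos, n_ref_neg)):
        rows += [{"study_id": study_id, "arm": arm, "outcome": "positive"}] * pos
        rows += [{"study_id": study_id, "arm": arm, "outcome": "negative"}] * neg
    return make_cohort(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """Analysis-ready three-site cohort at the study-condition defaults."""
    cohort, _ = simulate_analytic_cohort(default_config(seed=11))
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
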