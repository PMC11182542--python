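"""Participant-level cohort data model and pre-analysis processing.

One row per randomized participant. The analysis-ready cohort is produced by
two fixed-order steps:

1. :func:`apply_exclusions` — drop participants who were transferred to
   prison, were incarcerated at the time of their 6-month follow-up window,
   or died; research interviews could not be completed for these groups, so
   they are removed from the analytic set (CONSORT-style accounting is
   returned alongside).
2. :func:`impute_missing_as_positive` — participants who were alive and in
   the community but could not be assessed are counted as having a current
   OUD diagnosis. This is a deliberately conservative (worst-case for
   treatment) single imputation of the binary endpoint.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`COHORT_COLUMNS`; :class:`ParticipantRecord` is the
record-level view used for construction and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractViolationError, ValidationError

logger = logging.getLogger(__name__)

ARMS = ("ETAU", "MED", "MED_PN")
MEDICATION_TYPES = ("XR-NTX", "IM", "none")
SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("Black", "White", "Other")
FOLLOWUP_STATUSES = (
    "in_community",
    "prison_transfer",
    "incarcerated_at_followup",
    "deceased",
)
OUTCOME_LEVELS = ("positive", "negative", "missing")

#: exclusion reason labels keyed by follow-up status
EXCLUSION_REASONS = {
    "prison_transfer": "PRISON_TRANSFER",
    "incarcerated_at_followup": "INCARCERATED",
    "deceased": "DECEASED",
}

COHORT_COLUMNS = [
    "participant_id",
    "study_id",
    "arm",
    "medication_type",
    "age",
    "sex",
    "race",
    "hispanic",
    "unhoused",
    "stimulant_use",
    "follow_up_status",
    "outcome",
    "outcome_imputed",
]

_BOOL_COLUMNS = ("hispanic", "unhoused", "stimulant_use", "outcome_imputed")


@dataclass
class ParticipantRecord:
    """One randomized participant.

    ``follow_up_status`` and ``outcome`` may be ``None`` before the follow-up
    process has run; ``outcome_imputed`` flags outcomes set by the
    missing-as-positive rule.
    """

    participant_id: str
    study_id: str
    arm: str
    medication_type: str
    age: float
    sex: str
    race: str
    hispanic: bool
    unhoused: bool
    stimulant_use: bool
    follow_up_status: str | None = None
    outcome: str | None = None
    outcome_imputed: bool = False

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm: unknown level {self.arm!r} "
                                  f"(participant {self.participant_id})")
        if self.medication_type not in MEDICATION_TYPES:
            raise ValidationError(
                f"medication_type: unknown level {self.medication_type!r} "
                f"(participant {self.participant_id})")
        if self.arm == "ETAU" and self.medication_type != "none":
            raise ValidationError(
                f"medication_type: ETAU arm must have medication_type 'none', "
                f"got {self.medication_type!r} (participant {self.participant_id})")
        if self.arm in ("MED", "MED_PN") and self.medication_type == "none":
            raise ValidationError(
                f"medication_type: medication arm requires a medication, "
                f"got 'none' (participant {self.participant_id})")
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"sex: unknown level {self.sex!r} "
                                  f"(participant {self.participant_id})")
        if self.race not in RACE_LEVELS:
            raise ValidationError(f"race: unknown level {self.race!r} "
                                  f"(participant {self.participant_id})")
        if self.follow_up_status is not None and self.follow_up_status not in FOLLOWUP_STATUSES:
            raise ValidationError(
                f"follow_up_status: unknown level {self.follow_up_status!r} "
                f"(participant {self.participant_id})")
        if self.outcome is not None and self.outcome not in OUTCOME_LEVELS:
            raise ValidationError(f"outcome: unknown level {self.outcome!r} "
                                  f"(participant {self.participant_id})")
        if not np.isfinite(self.age) or self.age < 0:
            raise ValidationError(f"age: invalid value {self.age!r} "
                                  f"(participant {self.participant_id})")


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Convert records to the canonical cohort DataFrame (validating each)."""
    rows = []
    for rec in records:
        rec.validate()
        rows.append(asdict(rec))
    if not rows:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    recs = []
    for row in df[COHORT_COLUMNS].itertuples(index=False):
        rec = ParticipantRecord(*row)
        if pd.isna(rec.follow_up_status):
            rec.follow_up_status = None
        if pd.isna(rec.outcome):
            rec.outcome = None
        rec.validate()
        recs.append(rec)
    return recs


def validate_cohort(df: pd.DataFrame, strict: bool = True) -> list[str]:
    """Validate a cohort frame; returns warnings, raises on hard errors.

    In non-strict mode unrecognized columns produce a warning and are
    ignored; in strict mode they raise.
    """
    warnings: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        msg = f"unrecognized column(s): {', '.join(extra)}"
        if strict:
            raise ValidationError(msg)
        warnings.append(msg + " (ignored)")
        logger.warning(msg)

    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValidationError(f"participant_id: duplicate id {dup!r}")

    def _check_levels(col: str, levels: tuple, allow_na: bool = False) -> None:
        vals = df[col]
        bad = ~vals.isin(levels)
        if allow_na:
            bad &= vals.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}, row {i}: unparseable level {vals.iloc[i]!r}")

    _check_levels("arm", ARMS)
    _check_levels("medication_type", MEDICATION_TYPES)
    _check_levels("sex", SEX_LEVELS)
    _check_levels("race", RACE_LEVELS)
    _check_levels("follow_up_status", FOLLOWUP_STATUSES, allow_na=True)
    _check_levels("outcome", OUTCOME_LEVELS, allow_na=True)

    bad_med = ((df["arm"] == "ETAU") & (df["medication_type"] != "none")) | (
        df["arm"].isin(["MED", "MED_PN"]) & (df["medication_type"] == "none"))
    if bad_med.any():
        i = int(np.flatnonzero(bad_med.to_numpy())[0])
        raise ValidationError(
            f"column 'medication_type', row {i}: inconsistent with arm "
            f"{df['arm'].iloc[i]!r} (participant {df['participant_id'].iloc[i]!r})")
    return warnings


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionReport:
    """CONSORT-style accounting of post-randomization exclusions."""

    n_input: int
    n_kept: int
    counts: dict  # {study_id: {reason: count}}
    excluded_ids: list = field(default_factory=list)

    def totals(self) -> dict:
        out: dict[str, int] = {}
        for per_study in self.counts.values():
            for reason, k in per_study.items():
                out[reason] = out.get(reason, 0) + k
        return out

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "counts": self.counts,
            "totals": self.totals(),
            "excluded_ids": list(self.excluded_ids),
        }


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove participants not alive and in the community at follow-up.

    Every record must have ``follow_up_status`` set. Row order among kept
    records is preserved.
    """
    status = df["follow_up_status"]
    if status.isna().any():
        pid = df.loc[status.isna(), "participant_id"].iloc[0]
        raise ValidationError(
            f"follow_up_status: unset for participant {pid!r}; run the "
            "follow-up process first")
    keep = status == "in_community"
    excluded = df.loc[~keep]
    counts: dict[str, dict[str, int]] = {}
    for (study, st), grp in excluded.groupby(["study_id", "follow_up_status"],
                                             observed=True):
        counts.setdefault(str(study), {})[EXCLUSION_REASONS[str(st)]] = len(grp)
    report = ExclusionReport(
        n_input=len(df),
        n_kept=int(keep.sum()),
        counts=counts,
        excluded_ids=excluded["participant_id"].tolist(),
    )
    logger.info("exclusions: %d records in, %d kept, %s",
                report.n_input, report.n_kept, report.totals() or "none")
    return df.loc[keep].copy(), report


def impute_missing_as_positive(df: pd.DataFrame) -> pd.DataFrame:
    """Set every missing outcome to positive, flagging the imputed rows.

    Precondition: exclusions already applied (everyone in the frame is alive
    and in the community); violating this raises ``ContractViolationError``.
    """
    not_community = df["follow_up_status"] != "in_community"
    if not_community.any():
        pid = df.loc[not_community, "participant_id"].iloc[0]
        raise ContractViolationError(
            f"participant {pid!r} with status "
            f"{df.loc[not_community, 'follow_up_status'].iloc[0]!r} reached "
            "imputation; apply_exclusions must run first")
    out = df.copy()
    is_missing = out["outcome"].isna() | (out["outcome"] == "missing")
    out.loc[is_missing, "outcome"] = "positive"
    out.loc[is_missing, "outcome_imputed"] = True
    n = int(is_missing.sum())
    if n:
        logger.info("imputed %d missing outcomes as positive", n)
    return out


# ---------------------------------------------------------------------------
# baseline summary

_CATEGORICAL = {
    "arm": list(ARMS),
    "sex": list(SEX_LEVELS),
    "race": list(RACE_LEVELS),
    "hispanic": [True, False],
    "unhoused": [True, False],
    "stimulant_use": [True, False],
    "study_id": None,  # levels taken from the data
}
_CONTINUOUS = ("age",)


def _round1(x: float) -> float:
    # one decimal, round-half-even
    return float(round(x, 1))


@dataclass
class BaselineSummary:
    """Per-group baseline table: n, count (percent) for categorical variables,
    mean (SD) for continuous ones. Percents use non-missing denominators and
    one-decimal round-half-even formatting."""

    groups: list
    n: dict
    categorical: dict  # var -> group -> level -> {"count": int, "percent": float}
    continuous: dict   # var -> group -> {"mean": float, "sd": float}
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        cat = {
            var: {g: {str(lv): dict(v) for lv, v in per_g.items()}
                  for g, per_g in per_var.items()}
            for var, per_var in self.categorical.items()
        }
        return {"groups": self.groups, "n": self.n, "categorical": cat,
                "continuous": self.continuous, "warnings": self.warnings}

    def to_frame(self) -> pd.DataFrame:
        """Render as a long table (variable, level, one column per group)."""
        rows = []
        for var, per_var in self.categorical.items():
            levels = next(iter(per_var.values())).keys()
            for lv in levels:
                row = {"variable": var, "level": str(lv)}
                for g in self.groups:
                    c = per_var[g][lv]
                    row[g] = f"{c['count']} ({c['percent']}%)"
                rows.append(row)
        for var, per_var in self.continuous.items():
            row = {"variable": var, "level": "mean (SD)"}
            for g in self.groups:
                m = per_var[g]
                row[g] = f"{m['mean']} ({m['sd']})"
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_baseline(df: pd.DataFrame, grouping: str = "treatment") -> BaselineSummary:
    """Summarize baseline characteristics per group plus an overall column.

    ``grouping='treatment'`` groups ETAU vs any-treatment (the pooled-trial
    presentation); ``grouping='study'`` groups by study id.
    """
    if len(df) == 0:
        raise ValidationError("empty cohort: nothing to summarize")
    if grouping == "treatment":
        labels = np.where(df["arm"] == "ETAU", "ETAU", "any_treatment")
    elif grouping == "study":
        labels = df["study_id"].astype(str).to_numpy()
    else:
        raise ValidationError(f"grouping: unknown value {grouping!r}")

    group_names = sorted(set(labels)) + ["overall"]
    masks = {g: labels == g for g in sorted(set(labels))}
    masks["overall"] = np.ones(len(df), dtype=bool)

    warnings: list[str] = []
    n = {g: int(m.sum()) for g, m in masks.items()}
    categorical: dict = {}
    for var, levels in _CATEGORICAL.items():
        if levels is None:
            levels = sorted(df[var].astype(str).unique())
        per_var: dict = {}
        for g, m in masks.items():
            col = df.loc[m, var]
            denom = int(col.notna().sum())
            per_g = {}
            for lv in levels:
                count = int((col == lv).sum())
                pct = _round1(100.0 * count / denom) if denom else float("nan")
                per_g[lv] = {"count": count, "percent": pct}
            per_var[g] = per_g
        categorical[var] = per_var

    continuous: dict = {}
    for var in _CONTINUOUS:
        per_var = {}
        for g, m in masks.items():
            col = df.loc[m, var].astype(float)
            mean = float(col.mean())
            if col.notna().sum() < 2:
                sd = 0.0
                warnings.append(f"{var}: group {g!r} has n<2; SD reported as 0.0")
            else:
                sd = float(col.std(ddof=1))
            per_var[g] = {"mean": _round1(mean), "sd": _round1(sd)}
        continuous[var] = per_var

    return BaselineSummary(groups=group_names, n=n, categorical=categorical,
                           continuous=continuous, warnings=warnings)


# ---------------------------------------------------------------------------
# CSV round-trip


def write_cohort_csv(df: pd.DataFrame | Sequence[ParticipantRecord], path) -> None:
    """Write a cohort to CSV with the documented header (lossless round-trip)."""
    if not isinstance(df, pd.DataFrame):
        df = records_to_frame(df)
    validate_cohort(df, strict=True)
    out = df[COHORT_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_cohort_csv(path, strict: bool = True) -> pd.DataFrame:
    """Read a cohort CSV, validating columns, levels and arm/medication
    consistency. Unknown columns raise in strict mode, warn otherwise."""
    df = pd.read_csv(path, dtype={"participant_id": str, "study_id": str})
    for col in _BOOL_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            mapped = df[col].map({"True": True, "False": False, "true": True,
                                  "false": False, "1": True, "0": False})
            if mapped.isna().any() and df[col].notna().any():
                i = int(np.flatnonzero(mapped.isna().to_numpy())[0])
                raise ValidationError(
                    f"column {col!r}, row {i}: unparseable boolean "
                    f"{df[col].iloc[i]!r}")
            df[col] = mapped
    validate_cohort(df, strict=strict)
    df = df[COHORT_COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["age"] = df["age"].astype(float)
    return df
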