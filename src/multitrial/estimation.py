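"""Two-stage estimation of the pooled treatment effect.

Stage 1 fits, within each study, a covariate-adjusted logistic model of the
binary endpoint on a treatment indicator defined by a :class:`ContrastSpec`
(any medication vs ETAU, or medication+navigation vs medication alone),
giving the study-specific log-odds ratio ``theta_j`` and its variance from
the inverse observed information. Stage 2 combines the study estimates with
fixed-effect inverse-variance weights ``w_j = 1/Var(theta_j)`` into the
pooled log-odds ratio

    theta_p = sum_j w_j theta_j / sum_j w_j,   se_p = sqrt(1 / sum_j w_j).

Covariate encoding: intercept; treatment indicator; age centered at the
study mean (stabilizes the intercept, leaves the treatment effect
unchanged); female, unhoused, stimulant-use as 0/1; race as two dummies
with Black the reference. Covariates constant within a study are dropped
with a warning. Separated or non-converged stage-1 fits fall back to Firth
penalization (see :mod:`multitrial.logistic`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NonEstimableError, ValidationError
from .logistic import fit_logistic

__all__ = [
    "ContrastSpec", "ANY_MED_VS_ETAU", "MED_PN_VS_MED", "get_contrast",
    "DEFAULT_COVARIATES", "StudyData", "prepare_analysis_data",
    "encode_covariates", "fit_study_logistic", "fit_prepared",
    "pool_estimates", "StudyEstimate", "PooledEstimate", "format_forest",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A treatment contrast: arms coded 1 vs arms coded 0."""

    name: str
    treated_arms: frozenset
    reference_arms: frozenset

    def __post_init__(self):
        if not self.treated_arms or not self.reference_arms:
            raise ValidationError("contrast arm sets must be nonempty")
        if self.treated_arms & self.reference_arms:
            raise ValidationError("contrast arm sets must be disjoint")

    def eligible(self, df: pd.DataFrame) -> list[str]:
        """Study ids containing at least one arm from each side."""
        out = []
        for study, grp in df.groupby("study_id", sort=True):
            arms = set(grp["arm"])
            if arms & self.treated_arms and arms & self.reference_arms:
                out.append(str(study))
        return out


ANY_MED_VS_ETAU = ContrastSpec("ANY_MED_VS_ETAU",
                               frozenset({"MED", "MED_PN"}),
                               frozenset({"ETAU"}))
MED_PN_VS_MED = ContrastSpec("MED_PN_VS_MED",
                             frozenset({"MED_PN"}),
                             frozenset({"MED"}))

_CONTRASTS = {c.name: c for c in (ANY_MED_VS_ETAU, MED_PN_VS_MED)}


def get_contrast(name) -> ContrastSpec:
    if isinstance(name, ContrastSpec):
        return name
    try:
        return _CONTRASTS[str(name).upper()]
    except KeyError:
        raise ValidationError(f"unknown contrast {name!r}; "
                              f"choose from {sorted(_CONTRASTS)}") from None


DEFAULT_COVARIATES = ("age", "sex", "race", "unhoused", "stimulant_use")
_KNOWN_COVARIATES = DEFAULT_COVARIATES + ("hispanic",)


@dataclass
class StudyData:
    """Array-level per-study analysis data (fast path for resampling)."""

    study_id: str
    y: np.ndarray          # 0/1 outcome
    treat: np.ndarray      # 0/1 treatment indicator
    Z: np.ndarray          # covariate block (no intercept, no treatment)
    colnames: list         # names for (intercept, treat, *Z columns)
    arm: np.ndarray        # original arm labels (bootstrap strata)
    warnings: list = field(default_factory=list)


def encode_covariates(df_study: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                      contrast: ContrastSpec = ANY_MED_VS_ETAU) -> StudyData:
    """Encode one study's records into a design under the given contrast.

    Records in arms outside the contrast are dropped; the returned columns
    are (intercept, treat, age_c, female, race_White, race_Other, unhoused,
    stimulant) restricted to the requested covariates, with constant
    columns removed (warning recorded).
    """
    for c in covariates:
        if c not in _KNOWN_COVARIATES:
            raise ValidationError(f"covariates: unknown covariate {c!r}")
    contrast = get_contrast(contrast)
    in_contrast = df_study["arm"].isin(contrast.treated_arms | contrast.reference_arms)
    sub = df_study.loc[in_contrast]
    study_id = str(sub["study_id"].iloc[0]) if len(sub) else "?"
    treat = sub["arm"].isin(contrast.treated_arms).to_numpy(float)
    y = (sub["outcome"] == "positive").to_numpy(float)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if "age" in covariates:
        age = sub["age"].to_numpy(float)
        cols.append(age - age.mean())
        names.append("age_c")
    if "sex" in covariates:
        cols.append((sub["sex"] == "female").to_numpy(float))
        names.append("female")
    if "race" in covariates:
        cols.append((sub["race"] == "White").to_numpy(float))
        names.append("race_White")
        cols.append((sub["race"] == "Other").to_numpy(float))
        names.append("race_Other")
    if "hispanic" in covariates:
        cols.append(sub["hispanic"].to_numpy(float))
        names.append("hispanic")
    if "unhoused" in covariates:
        cols.append(sub["unhoused"].to_numpy(float))
        names.append("unhoused")
    if "stimulant_use" in covariates:
        cols.append(sub["stimulant_use"].to_numpy(float))
        names.append("stimulant")

    warnings = []
    keep_cols, keep_names = [], []
    for col, name in zip(cols, names):
        if np.ptp(col) == 0.0:
            warnings.append(f"study {study_id}: covariate {name!r} has a "
                            "single level; dropped")
        else:
            keep_cols.append(col)
            keep_names.append(name)
    Z = np.column_stack(keep_cols) if keep_cols else np.empty((len(sub), 0))
    return StudyData(study_id=study_id, y=y, treat=treat, Z=Z,
                     colnames=["intercept", "treat"] + keep_names,
                     arm=sub["arm"].to_numpy(), warnings=warnings)


def prepare_analysis_data(df: pd.DataFrame, contrast=ANY_MED_VS_ETAU,
                          covariates=DEFAULT_COVARIATES) -> list[StudyData]:
    """Encode every eligible study; raises if no study supports the contrast."""
    contrast = get_contrast(contrast)
    eligible = contrast.eligible(df)
    if not eligible:
        raise NonEstimableError(
            f"contrast {contrast.name}: no study contains both arm sets")
    return [
        encode_covariates(df[df["study_id"] == s], covariates, contrast)
        for s in eligible
    ]


# ---------------------------------------------------------------------------
# stage 1


@dataclass
class StudyEstimate:
    """Study-specific treatment log-OR with its variance."""

    study_id: str
    theta_hat: float
    variance: float
    se: float
    n_treated: int
    n_reference: int
    converged: bool
    penalized: bool
    warnings: list = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta_hat)

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id, "theta_hat": self.theta_hat,
            "variance": self.variance, "se": self.se,
            "odds_ratio": self.odds_ratio, "n_treated": self.n_treated,
            "n_reference": self.n_reference, "converged": self.converged,
            "penalized": self.penalized, "warnings": list(self.warnings),
        }


def fit_prepared(sd: StudyData, strict_outcome: bool = True) -> StudyEstimate:
    """Fit the stage-1 logistic model on prepared arrays.

    With ``strict_outcome=False`` a study whose outcome has a single level is
    fitted by Firth penalization instead of raising; resampling replicates
    use this so degenerate draws are retained, never dropped.
    """
    if np.ptp(sd.treat) == 0.0:
        raise NonEstimableError(
            f"study {sd.study_id}: only one contrast arm present")
    y = sd.y
    if strict_outcome and y.min() == y.max():
        raise NonEstimableError(
            f"study {sd.study_id}: outcome has a single level")
    # drop covariate columns made constant (e.g. by resampling)
    Z, names, warns = sd.Z, sd.colnames, list(sd.warnings)
    if Z.shape[1]:
        keep = np.ptp(Z, axis=0) != 0.0
        if not keep.all():
            dropped = [n for n, k in zip(names[2:], keep) if not k]
            warns = warns + [f"study {sd.study_id}: constant covariate(s) "
                             f"{dropped} dropped in this fit"]
            Z = Z[:, keep]
    X = np.column_stack([np.ones(len(y)), sd.treat, Z])
    fit = fit_logistic(X, y)
    var = float(fit.cov[1, 1])
    return StudyEstimate(
        study_id=sd.study_id,
        theta_hat=float(fit.coef[1]),
        variance=var,
        se=math.sqrt(var) if var > 0 else float("nan"),
        n_treated=int(sd.treat.sum()),
        n_reference=int(len(y) - sd.treat.sum()),
        converged=bool(fit.converged),
        penalized=bool(fit.penalized),
        warnings=warns,
    )


def fit_study_logistic(df_study: pd.DataFrame, contrast=ANY_MED_VS_ETAU,
                       covariates=DEFAULT_COVARIATES) -> StudyEstimate:
    """Stage 1 for one study's records: encode, fit, extract the treatment
    log-OR and its variance."""
    sd = encode_covariates(df_study, covariates, get_contrast(contrast))
    return fit_prepared(sd)


# ---------------------------------------------------------------------------
# stage 2


@dataclass
class PooledEstimate:
    """Inverse-variance (fixed-effect) pooled treatment log-OR."""

    theta_p: float
    se_p: float
    weights: dict  # study_id -> w_j = 1/variance_j

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta_p)

    def to_dict(self) -> dict:
        return {"theta_p": self.theta_p, "se_p": self.se_p,
                "odds_ratio": self.odds_ratio, "weights": dict(self.weights)}


def pool_estimates(estimates: list[StudyEstimate]) -> PooledEstimate:
    """Combine study estimates with weights proportional to inverse variance."""
    if not estimates:
        raise ValidationError("pool_estimates: empty estimate list")
    for est in estimates:
        if not (est.variance > 0 and np.isfinite(est.variance)):
            raise ValidationError(
                f"pool_estimates: nonpositive variance for study "
                f"{est.study_id!r}")
    w = np.array([1.0 / est.variance for est in estimates])
    th = np.array([est.theta_hat for est in estimates])
    wsum = w.sum()
    return PooledEstimate(
        theta_p=float((w * th).sum() / wsum),
        se_p=float(math.sqrt(1.0 / wsum)),
        weights={est.study_id: float(wi) for est, wi in zip(estimates, w)},
    )


def two_stage_theta_p(studies: list[StudyData],
                      strict_outcome: bool = False) -> tuple[float, int]:
    """Fast path used by resampling: pooled theta_p from prepared studies.

    Returns (theta_p, number of penalized stage-1 fits).
    """
    ests = [fit_prepared(sd, strict_outcome=strict_outcome) for sd in studies]
    n_pen = sum(e.penalized for e in ests)
    return pool_estimates(ests).theta_p, n_pen


def format_forest(estimates: list[StudyEstimate], pooled: PooledEstimate) -> str:
    """Plain-text forest-style summary of study and pooled effects."""
    lines = [f"{'study':<10} {'theta_j':>9} {'se':>7} {'OR':>7} {'weight':>9}"]
    wsum = sum(pooled.weights.values())
    for est in estimates:
        lines.append(
            f"{est.study_id:<10} {est.theta_hat:>9.3f} {est.se:>7.3f} "
            f"{est.odds_ratio:>7.3f} {pooled.weights[est.study_id]/wsum:>8.1%}"
            + ("  [penalized]" if est.penalized else ""))
    lines.append("-" * len(lines[0]))
    lines.append(f"{'pooled':<10} {pooled.theta_p:>9.3f} {pooled.se_p:>7.3f} "
                 f"{pooled.odds_ratio:>7.3f} {1:>8.0%}")
    return "\n".join(lines)
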