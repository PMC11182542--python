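"""Randomization inference and bootstrap for the pooled treatment effect.

Both procedures re-run the *entire* two-stage estimator (per-study adjusted
logistic fits, then inverse-variance pooling) on every replicate:

* Permutation test — treatment labels are re-assigned uniformly at random
  within each study, preserving the study's treated/reference counts, which
  realizes the randomization null. P-values use the add-one rule
  ``(count + 1)/(B + 1)`` so they are never zero; the one-sided value is for
  the alternative ``theta_p > 0``, the two-sided value compares ``|theta_p|``.
* Stratified bootstrap — participants are resampled with replacement within
  study x arm strata (keeping every design fixed); the confidence interval
  is the percentile interval of replicate pooled log-ORs, and the OR-scale
  interval is the elementwise exponential of the log-scale endpoints.

Replicates with separation are retained through the Firth fallback and
counted, never dropped. An exhaustive-enumeration oracle
(:func:`exact_permutation_p`) is provided for small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from .estimation import (StudyData, get_contrast, prepare_analysis_data,
                         two_stage_theta_p, DEFAULT_COVARIATES)
from .exceptions import NonEstimableError, TooLargeError, ValidationError

__all__ = ["PermutationResult", "BootstrapResult", "permute_within_study",
           "permutation_test", "exact_permutation_p", "bootstrap_ci"]


@dataclass
class PermutationResult:
    observed_theta_p: float
    null_draws: np.ndarray
    p_one_sided: float   # H1: theta_p > 0
    p_two_sided: float
    B: int
    seed: int | None
    n_degenerate: int = 0

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {"observed_theta_p": self.observed_theta_p,
             "observed_odds_ratio": math.exp(self.observed_theta_p),
             "p_one_sided": self.p_one_sided, "p_two_sided": self.p_two_sided,
             "B": self.B, "seed": self.seed, "n_degenerate": self.n_degenerate}
        if include_draws:
            d["null_draws"] = self.null_draws.tolist()
        return d


@dataclass
class BootstrapResult:
    level: float
    lower: float              # log-OR scale
    upper: float
    lower_or: float
    upper_or: float
    point_estimate: float
    replicate_draws: np.ndarray
    B: int
    seed: int | None
    n_degenerate: int = 0

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {"level": self.level, "lower": self.lower, "upper": self.upper,
             "lower_or": self.lower_or, "upper_or": self.upper_or,
             "point_estimate": self.point_estimate, "B": self.B,
             "seed": self.seed, "n_degenerate": self.n_degenerate}
        if include_draws:
            d["replicate_draws"] = self.replicate_draws.tolist()
        return d


def permute_within_study(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Re-assign treatment labels uniformly within each study.

    The (arm, medication_type) pair travels together; covariates and
    outcomes stay attached to participants, and per-study arm counts are
    preserved exactly. Labels never cross studies.
    """
    out = df.copy()
    for _, idx in out.groupby("study_id", sort=False).groups.items():
        perm = rng.permutation(len(idx))
        out.loc[idx, "arm"] = out.loc[idx, "arm"].to_numpy()[perm]
        out.loc[idx, "medication_type"] = (
            out.loc[idx, "medication_type"].to_numpy()[perm])
    return out


def permutation_test(df: pd.DataFrame, contrast=None, covariates=DEFAULT_COVARIATES,
                     B: int = 5000, seed: int | None = None,
                     studies: list[StudyData] | None = None) -> PermutationResult:
    """Permutation test of H0: theta_p = 0 (two-sided) / theta_p <= 0
    (one-sided), re-running the full two-stage estimator per replicate."""
    if B < 1:
        raise ValidationError("B: must be >= 1")
    if studies is None:
        studies = prepare_analysis_data(df, get_contrast(contrast), covariates)
    rng = np.random.default_rng(seed)
    observed, _ = two_stage_theta_p(studies)

    null = np.empty(B)
    n_degenerate = 0
    permuted = [StudyData(sd.study_id, sd.y, sd.treat.copy(), sd.Z,
                          sd.colnames, sd.arm) for sd in studies]
    for b in range(B):
        for sd in permuted:
            rng.shuffle(sd.treat)
        theta, n_pen = two_stage_theta_p(permuted)
        null[b] = theta
        n_degenerate += n_pen

    eps = 1e-12
    p_two = (np.sum(np.abs(null) >= abs(observed) - eps) + 1.0) / (B + 1.0)
    p_one = (np.sum(null >= observed - eps) + 1.0) / (B + 1.0)
    return PermutationResult(observed_theta_p=float(observed), null_draws=null,
                             p_one_sided=float(p_one), p_two_sided=float(p_two),
                             B=B, seed=seed, n_degenerate=n_degenerate)


def exact_permutation_p(df: pd.DataFrame, contrast=None,
                        covariates: tuple = (),
                        max_assignments: int = 50_000,
                        sided: str = "two") -> float:
    """Exact permutation p-value by exhaustive enumeration of within-study
    treatment-label assignments (instances up to ``max_assignments``).

    The observed assignment is included in the reference set, so the
    returned probability is the exact randomization-test p-value.
    """
    studies = prepare_analysis_data(df, get_contrast(contrast), covariates)
    if all(sd.y.min() == sd.y.max() for sd in studies):
        return 1.0  # the statistic is constant over all assignments
    total = 1
    for sd in studies:
        total *= math.comb(len(sd.y), int(sd.treat.sum()))
        if total > max_assignments:
            raise TooLargeError(
                f"exact enumeration would need {total}+ assignments "
                f"(cap {max_assignments})")
    observed, _ = two_stage_theta_p(studies)

    per_study_assignments = []
    for sd in studies:
        n, t = len(sd.y), int(sd.treat.sum())
        assigns = []
        for chosen in combinations(range(n), t):
            treat = np.zeros(n)
            treat[list(chosen)] = 1.0
            assigns.append(treat)
        per_study_assignments.append(assigns)

    work = [StudyData(sd.study_id, sd.y, sd.treat, sd.Z, sd.colnames, sd.arm)
            for sd in studies]
    count = 0
    n_total = 0
    eps = 1e-12
    for combo in product(*per_study_assignments):
        for sd, treat in zip(work, combo):
            sd.treat = treat
        theta, _ = two_stage_theta_p(work)
        n_total += 1
        if sided == "two":
            count += abs(theta) >= abs(observed) - eps
        elif sided == "greater":
            count += theta >= observed - eps
        else:
            raise ValidationError(f"sided: unknown value {sided!r}")
    return count / n_total


def bootstrap_ci(df: pd.DataFrame, contrast=None, covariates=DEFAULT_COVARIATES,
                 B: int = 2000, level: float = 0.95, seed: int | None = None,
                 studies: list[StudyData] | None = None) -> BootstrapResult:
    """Stratified percentile bootstrap interval for the pooled log-OR.

    Participants are resampled with replacement within study x arm strata,
    so every replicate keeps the original arm sizes.
    """
    if B < 1:
        raise ValidationError("B: must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("level: must be in (0, 1)")
    if studies is None:
        studies = prepare_analysis_data(df, get_contrast(contrast), covariates)
    rng = np.random.default_rng(seed)
    observed, _ = two_stage_theta_p(studies)

    strata = []  # (study index, row indices of one study x arm stratum)
    for j, sd in enumerate(studies):
        for arm in np.unique(sd.arm):
            rows = np.flatnonzero(sd.arm == arm)
            if len(rows) == 0:
                raise NonEstimableError(
                    f"stratum {sd.study_id}/{arm}: empty")
            strata.append((j, rows))

    draws = np.empty(B)
    n_degenerate = 0
    for b in range(B):
        resampled = []
        for j, sd in enumerate(studies):
            idx_parts = [rows[rng.integers(0, len(rows), size=len(rows))]
                         for jj, rows in strata if jj == j]
            idx = np.concatenate(idx_parts)
            resampled.append(StudyData(sd.study_id, sd.y[idx], sd.treat[idx],
                                       sd.Z[idx], sd.colnames, sd.arm[idx]))
        theta, n_pen = two_stage_theta_p(resampled)
        draws[b] = theta
        n_degenerate += n_pen

    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [alpha, 1.0 - alpha])
    return BootstrapResult(level=level, lower=float(lower), upper=float(upper),
                           lower_or=float(math.exp(lower)),
                           upper_or=float(math.exp(upper)),
                           point_estimate=float(observed),
                           replicate_draws=draws, B=B, seed=seed,
                           n_degenerate=n_degenerate)
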