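"""Model/Results interface for the pooled multisite trial analysis.

:class:`PooledTrialModel` is constructed from a participant-level cohort
(one row per randomized participant) and a treatment contrast; ``fit()``
runs the full inferential stack — per-study covariate-adjusted logistic
fits, inverse-variance pooling, within-study permutation test, stratified
bootstrap interval and (optionally) the Bayesian hierarchical sensitivity
model — and returns a :class:`PooledTrialResults` carrying the estimates,
their uncertainties and diagnostics, with a ``summary()`` table.

Example
-------
>>> from multitrial import PooledTrialModel, simulate
>>> cohort, _ = simulate.simulate_analytic_cohort(simulate.default_config(seed=7))
>>> res = PooledTrialModel.from_dataframe(cohort).fit(permutations=1000,
...                                                   bootstrap=1000, seed=7)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bayes import PosteriorSummary, PriorSpec, fit_bayesian_hierarchical
from .cohort import apply_exclusions, impute_missing_as_positive, read_cohort_csv
from .estimation import (DEFAULT_COVARIATES, PooledEstimate, fit_prepared,
                         format_forest, get_contrast, pool_estimates,
                         prepare_analysis_data)
from .exceptions import ValidationError
from .resampling import (BootstrapResult, PermutationResult, bootstrap_ci,
                         permutation_test)

__all__ = ["PooledTrialModel", "PooledTrialResults", "crude_proportions"]


def crude_proportions(df: pd.DataFrame, contrast) -> dict:
    """Positive-outcome proportion per contrast group (counts, denominators,
    full-precision proportion and whole-percent display value)."""
    contrast = get_contrast(contrast)
    out = {}
    for label, arms in (("treated", contrast.treated_arms),
                        ("reference", contrast.reference_arms)):
        grp = df[df["arm"].isin(arms)]
        n = len(grp)
        pos = int((grp["outcome"] == "positive").sum())
        if n == 0:
            out[label] = {"n": 0, "positive": 0, "proportion": None,
                          "percent": None}
        else:
            prop = pos / n
            out[label] = {"n": n, "positive": pos, "proportion": prop,
                          "percent": int(round(100.0 * prop))}
    t, r = out["treated"], out["reference"]
    if t["proportion"] not in (None, 0.0, 1.0) and r["proportion"] not in (None, 0.0, 1.0):
        odds_t = t["proportion"] / (1 - t["proportion"])
        odds_r = r["proportion"] / (1 - r["proportion"])
        out["crude_odds_ratio"] = odds_t / odds_r
    else:
        out["crude_odds_ratio"] = None
    return out


class PooledTrialModel:
    """Two-stage pooled treatment-effect model for a multisite trial cohort.

    Parameters
    ----------
    data : DataFrame
        Participant-level cohort (documented column set), assumed
        analysis-ready (exclusions and imputation already applied). Pass
        ``preprocess=True`` to run both rules on construction.
    contrast : str or ContrastSpec
        ``"ANY_MED_VS_ETAU"`` (default) or ``"MED_PN_VS_MED"``.
    covariates : sequence of str
        Adjustment set for the stage-1 logistic models.
    """

    def __init__(self, data: pd.DataFrame, contrast="ANY_MED_VS_ETAU",
                 covariates=DEFAULT_COVARIATES, preprocess: bool = False):
        self.contrast = get_contrast(contrast)
        self.covariates = tuple(covariates)
        self.exclusion_report = None
        if preprocess:
            data, self.exclusion_report = apply_exclusions(data)
            data = impute_missing_as_positive(data)
        remaining_missing = data["outcome"].isna() | (data["outcome"] == "missing")
        if remaining_missing.any():
            raise ValidationError(
                "outcome: missing outcomes remain; run the imputation step "
                "or construct with preprocess=True")
        self.data = data
        self._studies = prepare_analysis_data(data, self.contrast, self.covariates)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PooledTrialModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PooledTrialModel":
        return cls(read_cohort_csv(path), **kwargs)

    def fit(self, permutations: int = 5000, bootstrap: int = 2000,
            bayes: bool = False, level: float = 0.95, seed: int | None = None,
            priors: PriorSpec | None = None, chains: int = 2,
            iterations: int = 1000) -> "PooledTrialResults":
        """Run the full two-stage analysis.

        ``permutations=0`` / ``bootstrap=0`` skip the corresponding stage.
        All resampling and MCMC randomness derives from ``seed``.
        """
        study_estimates = [fit_prepared(sd) for sd in self._studies]
        pooled = pool_estimates(study_estimates)

        root = np.random.SeedSequence(seed)
        perm_seed, boot_seed, bayes_seed = [
            int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(3)]

        perm = None
        if permutations:
            perm = permutation_test(self.data, self.contrast, self.covariates,
                                    B=permutations, seed=perm_seed,
                                    studies=self._studies)
        boot = None
        if bootstrap:
            boot = bootstrap_ci(self.data, self.contrast, self.covariates,
                                B=bootstrap, level=level, seed=boot_seed,
                                studies=self._studies)
        posterior = None
        if bayes:
            posterior = fit_bayesian_hierarchical(
                self.data, self.contrast, self.covariates, priors=priors,
                chains=chains, iterations=iterations, seed=bayes_seed)

        return PooledTrialResults(
            model=self, study_estimates=study_estimates, pooled=pooled,
            permutation=perm, bootstrap=boot, posterior=posterior,
            crude=crude_proportions(self.data, self.contrast),
            seed=seed, level=level)


@dataclass
class PooledTrialResults:
    """Estimates, uncertainty and diagnostics from :meth:`PooledTrialModel.fit`."""

    model: PooledTrialModel
    study_estimates: list
    pooled: PooledEstimate
    permutation: PermutationResult | None
    bootstrap: BootstrapResult | None
    posterior: PosteriorSummary | None
    crude: dict
    seed: int | None
    level: float
    warnings: list = field(default_factory=list)

    @property
    def theta_p(self) -> float:
        return self.pooled.theta_p

    @property
    def odds_ratio(self) -> float:
        return self.pooled.odds_ratio

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {
            "version": _version,
            "contrast": self.model.contrast.name,
            "covariates": list(self.model.covariates),
            "seed": self.seed,
            "level": self.level,
            "eligible_studies": [e.study_id for e in self.study_estimates],
            "study_estimates": [e.to_dict() for e in self.study_estimates],
            "pooled": self.pooled.to_dict(),
            "crude_proportions": self.crude,
            "warnings": sorted({w for e in self.study_estimates
                                for w in e.warnings} | set(self.warnings)),
        }
        if self.permutation is not None:
            d["permutation"] = self.permutation.to_dict(include_draws)
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.to_dict(include_draws)
        if self.posterior is not None:
            d["bayes"] = self.posterior.to_dict(include_draws)
        return d

    def summary(self) -> str:
        lines = [
            f"Pooled multisite trial analysis ({self.model.contrast.name})",
            f"covariate adjustment: {', '.join(self.model.covariates)}",
            "",
            format_forest(self.study_estimates, self.pooled),
            "",
            f"pooled log-OR theta_p = {self.pooled.theta_p:.3f} "
            f"(se {self.pooled.se_p:.3f}), OR = {self.pooled.odds_ratio:.2f}",
        ]
        crude = self.crude
        if crude["treated"]["percent"] is not None:
            lines.append(
                f"crude outcome: treated {crude['treated']['positive']}/"
                f"{crude['treated']['n']} ({crude['treated']['percent']}%), "
                f"reference {crude['reference']['positive']}/"
                f"{crude['reference']['n']} ({crude['reference']['percent']}%)")
        if self.permutation is not None:
            p = self.permutation
            lines.append(
                f"permutation test (B={p.B}): two-sided p = {p.p_two_sided:.4f}, "
                f"one-sided (H1: theta_p>0) p = {p.p_one_sided:.4f}")
        if self.bootstrap is not None:
            b = self.bootstrap
            lines.append(
                f"bootstrap {b.level:.0%} CI (B={b.B}): "
                f"OR {b.lower_or:.2f} to {b.upper_or:.2f} "
                f"(log-OR {b.lower:.3f} to {b.upper:.3f})")
        if self.posterior is not None:
            lo, hi = self.posterior.or_intervals["theta_p"]
            med = math.exp(self.posterior.medians["theta_p"])
            flag = "" if self.posterior.converged else "  ** NOT CONVERGED **"
            lines.append(
                f"Bayesian hierarchical model: posterior median OR {med:.2f}, "
                f"95% CrI {lo:.2f} to {hi:.2f}{flag}")
        return "\n".join(lines)
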