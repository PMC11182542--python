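"""Operating-characteristic simulations for the two-stage pooled estimator.

Each function simulates full analytic cohorts from a generative
configuration, runs the complete pipeline (follow-up, exclusions,
missing-as-positive imputation, two-stage estimation, resampling) on every
replicate, and reports frequency properties: type-I error of the
permutation test under the null, bias of the pooled estimate against the
generating conditional log-OR, coverage of the stratified bootstrap
interval, and power along an effect grid (common random numbers across grid
points).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimation import DEFAULT_COVARIATES, fit_prepared, pool_estimates, prepare_analysis_data
from .resampling import bootstrap_ci, permutation_test
from .simulate import (SimulationConfig, default_config, null_config,
                       simulate_analytic_cohort, true_pooled_log_or)

__all__ = ["type_one_error", "parameter_recovery", "bootstrap_coverage",
           "power_curve", "scaled_config", "known_effect_config"]


def known_effect_config(seed: int = 0, theta_med: float | None = None) -> SimulationConfig:
    """Study-condition config whose analyzed-outcome estimand is exactly the
    configured ``theta_med``: the navigation increment is zero (so the
    collapsed any-medication contrast carries a single effect) and outcome
    missingness is zero (the worst-case missing-as-positive imputation
    otherwise attenuates the conditional effect by design)."""
    kw = {} if theta_med is None else {"theta_med": theta_med}
    cfg = default_config(seed=seed, theta_pn=0.0, **kw)
    cfg.missingness = replace(cfg.missingness, rate=0.0)
    return cfg


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31, size=n)


def _with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))


def scaled_config(config: SimulationConfig, factor: int) -> SimulationConfig:
    """Multiply every arm size by ``factor`` (e.g. 10x designs for bias runs)."""
    designs = [replace(d, arm_sizes={a: n * factor for a, n in d.arm_sizes.items()})
               for d in config.designs]
    return replace(config, designs=designs)


def type_one_error(n_datasets: int = 300, B: int = 200, alpha: float = 0.05,
                   seed: int = 0, config: SimulationConfig | None = None,
                   contrast: str = "ANY_MED_VS_ETAU",
                   covariates=DEFAULT_COVARIATES,
                   return_pvalues: bool = False) -> dict:
    """Rejection rate of the two-sided permutation test under theta = 0."""
    base = config or null_config()
    seeds = _child_seeds(seed, 2 * n_datasets).reshape(2, n_datasets)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        cohort, _ = simulate_analytic_cohort(_with_seed(base, seeds[0, i]))
        res = permutation_test(cohort, contrast, covariates, B=B,
                               seed=int(seeds[1, i]))
        pvals[i] = res.p_two_sided
    rate = float((pvals <= alpha).mean())
    out = {"rejection_rate": rate, "n_datasets": n_datasets, "B": B,
           "alpha": alpha,
           "mc_se": float(np.sqrt(rate * (1 - rate) / n_datasets))}
    if return_pvalues:
        out["pvalues"] = pvals
    return out


def parameter_recovery(n_reps: int = 300, scale: int = 10, seed: int = 0,
                       config: SimulationConfig | None = None,
                       contrast: str = "ANY_MED_VS_ETAU",
                       covariates=DEFAULT_COVARIATES) -> dict:
    """Mean pooled estimate over replicates vs the generating conditional
    log-OR, at ``scale`` times the design sizes.

    The default configuration is :func:`known_effect_config`, whose
    analyzed-outcome estimand equals the configured ``theta_med`` exactly;
    with a navigation increment or missing-as-positive imputation in play
    the collapsed contrast targets a blended or attenuated effect and a
    single-number truth is undefined.
    """
    base = scaled_config(config or known_effect_config(), scale)
    truth = true_pooled_log_or(base).theta_p_true
    seeds = _child_seeds(seed, n_reps)
    thetas = np.empty(n_reps)
    for i in range(n_reps):
        cohort, _ = simulate_analytic_cohort(_with_seed(base, seeds[i]))
        studies = prepare_analysis_data(cohort, contrast, covariates)
        thetas[i] = pool_estimates([fit_prepared(sd) for sd in studies]).theta_p
    mean = float(thetas.mean())
    mc_se = float(thetas.std(ddof=1) / np.sqrt(n_reps))
    return {"mean_theta_p": mean, "truth": float(truth), "bias": mean - truth,
            "mc_se": mc_se, "n_reps": n_reps, "scale": scale}


def bootstrap_coverage(n_datasets: int = 300, B: int = 200, level: float = 0.95,
                       seed: int = 0, config: SimulationConfig | None = None,
                       contrast: str = "ANY_MED_VS_ETAU",
                       covariates=DEFAULT_COVARIATES) -> dict:
    """Fraction of stratified percentile intervals containing the generating
    conditional pooled log-OR (defaults to :func:`known_effect_config`; see
    :func:`parameter_recovery`)."""
    base = config or known_effect_config()
    truth = true_pooled_log_or(base).theta_p_true
    seeds = _child_seeds(seed, 2 * n_datasets).reshape(2, n_datasets)
    covered = 0
    for i in range(n_datasets):
        cohort, _ = simulate_analytic_cohort(_with_seed(base, seeds[0, i]))
        ci = bootstrap_ci(cohort, contrast, covariates, B=B, level=level,
                          seed=int(seeds[1, i]))
        covered += ci.lower <= truth <= ci.upper
    rate = covered / n_datasets
    return {"coverage": rate, "truth": float(truth), "n_datasets": n_datasets,
            "B": B, "level": level,
            "mc_se": float(np.sqrt(rate * (1 - rate) / n_datasets))}


def power_curve(effects=(0.0, 0.3, 0.6, 0.9), n_datasets: int = 100,
                B: int = 200, alpha: float = 0.05, seed: int = 0,
                contrast: str = "ANY_MED_VS_ETAU",
                covariates=DEFAULT_COVARIATES) -> dict:
    """Two-sided rejection rate along a grid of |conditional log-OR| values.

    Common random numbers: the same dataset and permutation seeds are used
    at every grid point, so the curve is monotone up to estimator noise
    only.
    """
    seeds = _child_seeds(seed, 2 * n_datasets).reshape(2, n_datasets)
    rates = {}
    for eff in effects:
        base = default_config(theta_med=float(eff), theta_pn=0.0)
        rejections = 0
        for i in range(n_datasets):
            cohort, _ = simulate_analytic_cohort(_with_seed(base, seeds[0, i]))
            res = permutation_test(cohort, contrast, covariates, B=B,
                                   seed=int(seeds[1, i]))
            rejections += res.p_two_sided <= alpha
        rates[float(eff)] = rejections / n_datasets
    return {"rejection_rates": rates, "n_datasets": n_datasets, "B": B,
            "alpha": alpha}
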