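"""Bayesian hierarchical sensitivity model for the pooled treatment effect.

Model (participant level, study j, participant i):

    y_ij ~ Bernoulli(logit^-1(alpha_j + x_ij' beta_j + theta_j t_ij))
    theta_j ~ Normal(theta_p, tau^2)
    theta_p ~ Normal(0, sd_pooled_effect^2)
    tau     ~ Half-Normal(scale_tau)
    alpha_j, beta_jk ~ Normal(0, sd_nuisance^2)

Between-study heterogeneity in the treatment effect lives in tau; as
scale_tau -> 0 the posterior for theta_p approaches the fixed-effect pooled
estimate. Sampling is adaptive random-walk Metropolis within Gibbs using
the non-centered parameterization theta_j = theta_p + tau u_j, u_j ~ N(0,1),
which keeps mixing healthy in the weak-data and small-tau regimes. Step
sizes adapt only during warmup (targeting ~30% acceptance, within the
20-40% band); warmup draws are discarded, no thinning.

Convergence is reported per parameter via split-Rhat and effective sample
size (arviz); the summary carries a prominent non-convergence flag when any
Rhat > 1.05 or ESS < 100 — the result is still returned, the caller
decides.

A summary-level normal-normal variant (:func:`fit_summary_normal`), whose
likelihood replaces the participant data with fixed study estimates
(theta_hat_j, var_j), is provided for closed-form limit checks: with a flat
pooled prior and tau fixed at 0 its posterior for theta_p is exactly
Normal(theta_IV, se_p^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (DEFAULT_COVARIATES, get_contrast,
                         prepare_analysis_data, fit_prepared, pool_estimates)
from .exceptions import ValidationError
from .logistic import fit_logistic

__all__ = ["PriorSpec", "PosteriorSummary", "fit_bayesian_hierarchical",
           "fit_summary_normal", "posterior_interval"]

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 100.0


@dataclass
class PriorSpec:
    """Prior scales (all on the log-odds scale; must be positive)."""

    sd_pooled_effect: float = 10.0
    sd_nuisance: float = 10.0
    scale_tau: float = 1.0

    def validate(self) -> None:
        for name in ("sd_pooled_effect", "sd_nuisance", "scale_tau"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be > 0")


@dataclass
class PosteriorSummary:
    """Posterior draws with medians, equal-tailed 95% intervals and
    convergence diagnostics for every parameter."""

    draws: dict                 # name -> array (chains, draws)
    medians: dict
    intervals: dict             # name -> (lo, hi), log-OR scale
    or_intervals: dict          # effect parameters only, OR scale
    rhat: dict
    ess: dict
    chains: int
    converged: bool
    warnings: list = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).reshape(-1)

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {"medians": self.medians,
             "intervals": {k: list(v) for k, v in self.intervals.items()},
             "or_intervals": {k: list(v) for k, v in self.or_intervals.items()},
             "rhat": self.rhat, "ess": self.ess, "chains": self.chains,
             "converged": self.converged, "warnings": list(self.warnings)}
        if include_draws:
            d["draws"] = {k: np.asarray(v).tolist() for k, v in self.draws.items()}
        return d


def posterior_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical-percentile credible interval."""
    arr = np.asarray(draws, dtype=float).reshape(-1)
    if arr.size == 0:
        raise ValidationError("posterior_interval: empty draws")
    if not 0.0 < level < 1.0:
        raise ValidationError("level: must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# adaptive scalar random-walk kernel


class _AdaptiveStep:
    """Scalar random-walk step with Robbins-Monro adaptation during warmup."""

    __slots__ = ("log_step", "target", "k", "frozen")

    def __init__(self, step: float, target: float = 0.3):
        self.log_step = math.log(step)
        self.target = target
        self.k = 0
        self.frozen = False

    @property
    def step(self) -> float:
        return math.exp(self.log_step)

    def update(self, accept_prob: float) -> None:
        if self.frozen:
            return
        self.k += 1
        self.log_step += (accept_prob - self.target) * self.k ** -0.6


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2 - math.log(scale)


# ---------------------------------------------------------------------------
# full participant-level model


def _loglik(eta: np.ndarray, y: np.ndarray, weight: float) -> float:
    if weight == 0.0:
        return 0.0
    return weight * float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_bayesian_hierarchical(df: pd.DataFrame, contrast=None,
                              covariates=DEFAULT_COVARIATES,
                              priors: PriorSpec | None = None,
                              chains: int = 2, iterations: int = 1000,
                              warmup: int | None = None,
                              seed: int | None = None,
                              likelihood_weight: float = 1.0,
                              adapt_target: float = 0.3) -> PosteriorSummary:
    """Fit the hierarchical logistic model by adaptive MH-within-Gibbs.

    ``iterations`` are post-warmup draws per chain; ``warmup`` defaults to
    ``iterations`` and is discarded. ``likelihood_weight`` scales the data
    log-likelihood (0 gives a prior-only run). Deterministic given ``seed``
    and ``chains``.
    """
    priors = priors or PriorSpec()
    priors.validate()
    if chains < 2:
        raise ValidationError("chains: at least 2 required for split-Rhat")
    if warmup is None:
        warmup = iterations
    studies = prepare_analysis_data(df, get_contrast(contrast), covariates)
    J = len(studies)

    # frequentist initialization (penalization-safe); the fitted covariance
    # of the nuisance block shapes its joint random-walk proposal
    inits, full_chol = [], []
    for sd in studies:
        X = np.column_stack([np.ones(len(sd.y)), sd.treat, sd.Z])
        fit = fit_logistic(X, sd.y)
        inits.append(fit.coef)
        # reorder to (theta, alpha, betas) for the joint block proposal
        order = [1, 0] + list(range(2, X.shape[1]))
        cov_o = fit.cov[np.ix_(order, order)]
        try:
            full_chol.append(np.linalg.cholesky(cov_o))
        except np.linalg.LinAlgError:
            full_chol.append(np.diag(np.sqrt(np.abs(np.diag(cov_o)) + 1e-6)))
    theta0 = [c[1] for c in inits]
    pooled0 = pool_estimates([fit_prepared(sd) for sd in studies]).theta_p

    param_names = (["theta_p", "tau"]
                   + [f"theta[{sd.study_id}]" for sd in studies]
                   + [f"alpha[{sd.study_id}]" for sd in studies]
                   + [f"beta[{sd.study_id},{name}]"
                      for sd in studies for name in sd.colnames[2:]])
    store = {name: np.empty((chains, iterations)) for name in param_names}

    w = float(likelihood_weight)
    for c in range(chains):
        rng = np.random.default_rng(
            [0 if seed is None else int(seed), c])
        # jittered start for overdispersion across chains
        theta_p = pooled0 + 0.2 * rng.standard_normal()
        tau = abs(0.25 * priors.scale_tau * (1.0 + 0.5 * rng.standard_normal()))
        tau = max(tau, 1e-3)
        u = np.array([(t - theta_p) / max(tau, 0.05) for t in theta0])
        u += 0.1 * rng.standard_normal(J)
        coefs = [ci.copy() + 0.05 * rng.standard_normal(len(ci)) for ci in inits]
        for cj in coefs:
            cj[1] = 0.0  # treatment effect lives in theta_j, not the coef block

        # per-study cached state
        nuis_X = []   # [1, Z] design for nuisance block
        for sd in studies:
            nuis_X.append(np.column_stack([np.ones(len(sd.y)), sd.Z]))
        nuis = [np.concatenate([[cj[0]], cj[2:]]) for cj in coefs]
        theta_j = theta_p + tau * u
        base_eta = [nx @ nv for nx, nv in zip(nuis_X, nuis)]
        eta = [be + th * sd.treat for be, th, sd in zip(base_eta, theta_j, studies)]
        ll = [_loglik(e, sd.y, w) for e, sd in zip(eta, studies)]

        steps = {
            "theta_p": _AdaptiveStep(0.2, adapt_target),
            "log_tau": _AdaptiveStep(0.3, adapt_target),
            "log_tau_c": _AdaptiveStep(0.5, adapt_target),
        }
        for j in range(J):
            steps[f"u{j}"] = _AdaptiveStep(1.0, adapt_target)
            steps[f"c{j}"] = _AdaptiveStep(1.0, 0.25)

        def theta_prior_lp(tp):
            return -0.5 * (tp / priors.sd_pooled_effect) ** 2

        def nuis_prior_lp(v):
            return -0.5 * float(v @ v) / priors.sd_nuisance ** 2

        total = warmup + iterations
        for it in range(total):
            if it == warmup:
                for s in steps.values():
                    s.frozen = True

            # theta_p: random-walk MH (moves every theta_j through the
            # non-centered map)
            st = steps["theta_p"]
            dp = st.step * rng.standard_normal()
            cand_eta = [e + dp * sd.treat for e, sd in zip(eta, studies)]
            cand_ll = [_loglik(e, sd.y, w) for e, sd in zip(cand_eta, studies)]
            logr = (sum(cand_ll) - sum(ll)
                    + theta_prior_lp(theta_p + dp) - theta_prior_lp(theta_p))
            acc = min(1.0, math.exp(min(logr, 0.0)))
            if rng.random() < acc:
                theta_p += dp
                theta_j = theta_j + dp
                eta, ll = cand_eta, cand_ll
            st.update(acc)

            # interweaved (centered) Gibbs for theta_p: theta_j are held
            # fixed, so no likelihood evaluation is needed; breaks the
            # theta_p <-> u ridge of the non-centered walk
            prec_p = J / tau ** 2 + priors.sd_pooled_effect ** -2
            mean_p = (theta_j.sum() / tau ** 2) / prec_p
            theta_p = mean_p + rng.standard_normal() / math.sqrt(prec_p)
            u = (theta_j - theta_p) / tau

            # tau on the log scale, non-centered (Jacobian included)
            st = steps["log_tau"]
            x_new = math.log(tau) + st.step * rng.standard_normal()
            tau_new = math.exp(x_new)
            theta_new = theta_p + tau_new * u
            cand_eta = [be + th * sd.treat
                        for be, th, sd in zip(base_eta, theta_new, studies)]
            cand_ll = [_loglik(e, sd.y, w) for e, sd in zip(cand_eta, studies)]
            logr = (sum(cand_ll) - sum(ll)
                    + _halfnormal_logpdf(tau_new, priors.scale_tau)
                    - _halfnormal_logpdf(tau, priors.scale_tau)
                    + x_new - math.log(tau))
            acc = min(1.0, math.exp(min(logr, 0.0)))
            if rng.random() < acc:
                tau = tau_new
                theta_j = theta_new
                eta, ll = cand_eta, cand_ll
            st.update(acc)

            # interweaved centered MH for tau (theta_j fixed, no likelihood);
            # cheap, so applied twice per sweep
            st = steps["log_tau_c"]
            resid2 = float(((theta_j - theta_p) ** 2).sum())

            def _tau_lp(t):
                return (-J * math.log(t) - 0.5 * resid2 / t ** 2
                        + _halfnormal_logpdf(t, priors.scale_tau) + math.log(t))

            for _ in range(2):
                x_new = math.log(tau) + st.step * rng.standard_normal()
                tau_new = math.exp(x_new)
                logr = _tau_lp(tau_new) - _tau_lp(tau)
                acc = min(1.0, math.exp(min(logr, 0.0)))
                if rng.random() < acc:
                    tau = tau_new
                st.update(acc)
            u = (theta_j - theta_p) / tau

            # study-level effects u_j and joint nuisance-block proposals
            for j, sd in enumerate(studies):
                st = steps[f"u{j}"]
                du = st.step * rng.standard_normal()
                cand_e = eta[j] + tau * du * sd.treat
                cand_l = _loglik(cand_e, sd.y, w)
                logr = cand_l - ll[j] - 0.5 * ((u[j] + du) ** 2 - u[j] ** 2)
                acc = min(1.0, math.exp(min(logr, 0.0)))
                if rng.random() < acc:
                    u[j] += du
                    theta_j[j] = theta_p + tau * u[j]
                    eta[j], ll[j] = cand_e, cand_l
                st.update(acc)

                # joint correlated random walk over (alpha_j, beta_j,
                # theta_j) shaped by the full frequentist covariance, which
                # carries the treatment/intercept correlation; three moves
                # per sweep
                st = steps[f"c{j}"]
                for _ in range(3):
                    d_all = st.step * (full_chol[j] @
                                       rng.standard_normal(1 + len(nuis[j])))
                    d_theta, d_nuis = d_all[0], d_all[1:]
                    cand_v = nuis[j] + d_nuis
                    cand_th = theta_j[j] + d_theta
                    cand_base = base_eta[j] + nuis_X[j] @ d_nuis
                    cand_e = cand_base + cand_th * sd.treat
                    cand_l = _loglik(cand_e, sd.y, w)
                    logr = (cand_l - ll[j]
                            + nuis_prior_lp(cand_v) - nuis_prior_lp(nuis[j])
                            - 0.5 * ((cand_th - theta_p) ** 2
                                     - (theta_j[j] - theta_p) ** 2) / tau ** 2)
                    acc = min(1.0, math.exp(min(logr, 0.0)))
                    if rng.random() < acc:
                        nuis[j] = cand_v
                        theta_j[j] = cand_th
                        u[j] = (cand_th - theta_p) / tau
                        base_eta[j] = cand_base
                        eta[j], ll[j] = cand_e, cand_l
                    st.update(acc)

            if it >= warmup:
                s = it - warmup
                store["theta_p"][c, s] = theta_p
                store["tau"][c, s] = tau
                for j, sd in enumerate(studies):
                    store[f"theta[{sd.study_id}]"][c, s] = theta_j[j]
                    store[f"alpha[{sd.study_id}]"][c, s] = nuis[j][0]
                    for k, name in enumerate(sd.colnames[2:]):
                        store[f"beta[{sd.study_id},{name}]"][c, s] = nuis[j][k + 1]

    effect_params = ["theta_p"] + [f"theta[{sd.study_id}]" for sd in studies]
    return _summarize(store, chains, effect_params)


def _summarize(store: dict, chains: int, effect_params: list) -> PosteriorSummary:
    import arviz as az

    medians, intervals, or_intervals, rhat, ess = {}, {}, {}, {}, {}
    warnings = []
    for name, arr in store.items():
        flat = arr.reshape(-1)
        medians[name] = float(np.median(flat))
        intervals[name] = posterior_interval(flat, 0.95)
        if name in effect_params:
            lo, hi = intervals[name]
            or_intervals[name] = (math.exp(lo), math.exp(hi))
        if np.ptp(flat) == 0.0:  # degenerate (e.g. fixed tau): no variance
            rhat[name], ess[name] = 1.0, float(flat.size)
        else:
            rhat[name] = float(az.rhat(arr))
            ess[name] = float(az.ess(arr))
    bad = [n for n in store
           if rhat[n] > RHAT_THRESHOLD or ess[n] < ESS_THRESHOLD]
    converged = not bad
    if bad:
        warnings.append("NON-CONVERGENCE: Rhat/ESS thresholds violated for "
                        + ", ".join(sorted(bad)))
    return PosteriorSummary(draws=store, medians=medians, intervals=intervals,
                            or_intervals=or_intervals, rhat=rhat, ess=ess,
                            chains=chains, converged=converged,
                            warnings=warnings)


# ---------------------------------------------------------------------------
# summary-level normal-normal variant (conjugate limit oracle)


def fit_summary_normal(theta_hat, variances, priors: PriorSpec | None = None,
                       tau_fixed: float | None = None,
                       flat_pooled_prior: bool = False,
                       chains: int = 2, iterations: int = 2000,
                       seed: int | None = None,
                       study_ids=None) -> PosteriorSummary:
    """Hierarchical normal-normal model on study summaries.

    Likelihood: theta_hat_j ~ N(theta_j, var_j); hierarchy as in the full
    model. theta_j and theta_p updates are conjugate Gibbs draws; tau (when
    not fixed) is random-walk MH on the log scale. With ``tau_fixed=0`` and
    ``flat_pooled_prior=True`` the theta_p posterior is exactly
    Normal(theta_IV, 1/sum(1/var_j)).
    """
    priors = priors or PriorSpec()
    priors.validate()
    th = np.asarray(theta_hat, dtype=float)
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("variances: must be positive")
    J = len(th)
    ids = list(study_ids) if study_ids is not None else [str(j) for j in range(J)]
    prior_prec = 0.0 if flat_pooled_prior else priors.sd_pooled_effect ** -2

    names = ["theta_p", "tau"] + [f"theta[{s}]" for s in ids]
    store = {name: np.empty((chains, iterations)) for name in names}

    for c in range(chains):
        rng = np.random.default_rng([0 if seed is None else int(seed), c])
        theta_p = float(np.sum(th / v) / np.sum(1.0 / v)) + 0.1 * rng.standard_normal()
        tau = priors.scale_tau * 0.5 if tau_fixed is None else float(tau_fixed)
        theta_j = th.copy()
        step = _AdaptiveStep(0.3)
        for it in range(2 * iterations):
            if it == iterations:
                step.frozen = True
            if tau > 0:
                prec = 1.0 / v + tau ** -2
                mean = (th / v + theta_p / tau ** 2) / prec
                theta_j = mean + rng.standard_normal(J) / np.sqrt(prec)
                prec_p = J / tau ** 2 + prior_prec
                mean_p = (theta_j.sum() / tau ** 2) / prec_p
                theta_p = mean_p + rng.standard_normal() / math.sqrt(prec_p)
            else:
                # tau = 0: theta_j degenerate at theta_p; direct conjugate draw
                prec_p = np.sum(1.0 / v) + prior_prec
                mean_p = np.sum(th / v) / prec_p
                theta_p = mean_p + rng.standard_normal() / math.sqrt(prec_p)
                theta_j = np.full(J, theta_p)
            if tau_fixed is None:
                x_new = math.log(tau) + step.step * rng.standard_normal()
                tau_new = math.exp(x_new)
                resid = theta_j - theta_p
                def _lp(t):
                    return (-J * math.log(t) - 0.5 * np.sum(resid ** 2) / t ** 2
                            + _halfnormal_logpdf(t, priors.scale_tau)
                            + math.log(t))
                logr = _lp(tau_new) - _lp(tau)
                acc = min(1.0, math.exp(min(logr, 0.0)))
                if rng.random() < acc:
                    tau = tau_new
                step.update(acc)
            if it >= iterations:
                s = it - iterations
                store["theta_p"][c, s] = theta_p
                store["tau"][c, s] = tau
                for j, sid in enumerate(ids):
                    store[f"theta[{sid}]"][c, s] = theta_j[j]

    effect = ["theta_p"] + [f"theta[{s}]" for s in ids]
    return _summarize(store, chains, effect)
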