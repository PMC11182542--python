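"""Synthetic multi-site randomized-trial cohort generator.

Emulates the structure of three jail-based randomized trials of medication
for opioid use disorder (MOUD): per-study designs with an enhanced
treatment-as-usual (ETAU) control arm, a medication arm (extended-release
naltrexone or interim methadone), and — in two of the three studies — a
medication-plus-patient-navigation arm. The binary endpoint (current OUD
diagnosis at 6 months post-release) is drawn from a logistic model with
study-specific intercepts, covariate effects, and treatment log-odds
ratios placed on the conditional (covariate-adjusted) scale, so that the
generating effect matches the estimand of the adjusted logistic analysis.
Because the odds ratio is noncollapsible, the crude (marginal) odds ratio
in generated data differs slightly from the configured conditional one;
this is documented, not reconciled.

Follow-up is modelled in a second pass: each participant is assigned a
follow-up status (in community / prison transfer / incarcerated at
follow-up / deceased) and, among those in the community, outcomes are set
to missing either completely at random (MCAR) or with probability shifted
on the logit scale by the latent outcome.

Default parameter values are the study conditions of the motivating
collaborative: the three-site design registry (N = 330 analyzed), the
printed baseline covariate marginals, generating treatment odds ratios
0.67 (any medication vs ETAU) and 0.61 (medication+navigation vs
medication), and a control-arm post-imputation outcome prevalence of 75%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .cohort import ARMS, COHORT_COLUMNS
from .exceptions import ValidationError

__all__ = [
    "StudyDesign", "CovariateDistributions", "Missingness", "SimulationConfig",
    "TrueParameters", "three_site_designs", "default_config", "null_config",
    "consort_flow_config", "generate_cohort", "apply_followup_process",
    "simulate_analytic_cohort", "true_pooled_log_or",
]


@dataclass
class StudyDesign:
    """Arms and sizes of one randomized study."""

    study_id: str
    arm_sizes: dict  # arm label -> count
    medication_type: str  # "XR-NTX" or "IM"

    @property
    def has_pn_arm(self) -> bool:
        return "MED_PN" in self.arm_sizes

    @property
    def n_total(self) -> int:
        return int(sum(self.arm_sizes.values()))

    def validate(self) -> None:
        for arm, n in self.arm_sizes.items():
            if arm not in ARMS:
                raise ValidationError(
                    f"arm_sizes: unknown arm {arm!r} in study {self.study_id!r}")
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ValidationError(
                    f"arm_sizes: size for arm {arm!r} in study "
                    f"{self.study_id!r} must be an integer >= 1, got {n!r}")
        for required in ("ETAU", "MED"):
            if required not in self.arm_sizes:
                raise ValidationError(
                    f"arm_sizes: study {self.study_id!r} must contain an "
                    f"{required} arm")
        if self.medication_type not in ("XR-NTX", "IM"):
            raise ValidationError(
                f"medication_type: must be 'XR-NTX' or 'IM', got "
                f"{self.medication_type!r} (study {self.study_id!r})")


@dataclass
class CovariateDistributions:
    """Sampling spec for baseline covariates.

    Age is normal truncated (by rejection-free clipping) to ``age_bounds``;
    binary covariates are Bernoulli; race is a 3-category draw over
    (Black, White, Other).
    """

    age_mean: float = 39.2
    age_sd: float = 10.9
    age_bounds: tuple = (18.0, 80.0)
    p_female: float = 0.212
    race_probs: tuple = (0.491, 0.409, 0.100)  # Black, White, Other
    p_hispanic: float = 0.294
    p_unhoused: float = 0.319
    p_stimulant_use: float = 0.65

    def validate(self) -> None:
        for name in ("p_female", "p_hispanic", "p_unhoused", "p_stimulant_use"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}: probability {p!r} outside [0,1]")
        if any(p < 0 for p in self.race_probs):
            raise ValidationError("race_probs: negative probability")
        if abs(sum(self.race_probs) - 1.0) > 1e-9:
            raise ValidationError("race_probs: probabilities must sum to 1")
        if self.age_sd <= 0:
            raise ValidationError("age_sd: must be positive")


@dataclass
class Missingness:
    """Outcome missingness among participants in the community.

    ``mechanism='MCAR'`` drops outcomes uniformly at ``rate``;
    ``'outcome_dependent'`` shifts the missingness logit by ``logit_shift``
    for participants whose latent outcome is positive.
    """

    mechanism: str = "MCAR"
    rate: float = 0.15
    logit_shift: float = 0.0

    def validate(self) -> None:
        if self.mechanism not in ("MCAR", "outcome_dependent"):
            raise ValidationError(
                f"missingness.mechanism: {self.mechanism!r} not in "
                "{'MCAR', 'outcome_dependent'}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValidationError(f"missingness.rate: {self.rate!r} outside [0,1]")


#: covariate-effect keys accepted by the generator (log-odds per unit)
COVARIATE_EFFECT_KEYS = ("age", "female", "race_White", "race_Other",
                         "hispanic", "unhoused", "stimulant_use")

DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.015,        # per year, centered at the generating mean
    "female": -0.2,
    "race_White": 0.1,
    "race_Other": -0.1,
    "hispanic": 0.0,
    "unhoused": 0.3,
    "stimulant_use": 0.4,
}


@dataclass
class SimulationConfig:
    """Full generative specification for a multi-site trial cohort."""

    designs: list
    study_intercepts: dict          # study_id -> baseline log-odds
    theta_med: dict                 # study_id -> log-OR any medication vs ETAU
    theta_pn: dict = field(default_factory=dict)   # study_id -> log-OR MED_PN vs MED
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    covariate_distributions: CovariateDistributions = field(default_factory=CovariateDistributions)
    missingness: Missingness = field(default_factory=Missingness)
    exclusion_rates: dict = field(default_factory=lambda: {
        "prison_transfer": 0.0, "incarcerated_at_followup": 0.0, "deceased": 0.0})
    seed: int = 0

    def validate(self) -> None:
        if not self.designs:
            raise ValidationError("designs: at least one study design required")
        ids = [d.study_id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise ValidationError("designs: duplicate study_id")
        for d in self.designs:
            d.validate()
            if d.study_id not in self.study_intercepts:
                raise ValidationError(
                    f"study_intercepts: missing entry for study {d.study_id!r}")
            if d.study_id not in self.theta_med:
                raise ValidationError(
                    f"theta_med: missing entry for study {d.study_id!r}")
            if d.has_pn_arm and d.study_id not in self.theta_pn:
                raise ValidationError(
                    f"theta_pn: missing entry for PN-arm study {d.study_id!r}")
        for key in self.covariate_effects:
            if key not in COVARIATE_EFFECT_KEYS:
                raise ValidationError(f"covariate_effects: unknown key {key!r}")
        self.covariate_distributions.validate()
        self.missingness.validate()
        for key in self.exclusion_rates:
            if key not in ("prison_transfer", "incarcerated_at_followup", "deceased"):
                raise ValidationError(f"exclusion_rates: unknown key {key!r}")
            if not 0.0 <= self.exclusion_rates[key] <= 1.0:
                raise ValidationError(
                    f"exclusion_rates[{key!r}]: outside [0,1]")
        if sum(self.exclusion_rates.values()) > 1.0:
            raise ValidationError("exclusion_rates: rates sum above 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_distributions"]["age_bounds"] = list(
            self.covariate_distributions.age_bounds)
        d["covariate_distributions"]["race_probs"] = list(
            self.covariate_distributions.race_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["designs"] = [StudyDesign(**x) if not isinstance(x, StudyDesign) else x
                        for x in d["designs"]]
        cd = d.get("covariate_distributions", {})
        if not isinstance(cd, CovariateDistributions):
            cd = dict(cd)
            if "age_bounds" in cd:
                cd["age_bounds"] = tuple(cd["age_bounds"])
            if "race_probs" in cd:
                cd["race_probs"] = tuple(cd["race_probs"])
            d["covariate_distributions"] = CovariateDistributions(**cd)
        ms = d.get("missingness", {})
        if not isinstance(ms, Missingness):
            d["missingness"] = Missingness(**dict(ms))
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a config from YAML or JSON (YAML is a JSON superset)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def three_site_designs() -> list[StudyDesign]:
    """The three-study design registry: a two-arm naltrexone study and two
    three-arm studies (naltrexone and interim methadone) carrying a
    medication+patient-navigation arm. Combined analyzed N = 330."""
    return [
        StudyDesign("site1", {"MED": 58, "ETAU": 52}, "XR-NTX"),
        StudyDesign("site2", {"MED": 29, "MED_PN": 21, "ETAU": 19}, "XR-NTX"),
        StudyDesign("site3", {"MED": 46, "MED_PN": 54, "ETAU": 51}, "IM"),
    ]


#: baseline log-odds giving a 75% control-arm post-imputation outcome
#: prevalence under the default covariate effects and 15% MCAR missingness
#: (design-time bisection at n = 2e6)
DEFAULT_INTERCEPT = 0.55

#: generating treatment effects on the conditional log-odds scale
THETA_MED_DEFAULT = math.log(0.67)
THETA_PN_DEFAULT = math.log(0.61)


def default_config(seed: int = 0, theta_med: float = THETA_MED_DEFAULT,
                   theta_pn: float = THETA_PN_DEFAULT) -> SimulationConfig:
    """Study-condition defaults: three-site registry, common conditional
    treatment effects, printed covariate marginals, MCAR 15% missingness and
    no post-randomization exclusions (the design sizes are analyzed sizes)."""
    designs = three_site_designs()
    cfg = SimulationConfig(
        designs=designs,
        study_intercepts={d.study_id: DEFAULT_INTERCEPT for d in designs},
        theta_med={d.study_id: theta_med for d in designs},
        theta_pn={d.study_id: theta_pn for d in designs if d.has_pn_arm},
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_config(seed: int = 0) -> SimulationConfig:
    """Defaults with all treatment effects set to zero (type-I error runs)."""
    return default_config(seed=seed, theta_med=0.0, theta_pn=0.0)


def consort_flow_config(seed: int = 0) -> SimulationConfig:
    """Enrollment-scale variant emulating the participant flow: 488 enrolled,
    expected 48 prison transfers and 110 incarcerated at follow-up, leaving
    ~330 analyzed."""
    scale = 488 / 330
    designs = [
        StudyDesign(d.study_id,
                    {a: int(round(n * scale)) for a, n in d.arm_sizes.items()},
                    d.medication_type)
        for d in three_site_designs()
    ]
    cfg = default_config(seed=seed)
    cfg.designs = designs
    cfg.study_intercepts = {d.study_id: DEFAULT_INTERCEPT for d in designs}
    cfg.theta_med = {d.study_id: THETA_MED_DEFAULT for d in designs}
    cfg.theta_pn = {d.study_id: THETA_PN_DEFAULT for d in designs if d.has_pn_arm}
    cfg.exclusion_rates = {"prison_transfer": 48 / 488,
                           "incarcerated_at_followup": 110 / 488,
                           "deceased": 0.0}
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation


def _study_rng(seed: int, study_index: int, stream: int) -> np.random.Generator:
    # fixed per-study substreams: reproducible under study-count changes
    return np.random.default_rng([int(seed), int(study_index), int(stream)])


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a fully observed cohort: one row per randomized participant,
    outcomes from the configured logistic model, follow-up status unset.

    Deterministic given ``config.seed``.
    """
    config.validate()
    cd = config.covariate_distributions
    eff = {**{k: 0.0 for k in COVARIATE_EFFECT_KEYS}, **config.covariate_effects}
    frames = []
    for k, design in enumerate(config.designs):
        rng = _study_rng(config.seed, k, 0)
        n = design.n_total
        arms = np.concatenate([
            np.repeat(arm, size) for arm, size in sorted(design.arm_sizes.items())
        ])
        rng.shuffle(arms)  # randomized allocation order
        age = np.clip(rng.normal(cd.age_mean, cd.age_sd, n), *cd.age_bounds)
        female = rng.random(n) < cd.p_female
        race = rng.choice(np.array(["Black", "White", "Other"]), size=n,
                          p=cd.race_probs)
        hispanic = rng.random(n) < cd.p_hispanic
        unhoused = rng.random(n) < cd.p_unhoused
        stimulant = rng.random(n) < cd.p_stimulant_use

        treated = arms != "ETAU"
        pn = arms == "MED_PN"
        eta = (config.study_intercepts[design.study_id]
               + config.theta_med[design.study_id] * treated
               + config.theta_pn.get(design.study_id, 0.0) * pn
               + eff["age"] * (age - cd.age_mean)
               + eff["female"] * female
               + eff["race_White"] * (race == "White")
               + eff["race_Other"] * (race == "Other")
               + eff["hispanic"] * hispanic
               + eff["unhoused"] * unhoused
               + eff["stimulant_use"] * stimulant)
        y = rng.random(n) < expit(eta)

        frames.append(pd.DataFrame({
            "participant_id": [f"{design.study_id}-{i:04d}" for i in range(n)],
            "study_id": design.study_id,
            "arm": arms,
            "medication_type": np.where(treated, design.medication_type, "none"),
            "age": age,
            "sex": np.where(female, "female", "male"),
            "race": race,
            "hispanic": hispanic,
            "unhoused": unhoused,
            "stimulant_use": stimulant,
            "follow_up_status": pd.Series([None] * n, dtype=object),
            "outcome": np.where(y, "positive", "negative"),
            "outcome_imputed": False,
        }))
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


def apply_followup_process(df: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign follow-up statuses and apply outcome missingness.

    Statuses are drawn at the configured exclusion rates (independently of
    the outcome); among participants in the community, outcomes are set to
    missing per the configured mechanism. Deterministic given ``config.seed``.
    """
    config.validate()
    if df["follow_up_status"].notna().any():
        raise ValidationError("follow_up_status: already set; follow-up "
                              "process must run on a freshly generated cohort")
    if df["outcome"].isna().any() or (df["outcome"] == "missing").any():
        raise ValidationError("outcome: must be fully observed before the "
                              "follow-up process")
    rates = config.exclusion_rates
    p_pt = rates.get("prison_transfer", 0.0)
    p_inc = rates.get("incarcerated_at_followup", 0.0)
    p_dec = rates.get("deceased", 0.0)

    out = df.copy()
    study_order = {d.study_id: k for k, d in enumerate(config.designs)}
    ms = config.missingness
    for study, idx in out.groupby("study_id", sort=False).groups.items():
        k = study_order.get(str(study))
        if k is None:
            raise ValidationError(f"study_id: {study!r} not in config.designs")
        rng = _study_rng(config.seed, k, 1)
        n = len(idx)
        u = rng.random(n)
        status = np.full(n, "in_community", dtype=object)
        status[u < p_pt] = "prison_transfer"
        status[(u >= p_pt) & (u < p_pt + p_inc)] = "incarcerated_at_followup"
        status[(u >= p_pt + p_inc) & (u < p_pt + p_inc + p_dec)] = "deceased"
        out.loc[idx, "follow_up_status"] = status

        in_comm = status == "in_community"
        positive = (out.loc[idx, "outcome"] == "positive").to_numpy()
        if ms.mechanism == "MCAR":
            p_miss = np.full(n, ms.rate)
        else:
            if ms.rate in (0.0, 1.0):
                p_miss = np.full(n, ms.rate)
            else:
                p_miss = expit(logit(ms.rate) + ms.logit_shift * positive)
        miss = in_comm & (rng.random(n) < p_miss)
        sub = out.loc[idx, "outcome"].to_numpy(dtype=object)
        sub[miss] = "missing"
        out.loc[idx, "outcome"] = sub
    return out


def simulate_analytic_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, "object"]:
    """Convenience: generate, follow up, exclude and impute in one call.

    Returns the analysis-ready cohort and the exclusion report.
    """
    from .cohort import apply_exclusions, impute_missing_as_positive

    df = apply_followup_process(generate_cohort(config), config)
    kept, report = apply_exclusions(df)
    return impute_missing_as_positive(kept), report


# ---------------------------------------------------------------------------
# simulation-side estimand


@dataclass
class TrueParameters:
    """Design-implied per-study and pooled conditional treatment log-ORs."""

    theta_j_true: dict
    theta_p_true: float


def true_pooled_log_or(config: SimulationConfig, weights: dict | None = None,
                       parameter: str = "theta_med") -> TrueParameters:
    """Weighted average of the configured per-study conditional log-ORs.

    ``weights`` default to the per-study total sample size; for
    ``parameter='theta_pn'`` only studies with a PN arm contribute.
    """
    config.validate()
    if parameter == "theta_med":
        thetas = {d.study_id: config.theta_med[d.study_id] for d in config.designs}
        sizes = {d.study_id: d.n_total for d in config.designs}
    elif parameter == "theta_pn":
        thetas = {d.study_id: config.theta_pn[d.study_id]
                  for d in config.designs if d.has_pn_arm}
        sizes = {d.study_id: d.n_total for d in config.designs if d.has_pn_arm}
        if not thetas:
            raise ValidationError("theta_pn: no study with a PN arm")
    else:
        raise ValidationError(f"parameter: unknown value {parameter!r}")
    if weights is None:
        weights = sizes
    w = np.array([weights[s] for s in thetas])
    if np.any(w <= 0):
        bad = [s for s in thetas if weights[s] <= 0]
        raise ValidationError(f"weights: nonpositive weight for study {bad[0]!r}")
    th = np.array(list(thetas.values()))
    return TrueParameters(theta_j_true=dict(thetas),
                          theta_p_true=float(np.sum(w * th) / np.sum(w)))
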