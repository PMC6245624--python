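"""Synthetic ART-cohort generator with known ground truth.

Emulates a cohort of ~910 adults starting antiretroviral therapy and followed
for ten years: baseline covariates (sex, age, severe poverty, urban residence,
weight, CD4 count, advanced WHO stage, baseline TB), a logistic model for
death by ten years on the clinically scaled covariates, a loss-to-follow-up
(LTF) mechanism that is missing-at-random given covariates by default (with an
explicit MNAR switch), documented transfers sampled among the truly alive, and
an outcome-tracing step whose success probability may depend on how recently a
patient was lost.

Every draw is a pure function of ``(config, config.seed)``, so downstream
estimators can be tested against the generating truth without any external
data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import AlignmentError, ConfigError
from .tracing import TracingResult

STATUS_ALIVE = "alive_in_care"
STATUS_DEAD = "dead_documented"
STATUS_TRANSFER = "transferred"
STATUS_LTF = "ltf"
STATUSES = (STATUS_ALIVE, STATUS_DEAD, STATUS_TRANSFER, STATUS_LTF)

#: covariates entering the outcome and LTF models, on the reporting scale
#: (age per 10 years, weight per 10 kg, CD4 per 100 cells/uL).
MODEL_COVARIATES = (
    "female",
    "age_years",
    "severe_poverty",
    "residence_pap",
    "weight_kg",
    "cd4",
    "who_stage_advanced",
    "tb_baseline",
)


@dataclass
class CovariateParams:
    """Marginal distributions of the baseline covariates.

    Continuous covariates use simple parametric families whose medians and
    spreads match the cohort being emulated: weight is normal by sex
    (men median 56 kg, IQR 50-63; women 49 kg, IQR 44-56) and CD4 lognormal
    with median 131 cells/uL and IQR 51-212, truncated to [0, 1500].
    """

    p_female: float = 0.58
    age_mean: float = 36.0
    age_sd: float = 10.0
    age_min: float = 13.0
    p_severe_poverty: float = 0.50
    p_residence_pap: float = 0.62
    weight_mean_male: float = 56.0
    weight_mean_female: float = 49.0
    weight_sd_male: float = 9.6
    weight_sd_female: float = 8.9
    weight_min: float = 25.0
    cd4_median: float = 131.0
    cd4_log_sigma: float = 1.06
    cd4_max: float = 1500.0
    p_who_advanced: float = 0.55
    p_tb_baseline: float = 0.16


@dataclass
class OutcomeModel:
    """Log-odds model for death by 10 years on scaled covariates.

    ``intercept=None`` calibrates the intercept at generation time so the
    model-implied marginal death probability over the simulated covariates
    equals ``marginal_death``.
    """

    coefficients: dict = field(
        default_factory=lambda: {
            "female": math.log(0.62),
            "age_years": math.log(1.37),       # per 10 years
            "severe_poverty": math.log(1.80),
            "residence_pap": math.log(1.18),
            "weight_kg": math.log(0.66),       # per 10 kg
            "cd4": math.log(0.91),             # per 100 cells
            "who_stage_advanced": math.log(1.76),
            "tb_baseline": math.log(1.61),
        }
    )
    intercept: float | None = None
    marginal_death: float = 0.29


@dataclass
class LtfModel:
    """Log-odds model for becoming lost to follow-up.

    ``outcome_coef`` is the MNAR switch: its default of zero makes loss
    missing-at-random given covariates, the working assumption of the
    imputation methods; positive values make the truly dead likelier to be
    lost.
    """

    coefficients: dict = field(
        default_factory=lambda: {
            "severe_poverty": 0.25,
            "cd4": -0.15,                    # per 100 cells
            "age_years": -0.10,              # per 10 years
            "who_stage_advanced": 0.15,
        }
    )
    intercept: float | None = None
    marginal_ltf: float = 0.12
    outcome_coef: float = 0.0


@dataclass
class TracingParams:
    """Tracing success: base probability plus a recency effect.

    ``recency_coef`` shifts the success log-odds per year of last-visit time
    centred at mid-follow-up, so recently lost patients are easier to find
    when it is positive; zero keeps success uniform at ``success_prob``.
    """

    success_prob: float = 0.29
    recency_coef: float = 0.0


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort draw."""

    n_patients: int = 910
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    ltf_model: LtfModel = field(default_factory=LtfModel)
    transfer_prob: float = 0.13
    cov_missing_rates: dict = field(
        default_factory=lambda: {"weight_kg": 0.03, "cd4": 0.12}
    )
    tracing_params: TracingParams = field(default_factory=TracingParams)
    follow_up_years: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be at least 1")
        probs = {
            "transfer_prob": self.transfer_prob,
            "tracing success_prob": self.tracing_params.success_prob,
            "marginal_ltf": self.ltf_model.marginal_ltf,
            "marginal_death": self.outcome_model.marginal_death,
            **{f"missing rate {k}": v for k, v in self.cov_missing_rates.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} = {p} is not a probability")

    def config_hash(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (
            ("covariate_params", CovariateParams),
            ("outcome_model", OutcomeModel),
            ("ltf_model", LtfModel),
            ("tracing_params", TracingParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def _scaled_design(cohort: pd.DataFrame) -> pd.DataFrame:
    X = cohort[list(MODEL_COVARIATES)].astype(float).copy()
    X["age_years"] /= 10.0
    X["weight_kg"] /= 10.0
    X["cd4"] /= 100.0
    return X


def _calibrated_intercept(linpred: np.ndarray, target: float) -> float:
    """Solve mean(expit(a + linpred)) = target for the intercept a."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    fun = lambda a: expit(a + linpred).mean() - target
    return brentq(fun, -40.0, 40.0)


def linear_predictor(cohort: pd.DataFrame, coefficients: dict) -> np.ndarray:
    """Linear predictor of a coefficient dict over the scaled design."""
    X = _scaled_design(cohort)
    lp = np.zeros(len(cohort))
    for name, beta in coefficients.items():
        if name not in X.columns:
            raise ConfigError(f"unknown model covariate '{name}'")
        lp += beta * X[name].to_numpy()
    return lp


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a ground-truth cohort table.

    Returns one row per patient with baseline covariates, the true 10-year
    vital status ``true_dead10``, a death time in (0, 10] for the dead (drawn
    with decreasing hazard, mortality being front-loaded after ART start) and
    ``last_visit_years`` (the death time for the dead, end of follow-up
    otherwise).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cp = config.covariate_params
    fu = config.follow_up_years

    female = (rng.random(n) < cp.p_female).astype(int)
    age = np.maximum(rng.normal(cp.age_mean, cp.age_sd, n), cp.age_min)
    poverty = (rng.random(n) < cp.p_severe_poverty).astype(int)
    residence = (rng.random(n) < cp.p_residence_pap).astype(int)
    w_mean = np.where(female == 1, cp.weight_mean_female, cp.weight_mean_male)
    w_sd = np.where(female == 1, cp.weight_sd_female, cp.weight_sd_male)
    weight = np.maximum(rng.normal(w_mean, w_sd), cp.weight_min)
    cd4 = np.minimum(
        np.exp(rng.normal(np.log(cp.cd4_median), cp.cd4_log_sigma, n)), cp.cd4_max
    )
    who = (rng.random(n) < cp.p_who_advanced).astype(int)
    tb = (rng.random(n) < cp.p_tb_baseline).astype(int)

    cohort = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "female": female,
            "age_years": age,
            "severe_poverty": poverty,
            "residence_pap": residence,
            "weight_kg": weight,
            "cd4": cd4,
            "who_stage_advanced": who,
            "tb_baseline": tb,
        }
    )

    lp = linear_predictor(cohort, config.outcome_model.coefficients)
    a = config.outcome_model.intercept
    if a is None:
        a = _calibrated_intercept(lp, config.outcome_model.marginal_death)
    p_death = expit(a + lp) if np.isfinite(a) else np.full(n, float(a > 0))
    dead = (rng.random(n) < p_death).astype(int)

    # death times with decreasing density over follow-up (u^k, k>1)
    u = rng.random(n)
    death_time = np.where(dead == 1, fu * u**1.6, np.nan)
    death_time = np.where(dead == 1, np.maximum(death_time, 1e-3), np.nan)
    last_visit = np.where(dead == 1, death_time, fu)

    cohort["true_dead10"] = dead
    cohort["death_time_years"] = death_time
    cohort["last_visit_years"] = last_visit
    return cohort


def apply_missingness(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Produce the analyst's view of the cohort.

    Assigns the observed status (alive-in-care / documented dead /
    transferred / LTF), masks baseline weight and CD4 at the configured
    rates, and sets ``dead10`` to NaN for the lost (their vital status is the
    missing outcome).  Transfers, sampled only among the truly alive, are
    treated as alive at 10 years.  LTF last-visit times are uniform over
    follow-up (truncated at the death time for the covertly dead).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(cohort)
    fu = config.follow_up_years

    lp = linear_predictor(cohort, config.ltf_model.coefficients)
    lp = lp + config.ltf_model.outcome_coef * cohort["true_dead10"].to_numpy()
    a = config.ltf_model.intercept
    if a is None:
        a = _calibrated_intercept(lp, config.ltf_model.marginal_ltf)
    p_ltf = expit(a + lp) if np.isfinite(a) else np.full(n, float(a > 0))
    is_ltf = rng.random(n) < p_ltf

    dead = cohort["true_dead10"].to_numpy().astype(bool)
    transfer = (~dead) & (~is_ltf) & (rng.random(n) < config.transfer_prob)

    status = np.where(
        is_ltf,
        STATUS_LTF,
        np.where(dead, STATUS_DEAD, np.where(transfer, STATUS_TRANSFER, STATUS_ALIVE)),
    )

    last_visit = cohort["last_visit_years"].to_numpy().copy()
    u = rng.random(n)
    ltf_last = np.where(
        dead,
        u * np.minimum(cohort["death_time_years"].to_numpy(), fu),
        u * fu,
    )
    last_visit = np.where(is_ltf, ltf_last, last_visit)

    observed = cohort[
        ["patient_id", *MODEL_COVARIATES]
    ].copy()
    for col, rate in config.cov_missing_rates.items():
        if col not in observed.columns:
            raise ConfigError(f"missingness configured for unknown column '{col}'")
        mask = rng.random(n) < rate
        observed.loc[mask, col] = np.nan
    observed["status"] = status
    observed["last_visit_years"] = last_visit
    observed["dead10"] = np.where(
        status == STATUS_LTF, np.nan, (status == STATUS_DEAD).astype(float)
    )
    return observed


def simulate_tracing(
    observed: pd.DataFrame, truth: pd.DataFrame, config: GeneratorConfig
) -> TracingResult:
    """Attempt to trace every LTF patient and report who was found.

    Found patients report their true vital status.  Success probability is
    ``expit(logit(success_prob) + recency_coef * (last_visit - FU/2))`` so a
    positive recency coefficient favours the recently lost.
    """
    if not observed["patient_id"].equals(truth["patient_id"]):
        raise AlignmentError("observed and truth tables are not aligned by patient_id")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tp = config.tracing_params

    ltf = observed["status"] == STATUS_LTF
    ids = observed.loc[ltf, "patient_id"].to_numpy()
    lv = observed.loc[ltf, "last_visit_years"].to_numpy()
    n_ltf = len(ids)

    if tp.success_prob <= 0.0:
        p = np.zeros(n_ltf)
    elif tp.success_prob >= 1.0:
        p = np.ones(n_ltf)
    else:
        p = expit(logit(tp.success_prob) + tp.recency_coef * (lv - config.follow_up_years / 2))
    found = rng.random(n_ltf) < p
    true_dead = truth.set_index("patient_id").loc[ids, "true_dead10"].to_numpy()
    dead_if_found = np.where(found, true_dead.astype(float), np.nan)

    records = pd.DataFrame(
        {"patient_id": ids, "found": found.astype(int), "dead_if_found": dead_if_found}
    )
    return TracingResult(
        n_ltf=n_ltf,
        n_attempted=n_ltf,
        n_found=int(found.sum()),
        n_found_dead=int(np.nansum(dead_if_found)),
        records=records,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a cohort table as delimited text (missing cells empty)."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> GeneratorConfig:
    """Read a generator configuration from a JSON/YAML key-value file."""
    import yaml

    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))
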