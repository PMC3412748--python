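"""Synthetic subject-level cohorts with the statistical structure the
risk analysis assumes.

Predictors are drawn multivariate normal with configurable moments (defaults
are the published pre-trauma sample means/SDs); the binary high-PTSS labels
follow a logistic model on a small set of generating predictors whose
per-unit odds ratios default to the fitted-model values (subjective outcome:
estimated IQ 0.95, extinction-phase differential corrugator EMG 1.17,
depression score 1.15; physiologic outcome: estimated IQ 0.94, mean SC
response to loud tones 4.02), with the intercept solved numerically for a
target high-group prevalence of 1/3 (the upper-tertile split).  Continuous
outcome scores are drawn as a right-skewed two-component mixture consistent
with the labels; missingness is applied MCAR to predictors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import InvalidInputError, ValidationError

#: Published pre-trauma predictor moments (mean, SD), lower-snake-case names.
TABLE1_MOMENTS: Dict[str, Tuple[float, float]] = {
    # demographics
    "age": (27.0, 6.5),
    "education": (14.1, 1.8),
    # psychometrics
    "scl_gsi": (0.3, 0.4),
    "bdi": (2.5, 3.2),
    "est_iq": (101.8, 10.0),
    "stai_t": (31.2, 8.2),
    "neo_n": (46.7, 8.0),
    "neo_e": (54.7, 8.2),
    "neo_o": (48.0, 11.3),
    "neo_a": (48.0, 9.4),
    # loud-tone block
    "hr_pre_tone_level": (71.6, 11.6),
    "hr_mean_response": (0.6, 0.9),
    "hr_slope": (0.1, 1.0),
    "sc_pre_tone_level": (7.2, 5.6),
    "sc_mean_response": (0.6, 0.3),
    "sc_slope": (-0.4, 0.2),
    "sc_trials_to_criterion": (9.7, 4.2),
    "emg_mean_response": (2.3, 1.7),
    # conditioning block
    "sc_orienting": (0.6, 0.7),
    "sc_diff_acq": (0.2, 0.5),
    "emg_diff_acq": (0.2, 2.9),
    "hr_diff_acq": (1.0, 5.7),
    "sc_diff_ext": (-0.1, 0.5),
    "emg_diff_ext": (-0.7, 4.4),
    "sc_csplus_acq": (0.6, 0.6),
    "emg_csplus_acq": (2.5, 3.0),
    "hr_csplus_acq": (5.8, 4.8),
    "sc_csplus_ext": (0.2, 0.4),
    "emg_csplus_ext": (3.1, 4.2),
}

#: Binary demographics generated as Bernoulli indicators (proportion of 1s).
BINARY_PREDICTORS: Dict[str, float] = {
    "gender_male": 0.918,
    "race_white": 0.822,
}

#: Fitted-model per-unit odds ratios for the two outcomes.
IESR_ODDS_RATIOS: Dict[str, float] = {"est_iq": 0.95, "emg_diff_ext": 1.17, "bdi": 1.15}
PP_ODDS_RATIOS: Dict[str, float] = {"est_iq": 0.94, "sc_mean_response": 4.02}

#: Covariate generators: time since trauma (months) and clinician-rated
#: trauma severity (0-12 scale), moments from the study cohort.
TIME_SINCE_TRAUMA_MOMENTS = (12.3, 11.5)
SEVERITY_MOMENTS = (7.79, 1.41)

PREDICTOR_NAMES = list(TABLE1_MOMENTS) + list(BINARY_PREDICTORS)
OUTCOME_NAMES = ("ies_r_total", "posterior_probability")
COVARIATE_NAMES = ("time_since_trauma", "severity_rating")


@dataclass
class CohortConfig:
    n: int = 99
    moments: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_MOMENTS)
    )
    binary_predictors: Dict[str, float] = field(
        default_factory=lambda: dict(BINARY_PREDICTORS)
    )
    correlation: Optional[np.ndarray] = None  # over `moments` order; default identity
    iesr_odds_ratios: Dict[str, float] = field(
        default_factory=lambda: dict(IESR_ODDS_RATIOS)
    )
    pp_odds_ratios: Dict[str, float] = field(default_factory=lambda: dict(PP_ODDS_RATIOS))
    prevalence: float = 1 / 3
    missing_rate: Union[float, Dict[str, float]] = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 0:
            raise InvalidInputError("cohort size must be non-negative")
        if not 0 < self.prevalence < 1:
            raise InvalidInputError("target prevalence must lie in (0, 1)")
        for name, (_, sd) in self.moments.items():
            if sd <= 0:
                raise InvalidInputError(f"SD for {name!r} must be positive")
        if self.correlation is not None:
            c = np.asarray(self.correlation, float)
            k = len(self.moments)
            if c.shape != (k, k):
                raise ValidationError("correlation matrix shape mismatch")
            np.linalg.cholesky(c)  # must be SPD

    def rate_for(self, name: str) -> float:
        if isinstance(self.missing_rate, dict):
            return float(self.missing_rate.get(name, 0.0))
        return float(self.missing_rate)


def solve_intercept(
    betas: np.ndarray, means: np.ndarray, sds: np.ndarray, prevalence: float,
    cov: Optional[np.ndarray] = None,
) -> float:
    """Intercept alpha with E[expit(alpha + beta.X)] = prevalence for normal X.

    The linear predictor beta.X is normal, so the expectation reduces to a
    1-D Gauss-Hermite quadrature; alpha is found by bisection.
    """
    m = float(betas @ means)
    if cov is None:
        v = float(np.sum((betas * sds) ** 2))
    else:
        d = betas * sds
        v = float(d @ cov @ d)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    wsum = weights.sum()

    def mean_prob(alpha):
        return float(np.sum(weights * expit(alpha + m + np.sqrt(max(v, 0.0)) * nodes)) / wsum)

    lo, hi = -60.0, 60.0
    if not mean_prob(lo) < prevalence < mean_prob(hi):
        raise InvalidInputError("target prevalence unreachable for this model")
    return brentq(lambda a: mean_prob(a) - prevalence, lo, hi, xtol=1e-10)


def _skewed_outcome(rng, labels, kind):
    """Right-skewed continuous outcome consistent with the high/low labels.

    Low and high components are separated at a fixed symptom cut so that an
    empirical upper-tertile split approximately recovers the labels.
    """
    n = len(labels)
    out = np.empty(n)
    lo = labels == 0
    hi = ~lo
    if kind == "ies_r_total":
        out[lo] = np.minimum(rng.gamma(1.4, 2.2, size=lo.sum()), 9.5)
        out[hi] = np.minimum(10.0 + rng.gamma(1.6, 7.0, size=hi.sum()), 88.0)
    elif kind == "posterior_probability":
        out[lo] = 0.15 + 0.25 * rng.beta(1.6, 3.5, size=lo.sum())
        out[hi] = np.minimum(0.402 + 0.5 * rng.beta(1.3, 4.0, size=hi.sum()), 0.95)
    else:
        raise InvalidInputError(f"unknown outcome kind {kind!r}")
    return out


def generate_cohort(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus a ground-truth record.

    Returns ``(table, truth)``: the table holds predictors (with MCAR
    missingness), covariates and continuous outcomes; ``truth`` holds the
    generating coefficients, intercepts and the binary high-PTSS labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(config.moments)
    means = np.array([config.moments[k][0] for k in names])
    sds = np.array([config.moments[k][1] for k in names])
    n = config.n

    if config.correlation is None:
        X = means + rng.standard_normal((n, len(names))) * sds
        cov = None
    else:
        cov = np.asarray(config.correlation, float)
        L = np.linalg.cholesky(cov)
        X = means + (rng.standard_normal((n, len(names))) @ L.T) * sds
    table = pd.DataFrame(X, columns=names)
    for bname, prop in config.binary_predictors.items():
        table[bname] = (rng.random(n) < prop).astype(float)

    truth = {"config_n": n, "prevalence": config.prevalence, "models": {}}
    labels = {}
    for outcome, ors in (
        ("ies_r_total", config.iesr_odds_ratios),
        ("posterior_probability", config.pp_odds_ratios),
    ):
        pred = list(ors)
        missing = [p for p in pred if p not in table.columns]
        if missing:
            raise ValidationError(f"outcome model predictors absent from moments: {missing}")
        betas = np.log(np.array([ors[p] for p in pred]))
        mu = np.array([config.moments[p][0] for p in pred])
        sd = np.array([config.moments[p][1] for p in pred])
        sub_cov = None
        if cov is not None:
            idx = [names.index(p) for p in pred]
            sub_cov = cov[np.ix_(idx, idx)]
        alpha = solve_intercept(betas, mu, sd, config.prevalence, sub_cov)
        lp = alpha + table[pred].to_numpy() @ betas
        lab = (rng.random(n) < expit(lp)).astype(int)
        labels[outcome] = lab
        truth["models"][outcome] = {
            "predictors": pred,
            "odds_ratios": {p: float(ors[p]) for p in pred},
            "log_odds_ratios": {p: float(b) for p, b in zip(pred, betas)},
            "intercept": float(alpha),
            "labels": lab.tolist(),
        }
        table[outcome] = _skewed_outcome(rng, lab, outcome)

    tmu, tsd = TIME_SINCE_TRAUMA_MOMENTS
    shape = (tmu / tsd) ** 2
    table["time_since_trauma"] = rng.gamma(shape, tmu / shape, size=n) if n else np.array([])
    smu, ssd = SEVERITY_MOMENTS
    table["severity_rating"] = np.clip(smu + ssd * rng.standard_normal(n), 0.0, 12.0)

    # MCAR missingness on predictors only (outcomes and covariates intact).
    for name in list(names) + list(config.binary_predictors):
        rate = config.rate_for(name)
        if rate > 0 and n:
            mask = rng.random(n) < rate
            table.loc[mask, name] = np.nan

    table.insert(0, "subject_id", [f"S{i+1:04d}" for i in range(n)])
    truth["high_iesr"] = labels.get("ies_r_total", np.array([], int)).tolist()
    truth["high_pp"] = labels.get("posterior_probability", np.array([], int)).tolist()
    return table, truth
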