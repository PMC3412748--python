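"""Repeated-cohort simulation experiments over the fitted outcome models.

These drive the package's consistency checks: cohorts are generated under
the published predictor moments and fitted-model odds ratios, refitted, and
summarized (in-sample c-statistic at the study's sample size; recovered
odds ratios at large n; stepwise selection and Wald-CI coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .analysis import fit_logistic, screen_predictors, stepwise_logistic
from .cohort import CohortConfig, PREDICTOR_NAMES, generate_cohort
from .exceptions import NumericalError, PtssRiskError

_OUTCOME_KEY = {"ies_r_total": "high_iesr", "posterior_probability": "high_pp"}


def _labelled_cohort(outcome: str, n: int, rng: np.random.Generator):
    import pandas as pd

    table, truth = generate_cohort(CohortConfig(n=n, missing_rate=0.0), rng)
    labels = pd.Series(np.array(truth[_OUTCOME_KEY[outcome]], dtype=float))
    model = truth["models"][outcome]
    return table, labels, model


def mean_insample_c_statistic(
    outcome: str, n: int, reps: int, rng: np.random.Generator
) -> Dict[str, float]:
    """Mean in-sample c-statistic of the outcome's generating-predictor model
    refit per simulated cohort of size ``n``."""
    cs: List[float] = []
    skipped = 0
    while len(cs) < reps:
        table, labels, model = _labelled_cohort(outcome, n, rng)
        if labels.sum() < 3 or (1 - labels).sum() < 3:
            skipped += 1
            continue
        try:
            fit = fit_logistic(table, labels, model["predictors"], outcome)
        except PtssRiskError:
            skipped += 1
            continue
        cs.append(fit.c_statistic)
    return {"value": float(np.mean(cs)), "n": n, "reps": reps, "skipped": skipped}


def mean_recovered_odds_ratio(
    outcome: str, predictor: str, n: int, reps: int, rng: np.random.Generator
) -> Dict[str, float]:
    """Mean maximum-likelihood odds ratio for one generating predictor across
    large simulated cohorts."""
    ors: List[float] = []
    while len(ors) < reps:
        table, labels, model = _labelled_cohort(outcome, n, rng)
        try:
            fit = fit_logistic(table, labels, model["predictors"], outcome)
        except PtssRiskError:
            continue
        ors.append(next(t.odds_ratio for t in fit.terms if t.name == predictor))
    return {"value": float(np.mean(ors)), "n": n, "reps": reps}


@dataclass
class RecoveryResult:
    reps: int
    n: int
    all_selected_rate: float
    coverage: float  # pooled over generating coefficients
    n_cis: int


def stepwise_recovery(
    outcome: str,
    n: int,
    reps: int,
    rng: np.random.Generator,
    alpha_screen: float = 0.20,
    p_enter: float = 0.15,
    p_remove: float = 0.15,
) -> RecoveryResult:
    """Run the full screening + stepwise pipeline on simulated cohorts.

    Reports how often all generating predictors are selected and the pooled
    95% Wald-CI coverage of the generating log odds ratios (evaluated in the
    final model whenever the predictor is selected).
    """
    all_sel = 0
    covered = 0
    n_cis = 0
    done = 0
    while done < reps:
        table, labels, model = _labelled_cohort(outcome, n, rng)
        candidates = [c for c in PREDICTOR_NAMES if c in table.columns]
        screened, _ = screen_predictors(table, labels, candidates, alpha_screen)
        try:
            fit = stepwise_logistic(table, labels, screened, p_enter, p_remove, outcome)
        except NumericalError:
            continue
        done += 1
        gen = model["log_odds_ratios"]
        if set(gen).issubset(fit.selected):
            all_sel += 1
        for term in fit.terms:
            if term.name in gen:
                se = abs(term.coefficient) / np.sqrt(term.wald_chi_square)
                lo = term.coefficient - 1.959963984540054 * se
                hi = term.coefficient + 1.959963984540054 * se
                n_cis += 1
                covered += int(lo <= gen[term.name] <= hi)
    return RecoveryResult(
        reps=done,
        n=n,
        all_selected_rate=all_sel / done,
        coverage=covered / n_cis,
        n_cis=n_cis,
    )
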