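"""Cohort-level risk analysis.

The outcome (IES-R total, or the imagery posterior probability) is
dichotomized at its empirical upper tertile into high vs low symptom groups;
candidate predictors are screened univariately with Welch's unequal-variance
t-test at a liberal alpha (0.20, uncorrected by design); missing predictor
values are singly imputed at the conditional means of a multivariate-normal
EM fit; a forward-stepwise logistic regression with backward Wald checks
selects the predictor set; model discrimination is summarized by the
c-statistic (ROC area).  Covariate-adjusted refits force time-since-trauma
and trauma-severity into the selected model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateFitError,
    InvalidInputError,
    SeparationError,
    ValidationError,
)

DICHOTOMIZATION_SCHEMES = ("T_upper_vs_rest", "Q4_vs_Q1", "T3_vs_T1")


def dichotomize(scores, scheme: str = "T_upper_vs_rest") -> pd.Series:
    """Split outcome scores into high (1.0) vs low (0.0) groups.

    ``T_upper_vs_rest`` labels the upper tertile high and the lower two
    tertiles low; the contrast-only schemes ``Q4_vs_Q1`` and ``T3_vs_T1``
    mark middle observations NaN (excluded).  Cut points are empirical
    quantiles; ties at a boundary go to the lower group.  Missing scores
    yield NaN labels.
    """
    s = pd.Series(scores, dtype=float)
    finite = s.dropna()
    if len(finite) < 3:
        raise InvalidInputError("dichotomization needs >= 3 finite scores")
    if np.ptp(finite.to_numpy()) == 0:
        raise DegenerateFitError("all outcome scores identical; cannot dichotomize")
    if scheme == "T_upper_vs_rest":
        cut = float(np.quantile(finite, 2 / 3))
        out = (s > cut).astype(float)
    elif scheme in ("Q4_vs_Q1", "T3_vs_T1"):
        q = 0.25 if scheme == "Q4_vs_Q1" else 1 / 3
        lo_cut = float(np.quantile(finite, q))
        hi_cut = float(np.quantile(finite, 1 - q))
        out = pd.Series(np.nan, index=s.index)
        out[s <= lo_cut] = 0.0
        out[s > hi_cut] = 1.0
    else:
        raise InvalidInputError(f"unknown dichotomization scheme {scheme!r}")
    out[s.isna()] = np.nan
    return out


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("Welch test needs >= 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # Identical degenerate groups: no evidence of a difference.
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise DegenerateFitError("both groups have zero variance but differ in mean")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def screen_predictors(
    table: pd.DataFrame,
    outcome_labels: pd.Series,
    candidates: Sequence[str],
    alpha: float = 0.20,
) -> Tuple[List[str], pd.DataFrame]:
    """Univariate Welch screening of predictors against high/low groups.

    Returns the predictors whose two-sided Welch p is below ``alpha``
    (no multiple-testing correction, by design) together with the full
    screening table.
    """
    labels = pd.Series(outcome_labels).reindex(table.index)
    rows = []
    for name in candidates:
        col = table[name]
        a = col[labels == 1.0].dropna()
        b = col[labels == 0.0].dropna()
        try:
            res = welch_t(a, b)
            rows.append((name, res.t, res.df, res.p))
        except (InvalidInputError, DegenerateFitError):
            rows.append((name, np.nan, np.nan, np.nan))
    screen = pd.DataFrame(rows, columns=["predictor", "t", "df", "p"])
    selected = [r.predictor for r in screen.itertuples() if np.isfinite(r.p) and r.p < alpha]
    return selected, screen


# ---------------------------------------------------------------------------
# EM imputation (multivariate normal, single imputation at conditional means)
# ---------------------------------------------------------------------------


def _obs_loglik(X, mu, sigma, patterns):
    ll = 0.0
    for obs_idx, rows in patterns:
        sub = X[np.ix_(rows, obs_idx)]
        ll += np.sum(
            stats.multivariate_normal.logpdf(
                sub, mean=mu[obs_idx], cov=sigma[np.ix_(obs_idx, obs_idx)],
                allow_singular=True,
            )
        )
    return ll


def em_impute(
    table: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: Optional[float] = None,
) -> pd.DataFrame:
    """Single imputation at conditional means of a multivariate-normal EM fit.

    Observed values are untouched.  Convergence is declared when the
    observed-data log-likelihood changes by less than ``tol``; on
    non-convergence the best iterate is returned with a warning.  When the
    sample is small relative to the number of predictors (or the covariance
    is near singular) a small ridge is added to keep it invertible.
    """
    df = table.astype(float)
    X = df.to_numpy(copy=True)
    n, p = X.shape
    miss = ~np.isfinite(X)
    if n == 0 or not miss.any():
        return df.copy()
    if miss.all(axis=0).any():
        bad = df.columns[miss.all(axis=0)].tolist()
        raise ValidationError(f"columns entirely missing, cannot impute: {bad}")

    # Group rows by missingness pattern once.
    pat_map: Dict[bytes, List[int]] = {}
    for i in range(n):
        pat_map.setdefault(miss[i].tobytes(), []).append(i)
    patterns = []
    for key, rows in pat_map.items():
        m = np.frombuffer(key, dtype=bool)
        obs_idx = np.where(~m)[0]
        mis_idx = np.where(m)[0]
        patterns.append((obs_idx, mis_idx, np.array(rows)))
    obs_patterns = [(o, r) for o, _m, r in patterns if len(o)]

    col_means = np.nanmean(X, axis=0)
    Xw = np.where(miss, col_means, X)
    mu = Xw.mean(axis=0)
    sigma = np.cov(Xw, rowvar=False, ddof=0) + 1e-8 * np.eye(p)
    if ridge is None:
        ridge = 1e-6 * float(np.mean(np.diag(sigma))) if n <= p + 1 else 0.0

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        Ex = np.where(miss, 0.0, X)
        Exx = np.zeros((p, p))
        for obs_idx, mis_idx, rows in patterns:
            if len(mis_idx) == 0:
                continue
            if len(obs_idx) == 0:
                cond_mean = np.broadcast_to(mu[mis_idx], (len(rows), len(mis_idx)))
                cond_cov = sigma[np.ix_(mis_idx, mis_idx)]
            else:
                Soo = sigma[np.ix_(obs_idx, obs_idx)] + ridge * np.eye(len(obs_idx))
                Smo = sigma[np.ix_(mis_idx, obs_idx)]
                beta = np.linalg.solve(Soo, Smo.T).T  # (mis, obs)
                resid = X[np.ix_(rows, obs_idx)] - mu[obs_idx]
                cond_mean = mu[mis_idx] + resid @ beta.T
                cond_cov = sigma[np.ix_(mis_idx, mis_idx)] - beta @ Smo.T
            Ex[np.ix_(rows, mis_idx)] = cond_mean
            Exx[np.ix_(mis_idx, mis_idx)] += len(rows) * cond_cov
        mu = Ex.mean(axis=0)
        centered = Ex - mu
        sigma = (centered.T @ centered + Exx) / n
        sigma = 0.5 * (sigma + sigma.T)
        ll = _obs_loglik(X, mu, sigma + ridge * np.eye(p), obs_patterns)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations "
            f"(last log-likelihood change {abs(ll - ll_old):.3g}); "
            "returning best iterate",
            RuntimeWarning,
        )

    # Final imputation at the converged conditional means.
    out = X.copy()
    for obs_idx, mis_idx, rows in patterns:
        if len(mis_idx) == 0:
            continue
        if len(obs_idx) == 0:
            out[np.ix_(rows, mis_idx)] = mu[mis_idx]
            continue
        Soo = sigma[np.ix_(obs_idx, obs_idx)] + ridge * np.eye(len(obs_idx))
        Smo = sigma[np.ix_(mis_idx, obs_idx)]
        beta = np.linalg.solve(Soo, Smo.T).T
        resid = X[np.ix_(rows, obs_idx)] - mu[obs_idx]
        out[np.ix_(rows, mis_idx)] = mu[mis_idx] + resid @ beta.T
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermResult:
    name: str
    coefficient: float
    odds_ratio: float
    wald_chi_square: float
    df: int
    p: float
    forced: bool = False


@dataclass
class ModelFit:
    """One fitted logistic model: selected terms, Wald tests, c-statistic."""

    outcome: str
    n: int
    terms: List[TermResult]
    intercept: float
    c_statistic: float
    p_enter: float
    p_remove: float
    log_likelihood: float
    covariates: List[str] = field(default_factory=list)

    @property
    def selected(self) -> List[str]:
        return [t.name for t in self.terms if not t.forced]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "intercept": self.intercept,
            "terms": [asdict(t) for t in self.terms],
            "c_statistic": self.c_statistic,
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "log_likelihood": self.log_likelihood,
            "covariates": self.covariates,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def report_rows(self) -> List[tuple]:
        """Rows shaped like the published model table."""
        rows = []
        for i, t in enumerate(self.terms):
            rows.append(
                (
                    self.outcome if i == 0 else "",
                    self.n if i == 0 else "",
                    t.name + (" (forced)" if t.forced else ""),
                    f"{t.odds_ratio:.2f}",
                    f"{t.wald_chi_square:.2f}",
                    t.df,
                    f"{t.p:.3f}",
                )
            )
        if not self.terms:
            rows.append((self.outcome, self.n, "(none selected)", "", "", "", ""))
        return rows


def c_statistic(fitted_probabilities, labels) -> float:
    """ROC area: P(score_high > score_low) with ties counted 1/2."""
    p = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y[np.isfinite(y)])) < 2:
        raise InvalidInputError("c-statistic needs both outcome classes present")
    if np.ptp(p) == 0:
        return 0.5  # constant scores carry no discrimination
    return float(roc_auc_score(y, p))


def _fit_logit(y: np.ndarray, X: np.ndarray, names: Sequence[str]):
    """Maximum-likelihood logistic fit with separation/convergence checks."""
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"design matrix rank deficient for terms {list(names)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparation* variously
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                raise SeparationError(
                    f"separation or singularity fitting terms {list(names)}"
                ) from exc
            raise ConvergenceError(str(exc)) from exc
    big = [nm for nm, b in zip(names, fit.params[1:]) if abs(b) > 50]
    if not fit.mle_retvals.get("converged", True) or big:
        probs = np.asarray(fit.predict())
        hi = probs[y == 1].min(initial=1.0)
        lo = probs[y == 0].max(initial=0.0)
        if big or (hi > 0.999 and lo < 0.001):
            raise SeparationError(
                f"complete or quasi-complete separation fitting terms {list(names)}"
                + (f" (offending: {big})" if big else "")
            )
        raise ConvergenceError(f"logistic fit did not converge for terms {list(names)}")
    return fit


def fit_logistic(
    table: pd.DataFrame, outcome_labels: pd.Series, predictors: Sequence[str],
    outcome_name: str = "outcome",
) -> ModelFit:
    """Plain maximum-likelihood logistic fit of a fixed predictor set."""
    labels = pd.Series(outcome_labels).reindex(table.index)
    keep = labels.notna()
    for c in predictors:
        keep &= table[c].notna()
    y = labels[keep].to_numpy(dtype=float)
    X = table.loc[keep, list(predictors)].to_numpy(dtype=float)
    fit = _fit_logit(y, X, predictors)
    return _model_fit_from(fit, predictors, outcome_name, y, p_enter=np.nan, p_remove=np.nan)


def _model_fit_from(fit, names, outcome_name, y, p_enter, p_remove, forced=()):
    terms = []
    for i, nm in enumerate(names, start=1):
        b = float(fit.params[i])
        se = float(fit.bse[i])
        wald = (b / se) ** 2 if se > 0 else np.inf
        terms.append(
            TermResult(
                name=nm,
                coefficient=b,
                odds_ratio=float(np.exp(b)),
                wald_chi_square=float(wald),
                df=1,
                p=float(stats.chi2.sf(wald, 1)),
                forced=nm in forced,
            )
        )
    probs = np.asarray(fit.predict())
    return ModelFit(
        outcome=outcome_name,
        n=int(len(y)),
        terms=terms,
        intercept=float(fit.params[0]),
        c_statistic=c_statistic(probs, y) if len(names) else 0.5,
        p_enter=float(p_enter),
        p_remove=float(p_remove),
        log_likelihood=float(fit.llf),
        covariates=[nm for nm in forced],
    )


def _score_test_p(y, design, phat, x):
    """Rao score test p for adding column x to the current logistic model.

    Uses the current-model fit only: U = x'(y - p),
    V = x'Wx - x'WZ (Z'WZ)^-1 Z'Wx with W = diag(p(1-p)) and Z the current
    design (including the intercept).
    """
    w = phat * (1 - phat)
    u = float(x @ (y - phat))
    zwz = design.T @ (design * w[:, None])
    zwx = design.T @ (x * w)
    v = float(x @ (x * w) - zwx @ np.linalg.solve(zwz, zwx))
    if v <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / v, 1))


def stepwise_logistic(
    table: pd.DataFrame,
    outcome_labels: pd.Series,
    candidates: Sequence[str],
    p_enter: float = 0.15,
    p_remove: float = 0.15,
    outcome_name: str = "outcome",
    max_steps: int = 100,
) -> ModelFit:
    """Forward-stepwise logistic regression with backward Wald checks.

    At each step the candidate with the smallest Rao score-test p enters if
    below ``p_enter``; any included term whose Wald p exceeds ``p_remove``
    is then dropped.  Iterates to stability; the final model is refit by
    maximum likelihood.  Subjects with a missing outcome label are excluded;
    candidate columns must be complete (post-imputation).
    """
    labels = pd.Series(outcome_labels).reindex(table.index)
    keep = labels.notna()
    y = labels[keep].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("outcome must have both classes after exclusions")
    cols = {c: table.loc[keep, c].to_numpy(dtype=float) for c in candidates}
    for c, v in cols.items():
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"candidate {c!r} has missing values; impute first")

    selected: List[str] = []
    for _ in range(max_steps):
        changed = False
        # Forward: smallest score-test p among remaining candidates.
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            if selected:
                Z = np.column_stack([cols[c] for c in selected])
                cur = _fit_logit(y, Z, selected)
                design = sm.add_constant(Z, has_constant="add")
                phat = np.asarray(cur.predict())
            else:
                design = np.ones((len(y), 1))
                phat = np.full(len(y), y.mean())
            pvals = {c: _score_test_p(y, design, phat, cols[c]) for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        # Backward: drop included terms with Wald p above the stay threshold.
        while selected:
            X = np.column_stack([cols[c] for c in selected])
            fit = _fit_logit(y, X, selected)
            wald_p = {
                c: float(stats.chi2.sf((fit.params[i + 1] / fit.bse[i + 1]) ** 2, 1))
                for i, c in enumerate(selected)
            }
            worst = max(wald_p, key=wald_p.get)
            if wald_p[worst] > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        X = np.column_stack([cols[c] for c in selected])
        fit = _fit_logit(y, X, selected)
        return _model_fit_from(fit, selected, outcome_name, y, p_enter, p_remove)
    fit = _fit_logit(y, np.empty((len(y), 0)), [])
    return _model_fit_from(fit, [], outcome_name, y, p_enter, p_remove)


def fit_adjusted(
    model_fit: ModelFit,
    table: pd.DataFrame,
    outcome_labels: pd.Series,
    covariates: Sequence[str] = ("time_since_trauma", "severity_rating"),
) -> ModelFit:
    """Refit the selected model with covariates forced in.

    Subjects missing a covariate are dropped (logged upstream); the forced
    covariates always appear in the output regardless of significance.
    """
    names = model_fit.selected + [c for c in covariates if c not in model_fit.selected]
    labels = pd.Series(outcome_labels).reindex(table.index)
    keep = labels.notna()
    for c in names:
        keep &= table[c].notna()
    y = labels[keep].to_numpy(dtype=float)
    X = table.loc[keep, names].to_numpy(dtype=float)
    fit = _fit_logit(y, X, names)
    out = _model_fit_from(
        fit, names, model_fit.outcome, y, model_fit.p_enter, model_fit.p_remove,
        forced=tuple(covariates),
    )
    return out
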