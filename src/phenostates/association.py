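"""Post hoc association analyses.

Two analyses link the fitted state dynamics to external variables:

* per-transition ordinary least squares of the K² subject-level transition
  probabilities on demographic covariates (female, age, ethnoracial
  minority), reported with unstandardised b, 95% CI, t, p and the
  standardised coefficient β = b·sd(x)/sd(y);
* per-disorder linear mixed models of weekly comorbidity severity on
  concurrent-state indicators (low state as reference), sex, age and the
  three state inertias, with a subject random intercept and lag-1
  autoregressive within-subject residual correlation, estimated by maximum
  likelihood.  Significance is flagged at the Bonferroni-adjusted level
  α/n_disorders.

Transition probabilities are regressed on the raw probability scale by
default (a logit option is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .io_tables import DISORDERS

logger = logging.getLogger(__name__)

__all__ = [
    "bonferroni_adjust",
    "regress_transitions",
    "LmmAr1Result",
    "fit_lmm_ar1",
    "ComorbidityModelResult",
    "fit_comorbidity_model",
]

PREDICTORS = ["female", "age", "ethnoracial_minority"]


def bonferroni_adjust(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test alpha: α / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive count")
    return alpha / n_tests


def _subject_gammas(dyn) -> tuple[list, np.ndarray]:
    """Accept a list of SubjectDynamics or a (ids, (n,K,K)) pair."""
    if isinstance(dyn, tuple):
        return list(dyn[0]), np.asarray(dyn[1], dtype=float)
    return [d.subject_id for d in dyn], np.stack([d.gamma for d in dyn])


def regress_transitions(dyn, cov: pd.DataFrame, scale: str = "probability") -> pd.DataFrame:
    """Per-transition OLS of subject transition probabilities on demographics.

    One ordinary-least-squares model per ordered state pair (including the
    diagonal inertias), with female, age and ethnoracial minority entered
    jointly.  Returns a tidy table with one row per (transition, predictor).
    A constant outcome yields zero coefficients with a warning; collinear
    predictors raise.
    """
    ids, gammas = _subject_gammas(dyn)
    cov = cov.set_index("subject_id").loc[ids].reset_index()
    if cov[PREDICTORS].isna().any().any():
        raise ValueError("covariates must not contain missing values")
    n, K, _ = gammas.shape
    if n < 10:
        raise ValueError("at least 10 subjects are required")
    X = cov[PREDICTORS].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
        raise ValueError("collinear predictors")
    rows = []
    for i in range(K):
        for j in range(K):
            y = gammas[:, i, j]
            if scale == "logit":
                y = np.log(np.clip(y, 1e-12, 1 - 1e-12)) - np.log1p(-np.clip(y, 1e-12, 1 - 1e-12))
            if np.std(y) < 1e-12:
                warnings.warn(f"constant outcome for transition {i}->{j}; coefficients set to 0")
                for pred in PREDICTORS:
                    rows.append({"from_state": i, "to_state": j, "predictor": pred,
                                 "b": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                                 "t": 0.0, "p": 1.0, "beta_std": 0.0})
                continue
            res = sm.OLS(y, sm.add_constant(X)).fit()
            ci = res.conf_int(alpha=0.05)
            for m, pred in enumerate(PREDICTORS, start=1):
                rows.append({
                    "from_state": i,
                    "to_state": j,
                    "predictor": pred,
                    "b": res.params[m],
                    "ci_low": ci[m, 0],
                    "ci_high": ci[m, 1],
                    "t": res.tvalues[m],
                    "p": res.pvalues[m],
                    "beta_std": res.params[m] * np.std(X[:, m - 1], ddof=1) / np.std(y, ddof=1),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear mixed model with random intercept and AR(1) residuals (ML)


@dataclass
class LmmAr1Result:
    """ML fit of y_it = x_it'β + b_i + e_it, b_i ~ N(0, τ²), e AR(1)(ρ, σ²)."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rho: float
    tau2: float
    sigma2: float
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int


def _ar1_corr(weeks: np.ndarray, rho: float) -> np.ndarray:
    lags = np.abs(weeks[:, None] - weeks[None, :])
    return rho**lags


def _profile_neg_loglik(theta, groups, fixed_rho=None):
    """−2·profile log-likelihood over (log σ², log τ², atanh ρ); β profiled."""
    log_s2, log_t2 = theta[0], theta[1]
    rho = np.tanh(theta[2]) if fixed_rho is None else fixed_rho
    s2, t2 = np.exp(log_s2), np.exp(log_t2)
    xtvx = 0.0
    xtvy = 0.0
    logdet = 0.0
    cache = []
    for X, y, weeks in groups:
        V = t2 + s2 * _ar1_corr(weeks, rho)
        try:
            L = scipy.linalg.cholesky(V, lower=True)
        except scipy.linalg.LinAlgError:
            return np.inf, None, None
        logdet += 2.0 * np.log(np.diag(L)).sum()
        Xi = scipy.linalg.solve_triangular(L, X, lower=True)
        yi = scipy.linalg.solve_triangular(L, y, lower=True)
        xtvx = xtvx + Xi.T @ Xi
        xtvy = xtvy + Xi.T @ yi
        cache.append((Xi, yi))
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rss = sum(((yi - Xi @ beta) ** 2).sum() for Xi, yi in cache)
    n = sum(len(y) for _, y, _ in groups)
    nll = logdet + rss + n * np.log(2.0 * np.pi)
    return nll, beta, xtvx


def fit_lmm_ar1(
    df: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str = "subject_id",
    time: str = "week",
    fix_rho: float | None = None,
) -> LmmAr1Result:
    """Maximum-likelihood linear mixed model with a subject random intercept
    and AR(1) within-subject residual correlation.

    The AR(1) correlation uses the actual week indices (ρ^|t−s|), so gaps
    from removed weeks decay the correlation correctly.  Fixed-effect
    standard errors come from the GLS information matrix; p-values use a t
    reference with n_obs − n_fixed degrees of freedom.  ``fix_rho`` pins the
    autocorrelation (used for the ρ=0 comparison fit).
    """
    cols = [group, time, response, *predictors]
    data = df[cols].dropna()
    groups = []
    for _, grp in data.groupby(group, sort=False):
        X = np.column_stack([np.ones(len(grp)), grp[predictors].to_numpy(dtype=float)])
        groups.append((X, grp[response].to_numpy(dtype=float),
                       grp[time].to_numpy(dtype=float)))
    names = ["intercept", *predictors]
    y_var = max(float(data[response].var()), 1e-6)
    x0 = np.array([np.log(0.7 * y_var), np.log(0.3 * y_var), np.arctanh(0.3)])
    if fix_rho is not None:
        x0 = x0[:2]

    def obj(theta):
        full = theta if fix_rho is None else np.append(theta, 0.0)
        return _profile_neg_loglik(full, groups, fixed_rho=fix_rho)[0]

    res = scipy.optimize.minimize(obj, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    theta = res.x if fix_rho is None else np.append(res.x, 0.0)
    nll, beta, xtvx = _profile_neg_loglik(theta, groups, fixed_rho=fix_rho)
    if beta is None:
        raise RuntimeError("mixed-model likelihood is degenerate at the optimum")
    covb = np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(covb))
    dof = sum(len(y) for _, y, _ in groups) - len(names)
    tvals = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), dof)
    tq = scipy.stats.t.ppf(0.975, dof)
    ci = pd.DataFrame(
        {"ci_low": beta - tq * se, "ci_high": beta + tq * se}, index=names
    )
    return LmmAr1Result(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        conf_int=ci,
        rho=float(np.tanh(theta[2]) if fix_rho is None else fix_rho),
        tau2=float(np.exp(theta[1])),
        sigma2=float(np.exp(theta[0])),
        loglik=float(-0.5 * nll),
        converged=bool(res.success),
        n_obs=int(len(data)),
        n_subjects=len(groups),
    )


@dataclass
class ComorbidityModelResult:
    """Per-disorder mixed-model tables with Bonferroni significance flags."""

    tables: dict  # disorder -> DataFrame (b, se, t, p, ci_low, ci_high, significant)
    fits: dict  # disorder -> LmmAr1Result
    failures: dict
    adjusted_alpha: float

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for d, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "disorder", d)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def fit_comorbidity_model(
    comorbidity: pd.DataFrame,
    decoded_states: pd.DataFrame,
    dyn,
    cov: pd.DataFrame,
    alpha: float = 0.05,
    disorders: list[str] | None = None,
    gamma_state_labels: tuple = ("low", "cognitive_physical", "elevated"),
) -> ComorbidityModelResult:
    """Mixed models linking weekly comorbidity severity to concurrent states
    and state inertias.

    ``decoded_states`` has columns (subject_id, week, state_label) from the
    decoded latent paths; the low state is the reference category.  Each
    disorder's model is
    severity ~ elevated + cognitive_physical + female + age
             + inertia_elevated + inertia_low + inertia_cognitive_physical
    with a subject random intercept and AR(1) residuals.  Non-convergence is
    recorded per disorder and the remaining disorders are still fitted.
    Significance flags use exactly the Bonferroni-adjusted alpha.
    """
    disorders = disorders or [d for d in DISORDERS if d in set(comorbidity["disorder"])]
    adj = bonferroni_adjust(alpha, len(disorders))
    ids, gammas = _subject_gammas(dyn)
    lab = {name: k for k, name in enumerate(gamma_state_labels)}
    inert = pd.DataFrame(
        {
            "subject_id": ids,
            "inertia_low": gammas[:, lab["low"], lab["low"]],
            "inertia_cognitive_physical": gammas[:, lab["cognitive_physical"],
                                                 lab["cognitive_physical"]],
            "inertia_elevated": gammas[:, lab["elevated"], lab["elevated"]],
        }
    )
    states = decoded_states.copy()
    states["elevated"] = (states["state_label"] == "elevated").astype(float)
    states["cognitive_physical"] = (states["state_label"] == "cognitive_physical").astype(float)
    base = (
        comorbidity.merge(states[["subject_id", "week", "elevated", "cognitive_physical"]],
                          on=["subject_id", "week"], how="inner")
        .merge(cov[["subject_id", "female", "age"]], on="subject_id")
        .merge(inert, on="subject_id")
    )
    predictors = ["elevated", "cognitive_physical", "female", "age",
                  "inertia_elevated", "inertia_low", "inertia_cognitive_physical"]
    tables, fits, failures = {}, {}, {}
    for d in disorders:
        sub = base[base["disorder"] == d]
        try:
            res = fit_lmm_ar1(sub, "severity", predictors)
        except Exception as exc:  # noqa: BLE001 - recorded per disorder
            logger.warning("comorbidity model for %s failed: %s", d, exc)
            failures[d] = str(exc)
            continue
        tab = pd.DataFrame(
            {
                "b": res.params,
                "se": res.se,
                "t": res.tvalues,
                "p": res.pvalues,
                "ci_low": res.conf_int["ci_low"],
                "ci_high": res.conf_int["ci_high"],
            }
        ).loc[predictors]
        tab["significant"] = tab["p"] < adj
        tables[d] = tab
        fits[d] = res
    return ComorbidityModelResult(tables=tables, fits=fits, failures=failures,
                                  adjusted_alpha=adj)
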