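"""Multivariate effect-size modeling for behavioral outcome metrics.

Every behavioral metric is modeled as

    metric ~ age + iq + sex + adhd_inatt + adhd_hyper + asd

with one model per metric, fitted by bisquare (Tukey biweight) robust
regression so that heavy-tailed behavioral measurements do not dominate the
fit.  The effect size of each predictor is

    ES = t / sqrt(DFE)

with DFE the error degrees of freedom (n_used - n_parameters).  For a binary
predictor this tracks Cohen's d up to a sqrt(p(1-p)) prevalence factor; for
continuous predictors it is a comparable standardized effect (the coefficient
in units of its own standard error, normalized by sample size).  Binary diagnostic outcomes (comorbidity
models) use maximum-likelihood logistic regression with odds ratios
OR = exp(beta).  Family-wise control across the outcome metrics of an
analysis block uses Bonferroni adjustment at alpha = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "PREDICTORS",
    "FitResult",
    "build_design",
    "fit_robust_linear",
    "fit_logistic",
    "fit_interaction",
    "effect_size",
    "bonferroni_flag",
    "spearman_rho",
]

#: Default predictor set; sex is coded female=1, male=0, diagnostic status
#: flags are binary with ADHD-Combined positive on both ADHD flags.
PREDICTORS = ["age", "iq_full", "sex", "adhd_inatt", "adhd_hyper", "asd"]

BISQUARE_TUNING = 4.685  # 95% Gaussian efficiency for Tukey's biweight


@dataclass
class FitResult:
    """One fitted model: per-term estimates plus fit metadata.

    ``table`` is indexed by term (``const`` first) with columns beta, se, t,
    p, es and — for logistic fits — odds_ratio.
    """

    outcome: str
    family: str                   # 'robust_linear' | 'logistic'
    table: pd.DataFrame
    dfe: int
    n_used: int
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def effect_sizes(self) -> pd.Series:
        return self.table["es"].drop("const")

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"].drop("const")


def build_design(
    records: pd.DataFrame,
    outcome_column: str,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Assemble (y, X, n_used) for one outcome model.

    Rows flagged ``excluded`` are dropped, then listwise deletion over the
    outcome and the predictors of *this* model (every participant counts as
    n = 1).  X carries an intercept column ``const``.
    """
    if outcome_column not in records.columns:
        raise KeyError(f"outcome column {outcome_column!r} not in table")
    missing = [p for p in predictors if p not in records.columns]
    if missing:
        raise KeyError(f"predictor column(s) {missing} not in table")
    df = records
    if "excluded" in df.columns:
        df = df[df["excluded"] != 1]
    cols = [outcome_column, *predictors]
    df = df[cols].dropna()
    n_used = len(df)
    n_par = len(predictors) + 1
    if n_used <= n_par:
        raise ValueError(
            f"underdetermined model for {outcome_column!r}: "
            f"{n_used} usable rows for {n_par} parameters")
    y = df[outcome_column].astype(float)
    X = sm.add_constant(df[list(predictors)].astype(float), has_constant="add")
    return y, X, n_used


def effect_size(t: float, dfe: int) -> float:
    """Standardized effect size t / sqrt(DFE)."""
    if dfe < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    return float(t) / np.sqrt(dfe)


def _result_table(terms, beta, se, dfe, p=None, odds=False) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    if p is None:
        p = 2 * scipy.stats.t.sf(np.abs(t), dfe)
    es = t / np.sqrt(dfe)
    tab = pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p, "es": es},
                       index=list(terms))
    if odds:
        tab["odds_ratio"] = np.exp(beta)
    return tab


def fit_robust_linear(
    y,
    X: pd.DataFrame,
    tuning: float = BISQUARE_TUNING,
    tol: float = 1e-8,
    max_iter: int = 200,
    outcome: str = "y",
) -> FitResult:
    """Bisquare robust linear fit via iteratively reweighted least squares.

    Residuals are scaled by the MAD-based robust scale and weighted with
    Tukey's biweight (tuning constant 4.685 by default); standard errors and
    t-statistics come from the weighted fit, p-values from the t reference
    distribution with DFE = n - p, and ES = t / sqrt(DFE).  Exactly linear
    data (robust scale underflow) falls back to the ordinary least-squares
    solution, which the IRLS fixed point equals in that case.
    """
    y = np.asarray(y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    if np.linalg.matrix_rank(Xv) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    dfe = n - p
    if dfe < 1:
        raise ValueError("not enough observations for the requested model")
    terms = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(p)]

    ols_beta, _, _, _ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ ols_beta
    scale0 = sm.robust.scale.mad(resid, center=0)
    y_scale = max(np.std(y), 1.0)
    if scale0 <= 1e-12 * y_scale:
        # exact (or numerically exact) linear data: OLS is the fixed point
        sigma2 = float(resid @ resid) / dfe
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        se = np.sqrt(np.maximum(sigma2, 0.0) * np.diag(XtX_inv))
        tab = _result_table(terms, ols_beta, se, dfe)
        return FitResult(outcome, "robust_linear", tab, dfe, n, converged=True)

    model = sm.RLM(y, Xv, M=sm.robust.norms.TukeyBiweight(c=tuning))
    res = model.fit(conv="coefs", tol=tol, maxiter=max_iter, scale_est="mad")
    n_iter = len(res.fit_history.get("params", []))
    converged = n_iter < max_iter
    result = FitResult(outcome, "robust_linear",
                       _result_table(terms, res.params, res.bse, dfe),
                       dfe, n, converged=converged)
    if not converged:
        msg = f"robust fit for {outcome!r} did not converge in {max_iter} iterations"
        warnings.warn(msg, stacklevel=2)
        result.warnings_.append(msg)
    return result


def fit_logistic(y01, X: pd.DataFrame, outcome: str = "y") -> FitResult:
    """Maximum-likelihood logistic fit with odds ratios exp(beta).

    Odds ratios are per unit change of the predictor (per year for age).
    Complete or quasi-complete separation is an error; penalized fits are out
    of scope.
    """
    y = np.asarray(y01, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic outcome must be binary 0/1")
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    dfe = n - p
    terms = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(p)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xv).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, RuntimeWarning) as exc:
        raise ValueError(
            "separation detected in logistic fit (diverging coefficients); "
            "penalized estimation is out of scope") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise ValueError(
            "separation detected in logistic fit (diverging coefficients); "
            "penalized estimation is out of scope")
    tab = _result_table(terms, res.params, res.bse, dfe,
                        p=res.pvalues, odds=True)
    return FitResult(outcome, "logistic", tab, dfe, n, converged=True)


def fit_interaction(
    records: pd.DataFrame,
    outcome_column: str,
    disorder_flag: str,
    predictors: Sequence[str] = PREDICTORS,
) -> FitResult:
    """Post-hoc model adding an age x disorder interaction term.

    The interaction tests whether the diagnostic gap widens or narrows with
    age; its p-value is reported uncorrected.
    """
    if disorder_flag not in ("asd", "adhd_inatt", "adhd_hyper"):
        raise ValueError(f"disorder_flag must be a diagnostic status flag, got {disorder_flag!r}")
    y, X, n_used = build_design(records, outcome_column, predictors)
    X = X.copy()
    X[f"age_x_{disorder_flag}"] = X["age"] * X[disorder_flag]
    return fit_robust_linear(y, X, outcome=outcome_column)


def bonferroni_flag(
    pvals, family_size: int, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment over a family of ``family_size`` models.

    Returns (flags, p_adjusted) with p_adj = min(1, m * p) and a flag wherever
    p_adj < alpha.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size < p.size:
        raise ValueError(
            f"family_size ({family_size}) smaller than the {p.size} tests supplied")
    p_adj = np.minimum(1.0, family_size * p)
    flags = p_adj < alpha
    return flags, p_adj


def spearman_rho(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation on pairwise-complete observations.

    Returns (rho, p, n); the parenthetical convention in reports is n - 2.
    Constant input leaves the correlation undefined: returns NaN with a
    warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p), n
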