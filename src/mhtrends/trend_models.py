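"""The statistical battery, implemented from first principles.

Binary logistic regression is fit by iteratively reweighted least squares
(Newton-Raphson on the Bernoulli log-likelihood); standard errors come from
the inverse observed information, Wald statistics are z^2 against a
chi-square(1) reference (the convention of mainstream commercial stats
packages; a flag exposes plain z), 95% CIs for odds ratios are
exp(B +/- 1.96 SE), and per-covariate likelihood-ratio tests refit the
model without that covariate. Also here: Pearson year-trend correlations,
sensitivity/specificity against a binary covariate, variance inflation
factors and sample skewness/kurtosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFitResult", "TrendCorrelation", "DiagnosticResult",
    "MomentsResult", "VifResult", "SingleClassError",
    "fit_logistic", "fit_paper_models", "pearson_trend",
    "diagnostics", "vif", "moments",
]

_Z95 = 1.96  # normal quantile for 95% CIs


class SingleClassError(ValueError):
    """Outcome vector contains only one class; the MLE does not exist."""


def _safe_exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:
        return math.inf


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    b: float
    se: float
    wald: float           # z^2 by default (chi-square, 1 df)
    z: float
    p_value: float
    exp_b: float
    ci_low_exp_b: float
    ci_high_exp_b: float
    lrt_stat: float | None = None        # 2*(LL_full - LL_reduced)
    lrt_p: float | None = None
    ll_reduced: float | None = None


@dataclass(frozen=True)
class LogisticFitResult:
    coefficients: dict[str, CoefficientEstimate]
    log_likelihood: float
    n: int
    converged: bool
    iterations: int
    warnings: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> CoefficientEstimate:
        return self.coefficients[name]

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.coefficients.values():
            rows.append({
                "term": c.name, "B": c.b, "SE": c.se, "Wald": c.wald,
                "p": c.p_value, "ExpB": c.exp_b,
                "ci_low": c.ci_low_exp_b, "ci_high": c.ci_high_exp_b,
                "LRT": c.lrt_stat, "LRT_p": c.lrt_p,
                "LL_reduced": c.ll_reduced,
            })
        return pd.DataFrame(rows)


def _bernoulli_ll(y, p, w):
    # clip away exact 0/1 so the LL stays finite under quasi-separation
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def _irls(y, X, w, tol=1e-8, max_iter=100, divergence_bound=30.0,
          slope_cols=None):
    """Newton-Raphson / IRLS for the Bernoulli GLM with logit link.

    Returns (beta, cov, ll, converged, iterations, warnings).
    """
    n, k = X.shape
    beta = np.zeros(k)
    warnings: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1 - p)
        # observed information X' W X; score X' w (y - p)
        XtW = X.T * W
        info = XtW @ X
        score = X.T @ (w * (y - p))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            info = info + 1e-10 * np.eye(k)
            step = np.linalg.solve(info, score)
            warnings.append("information matrix near-singular; ridge 1e-10 applied")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    # the intercept may be legitimately large with uncentered covariates;
    # the divergence check targets the slopes
    slope_cols = range(k) if slope_cols is None else slope_cols
    if any(abs(beta[j]) > divergence_bound for j in slope_cols):
        converged = False
        warnings.append(
            f"coefficient magnitude exceeds {divergence_bound}; "
            "quasi-separation suspected, estimates unreliable")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1 - p)
    info = (X.T * W) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        warnings.append("information matrix singular at optimum; pseudo-inverse used")
    ll = _bernoulli_ll(y, p, w)
    if not converged and not warnings:
        warnings.append(f"IRLS did not converge in {max_iter} iterations")
    return beta, cov, ll, converged, it, warnings


def fit_logistic(outcome, covariates, names: list[str] | None = None, *,
                 add_intercept: bool = True, sample_weight=None,
                 lrt: bool = True, wald_as_z: bool = False,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFitResult:
    """Maximum-likelihood binary logistic fit with Wald and LRT inference.

    Parameters
    ----------
    outcome : 0/1 vector.
    covariates : (n, k) matrix, or (n,) vector for a single covariate;
        an intercept column is prepended unless ``add_intercept=False``.
    names : covariate names (defaults ``x1..xk``); the intercept is named
        ``intercept``.
    sample_weight : optional frequency weights (grouped data).
    lrt : also compute, per non-intercept covariate, the likelihood-ratio
        test from a refit without that covariate.
    wald_as_z : report the Wald column as z rather than z^2.

    Raises :class:`SingleClassError` when the outcome has only one class.
    Non-convergence or diverging coefficients (quasi-separation) flag the
    result rather than raising; values are still reported.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("outcome and covariates disagree on n")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y[w > 0])) < 2:
        raise SingleClassError("outcome contains a single class; cannot fit")
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names length mismatch")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + list(names)
    n_eff = int(w.sum())
    if n_eff < X.shape[1] + 1:
        raise ValueError("fewer observations than coefficients + 1")

    slope_cols = range(1, X.shape[1]) if add_intercept else range(X.shape[1])
    beta, cov, ll, converged, iters, warns = _irls(y, X, w, tol=tol, max_iter=max_iter,
                                                   slope_cols=slope_cols)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    coefs: dict[str, CoefficientEstimate] = {}
    for j, name in enumerate(names):
        b, s = float(beta[j]), float(se[j])
        z = b / s if s > 0 else math.inf * np.sign(b)
        p_val = float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
        lrt_stat = lrt_p = ll_red = None
        if lrt and not (add_intercept and j == 0) and X.shape[1] > 1:
            X_red = np.delete(X, j, axis=1)
            _, _, llr, *_ = _irls(y, X_red, w, tol=tol, max_iter=max_iter)
            lrt_stat = max(2.0 * (ll - llr), 0.0)
            lrt_p = float(stats.chi2.sf(lrt_stat, df=1))
            ll_red = llr
        coefs[name] = CoefficientEstimate(
            name=name, b=b, se=s,
            wald=z if wald_as_z else z * z,
            z=z, p_value=min(max(p_val, np.nextafter(0, 1)), 1.0),
            exp_b=_safe_exp(b),
            ci_low_exp_b=_safe_exp(b - _Z95 * s),
            ci_high_exp_b=_safe_exp(b + _Z95 * s),
            lrt_stat=lrt_stat, lrt_p=lrt_p, ll_reduced=ll_red,
        )
    return LogisticFitResult(coefficients=coefs, log_likelihood=ll, n=n_eff,
                             converged=converged, iterations=iters,
                             warnings=tuple(warns))


OUTCOME_FLAGS = ("depression", "anxiety", "loneliness", "distress", "any_word")


def fit_paper_models(rows: pd.DataFrame, outcomes=OUTCOME_FLAGS,
                     ) -> dict[str, dict[str, LogisticFitResult]]:
    """Fit the two model layouts for every term outcome.

    Per outcome flag (each term's mention plus the any-word composite):

    * ``multivariable`` — mention ~ covid + complete;
    * ``year`` — mention ~ start_year (untransformed, per-year odds).

    Outcomes with a single class in the data are skipped with a warning
    entry instead of a fit.
    """
    report: dict[str, dict[str, LogisticFitResult]] = {}
    for outcome in outcomes:
        col = outcome if outcome in rows.columns else f"{outcome}_mention"
        y = rows[col].to_numpy()
        models: dict[str, LogisticFitResult] = {}
        try:
            models["multivariable"] = fit_logistic(
                y, rows[["covid", "complete"]].to_numpy(), names=["covid", "complete"])
            models["year"] = fit_logistic(
                y, rows[["start_year"]].to_numpy(), names=["start_year"])
        except SingleClassError:
            continue
        report[outcome] = models
    return report


@dataclass(frozen=True)
class TrendCorrelation:
    term: str
    status: str
    r: float
    n_points: int
    mode: str                # "per-year-mean" | "per-trial"
    computable: bool = True


def pearson_trend(rows: pd.DataFrame, term: str, status: str | None = None,
                  mode: str = "per-year-mean") -> TrendCorrelation:
    """Pearson r between start year and a term's frequency.

    ``per-year-mean`` correlates calendar year with the mean frequency among
    that status's trials in that year (one point per year); ``per-trial``
    uses one point per trial. Zero variance on either axis, or fewer than
    two points, is reported as not computable rather than raising.
    """
    if mode not in {"per-year-mean", "per-trial"}:
        raise ValueError(f"unknown mode {mode!r}")
    sub = rows if status is None else rows[rows["status"] == status]
    col = f"{term}_frequency"
    if mode == "per-year-mean":
        grouped = sub.groupby("start_year")[col].mean()
        x = grouped.index.to_numpy(dtype=float)
        yv = grouped.to_numpy(dtype=float)
    else:
        x = sub["start_year"].to_numpy(dtype=float)
        yv = sub[col].to_numpy(dtype=float)
    label = status if status is not None else "<all>"
    if len(x) < 2 or np.std(x) == 0 or np.std(yv) == 0:
        return TrendCorrelation(term=term, status=label, r=float("nan"),
                                n_points=len(x), mode=mode, computable=False)
    r = float(np.corrcoef(x, yv)[0, 1])
    return TrendCorrelation(term=term, status=label, r=r, n_points=len(x), mode=mode)


@dataclass(frozen=True)
class DiagnosticResult:
    predictor: str
    outcome: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float       # percent; NaN when TP+FN == 0
    specificity: float       # percent; NaN when TN+FP == 0
    flagged: bool = False


def diagnostics(predictor_flag, outcome_flag, *, predictor: str = "predictor",
                outcome: str = "outcome") -> DiagnosticResult:
    """Sensitivity/specificity of a binary covariate as a "test" for mention.

    The covariate plays the diagnostic-test role and the term mention the
    condition: TP counts trials with covariate 1 and mention 1, and
    sensitivity = 100*TP/(TP+FN), specificity = 100*TN/(TN+FP). Percentages
    are kept at full precision here; rounding is a report-layer concern.
    """
    p = np.asarray(predictor_flag, dtype=int).ravel()
    o = np.asarray(outcome_flag, dtype=int).ravel()
    if p.shape != o.shape:
        raise ValueError("predictor and outcome lengths differ")
    if not (np.isin(p, (0, 1)).all() and np.isin(o, (0, 1)).all()):
        raise ValueError("both vectors must be binary 0/1")
    tp = int(np.sum((p == 1) & (o == 1)))
    fp = int(np.sum((p == 1) & (o == 0)))
    tn = int(np.sum((p == 0) & (o == 0)))
    fn = int(np.sum((p == 0) & (o == 1)))
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else float("nan")
    return DiagnosticResult(predictor=predictor, outcome=outcome,
                            tp=tp, fp=fp, tn=tn, fn=fn,
                            sensitivity=sens, specificity=spec,
                            flagged=(tp + fn == 0) or (tn + fp == 0))


@dataclass(frozen=True)
class VifResult:
    vifs: dict[str, float]   # inf flags perfect collinearity
    r_squared: dict[str, float]

    def __getitem__(self, name):
        return self.vifs[name]


def vif(covariates, names: list[str] | None = None) -> VifResult:
    """Variance inflation factors, 1/(1-R^2_j).

    Each predictor is regressed (OLS, with intercept) on the remaining
    ones; perfect collinearity flags the involved predictors as infinite.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 predictors")
    if (X.std(axis=0) == 0).any():
        raise ValueError("every predictor must have non-zero variance")
    n, k = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    vifs, r2s = {}, {}
    for j in range(k):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        r2s[names[j]] = r2
        vifs[names[j]] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return VifResult(vifs=vifs, r_squared=r2s)


@dataclass(frozen=True)
class MomentsResult:
    mean: float
    skewness: float          # g1 = m3 / m2^1.5
    excess_kurtosis: float   # g2 = m4 / m2^2 - 3
    n: int
    flagged: bool = False    # zero variance


def moments(values) -> MomentsResult:
    """Sample skewness g1 and excess kurtosis g2 from central moments.

    For a 0/1 vector with success proportion p these approach
    (1-2p)/sqrt(p(1-p)) and (1-6p(1-p))/(p(1-p)) as n grows, which is how
    a rare mention flag shows up as right-skewed and leptokurtic.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for skewness and kurtosis")
    m = x.mean()
    d = x - m
    m2 = float(np.mean(d ** 2))
    if m2 == 0:
        return MomentsResult(mean=m, skewness=float("nan"),
                             excess_kurtosis=float("nan"), n=n, flagged=True)
    m3 = float(np.mean(d ** 3))
    m4 = float(np.mean(d ** 4))
    return MomentsResult(mean=m, skewness=m3 / m2 ** 1.5,
                         excess_kurtosis=m4 / m2 ** 2 - 3.0, n=n)
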