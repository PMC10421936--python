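"""Negative-binomial GLM differential expression with disease LRTs.

Each miRNA's counts are modelled with a log-link NB regression
(Var = mu + mu^2/theta) on sequencing depth, protocol, smoking, age, gender
and the two disease indicators.  Depth enters as a covariate (log total
counts), not an offset.  Disease significance is a likelihood-ratio test of
the model with both disease terms against the model with neither (chi^2,
2 df), BH-adjusted; a miRNA is called differential when q < 0.1 and either
disease coefficient exceeds 0.22 in magnitude on the natural-log scale
(exp(0.223) ~= 1.25-fold).

The fit alternates IRLS for the coefficients with 1-D maximum-likelihood
estimation of theta, the same scheme as the classic glm.nb fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

THETA_FLOOR = 1e-3
THETA_CEIL = 1e7


@dataclass
class NbFit:
    """A fitted NB regression: natural-log-scale slopes, theta, log-likelihood."""

    coefficients: pd.Series
    theta: float
    log_likelihood: float
    converged: bool
    n_iter: int = 0


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls(y: np.ndarray, X: np.ndarray, theta: float, beta: np.ndarray,
          max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Weighted least-squares iterations for a log-link NB with fixed theta."""
    eta = X @ beta
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)
        eta_new = X @ beta_new
        done = np.max(np.abs(eta_new - eta)) < tol
        beta, eta = beta_new, eta_new
        if done:
            break
    return beta


def fit_nb_glm(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NbFit:
    """Fit a log-link negative binomial GLM with ML theta.

    ``design`` must include an intercept column.  Alternates IRLS for the
    slopes with Brent maximization of the profile likelihood in log(theta)
    until the log-likelihood changes by less than ``tol`` (or ``max_iter``
    alternations, in which case ``converged`` is False).
    """
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(design).shape[1])
    ]
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    if not y.any():
        raise ValueError("all-zero response: no NB fit possible")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")

    # moment start: Poisson-scale intercept, theta from var/mean
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    m, v = y.mean(), y.var(ddof=1)
    theta = float(np.clip(m * m / max(v - m, 1e-8), THETA_FLOOR, THETA_CEIL))

    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = _irls(y, X, theta, beta)
        mu = np.exp(np.clip(X @ beta, -30, 30))

        def neg_ll(log_theta: float) -> float:
            return -_nb_loglik(y, mu, np.exp(log_theta))

        res = optimize.minimize_scalar(
            neg_ll, bounds=(np.log(THETA_FLOOR), np.log(THETA_CEIL)), method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        ll_new = -res.fun
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return NbFit(
        coefficients=pd.Series(beta, index=names),
        theta=theta, log_likelihood=ll, converged=converged, n_iter=it,
    )


def lrt_disease(full: NbFit, reduced: NbFit, df: int = 2) -> float:
    """Likelihood-ratio p-value for the disease terms (chi^2, ``df`` df)."""
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        warnings.warn(
            f"full model log-likelihood below reduced by {-stat / 2:.3g}; "
            "statistic clipped at 0 (consider refitting)",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    return float(stats.chi2.sf(stat, df))


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q(i) = min_{j: p(j) >= p(i)} p(j) * n / rank(j), capped at 1.  NaNs are
    excluded from n and propagated as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(qv, 1.0)
        q[ok] = out
    return q


def build_design(covariates: pd.DataFrame, include_disease: bool = True) -> pd.DataFrame:
    """Design matrix from a covariate table.

    Expects columns ``lib_size`` (sequencing depth; entered as log),
    ``protocol``, ``smoking``, ``age``, ``gender`` and ``disease`` (values
    Control/COPD/ILD).  Categorical terms are dummy-coded against their first
    level; disease expands to COPD and ILD indicators versus Control.
    """
    parts = {"intercept": np.ones(len(covariates))}
    if "lib_size" in covariates:
        parts["log_depth"] = np.log(covariates["lib_size"].to_numpy(dtype=float))
    for col in ("protocol", "smoking", "gender"):
        if col in covariates:
            dummies = pd.get_dummies(covariates[col], prefix=col, drop_first=True)
            for c in dummies.columns:
                parts[c] = dummies[c].to_numpy(dtype=float)
    if "age" in covariates:
        parts["age"] = covariates["age"].to_numpy(dtype=float)
    if include_disease and "disease" in covariates:
        disease = covariates["disease"]
        parts["copd"] = (disease == "COPD").to_numpy(dtype=float)
        parts["ild"] = (disease == "ILD").to_numpy(dtype=float)
    return pd.DataFrame(parts, index=covariates.index)


def de_scan(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    q_thresh: float = 0.1,
    coef_thresh: float = 0.22,
) -> pd.DataFrame:
    """Per-miRNA NB-GLM disease scan: full vs no-disease LRT, BH, FC call.

    Returns a table with the ANOVA p, q, COPD/ILD log coefficients, fold
    changes and the ``called`` flag.
    """
    full_design = build_design(covariates, include_disease=True)
    red_design = build_design(covariates, include_disease=False)
    rows = []
    for mirna, y in counts.iterrows():
        yv = y.to_numpy(dtype=float)
        if not yv.any():
            rows.append({"mirna": mirna, "p_anova": np.nan,
                         "coef_copd": np.nan, "coef_ild": np.nan})
            continue
        full = fit_nb_glm(yv, full_design)
        red = fit_nb_glm(yv, red_design)
        rows.append(
            {
                "mirna": mirna,
                "p_anova": lrt_disease(full, red),
                "coef_copd": full.coefficients["copd"],
                "coef_ild": full.coefficients["ild"],
            }
        )
    table = pd.DataFrame(rows).set_index("mirna")
    return call_differential(table, q_thresh=q_thresh, coef_thresh=coef_thresh)


def call_differential(
    results: pd.DataFrame, q_thresh: float = 0.1, coef_thresh: float = 0.22
) -> pd.DataFrame:
    """Apply the FDR + fold-change rule to a DE table.

    ``results`` needs columns ``p_anova``, ``coef_copd``, ``coef_ild``;
    adds ``q``, ``fc_copd``, ``fc_ild`` (exp of the coefficients) and
    ``called`` = (q < q_thresh) & (max |coef| > coef_thresh).
    """
    out = results.copy()
    out["q"] = bh_fdr(out["p_anova"])
    out["fc_copd"] = np.exp(out["coef_copd"])
    out["fc_ild"] = np.exp(out["coef_ild"])
    max_coef = np.maximum(out["coef_copd"].abs(), out["coef_ild"].abs())
    out["called"] = (out["q"] < q_thresh) & (max_coef > coef_thresh)
    return out
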