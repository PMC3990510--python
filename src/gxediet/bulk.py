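"""Vectorized per-study engines for genome-scale scans.

The single-SNP API in :mod:`gxediet.models` is the reference implementation;
these engines compute the same quantities for thousands of SNPs at once and
are cross-checked against it in the test suite.

* :func:`logistic_score_scan` — score test of each SNP's dosage added to a
  covariates-only logistic disease model (marginal-association screen), with
  the METAL-style one-step effect ``U/V`` and ``se = V**-0.5``;
* :func:`ols_scan` — covariate-adjusted linear coefficient of one design
  column for many response vectors at once (the G-on-E correlation screen in
  everyone and the case-only test among cases);
* :func:`batch_interaction_wald` — batched Newton-Raphson logistic fits of
  ``D ~ G + E + G*E + covariates`` returning the Wald interaction term.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit


def _with_const(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def logistic_score_scan(
    y: np.ndarray, covariates: np.ndarray, G: np.ndarray
) -> pd.DataFrame:
    """Score test for each dosage row of ``G`` (m x n) on the binary outcome.

    The covariates-only null model is fit once; each SNP's score statistic is
    U = G'(y - p0) with variance V = G'WG - G'WX (X'WX)^-1 X'WG.  Returns a
    frame with one-step beta = U/V, se = V**-0.5, z and two-sided p.
    """
    y = np.asarray(y, float)
    X = _with_const(np.asarray(covariates, float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    p0 = fit.predict(X)
    w = p0 * (1.0 - p0)
    U = G @ (y - p0)
    a = np.einsum("mn,n,mn->m", G, w, G)
    B = G @ (X * w[:, None])  # (m, p)
    xtwx = X.T @ (X * w[:, None])
    V = a - np.einsum("mp,pm->m", B, np.linalg.solve(xtwx, B.T))
    V = np.where(V > 1e-12, V, np.nan)
    beta = U / V
    se = 1.0 / np.sqrt(V)
    z = U / np.sqrt(V)
    return pd.DataFrame(
        {"beta": beta, "se": se, "z": z, "p": 2.0 * stats.norm.sf(np.abs(z))}
    )


def ols_scan(
    responses: np.ndarray, design: np.ndarray, target_col: int
) -> pd.DataFrame:
    """OLS coefficient of ``design[:, target_col]`` for many responses.

    ``responses`` is (m, n): one row per SNP dosage vector; ``design`` (n, p)
    must already include an intercept.  Returns beta/se/z/p of the target
    column per response row.
    """
    Y = np.asarray(responses, float).T  # (n, m)
    X = np.asarray(design, float)
    n, p = X.shape
    xtx = X.T @ X
    H = np.linalg.inv(xtx)
    coef = H @ (X.T @ Y)  # (p, m)
    resid = Y - X @ coef
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * H[target_col, target_col], 0.0))
    beta = coef[target_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    return pd.DataFrame(
        {"beta": beta, "se": se, "z": z, "p": 2.0 * stats.norm.sf(np.abs(z))}
    )


def batch_interaction_wald(
    y: np.ndarray,
    covariates: np.ndarray,
    e: np.ndarray,
    G: np.ndarray,
    chunk: int = 128,
    max_iter: int = 25,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Wald test of the G*E product term for many SNPs.

    Fits ``logit P(y) ~ 1 + covariates + E + G + G*E`` per dosage row of
    ``G`` by batched Newton-Raphson (a small ridge keeps degenerate designs
    from aborting the batch; such fits are reported unconverged).  Returns
    beta/se/z/p of the interaction term plus a ``converged`` flag.
    """
    y = np.asarray(y, float)
    e = np.asarray(e, float)
    Xb = np.column_stack([_with_const(np.asarray(covariates, float)), e])
    n, pb = Xb.shape
    p = pb + 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sm.Logit(y, Xb).fit(disp=0, maxiter=200)
    beta0 = np.concatenate([np.asarray(base.params), [0.0, 0.0]])

    m = G.shape[0]
    beta_ge = np.full(m, np.nan)
    se_ge = np.full(m, np.nan)
    conv = np.zeros(m, bool)
    ridge = 1e-9 * np.eye(p)

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        c = hi - lo
        Xs = np.empty((c, n, p))
        Xs[:, :, :pb] = Xb
        Xs[:, :, pb] = G[lo:hi]
        Xs[:, :, pb + 1] = G[lo:hi] * e
        Xt = np.ascontiguousarray(Xs.transpose(0, 2, 1))  # (c, p, n)
        beta = np.tile(beta0, (c, 1))
        done = np.zeros(c, bool)
        hess = None
        for _ in range(max_iter):
            mu = expit(np.matmul(Xs, beta[:, :, None])[:, :, 0])
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            grad = np.matmul(Xt, (y[None, :] - mu)[:, :, None])[:, :, 0]
            hess = np.matmul(Xt * w[:, None, :], Xs)
            step = np.linalg.solve(hess + ridge, grad[..., None])[..., 0]
            np.clip(step, -5.0, 5.0, out=step)
            beta += step
            done = np.abs(step).max(axis=1) < tol
            if done.all():
                break
        # observed-information variance of the interaction coefficient; the
        # Hessian from the last iteration is at most one sub-tolerance step
        # away from the optimum, so it serves as the covariance directly
        try:
            cov = np.linalg.inv(hess + ridge)
            var = cov[:, pb + 1, pb + 1]
        except np.linalg.LinAlgError:
            var = np.full(c, np.nan)
        b = beta[:, pb + 1]
        s = np.sqrt(np.where(var > 0, var, np.nan))
        ok = done & np.isfinite(b) & np.isfinite(s) & (s < 100.0)
        beta_ge[lo:hi] = np.where(ok, b, np.nan)
        se_ge[lo:hi] = np.where(ok, s, np.nan)
        conv[lo:hi] = ok

    with np.errstate(invalid="ignore"):
        z = beta_ge / se_ge
    return pd.DataFrame(
        {
            "beta": beta_ge,
            "se": se_ge,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "converged": conv,
        }
    )


def case_only_scan(
    G: np.ndarray,
    covariates: np.ndarray,
    e: np.ndarray,
    cases: np.ndarray,
    rescale: bool = True,
) -> pd.DataFrame:
    """Case-only interaction scan: adjusted linear G-on-E among cases.

    Asymptotically equivalent to the per-allele logistic case-only test; when
    ``rescale`` is set, beta and se are divided by the per-SNP dosage
    variance among cases so the estimate is on the interaction log-odds
    scale (the z statistic and p-value are invariant to this rescaling).
    """
    cases = np.asarray(cases, bool)
    Gc = G[:, cases]
    X = np.column_stack(
        [_with_const(np.asarray(covariates, float)[cases]), np.asarray(e, float)[cases]]
    )
    out = ols_scan(Gc, X, target_col=X.shape[1] - 1)
    if rescale:
        v = Gc.var(axis=1, ddof=1)
        v = np.where(v > 0, v, np.nan)
        out["beta"] = out["beta"] / v
        out["se"] = out["se"] / v
    return out


def ge_correlation_scan(
    G: np.ndarray, covariates: np.ndarray, e: np.ndarray
) -> pd.DataFrame:
    """Adjusted linear G-on-E screen in cases and controls combined."""
    X = np.column_stack([_with_const(np.asarray(covariates, float)), np.asarray(e, float)])
    return ols_scan(G, X, target_col=X.shape[1] - 1)
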