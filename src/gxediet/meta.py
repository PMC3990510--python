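"""Fixed-effects meta-analysis, Woolf heterogeneity and QQ diagnostics.

Per-study log-odds coefficients are pooled by inverse-variance weighting:
w_i = 1/se_i^2, pooled beta = sum(w_i b_i)/sum(w_i), pooled se =
sum(w_i)^-0.5, with Wald z and two-sided normal p.  Heterogeneity follows
Woolf's chi-square: Q = sum w_i (b_i - b_pooled)^2 on k-1 degrees of
freedom.  QQ diagnostics report expected vs observed -log10 p and the
genomic inflation factor lambda (median observed one-df chi-square over the
null median).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssocResult, MetaResult

#: Median of the chi-square distribution with one degree of freedom.
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def fixed_effects_meta(results: Sequence[AssocResult]) -> MetaResult:
    """Pool per-study coefficients; non-converged studies are excluded.

    Raises on empty input (or when no study converged).  With a single
    usable study the pooled result equals that study's and the heterogeneity
    statistic is undefined (emitted as missing, not 1).
    """
    usable = [r for r in results if r.converged and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise ValueError("no converged per-study results to pool")
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    beta, se = _pool(betas, ses)
    z = beta / se
    p = max(2.0 * stats.norm.sf(abs(z)), 5e-324)
    q, p_het = woolf_heterogeneity(betas, ses, beta)
    first = usable[0]
    return MetaResult(
        term=first.term, beta=beta, se=se, z=z, p=p, k=len(usable),
        q_stat=q, p_het=p_het, snp_id=first.snp_id, exposure=first.exposure,
        per_study=list(usable),
    )


def _pool(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    w = 1.0 / ses**2
    return float((w * betas).sum() / w.sum()), float(w.sum() ** -0.5)


def woolf_heterogeneity(
    betas: np.ndarray, ses: np.ndarray, beta_meta: Optional[float] = None
) -> tuple[Optional[float], Optional[float]]:
    """Woolf's heterogeneity test on log odds ratios.

    Q = sum w_i (b_i - b_meta)^2 ~ chi-square(k-1) under homogeneity.
    Undefined for k < 2 (returns (None, None)).
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    k = len(betas)
    if k < 2:
        return None, None
    w = 1.0 / ses**2
    if beta_meta is None:
        beta_meta = (w * betas).sum() / w.sum()
    q = float((w * (betas - beta_meta) ** 2).sum())
    p = float(stats.chi2.sf(q, k - 1))
    return q, max(p, 5e-324)


def meta_scan(
    betas: np.ndarray, ses: np.ndarray, valid: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Vectorized fixed-effects meta over a (k studies x m SNPs) grid.

    ``valid`` masks per-study-per-SNP usable results (e.g. QC failures or
    non-converged fits); SNPs with no usable study get NaN.  Returns
    beta/se/z/p/k/q_stat/p_het per SNP.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if valid is None:
        valid = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(valid, 1.0 / ses**2, 0.0)
        sw = w.sum(axis=0)
        k = valid.sum(axis=0)
        beta = np.where(sw > 0, (w * np.where(valid, betas, 0.0)).sum(axis=0) / sw, np.nan)
        se = np.where(sw > 0, sw**-0.5, np.nan)
        z = beta / se
        q = (w * np.where(valid, (betas - beta[None, :]) ** 2, 0.0)).sum(axis=0)
        q = np.where(k >= 2, q, np.nan)
        p_het = stats.chi2.sf(q, np.maximum(k - 1, 1))
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "k": k,
            "q_stat": q,
            "p_het": p_het,
        }
    )


def qq_diagnostics(pvalues: Sequence[float]) -> tuple[pd.DataFrame, float]:
    """Expected vs observed -log10 p plus the genomic inflation factor.

    Expected quantiles are -log10((i - 0.5)/m) for ranked p-values; lambda
    is the median observed chi-square (1 df, from p) over the chi-square
    median 0.4549.  Raises on empty input or p outside (0, 1].
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    obs = np.sort(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(obs)
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / _CHI2_1_MEDIAN)
    table = pd.DataFrame({"expected": expected, "observed": observed})
    return table, lam
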