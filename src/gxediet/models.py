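"""Per-study regression models for the gene-diet interaction analysis.

Every model is fit separately within each study and adjusted for the minimal
covariate set (age, sex, total energy when available, first three principal
components); study/center is handled by the per-study design itself.  SNPs
enter as allele dosage (0-2, fractional for imputed SNPs, log-additive) and
diet as the harmonized ordinal quartile code.

Models provided:

* ``fit_logistic`` — general covariate-adjusted logistic fit (Wald inference);
* ``gxe_interaction`` — case-control interaction model with the SNP x diet
  product term;
* ``case_only_test`` — per-allele logistic regression of the dosage on diet
  among cases (binomial GLM on dosage/2 with two trials); under population
  G-E independence and rare disease its diet coefficient estimates the
  multiplicative interaction directly, with smaller variance than the
  case-control test;
* ``ge_correlation_test`` — covariate-adjusted linear association of dosage
  on diet in cases and controls combined (the screening statistic for
  gene-environment correlation);
* ``stratified_by_genotype`` — per-quartile diet odds ratios within
  best-guess genotype strata.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import AssocResult, MINIMAL_COVARIATES, StudyDataset

LOW_N_CASES = 50
LOW_N_STRATUM = 20


def drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant/collinear columns (QR pivot), keeping earlier terms."""
    dropped: list[str] = []
    mat = X.to_numpy(dtype=float)
    keep: list[int] = []
    for j in range(mat.shape[1]):
        cand = mat[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    return X.iloc[:, keep], dropped


def _design(
    data: pd.DataFrame, terms: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    X = data.loc[:, list(terms)].astype(float)
    X.insert(0, "const", 1.0)
    return drop_collinear(X)


def _wald_results(
    params, bse, n: int, converged: bool, study_id: str, model: str, **ids
) -> dict[str, AssocResult]:
    out = {}
    for term in params.index:
        if term == "const":
            continue
        beta, se = float(params[term]), float(bse[term])
        ok = converged and np.isfinite(beta) and np.isfinite(se) and se > 0
        z = beta / se if ok else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if ok else np.nan
        out[term] = AssocResult(
            study_id=study_id, term=term, beta=beta, se=se, z=z,
            p=max(p, 5e-324) if ok else np.nan, n_used=n,
            converged=ok, model=model, **ids,
        )
    return out


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    study_id: str = "",
    model: str = "logistic",
    **ids,
) -> dict[str, AssocResult]:
    """Maximum-likelihood logistic fit with Wald SEs and two-sided normal p.

    Rows with any missing value among outcome/terms are dropped; collinear
    terms are dropped with a flag; non-convergence or separation is reported
    through ``converged=False``, never silently.
    """
    cols = [outcome, *terms]
    d = data.loc[:, cols].dropna()
    y = d[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome} needs both classes present")
    X, dropped = _design(d, terms)
    converged = True
    flags = tuple(f"DROPPED:{t}" for t in dropped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, bse = fit.params, fit.bse
        except Exception:
            converged = False
            params = pd.Series(np.nan, index=X.columns)
            bse = pd.Series(np.nan, index=X.columns)
    res = _wald_results(params, bse, len(d), converged, study_id, model, **ids)
    for t in dropped:
        res[t] = AssocResult(
            study_id=study_id, term=t, beta=np.nan, se=np.nan, z=np.nan,
            p=np.nan, n_used=len(d), converged=False, model=model,
            flags=("NOT_ESTIMABLE",), **ids,
        )
    if flags:
        res = {
            t: AssocResult(**{**r.__dict__, "flags": r.flags + flags})
            for t, r in res.items()
        }
    return res


def _frame_with_snp(
    dataset: StudyDataset, dosage: np.ndarray, exposure: str,
    covariates: Optional[Sequence[str]],
) -> tuple[pd.DataFrame, list[str], str]:
    pheno = dataset.phenotypes
    eq = f"{exposure}_q"
    if eq not in pheno.columns:
        raise ValueError(f"exposure {exposure} is not harmonized (missing {eq})")
    d = pheno.copy()
    d["G"] = np.asarray(dosage, dtype=float)
    requested = MINIMAL_COVARIATES if covariates is None else covariates
    covs = dataset.covariate_columns(requested)
    return d, covs, eq


def gxe_interaction(
    dataset: StudyDataset,
    dosage: np.ndarray,
    snp_id: str,
    exposure: str,
    covariates: Optional[Sequence[str]] = None,
) -> AssocResult:
    """Case-control interaction model; returns the SNP x diet product term.

    logit P(case) ~ G + E_q + G*E_q + covariates, where the returned
    coefficient is the interaction log-odds per count allele per quartile
    increment, with SNP and diet main effects retained.
    """
    d, covs, eq = _frame_with_snp(dataset, dosage, exposure, covariates)
    d["GxE"] = d["G"] * d[eq]
    if np.nanstd(d["GxE"].to_numpy()) == 0:
        return AssocResult(
            study_id=dataset.study_id, term="GxE", beta=np.nan, se=np.nan,
            z=np.nan, p=np.nan, n_used=0, converged=False, snp_id=snp_id,
            exposure=exposure, model="cc_interaction", flags=("NOT_ESTIMABLE",),
        )
    res = fit_logistic(
        d, "case", ["G", eq, "GxE", *covs], study_id=dataset.study_id,
        model="cc_interaction", snp_id=snp_id, exposure=exposure,
    )
    return res["GxE"]


def case_only_test(
    dataset: StudyDataset,
    dosage: np.ndarray,
    snp_id: str,
    exposure: str,
    covariates: Optional[Sequence[str]] = None,
) -> AssocResult:
    """Case-only interaction test: per-allele logistic G-on-E among cases.

    The dosage/2 is modelled as a two-trial binomial with logit link on the
    quartile code plus covariates; the diet coefficient estimates the
    interaction log-odds under G-E independence and rare disease.  Results
    are flagged ``LOW_N`` below 50 cases.
    """
    d, covs, eq = _frame_with_snp(dataset, dosage, exposure, covariates)
    d = d[d["case"] == 1].dropna(subset=["G", eq, *covs])
    flags: tuple[str, ...] = ("LOW_N",) if len(d) < LOW_N_CASES else ()
    X, dropped = _design(d, [eq, *covs])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                d["G"].to_numpy() / 2.0,
                X,
                family=sm.families.Binomial(),
                var_weights=np.full(len(d), 2.0),
            ).fit()
        beta, se = float(fit.params[eq]), float(fit.bse[eq])
        ok = np.isfinite(beta) and np.isfinite(se) and se > 0
    except Exception:
        beta, se, ok = np.nan, np.nan, False
    z = beta / se if ok else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if ok else np.nan
    return AssocResult(
        study_id=dataset.study_id, term=eq, beta=beta, se=se, z=z,
        p=max(p, 5e-324) if ok else np.nan, n_used=len(d), converged=ok,
        snp_id=snp_id, exposure=exposure, model="case_only", flags=flags,
    )


def ge_correlation_test(
    dataset: StudyDataset,
    dosage: np.ndarray,
    snp_id: str,
    exposure: str,
    covariates: Optional[Sequence[str]] = None,
) -> AssocResult:
    """Gene-environment correlation screen in cases and controls combined.

    Covariate-adjusted linear regression of the dosage on the quartile code;
    the Wald z of the diet coefficient is the screening statistic.
    """
    d, covs, eq = _frame_with_snp(dataset, dosage, exposure, covariates)
    d = d.dropna(subset=["G", eq, *covs])
    X, _ = _design(d, [eq, *covs])
    fit = sm.OLS(d["G"].to_numpy(), X).fit()
    beta, se = float(fit.params[eq]), float(fit.bse[eq])
    z = beta / se if se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return AssocResult(
        study_id=dataset.study_id, term=eq, beta=beta, se=se, z=z, p=p,
        n_used=len(d), converged=np.isfinite(z), snp_id=snp_id,
        exposure=exposure, model="ge_correlation",
    )


def marginal_snp_test(
    dataset: StudyDataset,
    dosage: np.ndarray,
    snp_id: str,
    covariates: Optional[Sequence[str]] = None,
) -> AssocResult:
    """Marginal SNP-on-disease logistic model (screening statistic)."""
    pheno = dataset.phenotypes.copy()
    pheno["G"] = np.asarray(dosage, dtype=float)
    covs = dataset.covariate_columns(
        MINIMAL_COVARIATES if covariates is None else covariates
    )
    res = fit_logistic(
        pheno, "case", ["G", *covs], study_id=dataset.study_id,
        model="marginal_g", snp_id=snp_id,
    )
    return res["G"]


def stratified_by_genotype(
    dataset: StudyDataset,
    dosage: np.ndarray,
    snp_id: str,
    exposure: str,
    covariates: Optional[Sequence[str]] = None,
) -> list[AssocResult]:
    """Per-quartile diet effect within each best-guess genotype stratum.

    Dosages are rounded to 0/1/2 for stratification; each stratum's logistic
    model returns the diet odds ratio per quartile with Wald CI.  Strata
    with fewer than 20 subjects are flagged; empty strata are omitted.
    """
    d, covs, eq = _frame_with_snp(dataset, dosage, exposure, covariates)
    g = np.clip(np.rint(d["G"].to_numpy()), 0, 2)
    out = []
    for stratum in (0, 1, 2):
        sub = d[g == stratum]
        if len(sub) == 0 or sub["case"].nunique() < 2:
            continue
        res = fit_logistic(
            sub, "case", [eq, *covs], study_id=dataset.study_id,
            model=f"stratum_{stratum}", snp_id=snp_id, exposure=exposure,
        )
        r = res[eq]
        if len(sub) < LOW_N_STRATUM:
            r = AssocResult(**{**r.__dict__, "flags": r.flags + ("LOW_N",)})
        out.append(r)
    return out
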