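"""Two-step Cocktail gene-environment interaction scan.

Step 1 (screening): every SNP is ranked by the larger of two fixed-effects
meta-analysis |z| statistics — its marginal association with disease and its
correlation with the dietary variable in cases and controls combined.  SNPs
are then pruned by proximity (only the best SNP within +/-50 kb is retained)
and partitioned, in rank order, into groups of doubling size (5, 10, 20, ...)
with geometrically decaying per-test levels alpha/(2^j * n_j), so the total
budget never exceeds the overall level (0.05 by default).

Step 2 (testing): each retained SNP's interaction is tested with the
case-only test when its screening winner was the marginal association, and
with the case-control interaction test otherwise — using the correlation
screen together with the case-only test would inflate type I error, since
the two are not independent.  A SNP is declared significant when its chosen
test's meta-analysis p-value falls strictly below its group's cutoff.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bulk
from .harmonize import harmonize_study
from .meta import meta_scan
from .qc import filter_snps
from .types import SnpPanel, StudyDataset, WeightScheme

PRUNE_WINDOW_BP = 50_000
GENOME_WIDE_ALPHA = 5e-8  # 0.05 / 1,000,000 independent tests


def screen_statistics(
    meta_marginal: pd.DataFrame,
    meta_correlation: pd.DataFrame,
    snp_info: pd.DataFrame,
) -> pd.DataFrame:
    """Combine the two screens into per-SNP screening records.

    Inputs carry one row per SNP (column ``snp_id`` plus ``z``/``k``); SNPs
    present in only one screen, or with an undefined z in either, are
    excluded and reported in the ``note`` of the returned attrs.  Ties in the
    max statistic go to the marginal screen (which feeds the more efficient
    case-only test).
    """
    m = meta_marginal.set_index("snp_id")
    c = meta_correlation.set_index("snp_id")
    only_m = sorted(set(m.index) - set(c.index))
    only_c = sorted(set(c.index) - set(m.index))
    common = m.index.intersection(c.index)
    zm = m.loc[common, "z"].to_numpy()
    zc = c.loc[common, "z"].to_numpy()
    ok = np.isfinite(zm) & np.isfinite(zc)
    rec = pd.DataFrame(
        {
            "snp_id": np.asarray(common)[ok],
            "z_marginal": zm[ok],
            "z_correlation": zc[ok],
        }
    )
    rec["screen_stat"] = np.maximum(np.abs(rec.z_marginal), np.abs(rec.z_correlation))
    rec["screen_winner"] = np.where(
        np.abs(rec.z_marginal) >= np.abs(rec.z_correlation), "marginal", "correlation"
    )
    info = snp_info.set_index("snp_id")
    rec["chrom"] = info.loc[rec.snp_id, "chrom"].to_numpy()
    rec["pos"] = info.loc[rec.snp_id, "pos"].to_numpy()
    rec = rec[["snp_id", "chrom", "pos", "z_marginal", "z_correlation",
               "screen_stat", "screen_winner"]]
    rec.attrs["excluded"] = {"marginal_only": only_m, "correlation_only": only_c,
                             "undefined_z": sorted(np.asarray(common)[~ok])}
    return rec


def prune_by_proximity(
    records: pd.DataFrame, window: int = PRUNE_WINDOW_BP
) -> pd.DataFrame:
    """Greedy proximity pruning: keep the best SNP, drop neighbours.

    Repeatedly retains the SNP with the highest remaining screen statistic
    (ties broken by chromosome then position, for determinism) and prunes
    every other SNP on the same chromosome within ``window`` base pairs.
    Output order and flags are independent of input order.
    """
    rec = records.sort_values(
        ["screen_stat", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)
    pruned = np.zeros(len(rec), bool)
    decided = np.zeros(len(rec), bool)
    chrom = rec["chrom"].to_numpy()
    pos = rec["pos"].to_numpy(dtype=np.int64)
    for i in range(len(rec)):
        if decided[i]:
            continue
        decided[i] = True  # retained
        near = (
            ~decided
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        pruned |= near
        decided |= near
    rec["pruned"] = pruned
    return rec


def assign_weight_groups(
    records: pd.DataFrame, scheme: WeightScheme = WeightScheme()
) -> pd.DataFrame:
    """Rank retained SNPs and attach weighted-testing group cutoffs.

    Retained SNPs are ranked 1..m by descending screen statistic (ties by
    chromosome/position); rank r falls in the group given by the doubling
    scheme, with per-test level alpha/(2^j * n_j).  Pruned SNPs get no rank.
    """
    rec = records.copy()
    rec["rank"] = pd.NA
    rec["group_index"] = pd.NA
    rec["alpha_cutoff"] = np.nan
    kept = rec.index[~rec["pruned"]]
    order = rec.loc[kept].sort_values(
        ["screen_stat", "chrom", "pos"], ascending=[False, True, True]
    ).index
    ranks = np.arange(1, len(order) + 1)
    rec.loc[order, "rank"] = ranks
    groups = np.array([scheme.group_of_rank(r) for r in ranks])
    rec.loc[order, "group_index"] = groups
    rec.loc[order, "alpha_cutoff"] = [scheme.group_alpha(j) for j in groups]
    return rec


def hybrid_test(
    records: pd.DataFrame,
    co_p: pd.Series,
    cc_p: pd.Series,
) -> pd.DataFrame:
    """Choose and apply the testing-step p-value per retained SNP.

    Case-only when the screening winner was the marginal association, the
    case-control interaction test otherwise.  When the chosen test is not
    estimable the other one is used with a ``FALLBACK`` flag (conservative:
    the case-control test is valid unconditionally).  Significance is a
    strict comparison against the group cutoff.
    """
    rec = records.copy()
    co = co_p.reindex(rec["snp_id"]).to_numpy()
    cc = cc_p.reindex(rec["snp_id"]).to_numpy()
    want_co = (rec["screen_winner"] == "marginal").to_numpy()
    chosen = np.where(want_co, "CO", "CC")
    p_test = np.where(want_co, co, cc)
    fallback = ~np.isfinite(p_test)
    p_test = np.where(fallback, np.where(want_co, cc, co), p_test)
    chosen = np.where(fallback, np.where(want_co, "CC", "CO"), chosen)
    rec["chosen_test"] = chosen
    rec["p_test"] = p_test
    rec["test_flag"] = np.where(fallback, "FALLBACK", "")
    tested = ~rec["pruned"] & np.isfinite(rec["alpha_cutoff"])
    rec["significant"] = tested & (rec["p_test"] < rec["alpha_cutoff"])
    rec.loc[rec["pruned"], ["chosen_test", "p_test"]] = [pd.NA, np.nan]
    return rec


def _study_arrays(
    dataset: StudyDataset,
    panel: SnpPanel,
    exposure: str,
    covariates: Optional[Sequence[str]],
):
    """Aligned outcome/covariate/exposure/dosage arrays for one study."""
    eq = f"{exposure}_q"
    if eq not in dataset.phenotypes.columns:
        harmonize_study(dataset, [exposure])
    pheno = dataset.phenotypes
    covs = dataset.covariate_columns(covariates) if covariates else dataset.covariate_columns()
    keep = pheno[eq].notna()
    for c in covs:
        keep &= pheno[c].notna()
    keep = keep.to_numpy()
    y = pheno.loc[keep, "case"].to_numpy(float)
    C = pheno.loc[keep, covs].to_numpy(float)
    e = pheno.loc[keep, eq].to_numpy(float)
    G = panel.dosages if keep.all() else panel.dosages[:, keep]
    return y, C, e, G


def _ensure_qc(dataset: StudyDataset, panel: SnpPanel) -> None:
    if "qc_pass" not in panel.snps.columns:
        controls = dataset.phenotypes["case"].to_numpy() == 0
        filter_snps(panel, controls)


def cocktail_scan(
    studies: Sequence[tuple[StudyDataset, SnpPanel]],
    exposure: str,
    scheme: WeightScheme = WeightScheme(),
    covariates: Optional[Sequence[str]] = None,
    window: int = PRUNE_WINDOW_BP,
) -> tuple[pd.DataFrame, dict]:
    """Run the full two-step scan across studies for one dietary exposure.

    Per study: QC filtering, score-test marginal screen, adjusted G-on-E
    correlation screen, case-only scan among cases; each statistic is pooled
    across studies by fixed-effects meta-analysis.  The case-control
    interaction test is fit (batched logistic) only where the testing step
    needs it.  Returns the per-SNP scan records and a summary block.
    """
    if not studies:
        raise ValueError("no studies")
    snp_info = studies[0][1].snps[["snp_id", "chrom", "pos"]]
    m = len(snp_info)

    per_study = []
    valid = np.zeros((len(studies), m), bool)
    for i, (ds, panel) in enumerate(studies):
        if not np.array_equal(panel.snps["snp_id"].to_numpy(), snp_info["snp_id"].to_numpy()):
            raise ValueError("studies carry different SNP panels")
        _ensure_qc(ds, panel)
        valid[i] = panel.snps["qc_pass"].to_numpy()
        per_study.append(_study_arrays(ds, panel, exposure, covariates))

    def _meta_over(results: list[pd.DataFrame]) -> pd.DataFrame:
        betas = np.vstack([r["beta"].to_numpy() for r in results])
        ses = np.vstack([r["se"].to_numpy() for r in results])
        out = meta_scan(betas, ses, valid)
        out.insert(0, "snp_id", snp_info["snp_id"].to_numpy())
        return out

    marg = _meta_over(
        [bulk.logistic_score_scan(y, C, G) for (y, C, e, G) in per_study]
    )
    corr = _meta_over(
        [bulk.ge_correlation_scan(G, C, e) for (y, C, e, G) in per_study]
    )
    co = _meta_over(
        [bulk.case_only_scan(G, C, e, y == 1) for (y, C, e, G) in per_study]
    )

    rec = screen_statistics(marg, corr, snp_info)
    excluded = rec.attrs.get("excluded", {})
    rec = prune_by_proximity(rec, window)
    rec = assign_weight_groups(rec, scheme)

    # case-control interaction fits only where the testing step needs them:
    # correlation winners, plus SNPs whose case-only test is unusable.
    co_p = co.set_index("snp_id")["p"]
    retained = rec[~rec["pruned"]]
    need_cc_ids = set(
        retained.loc[
            (retained["screen_winner"] == "correlation")
            | ~np.isfinite(co_p.reindex(retained["snp_id"]).to_numpy()),
            "snp_id",
        ]
    )
    idx = snp_info.index[snp_info["snp_id"].isin(need_cc_ids)].to_numpy()
    cc_p = pd.Series(np.nan, index=snp_info["snp_id"])
    if len(idx):
        parts = [
            bulk.batch_interaction_wald(y, C, e, G[idx]) for (y, C, e, G) in per_study
        ]
        betas = np.vstack([p_["beta"].to_numpy() for p_ in parts])
        ses = np.vstack([p_["se"].to_numpy() for p_ in parts])
        ok = np.vstack([p_["converged"].to_numpy() for p_ in parts]) & valid[:, idx]
        cc = meta_scan(betas, ses, ok)
        cc_p.iloc[idx] = cc["p"].to_numpy()

    rec = hybrid_test(rec, co_p, cc_p)
    n_by_group = (
        rec.loc[rec["significant"], "group_index"].value_counts().to_dict()
    )
    summary = {
        "exposure": exposure,
        "n_snps_input": m,
        "n_snps_screened": len(rec),
        "n_retained": int((~rec["pruned"]).sum()),
        "n_tested": int(rec["p_test"].notna().sum()),
        "n_significant": int(rec["significant"].sum()),
        "significant_by_group": {int(k): int(v) for k, v in n_by_group.items()},
        "alpha_total": scheme.alpha_total,
        "realized_budget": scheme.realized_budget(int((~rec["pruned"]).sum())),
        "excluded": excluded,
    }
    return rec, summary


def conventional_scan(
    studies: Sequence[tuple[StudyDataset, SnpPanel]],
    exposure: str,
    alpha: float = GENOME_WIDE_ALPHA,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Conventional case-control interaction scan at the genome-wide level.

    Fits the interaction model for every QC-passing SNP in every study,
    pools by fixed-effects meta-analysis and calls significance at the
    Bonferroni-style genome-wide threshold (5e-8 by default).
    """
    if not studies:
        raise ValueError("no studies")
    snp_info = studies[0][1].snps[["snp_id", "chrom", "pos"]]
    valid = np.zeros((len(studies), len(snp_info)), bool)
    parts = []
    for i, (ds, panel) in enumerate(studies):
        _ensure_qc(ds, panel)
        valid[i] = panel.snps["qc_pass"].to_numpy()
        y, C, e, G = _study_arrays(ds, panel, exposure, covariates)
        parts.append(bulk.batch_interaction_wald(y, C, e, G))
    betas = np.vstack([p_["beta"].to_numpy() for p_ in parts])
    ses = np.vstack([p_["se"].to_numpy() for p_ in parts])
    ok = np.vstack([p_["converged"].to_numpy() for p_ in parts]) & valid
    out = meta_scan(betas, ses, ok)
    out.insert(0, "snp_id", snp_info["snp_id"].to_numpy())
    out.insert(1, "chrom", snp_info["chrom"].to_numpy())
    out.insert(2, "pos", snp_info["pos"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out
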