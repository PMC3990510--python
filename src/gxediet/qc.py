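"""Per-SNP quality control: Hardy-Weinberg exact test and filter rules.

Filters mirror standard GWAS-consortium practice: genotyped SNPs fail on
call rate < 98% or lack of Hardy-Weinberg equilibrium in controls
(exact-test p < 1e-4); every SNP fails on per-study minor allele count <= 5;
imputed SNPs fail on imputation accuracy r^2 <= 0.3.  Reason codes are set
independently and a SNP passes QC iff it collects none.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import SnpPanel

HWE_ALPHA = 1e-4
CALL_RATE_MIN = 0.98
MAC_MIN = 5  # strictly greater than 5 passes
IMP_R2_MIN = 0.3  # strictly greater than 0.3 passes


@lru_cache(maxsize=100_000)
def _het_log_probs(n_rare: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele counts.

    For ``n_rare`` copies of the rarer allele among ``2*n_total`` alleles,
    P(n_het | n_rare, n_total) is supported on heterozygote counts with the
    parity of ``n_rare`` ranging up to ``n_rare`` (Levene-Haldane).  Returns
    (support, log-probabilities), normalized.
    """
    start = n_rare % 2
    het = np.arange(start, n_rare + 1, 2)
    n_rr = (n_rare - het) // 2
    n_cc = n_total - het - n_rr
    # log multinomial coefficient x 2^het, constant terms dropped pre-normalization
    logp = (
        het * np.log(2.0)
        - gammaln(n_rr + 1)
        - gammaln(het + 1)
        - gammaln(n_cc + 1)
    )
    logp -= logp.max()
    logp -= np.log(np.exp(logp).sum())
    return het, logp


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one.
    Monomorphic SNPs return p = 1 by convention; p is in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    n_rare = min(n_a, n_b)
    het, logp = _het_log_probs(n_rare, n)
    probs = np.exp(logp)
    obs = probs[np.searchsorted(het, n_ab)]
    # tolerance guards against ties broken by floating-point rounding
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Best-guess genotype counts (hom-other, het, hom-count) from dosages."""
    g = np.rint(np.asarray(dosages)).astype(int)
    g = np.clip(g, 0, 2)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def filter_snps(
    panel: SnpPanel,
    controls: np.ndarray,
    hwe_alpha: float = HWE_ALPHA,
    call_rate_min: float = CALL_RATE_MIN,
    mac_min: int = MAC_MIN,
    imp_r2_min: float = IMP_R2_MIN,
) -> pd.DataFrame:
    """Apply the per-SNP filters; returns the annotated metadata table.

    ``controls`` is a boolean mask over the panel's subjects.  Appends
    columns caf, mac, hwe_p, qc_reasons, qc_pass to ``panel.snps`` (dosages
    are never mutated).  HWE is evaluated on best-guess genotypes of
    genotyped SNPs in controls only; imputed SNPs are exempt (their accuracy
    filter is the r^2 rule).
    """
    controls = np.asarray(controls, dtype=bool)
    if controls.shape != (panel.n_subjects,):
        raise ValueError("controls mask must cover the panel's subjects")
    if not controls.any():
        raise ValueError("no controls available for QC")

    snps = panel.snps
    dos = panel.dosages
    n2 = 2.0 * panel.n_subjects
    total = dos.sum(axis=1)
    caf = total / n2
    mac = np.minimum(np.rint(total), np.rint(n2 - total)).astype(int)

    is_geno = (snps["type"] == "genotyped").to_numpy()
    hwe_p = np.full(len(snps), np.nan)
    geno_idx = np.flatnonzero(is_geno)
    if len(geno_idx):
        g = np.clip(np.rint(dos[np.ix_(geno_idx, controls)]), 0, 2)
        n0 = (g == 0).sum(axis=1)
        n1 = (g == 1).sum(axis=1)
        n2 = (g == 2).sum(axis=1)
        for j, i in enumerate(geno_idx):
            hwe_p[i] = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))

    call_rate = snps["call_rate"].to_numpy(float)
    imp_r2 = snps["imputation_r2"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        fail_cr = is_geno & (call_rate < call_rate_min)
        fail_hwe = is_geno & (hwe_p < hwe_alpha)
        fail_mac = mac <= mac_min
        fail_r2 = ~is_geno & ~(imp_r2 > imp_r2_min)
    reasons = [
        ",".join(
            tag
            for tag, bad in (
                ("CALL_RATE", cr), ("HWE", hw), ("MAC", mc), ("IMP_R2", r2f)
            )
            if bad
        )
        for cr, hw, mc, r2f in zip(fail_cr, fail_hwe, fail_mac, fail_r2)
    ]

    out = snps.copy()
    out["caf"] = caf
    out["mac"] = mac
    out["hwe_p"] = hwe_p
    out["qc_reasons"] = reasons
    out["qc_pass"] = [r == "" for r in reasons]
    panel.snps = out
    return out
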