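"""Calibration experiments: FWER, effect recovery, null calibration.

These are the simulation studies that validate the pipeline end to end:

* family-wise error of the full Cocktail scan under a complete-null
  consortium (4 studies x 1,000 cases + 1,000 controls, 2,000 independent
  genotyped SNPs per replicate);
* recovery of a planted interaction odds ratio (1.17 per count allele per
  processed-meat quartile) and of a planted marginal red-meat odds ratio
  (1.15 per quartile) at the full ten-study consortium scale
  (~9,300 cases / ~9,100 controls);
* the default exposure-correlation profile measured on generated data;
* uniformity of interaction p-values and Woolf heterogeneity p-values under
  the null, and the genomic inflation factor of a null scan.

Every function takes a single integer seed and is deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cocktail import cocktail_scan
from .harmonize import harmonize_study
from .meta import fixed_effects_meta, meta_scan, qq_diagnostics, woolf_heterogeneity
from .models import fit_logistic, gxe_interaction
from .synthetic import (
    BASE_MEANS,
    BASE_SDS,
    default_consortium,
    generate_consortium,
    generate_exposures,
    hit_snp_id,
)
from .types import (
    GeneratorConfig,
    StudySpec,
    TrueEffects,
    WeightScheme,
    default_exposure_correlation,
)


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# exposure correlation (generator calibration)
# ---------------------------------------------------------------------------

def exposure_correlation_estimate(
    seed: int, n: int = 10_000
) -> dict[tuple[str, str], float]:
    """Sample Pearson correlations of generated exposures, default profile."""
    spec = StudySpec(
        "calibration", n, 0,
        exposure_means=dict(BASE_MEANS), exposure_sds=dict(BASE_SDS),
    )
    df = generate_exposures(spec, default_exposure_correlation(), n, seed)
    pairs = [("fruit", "vegetable"), ("fruit", "fiber"), ("red_meat", "processed_meat")]
    return {
        (a, b): float(np.corrcoef(df[a], df[b])[0, 1]) for a, b in pairs
    }


# ---------------------------------------------------------------------------
# FWER of the cocktail scan under the complete null
# ---------------------------------------------------------------------------

def null_config(
    seed: int,
    n_studies: int = 4,
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_snps: int = 2000,
) -> GeneratorConfig:
    """Complete-null consortium: one exposure, no planted effects.

    SNPs are directly genotyped hard calls; every genetic and interaction
    effect is zero, so any significant call is a false positive.
    """
    studies = [
        StudySpec(
            f"null_{i + 1:02d}", n_cases, n_controls,
            exposure_means={"processed_meat": BASE_MEANS["processed_meat"]},
            exposure_sds={"processed_meat": BASE_SDS["processed_meat"]},
        )
        for i in range(n_studies)
    ]
    return GeneratorConfig(
        studies=studies,
        exposures=("processed_meat",),
        n_snps=n_snps,
        imputed_fraction=0.0,
        seed=seed,
    )


def fwer_replicate(seed: int, scheme: WeightScheme = WeightScheme(), **kw) -> bool:
    """One null replicate; True if the scan makes any significant call."""
    data = generate_consortium(null_config(seed, **kw))
    _, summary = cocktail_scan(data, "processed_meat", scheme=scheme)
    return summary["n_significant"] > 0

def fwer_simulation(
    seed: int, n_replicates: int = 200, progress=None, **kw
) -> dict:
    """Family-wise rejection rate over null replicates, with MC error."""
    hits = 0
    for r in range(n_replicates):
        hits += fwer_replicate(_child_seed(seed, r), **kw)
        if progress and (r + 1) % 25 == 0:
            progress(f"  fwer replicate {r + 1}/{n_replicates}: {hits} rejections")
    rate = hits / n_replicates
    mc_se = math.sqrt(max(rate * (1 - rate), 1.0 / n_replicates) / n_replicates)
    return {"fwer": rate, "mc_se": mc_se, "n_replicates": n_replicates,
            "alpha_total": WeightScheme().alpha_total}


# ---------------------------------------------------------------------------
# planted-effect recovery at consortium scale
# ---------------------------------------------------------------------------

def interaction_recovery_replicate(seed: int, n_snps: int = 22) -> float:
    """Pooled interaction log-OR estimate for one consortium replicate.

    The full ten-study consortium with the headline processed-meat
    interaction planted on the chromosome-10 hit SNP; per-study logistic
    interaction fits are combined by fixed-effects meta-analysis.
    """
    cfg = default_consortium(n_snps=n_snps, seed=seed, planted=True)
    hit = hit_snp_id(n_snps)
    fits = []
    for ds, panel in generate_consortium(cfg):
        harmonize_study(ds, ["processed_meat"])
        i = int(panel.snps.index[panel.snps["snp_id"] == hit][0])
        fit = gxe_interaction(ds, panel.dosages[i], hit, "processed_meat")
        if fit.converged:
            fits.append(fit)
    return fixed_effects_meta(fits).beta


def interaction_recovery(seed: int, n_replicates: int = 50, progress=None) -> dict:
    """Mean meta-analyzed interaction OR across replicates (planted 1.17)."""
    betas = []
    for r in range(n_replicates):
        betas.append(interaction_recovery_replicate(_child_seed(seed, 10_000 + r)))
        if progress and (r + 1) % 10 == 0:
            progress(f"  interaction replicate {r + 1}/{n_replicates}")
    ors = np.exp(betas)
    return {
        "mean_or": float(np.mean(ors)),
        "mc_se": float(np.std(ors, ddof=1) / math.sqrt(len(ors))),
        "n_replicates": n_replicates,
        "planted_or": 1.17,
    }


def marginal_recovery_replicate(seed: int) -> float:
    """Pooled per-quartile red-meat log-OR for one consortium replicate.

    Ten studies at full scale, marginal red-meat effect log(1.15) planted,
    no genetic effects; per-study logistic fit of disease on the quartile
    code plus covariates, pooled by fixed-effects meta-analysis.
    """
    cfg = default_consortium(n_snps=1, seed=seed, planted=False)
    cfg.true_effects = TrueEffects(
        beta_e={"red_meat": math.log(1.15)},
        covariate_betas={"age": 0.025, "sex": 0.25},
    )
    fits = []
    for ds, _panel in generate_consortium(cfg):
        harmonize_study(ds, ["red_meat"])
        covs = ds.covariate_columns()
        res = fit_logistic(
            ds.phenotypes, "case", ["red_meat_q", *covs], study_id=ds.study_id,
            model="marginal_e", exposure="red_meat",
        )["red_meat_q"]
        if res.converged:
            fits.append(res)
    return fixed_effects_meta(fits).beta


def marginal_recovery(seed: int, n_replicates: int = 50, progress=None) -> dict:
    """Mean meta-analyzed red-meat OR per quartile across replicates."""
    betas = []
    for r in range(n_replicates):
        betas.append(marginal_recovery_replicate(_child_seed(seed, 20_000 + r)))
        if progress and (r + 1) % 10 == 0:
            progress(f"  marginal replicate {r + 1}/{n_replicates}")
    ors = np.exp(betas)
    return {
        "mean_or": float(np.mean(ors)),
        "mc_se": float(np.std(ors, ddof=1) / math.sqrt(len(ors))),
        "n_replicates": n_replicates,
        "planted_or": 1.15,
    }


# ---------------------------------------------------------------------------
# null distributional calibration
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int, n_replicates: int = 1000, n_studies: int = 5, n: int = 400
) -> pd.DataFrame:
    """Interaction and heterogeneity p-values under a small-study null.

    Each replicate simulates ``n_studies`` homogeneous null studies (one
    SNP, one exposure), fits the per-study case-control interaction model
    and pools it; returns one row per replicate with the interaction p and
    Woolf heterogeneity p.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        betas, ses = [], []
        for _s in range(n_studies):
            g = rng.binomial(2, 0.3, n).astype(float)
            e = rng.integers(1, 5, n).astype(float)
            y = (rng.random(n) < 0.5).astype(float)
            d = pd.DataFrame({"case": y, "G": g, "E": e, "GxE": g * e})
            res = fit_logistic(d, "case", ["G", "E", "GxE"])["GxE"]
            if res.converged:
                betas.append(res.beta)
                ses.append(res.se)
        m = meta_scan(np.array(betas)[:, None], np.array(ses)[:, None])
        q, p_het = woolf_heterogeneity(np.array(betas), np.array(ses))
        rows.append({"p_interaction": float(m["p"][0]), "p_het": p_het})
    return pd.DataFrame(rows)


def null_scan_lambda(seed: int, **kw) -> float:
    """Genomic inflation factor of one null cocktail screen's CC p-values."""
    from .cocktail import conventional_scan

    data = generate_consortium(null_config(seed, **kw))
    scan = conventional_scan(data, "processed_meat")
    _, lam = qq_diagnostics(scan["p"].dropna())
    return lam
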