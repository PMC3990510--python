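"""Synthetic multi-study case-control consortium generator.

Emulates the statistical structure a genome-wide gene-diet interaction scan
assumes: roughly ten unequal case-control studies (~9,300 cases / ~9,100
controls in total), sex- and study-specific dietary intake distributions with
realistic inter-exposure correlations (fruit-vegetable 0.38, fruit-fiber 0.52,
red-processed meat 0.62), SNP dosages in Hardy-Weinberg equilibrium with
study-varying allele frequencies, imputation noise at a stated accuracy, and
plantable marginal and interaction log-odds effects.

Disease status is generated retrospectively: a population pool is simulated
under the logistic model

    logit P(D=1) = b0 + bG*G + bE*E_q + bGE*G*E_q + gamma'C

with the intercept calibrated to a ~5% prevalence (the rare-disease regime
under which the case-only interaction test is valid), and exactly the
requested numbers of cases and controls are drawn from the pool.  SNPs with
no planted effect are exchangeable with respect to disease status, so they
are simulated directly for the sampled subjects; SNPs with planted effects
are simulated for the whole pool.

Planted effects act on the *true* genotype; the emitted dosage is the noisy
measurement, so imputed risk SNPs show the expected mild attenuation.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .harmonize import CATEGORY_CODE_MAP
from .types import (
    EXPOSURES,
    GeneratorConfig,
    SnpPanel,
    StudyDataset,
    StudySpec,
    TrueEffects,
    validate_correlation,
)

#: Dosage jitter SD for imputed SNPs (latent proxy construction).
_IMPUTE_JITTER = 0.04

#: Hard cap on the population-pool size per study.
_POOL_CAP = 2_000_000

#: Default male/female multiplicative shifts on exposure means.
DEFAULT_SEX_SHIFT = {
    "red_meat": 1.20,
    "processed_meat": 1.25,
    "vegetable": 0.90,
    "fruit": 0.85,
    "fiber": 1.05,
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

def generate_exposures(
    spec: StudySpec,
    corr: pd.DataFrame,
    n: int,
    seed,
    sex: Optional[np.ndarray] = None,
    sex_shift: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Draw per-subject dietary exposures for one study.

    A Gaussian copula on the latent scale carries the configured pairwise
    correlations; each margin is scaled to the study's mean/SD and truncated
    at zero (intakes cannot be negative).  When ``sex`` is given (1=male),
    male means are multiplied by ``sex_shift`` to emulate sex-specific intake.
    Exposures the study recorded coarsely (``spec.n_exposure_categories`` < 4)
    are emitted as integer category indices 1..k from equal-probability bins
    of the underlying continuous value (computed within sex when available).
    """
    rng = _as_rng(seed)
    exposures = list(corr.columns)
    mat = validate_correlation(corr)
    if n == 0:
        return pd.DataFrame({e: pd.Series(dtype=float) for e in exposures})

    # eigenvalue factorization tolerates semi-definite matrices
    w, v = np.linalg.eigh(mat)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(exposures))) @ root.T

    shift = sex_shift or {}
    out = {}
    for j, e in enumerate(exposures):
        mean = spec.exposure_means.get(e, 1.0)
        sd = spec.exposure_sds.get(e, max(0.5 * mean, 0.25))
        means = np.full(n, mean)
        if sex is not None and e in shift:
            means = np.where(np.asarray(sex) == 1, mean * shift[e], mean)
        x = np.clip(means + sd * z[:, j], 0.0, None)
        k = spec.n_exposure_categories.get(e, 4)
        if k < 4:
            out[e] = _categorize(x, k, sex)
        else:
            out[e] = x
    return pd.DataFrame(out)


def _categorize(x: np.ndarray, k: int, sex: Optional[np.ndarray]) -> np.ndarray:
    """Equal-probability binning into integer categories 1..k, within sex."""
    cats = np.empty(len(x), dtype=float)
    groups = [np.ones(len(x), bool)] if sex is None else [
        np.asarray(sex) == s for s in np.unique(sex)
    ]
    for g in groups:
        if not g.any():
            continue
        cuts = np.quantile(x[g], np.linspace(0, 1, k + 1)[1:-1])
        cats[g] = 1 + np.searchsorted(cuts, x[g], side="left")
    return cats


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

def snp_metadata(n_snps: int, spacing_bp: int = 200_000) -> pd.DataFrame:
    """Deterministic panel layout: SNPs spread over 22 autosomes.

    Positions are strictly increasing within chromosome with ``spacing_bp``
    between neighbours (default 200 kb, i.e. outside the +/-50 kb pruning
    window, so independent SNPs stay independent after pruning).
    """
    ids = [f"snp_{i + 1:06d}" for i in range(n_snps)]
    chroms = [str((i % 22) + 1) for i in range(n_snps)]
    pos = [1_000_000 + (i // 22) * spacing_bp for i in range(n_snps)]
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": pos,
            "count_allele": "A",
            "other_allele": "G",
        }
    )


def _proxy_r(r2: float, freq: np.ndarray) -> np.ndarray:
    """Haplotype-level correlation needed so corr^2(dosage, hard call)=r2.

    The dosage is ``2f(1-r') + r' g* + jitter`` with g* a proxy genotype in
    LD r' with the true genotype; the jitter term requires inflating r'
    slightly (closed-form solution of the attenuation quadratic).
    """
    v = 2.0 * freq * (1.0 - freq)
    eps2 = _IMPUTE_JITTER**2
    x = (r2 * v + np.sqrt((r2 * v) ** 2 + 4.0 * v * r2 * eps2)) / (2.0 * v)
    return np.sqrt(np.clip(x, 0.0, 1.0))


def _simulate_snp_rows(
    freqs: np.ndarray,
    imputed: np.ndarray,
    r2: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage and true hard-call matrices (m x n) for one study's subjects."""
    m = len(freqs)
    f_col = freqs[:, None]
    # binomial(2, f) via the inverse CDF of one uniform draw: much faster
    # than rng.binomial with a per-row probability, identically distributed
    u = rng.random((m, n))
    hom_other = (1.0 - f_col) ** 2
    het_upper = hom_other + 2.0 * f_col * (1.0 - f_col)
    truth = np.add(u >= hom_other, u >= het_upper, dtype=np.float64)
    dosage = truth.copy()
    imp = np.flatnonzero(imputed)
    if len(imp) and r2 < 1.0:
        f = freqs[imp][:, None]
        r = _proxy_r(r2, freqs[imp])[:, None]
        d_ld = r * f * (1.0 - f)  # haplotype disequilibrium
        # conditional proxy-allele probabilities given the true allele
        p_b_given_a = np.clip((f * f + d_ld) / f, 0.0, 1.0)
        p_b_given_not_a = np.clip((f * (1.0 - f) - d_ld) / (1.0 - f), 0.0, 1.0)
        mi, ni = len(imp), n
        g = truth[imp]
        # per true allele, draw the linked proxy allele (haplotype-wise)
        u1, u2 = rng.random((mi, ni)), rng.random((mi, ni))
        p1 = np.where(g >= 1, p_b_given_a, p_b_given_not_a)
        p2 = np.where(g >= 2, p_b_given_a, p_b_given_not_a)
        g_star = np.add(u1 < p1, u2 < p2, dtype=np.float64)
        d = 2.0 * f * (1.0 - r) + r * g_star
        d += rng.normal(0.0, _IMPUTE_JITTER, size=d.shape)
        dosage[imp] = np.clip(d, 0.0, 2.0)
    return dosage, truth


def generate_dosages(
    spec: StudySpec,
    n_snps: int,
    imputed_fraction: float,
    r2: float,
    seed,
    freqs: Optional[np.ndarray] = None,
    imputed_mask: Optional[np.ndarray] = None,
    subject_ids: Optional[np.ndarray] = None,
) -> SnpPanel:
    """Simulate one study's SNP panel for its subjects.

    Genotyped SNPs are hard calls 0/1/2 drawn from Hardy-Weinberg proportions
    at the study's allele frequency; imputed SNPs are continuous dosages in
    [0, 2] whose squared correlation with the underlying hard call matches
    ``r2`` (exactly equal to the hard call when ``r2 == 1``).
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("imputation r2 must be in (0, 1]")
    rng = _as_rng(seed)
    meta = snp_metadata(n_snps)
    if freqs is None:
        freqs = rng.uniform(0.05, 0.5, n_snps)
    freqs = np.asarray(freqs, float).copy()
    for i, sid in enumerate(meta["snp_id"]):
        if sid in spec.allele_freq:
            freqs[i] = spec.allele_freq[sid]
    if np.any((freqs <= 0.0) | (freqs > 0.5)):
        bad = freqs[(freqs <= 0.0) | (freqs > 0.5)][0]
        raise ValueError(f"allele frequency {bad} outside (0, 0.5]")
    if imputed_mask is None:
        imputed_mask = rng.random(n_snps) < imputed_fraction
    if subject_ids is None:
        subject_ids = np.array(
            [f"{spec.study_id}_{i + 1:05d}" for i in range(spec.n_total)]
        )
    n = len(subject_ids)
    dosage, truth = _simulate_snp_rows(freqs, imputed_mask, r2, n, rng)

    meta = meta.copy()
    meta["type"] = np.where(imputed_mask, "imputed", "genotyped")
    meta["imputation_r2"] = np.where(imputed_mask, r2, np.nan)
    meta["call_rate"] = rng.uniform(0.985, 1.0, n_snps)
    meta["freq_true"] = freqs
    return SnpPanel(snps=meta, dosages=dosage, subject_ids=subject_ids, truth=truth)


def _proxy_hard_call(
    g: np.ndarray, freq: float, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Hard-call genotype of a locus in haplotype LD r with genotype ``g``."""
    d_ld = r * freq * (1.0 - freq)
    p_b_a = np.clip((freq * freq + d_ld) / freq, 0.0, 1.0)
    p_b_na = np.clip((freq * (1.0 - freq) - d_ld) / (1.0 - freq), 0.0, 1.0)
    gi = g.astype(np.int64)
    return (rng.binomial(gi, p_b_a) + rng.binomial(2 - gi, p_b_na)).astype(float)


def add_ld_proxy(
    studies: Sequence[tuple[StudyDataset, SnpPanel]],
    index_snp: str,
    proxy_snp: str,
    r2: float,
    seed,
    offset_bp: int = 10_000,
) -> None:
    """Turn an existing panel SNP into an LD proxy of ``index_snp``.

    In every study, ``proxy_snp``'s dosages are replaced by hard calls of a
    locus in haplotype LD sqrt(r2) with the index SNP's true genotype, and
    it is moved to ``offset_bp`` base pairs from the index (inside the
    default pruning window).  Used to exercise proximity pruning and
    regional signal attenuation; modifies the panels in place.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must be in (0, 1]")
    rng = _as_rng(seed)
    r = math.sqrt(r2)
    for _ds, panel in studies:
        snps = panel.snps
        i = snps.index[snps["snp_id"] == index_snp]
        j = snps.index[snps["snp_id"] == proxy_snp]
        if len(i) != 1 or len(j) != 1:
            raise ValueError("index or proxy SNP not in panel")
        i, j = int(i[0]), int(j[0])
        freq = float(snps.at[i, "freq_true"])
        g = panel.truth[i] if panel.truth is not None else panel.dosages[i]
        g_star = _proxy_hard_call(g, freq, r, rng)
        panel.dosages[j] = g_star
        if panel.truth is not None:
            panel.truth[j] = g_star
        snps.loc[j, ["chrom", "pos"]] = [snps.at[i, "chrom"],
                                         int(snps.at[i, "pos"]) + offset_bp]
        snps.loc[j, ["type", "imputation_r2", "freq_true"]] = [
            "genotyped", np.nan, freq,
        ]


# ---------------------------------------------------------------------------
# consortium
# ---------------------------------------------------------------------------

def _pool_quartile_codes(
    raw: pd.DataFrame,
    sex: np.ndarray,
    n_categories: dict[str, int],
) -> pd.DataFrame:
    """Sex-specific quartile codes on the population pool.

    The analysis recomputes codes from sampled controls; at ~5% prevalence
    the pool distribution is essentially the control distribution, so planted
    per-quartile effects carry through to the analysis scale.
    """
    codes = {}
    for e in raw.columns:
        k = n_categories.get(e, 4)
        if k < 4:
            codes[e] = np.asarray(
                [CATEGORY_CODE_MAP[k][int(c) - 1] for c in raw[e]], float
            )
            continue
        code = np.empty(len(raw), float)
        for s in np.unique(sex):
            m = sex == s
            cuts = np.quantile(raw.loc[m, e], [0.25, 0.5, 0.75])
            code[m] = 1 + np.searchsorted(cuts, raw.loc[m, e], side="left")
        codes[e] = code
    return pd.DataFrame(codes, index=raw.index)


def _solve_intercept(eta_rest: np.ndarray, prevalence: float) -> float:
    """Intercept giving the target pool disease prevalence."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta_rest))) - prevalence

    return brentq(gap, -30.0, 10.0, xtol=1e-10)


def generate_consortium(
    config: GeneratorConfig,
) -> list[tuple[StudyDataset, SnpPanel]]:
    """Simulate every study of the consortium; deterministic given config.

    Returns one ``(StudyDataset, SnpPanel)`` pair per study, with identical
    SNP metadata layout across studies (frequencies vary by study).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    panel_seed, *study_seeds = ss.spawn(len(config.studies) + 1)
    rng_panel = np.random.default_rng(panel_seed)
    base_freq = rng_panel.uniform(0.05, 0.48, config.n_snps)
    imputed_mask = rng_panel.random(config.n_snps) < config.imputed_fraction
    meta = snp_metadata(config.n_snps)
    snp_index = {sid: i for i, sid in enumerate(meta["snp_id"])}
    risk_snps = config.true_effects.risk_snps()
    for sid in risk_snps:
        if sid not in snp_index:
            raise ValueError(f"risk SNP {sid} not in the panel of {config.n_snps} SNPs")

    out = []
    for spec, sseed in zip(config.studies, study_seeds):
        rng = np.random.default_rng(sseed)
        study_freq = np.clip(
            base_freq + rng.uniform(-0.02, 0.02, config.n_snps), 0.01, 0.5
        )
        for sid, f in spec.allele_freq.items():
            if sid in snp_index:
                study_freq[snp_index[sid]] = f
        out.append(
            _simulate_study(
                spec, config, meta, snp_index, study_freq, imputed_mask, risk_snps, rng
            )
        )
    return out


def _simulate_study(
    spec: StudySpec,
    config: GeneratorConfig,
    meta: pd.DataFrame,
    snp_index: dict[str, int],
    study_freq: np.ndarray,
    imputed_mask: np.ndarray,
    risk_snps: list[str],
    rng: np.random.Generator,
) -> tuple[StudyDataset, SnpPanel]:
    eff = config.true_effects
    prev = config.prevalence
    n_pool = int(
        math.ceil(1.4 * max(spec.n_cases / prev, spec.n_controls / (1.0 - prev)))
    )
    n_pool = min(max(n_pool, 2000), _POOL_CAP)

    sex_shift = config.sex_exposure_shift or DEFAULT_SEX_SHIFT
    for _attempt in range(3):
        sex = (rng.random(n_pool) < spec.sex_ratio).astype(int)
        age = rng.normal(62.0, 8.0, n_pool)
        pcs = rng.standard_normal((n_pool, 3))
        energy = rng.normal(2000.0, 500.0, n_pool) if spec.energy_available else None
        raw = generate_exposures(
            spec, config.exposure_correlation, n_pool, rng, sex=sex, sex_shift=sex_shift
        )
        codes = _pool_quartile_codes(raw, sex, spec.n_exposure_categories)

        # risk SNPs are simulated for the whole pool (their true genotypes
        # enter the disease model); null SNPs only for sampled subjects.
        risk_idx = [snp_index[s] for s in risk_snps]
        risk_dos, risk_truth = _simulate_snp_rows(
            study_freq[risk_idx],
            imputed_mask[risk_idx],
            config.target_imputation_r2,
            n_pool,
            rng,
        ) if risk_idx else (np.empty((0, n_pool)), np.empty((0, n_pool)))

        eta = np.zeros(n_pool)
        for e, b in eff.beta_e.items():
            if b:
                eta += b * codes[e].to_numpy()
        for j, sid in enumerate(risk_snps):
            g = risk_truth[j]
            eta += eff.beta_g.get(sid, 0.0) * g
            for e in config.exposures:
                b = eff.beta_ge.get((sid, e), 0.0)
                if b:
                    eta += b * g * codes[e].to_numpy()
        cov_values = {"age": age, "sex": sex.astype(float), "pc1": pcs[:, 0],
                      "pc2": pcs[:, 1], "pc3": pcs[:, 2]}
        if energy is not None:
            cov_values["energy"] = energy
        for c, b in eff.covariate_betas.items():
            if b and c in cov_values:
                v = cov_values[c]
                eta += b * (v - v.mean())

        b0 = _solve_intercept(eta, prev)
        disease = rng.random(n_pool) < expit(b0 + eta)
        n_case_pool = int(disease.sum())
        if n_case_pool >= spec.n_cases and (n_pool - n_case_pool) >= spec.n_controls:
            break
        if n_pool >= _POOL_CAP:
            raise RuntimeError(
                f"{spec.study_id}: pool of {n_pool} cannot supply "
                f"{spec.n_cases} cases / {spec.n_controls} controls"
            )
        n_pool = min(n_pool * 4, _POOL_CAP)
    else:
        raise RuntimeError(f"{spec.study_id}: case-control sampling failed")

    case_pool = np.flatnonzero(disease)
    ctrl_pool = np.flatnonzero(~disease)
    take = np.concatenate(
        [
            rng.choice(case_pool, spec.n_cases, replace=False),
            rng.choice(ctrl_pool, spec.n_controls, replace=False),
        ]
    )
    subject_ids = np.array(
        [f"{spec.study_id}_{i + 1:05d}" for i in range(len(take))]
    )

    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "case": disease[take].astype(int),
            "age": age[take],
            "sex": sex[take],
            "pc1": pcs[take, 0],
            "pc2": pcs[take, 1],
            "pc3": pcs[take, 2],
        }
    )
    if energy is not None:
        pheno["energy"] = energy[take]
    for e in raw.columns:
        pheno[e] = raw[e].to_numpy()[take]

    n = len(take)
    null_rows = np.array([i for i in range(config.n_snps) if i not in
                          set(snp_index[s] for s in risk_snps)], dtype=int)
    dosage = np.empty((config.n_snps, n))
    truth = np.empty((config.n_snps, n))
    if len(null_rows):
        d_null, t_null = _simulate_snp_rows(
            study_freq[null_rows],
            imputed_mask[null_rows],
            config.target_imputation_r2,
            n,
            rng,
        )
        dosage[null_rows] = d_null
        truth[null_rows] = t_null
    for j, sid in enumerate(risk_snps):
        dosage[snp_index[sid]] = risk_dos[j][take]
        truth[snp_index[sid]] = risk_truth[j][take]

    study_meta = meta.copy()
    study_meta["type"] = np.where(imputed_mask, "imputed", "genotyped")
    study_meta["imputation_r2"] = np.where(
        imputed_mask, config.target_imputation_r2, np.nan
    )
    study_meta["call_rate"] = rng.uniform(0.985, 1.0, config.n_snps)
    study_meta["freq_true"] = study_freq

    panel = SnpPanel(
        snps=study_meta, dosages=dosage, subject_ids=subject_ids, truth=truth
    )
    dataset = StudyDataset(
        study_id=spec.study_id,
        phenotypes=pheno,
        n_exposure_categories=dict(spec.n_exposure_categories),
        energy_available=spec.energy_available,
    )
    return dataset, panel


# ---------------------------------------------------------------------------
# default consortium
# ---------------------------------------------------------------------------

_CASE_SIZES = (1780, 1520, 1230, 1010, 905, 800, 700, 602, 450, 290)
_CTRL_SIZES = (1700, 1480, 1220, 1000, 900, 810, 690, 607, 420, 290)
_SEX_RATIOS = (0.52, 0.48, 0.55, 0.45, 0.50, 0.60, 0.40, 0.50, 0.47, 0.53)
_MEAN_SCALE = (1.00, 0.92, 1.08, 0.97, 1.03, 0.88, 1.12, 1.00, 0.95, 1.05)

#: Study-level baseline intake means (servings/day; fiber g/day) and SDs.
BASE_MEANS = {
    "red_meat": 0.90,
    "processed_meat": 0.55,
    "vegetable": 2.40,
    "fruit": 2.00,
    "fiber": 18.0,
}
BASE_SDS = {
    "red_meat": 0.55,
    "processed_meat": 0.40,
    "vegetable": 1.10,
    "fruit": 1.00,
    "fiber": 7.0,
}

#: Planted conditional per-quartile diet effects (log-odds), calibrated so
#: single-factor marginal models reproduce the consortium-style estimates
#: (OR 1.15 red meat, 1.11 processed meat, 0.93 vegetables, 0.93 fruit,
#: 0.91 fiber): with correlated exposures each single-factor model absorbs
#: part of its partners' effects, so the conditional values are obtained by
#: solving the quartile-code correlation system, and the processed-meat main
#: effect additionally nets out the planted interaction's genotype-averaged
#: contribution (log 1.0869 at count-allele frequency 0.25).
DEFAULT_DIET_EFFECTS = {
    "red_meat": 0.1183,       # conditional OR 1.126
    "processed_meat": -0.0441,  # conditional OR 0.957 in non-carriers
    "vegetable": -0.0461,     # conditional OR 0.955
    "fruit": -0.0250,         # conditional OR 0.975
    "fiber": -0.0712,         # conditional OR 0.931
}

#: Headline planted interaction: OR 1.17 per count allele per quartile of
#: processed meat.
DEFAULT_INTERACTION_OR = 1.17


def hit_snp_id(n_snps: int) -> str:
    """The designated hit SNP: first panel SNP on chromosome 10."""
    meta = snp_metadata(n_snps)
    on10 = meta.loc[meta["chrom"] == "10", "snp_id"]
    if on10.empty:
        raise ValueError("panel too small to contain a chromosome-10 SNP")
    return str(on10.iloc[0])


def default_consortium(
    n_snps: int = 60,
    seed: int = 0,
    planted: bool = True,
    scale: float = 1.0,
) -> GeneratorConfig:
    """The default ten-study consortium configuration.

    ``planted=True`` plants the headline processed-meat interaction (OR 1.17
    per allele per quartile) on the chromosome-10 hit SNP with study-specific
    count-allele frequencies spread over 0.21-0.27, plus the marginal diet
    effects.  ``scale`` shrinks every study proportionally for quick runs.
    """
    hit = hit_snp_id(n_snps) if planted else None
    hit_freqs = np.linspace(0.21, 0.27, len(_CASE_SIZES))
    studies = []
    for i in range(len(_CASE_SIZES)):
        n_cat = {}
        if i == 8:
            n_cat["fiber"] = 3
        if i == 9:
            n_cat["vegetable"] = 2
        studies.append(
            StudySpec(
                study_id=f"study_{i + 1:02d}",
                n_cases=max(int(round(_CASE_SIZES[i] * scale)), 25),
                n_controls=max(int(round(_CTRL_SIZES[i] * scale)), 25),
                sex_ratio=_SEX_RATIOS[i],
                exposure_means={
                    e: m * _MEAN_SCALE[i] for e, m in BASE_MEANS.items()
                },
                exposure_sds=dict(BASE_SDS),
                n_exposure_categories=n_cat,
                allele_freq={hit: float(hit_freqs[i])} if planted else {},
            )
        )
    # the hit carries no *marginal* disease association (its screen p was
    # weak in the consortium): a crossing interaction, with the per-allele
    # main effect offsetting the interaction at the mean quartile code 2.5
    b_ge = math.log(DEFAULT_INTERACTION_OR)
    effects = TrueEffects(
        beta_e=dict(DEFAULT_DIET_EFFECTS) if planted else {},
        beta_g={hit: -2.5 * b_ge} if planted else {},
        beta_ge={(hit, "processed_meat"): b_ge} if planted else {},
        covariate_betas={"age": 0.025, "sex": 0.25} if planted else {},
    )
    return GeneratorConfig(
        studies=studies,
        true_effects=effects,
        n_snps=n_snps,
        imputed_fraction=0.3,
        target_imputation_r2=0.9,
        seed=seed,
    )
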