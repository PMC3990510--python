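"""Shared domain containers for the gene-diet interaction pipeline.

The pipeline moves per-study case-control data (outcome, covariates, dietary
exposures) and SNP dosage panels through harmonization, QC, per-study
regression, meta-analysis and the two-step interaction scan.  These containers
are deliberately thin: tabular payloads live in pandas DataFrames / numpy
arrays, and the dataclasses carry identity, metadata and invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical dietary exposures, in the order used by the default correlation
#: profile.  Meats in servings/day, vegetable/fruit in servings/day, fiber in
#: g/day.
EXPOSURES = ("red_meat", "processed_meat", "vegetable", "fruit", "fiber")

#: Minimal adjustment set used by every model unless overridden: age at
#: reference, sex, total energy (when available) and the first three principal
#: components of ancestry.  Study/center enters through per-study analysis.
MINIMAL_COVARIATES = ("age", "sex", "energy", "pc1", "pc2", "pc3")


@dataclass
class StudySpec:
    """Design of one synthetic case-control study."""

    study_id: str
    n_cases: int
    n_controls: int
    sex_ratio: float = 0.5  # proportion of males
    exposure_means: dict[str, float] = field(default_factory=dict)
    exposure_sds: dict[str, float] = field(default_factory=dict)
    #: exposures recorded with a coarse questionnaire get 2 or 3 categories;
    #: anything absent from this map is continuous (>=4 quartile categories).
    n_exposure_categories: dict[str, int] = field(default_factory=dict)
    #: per-SNP allele-frequency overrides (e.g. the hit SNP's study-specific
    #: frequency); SNPs not listed get panel-level frequencies.
    allele_freq: dict[str, float] = field(default_factory=dict)
    energy_available: bool = True

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError(f"{self.study_id}: negative sample size")
        if self.n_cases + self.n_controls == 0:
            raise ValueError(f"{self.study_id}: empty study")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError(f"{self.study_id}: sex_ratio outside [0,1]")
        for snp, f in self.allele_freq.items():
            if not 0.0 < f <= 0.5:
                raise ValueError(
                    f"{self.study_id}: allele frequency {f} for {snp} outside (0, 0.5]"
                )
        for exp, sd in self.exposure_sds.items():
            if sd <= 0:
                raise ValueError(f"{self.study_id}: sd for {exp} must be > 0")
        for exp, k in self.n_exposure_categories.items():
            if k < 2:
                raise ValueError(f"{self.study_id}: {exp} needs >= 2 categories")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class TrueEffects:
    """Planted log-odds effects of the disease model.

    ``beta_e`` is per quartile increment of the harmonized exposure code,
    ``beta_g`` per copy of the count allele, ``beta_ge`` per allele per
    quartile increment (the multiplicative interaction), and
    ``covariate_betas`` per unit of the (centered) covariate.
    """

    beta_e: dict[str, float] = field(default_factory=dict)
    beta_g: dict[str, float] = field(default_factory=dict)
    beta_ge: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, mapping in (
            ("beta_e", self.beta_e),
            ("beta_g", self.beta_g),
            ("beta_ge", self.beta_ge),
            ("covariate_betas", self.covariate_betas),
        ):
            for key, v in mapping.items():
                if not np.isfinite(v):
                    raise ValueError(f"{name}[{key}] is not finite")

    def risk_snps(self) -> list[str]:
        """SNP ids with any non-zero genetic or interaction effect."""
        snps = {s for s, b in self.beta_g.items() if b != 0.0}
        snps |= {s for (s, _e), b in self.beta_ge.items() if b != 0.0}
        return sorted(snps)


def default_exposure_correlation(exposures: tuple[str, ...] = EXPOSURES) -> pd.DataFrame:
    """Default latent correlation profile between dietary exposures.

    Fruit-vegetable 0.38, fruit-fiber 0.52, red-processed meat 0.62; the
    vegetable-fiber correlation (0.30) fills in a plausible value for a pair
    the consortium did not report, and meat-plant pairs are left at zero.
    """
    corr = pd.DataFrame(np.eye(len(exposures)), index=exposures, columns=exposures)

    def _set(a: str, b: str, r: float) -> None:
        if a in corr.index and b in corr.index:
            corr.loc[a, b] = corr.loc[b, a] = r

    _set("fruit", "vegetable", 0.38)
    _set("fruit", "fiber", 0.52)
    _set("red_meat", "processed_meat", 0.62)
    _set("vegetable", "fiber", 0.30)
    return corr


def validate_correlation(corr: pd.DataFrame) -> np.ndarray:
    """Check symmetry, unit diagonal and positive semi-definiteness.

    Returns the validated matrix as ndarray; raises ValueError naming the
    offending eigenvalue if the matrix is not PSD.
    """
    mat = np.asarray(corr, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(mat)
    if eig[0] < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eig[0]:.6g})"
        )
    return mat


@dataclass
class GeneratorConfig:
    """Full recipe for a synthetic multi-study consortium."""

    studies: list[StudySpec]
    exposures: tuple[str, ...] = EXPOSURES
    exposure_correlation: Optional[pd.DataFrame] = None
    true_effects: TrueEffects = field(default_factory=TrueEffects)
    n_snps: int = 100
    imputed_fraction: float = 0.3
    target_imputation_r2: float = 0.9
    seed: int = 0
    #: population disease prevalence targeted by the intercept (rare-disease
    #: regime under which the case-only test estimates the interaction).
    prevalence: float = 0.05
    #: male/female multiplicative shifts applied to exposure means.
    sex_exposure_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.exposure_correlation is None:
            self.exposure_correlation = default_exposure_correlation(self.exposures)

    def validate(self) -> None:
        if not self.studies:
            raise ValueError("config needs at least one study")
        for s in self.studies:
            s.validate()
        self.true_effects.validate()
        validate_correlation(self.exposure_correlation)
        if not 0.0 <= self.imputed_fraction <= 1.0:
            raise ValueError("imputed_fraction outside [0,1]")
        if not 0.0 < self.target_imputation_r2 <= 1.0:
            raise ValueError("target_imputation_r2 outside (0,1]")
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError("prevalence outside (0, 0.5)")


@dataclass
class SnpPanel:
    """Per-study SNP metadata plus the dosage matrix (SNPs x subjects).

    ``snps`` columns: snp_id, chrom, pos, count_allele, other_allele, type
    ('genotyped'|'imputed'), imputation_r2, call_rate — QC appends caf, mac,
    hwe_p, qc_pass, qc_reasons.  ``truth`` holds the simulation's underlying
    hard calls for imputed SNPs (equal to ``dosages`` for genotyped ones);
    it exists for calibration checks only and is never read by the analysis.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    subject_ids: np.ndarray
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.snps), len(self.subject_ids)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.subject_ids)} subjects"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset_snps(self, mask: np.ndarray) -> "SnpPanel":
        idx = np.asarray(mask)
        return SnpPanel(
            snps=self.snps.loc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
            subject_ids=self.subject_ids,
            truth=None if self.truth is None else self.truth[idx],
        )


@dataclass
class StudyDataset:
    """One study's subjects: outcome, covariates and dietary exposures.

    ``phenotypes`` columns: subject_id, case (0/1), age, sex (1=male),
    energy (may be absent), pc1..pc3, one raw column per exposure (continuous
    intake, or an integer category index for coarse questionnaires).
    Harmonization appends ``<exposure>_q`` quartile-code columns.
    """

    study_id: str
    phenotypes: pd.DataFrame
    #: exposures recorded as coarse categories: exposure -> n categories.
    n_exposure_categories: dict[str, int] = field(default_factory=dict)
    energy_available: bool = True

    @property
    def n_cases(self) -> int:
        return int(self.phenotypes["case"].sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotypes["case"]).sum())

    def covariate_columns(self, requested=MINIMAL_COVARIATES) -> list[str]:
        """Covariates actually available in this study (energy may be absent)."""
        cols = []
        for c in requested:
            if c == "energy" and not self.energy_available:
                continue
            if c in self.phenotypes.columns:
                cols.append(c)
        return cols


@dataclass
class AssocResult:
    """One fitted coefficient from a per-study model."""

    study_id: str
    term: str
    beta: float
    se: float
    z: float
    p: float
    n_used: int
    converged: bool = True
    snp_id: Optional[str] = None
    exposure: Optional[str] = None
    model: str = ""
    flags: tuple[str, ...] = ()

    @classmethod
    def from_beta_se(cls, beta: float, se: float, **kw) -> "AssocResult":
        from scipy import stats

        z = beta / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return cls(beta=beta, se=se, z=z, p=max(p, np.nextafter(0, 1)), **kw)

    def or_ci(self, level: float = 0.95) -> tuple[float, float, float]:
        """Odds ratio with Wald confidence bounds exp(beta +/- z* se)."""
        from scipy import stats

        zc = stats.norm.ppf(0.5 + level / 2.0)
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.beta - zc * self.se)),
            float(np.exp(self.beta + zc * self.se)),
        )


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects pooled coefficient across studies."""

    term: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    q_stat: Optional[float] = None
    p_het: Optional[float] = None
    snp_id: Optional[str] = None
    exposure: Optional[str] = None
    per_study: list[AssocResult] = field(default_factory=list)

    def or_ci(self, level: float = 0.95) -> tuple[float, float, float]:
        from scipy import stats

        zc = stats.norm.ppf(0.5 + level / 2.0)
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.beta - zc * self.se)),
            float(np.exp(self.beta + zc * self.se)),
        )


@dataclass(frozen=True)
class WeightScheme:
    """Weighted hypothesis testing with doubling group sizes.

    Group j holds ``first_group_size * growth**(j-1)`` ranked SNPs and is
    tested at per-SNP level ``alpha_total / (2**j * n_j)``; the geometric
    budget sums to ``alpha_total`` over infinitely many groups, so the
    realized finite scheme spends at most ``alpha_total``.
    """

    alpha_total: float = 0.05
    first_group_size: int = 5
    growth: int = 2

    def group_size(self, j: int) -> int:
        return self.first_group_size * self.growth ** (j - 1)

    def group_alpha(self, j: int) -> float:
        return self.alpha_total / (2.0**j * self.group_size(j))

    def group_of_rank(self, rank: int) -> int:
        """1-based group index for a 1-based rank."""
        if rank < 1:
            raise ValueError("rank must be >= 1")
        j, upper = 1, self.group_size(1)
        while rank > upper:
            j += 1
            upper += self.group_size(j)
        return j

    def alpha_for_rank(self, rank: int) -> float:
        return self.group_alpha(self.group_of_rank(rank))

    def realized_budget(self, n_snps: int) -> float:
        """Total alpha spent when n_snps ranked SNPs are tested."""
        total, j, placed = 0.0, 1, 0
        while placed < n_snps:
            size = min(self.group_size(j), n_snps - placed)
            total += size * self.group_alpha(j)
            placed += size
            j += 1
        return total


__all__ = [
    "EXPOSURES",
    "MINIMAL_COVARIATES",
    "StudySpec",
    "TrueEffects",
    "GeneratorConfig",
    "SnpPanel",
    "StudyDataset",
    "AssocResult",
    "MetaResult",
    "WeightScheme",
    "default_exposure_correlation",
    "validate_correlation",
]
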