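"""Sex- and study-specific quartile harmonization of dietary intake.

Raw intake (servings/day or g/day) is converted to ordinal codes 1-4 using
quartile cutpoints computed from the *controls* of each study and sex; the
codes are then assigned to all subjects, cases included, from those control
cutpoints.  Studies that recorded an exposure in fewer than four categories
map their categories onto the quartile scale: two categories to codes {2, 3},
three categories to codes {1, 2, 3}.

The exposure enters every downstream model as the ordinal code (1, 2, 3, 4)
treated as a single numeric covariate, the lowest category being the
reference.  Numerical conventions (not dictated by the harmonization idea
itself): cutpoints are linearly interpolated empirical quartiles (numpy's
default quantile rule) and values exactly at a cutpoint fall in the lower
quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Mapping of coarse questionnaire categories onto the quartile scale.
CATEGORY_CODE_MAP = {2: (2, 3), 3: (1, 2, 3)}

#: Minimum non-missing control values required per study x sex stratum.
MIN_CONTROLS_PER_STRATUM = 8


@dataclass
class HarmonizationAudit:
    """Cutpoints and warnings per study x sex stratum."""

    study: str
    exposure: str
    sex: object
    cutpoints: tuple[float, float, float] | None
    n_controls: int
    flags: tuple[str, ...] = ()


def quartile_code(
    raw_values: pd.Series,
    case_status: pd.Series,
    sex: pd.Series,
    study: str = "",
    exposure: str = "",
) -> tuple[pd.Series, list[HarmonizationAudit]]:
    """Quartile-code one exposure within one study.

    Cutpoints (25th/50th/75th percentiles) come from controls only, per sex;
    all subjects are coded 1-4 against their stratum's cutpoints.  Missing
    intake yields a missing code.  Strata with no usable controls are
    excluded (codes missing) and recorded in the audit; strata with fewer
    than ``MIN_CONTROLS_PER_STRATUM`` controls are coded but flagged.
    """
    values = pd.to_numeric(raw_values, errors="coerce")
    codes = pd.Series(np.nan, index=values.index, dtype=float)
    audits: list[HarmonizationAudit] = []
    is_control = np.asarray(case_status) == 0

    for s in pd.unique(sex):
        in_stratum = np.asarray(sex == s)
        ctrl = values[in_stratum & is_control].dropna()
        flags: list[str] = []
        if len(ctrl) == 0:
            audits.append(
                HarmonizationAudit(study, exposure, s, None, 0, ("ALL_MISSING",))
            )
            continue
        if len(ctrl) < MIN_CONTROLS_PER_STRATUM:
            flags.append("FEW_CONTROLS")
        cuts = np.quantile(ctrl.to_numpy(), [0.25, 0.5, 0.75])
        if cuts[0] == cuts[2]:
            flags.append("DEGENERATE_CUTPOINTS")
        v = values[in_stratum]
        # ties at a cutpoint fall into the lower quartile (v <= cut)
        code = 1.0 + (v > cuts[0]).astype(float) + (v > cuts[1]) + (v > cuts[2])
        code[v.isna()] = np.nan
        codes[in_stratum] = code
        audits.append(
            HarmonizationAudit(
                study, exposure, s, tuple(float(c) for c in cuts), len(ctrl),
                tuple(flags),
            )
        )
    return codes, audits


def map_categorical(
    raw_categories: pd.Series, n_categories: int
) -> pd.Series:
    """Map a coarse (2- or 3-level) intake category onto the quartile scale.

    Two categories become codes {2, 3}; three become {1, 2, 3}; order is
    preserved.  Exposures with four or more categories must be quartile-coded
    from the raw values instead.
    """
    if n_categories >= 4:
        raise ValueError("4+ categories: use quartile_code on the raw intake")
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    mapping = CATEGORY_CODE_MAP[n_categories]
    cats = pd.to_numeric(raw_categories, errors="coerce")
    if cats.dropna().lt(1).any() or cats.dropna().gt(n_categories).any():
        raise ValueError(f"category index outside 1..{n_categories}")
    out = pd.Series(np.nan, index=cats.index, dtype=float)
    ok = cats.notna()
    out[ok] = [mapping[int(c) - 1] for c in cats[ok]]
    return out


def harmonize_study(
    dataset,
    exposures: Optional[list[str]] = None,
) -> tuple["pd.DataFrame", list[HarmonizationAudit]]:
    """Append ``<exposure>_q`` quartile-code columns to a study's phenotypes.

    Continuous exposures are control-quartile coded per sex; coarse-category
    exposures are mapped with :func:`map_categorical`.  Returns the modified
    phenotype frame (in place on the dataset) and the cutpoint audit.
    """
    pheno = dataset.phenotypes
    exposures = exposures or [
        c for c in pheno.columns
        if c not in ("subject_id", "case", "age", "sex", "energy", "pc1", "pc2", "pc3")
        and not c.endswith("_q")
    ]
    audits: list[HarmonizationAudit] = []
    for e in exposures:
        k = dataset.n_exposure_categories.get(e, 4)
        if k < 4:
            pheno[f"{e}_q"] = map_categorical(pheno[e], k)
        else:
            codes, a = quartile_code(
                pheno[e], pheno["case"], pheno["sex"], dataset.study_id, e
            )
            pheno[f"{e}_q"] = codes
            audits.extend(a)
    return pheno, audits


def audit_table(audits: list[HarmonizationAudit]) -> pd.DataFrame:
    rows = []
    for a in audits:
        c1, c2, c3 = a.cutpoints if a.cutpoints else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "study": a.study,
                "exposure": a.exposure,
                "sex": a.sex,
                "q25": c1,
                "q50": c2,
                "q75": c3,
                "n_controls": a.n_controls,
                "flags": ",".join(a.flags),
            }
        )
    return pd.DataFrame(rows)
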