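"""Plain-text file formats for study data and results.

Per-study phenotypes travel as tab-separated tables (one row per subject);
genotypes as either a plain dosage TSV (rows are SNPs: metadata columns
followed by one dosage column per subject) or a minimal VCF with a per-
genotype ``DS`` dosage field.  A JSON manifest lists every emitted file with
its SHA-256 content hash and the generator seed, so a re-run with the same
configuration can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import SnpPanel, StudyDataset

_DOSAGE_META_COLS = [
    "snp_id", "chrom", "pos", "count_allele", "other_allele",
    "type", "imputation_r2", "call_rate",
]


def write_phenotypes(dataset: StudyDataset, path: Path) -> Path:
    path = Path(path)
    dataset.phenotypes.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_phenotypes(path: Path, study_id: Optional[str] = None,
                    n_exposure_categories: Optional[dict] = None) -> StudyDataset:
    pheno = pd.read_csv(path, sep="\t")
    return StudyDataset(
        study_id=study_id or Path(path).stem.replace("_pheno", ""),
        phenotypes=pheno,
        n_exposure_categories=n_exposure_categories or {},
        energy_available="energy" in pheno.columns,
    )


def write_dosage_tsv(panel: SnpPanel, path: Path) -> Path:
    path = Path(path)
    meta = panel.snps.reindex(columns=_DOSAGE_META_COLS)
    dos = pd.DataFrame(
        np.round(panel.dosages, 4), columns=list(panel.subject_ids)
    )
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_dosage_tsv(path: Path) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[_DOSAGE_META_COLS].copy()
    subject_ids = np.array([c for c in df.columns if c not in _DOSAGE_META_COLS])
    dosages = df[subject_ids].to_numpy(dtype=float)
    return SnpPanel(snps=meta, dosages=dosages, subject_ids=subject_ids)


def write_vcf(panel: SnpPanel, path: Path) -> Path:
    """Minimal VCF 4.2 with GT (best guess) and DS (dosage) per genotype."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the count allele">',
        '##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">',
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation accuracy">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in panel.subject_ids),
    ]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for i, row in panel.snps.iterrows():
        d = panel.dosages[i]
        if row["type"] == "genotyped":
            info = "TYPED"
        else:
            info = f"R2={row['imputation_r2']:.3f}"
        best = np.clip(np.rint(d).astype(int), 0, 2)
        cells = [f"{gt_codes[g]}:{x:.3f}" for g, x in zip(best, d)]
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                    str(row["other_allele"]), str(row["count_allele"]),
                    ".", "PASS", info, "GT:DS", *cells,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf_dosages(path: Path) -> SnpPanel:
    """Read a VCF with a DS dosage field (cyvcf2 when available)."""
    try:
        return _read_vcf_cyvcf2(path)
    except ImportError:
        return _read_vcf_text(path)


def _read_vcf_cyvcf2(path: Path) -> SnpPanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).ravel()
        r2 = var.INFO.get("R2")
        typed = var.INFO.get("TYPED") is not None
        rows.append(
            {
                "snp_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                "count_allele": var.ALT[0], "other_allele": var.REF,
                "type": "genotyped" if typed else "imputed",
                "imputation_r2": np.nan if r2 is None else float(r2),
                "call_rate": np.nan,
            }
        )
        dosages.append(ds)
    return SnpPanel(
        snps=pd.DataFrame(rows),
        dosages=np.asarray(dosages, dtype=float),
        subject_ids=subject_ids,
    )


def _read_vcf_text(path: Path) -> SnpPanel:
    rows, dosages, subject_ids = [], [], None
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            subject_ids = np.array(parts[9:])
            continue
        info = parts[7]
        fmt = parts[8].split(":")
        ds_i = fmt.index("DS")
        r2 = np.nan
        for kv in info.split(";"):
            if kv.startswith("R2="):
                r2 = float(kv[3:])
        rows.append(
            {
                "snp_id": parts[2], "chrom": parts[0], "pos": int(parts[1]),
                "count_allele": parts[4], "other_allele": parts[3],
                "type": "genotyped" if "TYPED" in info.split(";") else "imputed",
                "imputation_r2": r2, "call_rate": np.nan,
            }
        )
        dosages.append([float(c.split(":")[ds_i]) for c in parts[9:]])
    return SnpPanel(
        snps=pd.DataFrame(rows),
        dosages=np.asarray(dosages, dtype=float),
        subject_ids=subject_ids,
    )


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path, files: list[Path], seed: Optional[int] = None,
    config_hash: Optional[str] = None, name: str = "manifest.json",
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "config_hash": config_hash,
        "files": {
            str(Path(f).relative_to(out_dir)): sha256_of(f) for f in files
        },
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
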