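"""Delimited-text input/output for markers, matrices and phenotypes.

Formats:

- marker tables: samples x markers, header row of marker ids, first
  column sample ids, integer dosages in {0, 1, 2};
- square covariance/relationship matrices: header labels, first column
  the same labels, values round-tripping to 1e-12;
- phenotype tables: long format with genotype / location / block / value
  columns (missing values allowed for unbalanced designs);
- optional VCF (biallelic sites, dosage of ALT) and PLINK additive-raw
  dialects for marker input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .relmat import CovStructure, InvalidInputError, MarkerMatrix

__all__ = [
    "read_markers",
    "write_markers",
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf_markers",
    "read_plink_raw",
]


def read_markers(path, sep: str = "\t") -> MarkerMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy()
    if not np.all(np.isin(vals, (0, 1, 2))):
        raise InvalidInputError(f"{path}: marker dosages must be in {{0, 1, 2}}")
    return MarkerMatrix(vals.astype(np.int64),
                        [str(s) for s in df.index], [str(m) for m in df.columns])


def write_markers(M: MarkerMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(M.dosages, index=M.sample_ids, columns=M.marker_ids).to_csv(
        path, sep=sep)


def read_matrix(path, sep: str = "\t", kind: str = "custom") -> CovStructure:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise InvalidInputError(f"{path}: row and column labels disagree")
    return CovStructure(df.to_numpy(float), kind=kind,
                        labels=[str(x) for x in df.index])


def write_matrix(S: CovStructure, path, sep: str = "\t") -> None:
    pd.DataFrame(S.matrix, index=S.labels, columns=S.labels).to_csv(
        path, sep=sep, float_format="%.17g")


def read_phenotypes(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    needed = {"genotype", "location", "block", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_vcf_markers(path) -> MarkerMatrix:
    """Biallelic sites from a VCF as ALT-dosage markers (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF markers requires the cyvcf2 extra") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=hom alt (3=unknown)
        dosage = np.where(gts == 3, -1, np.where(gts == 2, 2, gts))
        if (dosage < 0).any():
            continue  # skip sites with missing calls: no imputation
        rows.append(dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not rows:
        raise InvalidInputError(f"{path}: no complete biallelic sites")
    return MarkerMatrix(np.column_stack(rows), samples, ids)


def read_plink_raw(path) -> MarkerMatrix:
    """PLINK --recode A (additive) .raw dialect."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
            if c in df.columns]
    samples = df["IID"].astype(str).tolist() if "IID" in df.columns else None
    geno = df.drop(columns=meta)
    vals = geno.to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise InvalidInputError(f"{path}: missing genotypes are not supported")
    return MarkerMatrix(vals.astype(np.int64), samples or [],
                        [str(c) for c in geno.columns])
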