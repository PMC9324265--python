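"""Readers and writers for genotype, phenotype and variant-panel tables.

Supported formats: VCF v4.x (read; biallelic SNPs with diploid GT only, via
cyvcf2), a plain dosage TSV (read/write; lossless round trip), a phenotype
TSV (sample_id, status, sex, age, ethnicity) and a variant annotation TSV
mirroring the published panel columns.  Dosage in every format counts the
effect allele; for VCF the effect allele is ALT and the other allele REF.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix, SampleRecord, VariantRecord
from .errors import DosageValueError, UnsupportedRecordError, VcfParseError

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "attach_phenotypes",
    "read_variant_table",
    "write_variant_table",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Dosage is the per-sample ALT allele count; ``./.`` (and any half call)
    maps to missing.  Phased and unphased separators are both accepted.
    Multi-allelic records are rejected rather than split — the intended use
    is strictly biallelic SNP panels.

    Samples carry no phenotype information; use :func:`attach_phenotypes`.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"{path}: cannot parse VCF header ({exc})") from exc

    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT) or '.'}); split or drop it first"
            )
        rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(
                rsid=rsid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
            )
        )
        col = np.full(len(sample_ids), MISSING)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = float(a + b)
        columns.append(col)
    vcf.close()

    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    samples = [SampleRecord(sample_id=s) for s in sample_ids]
    return GenotypeMatrix(dosages, variants, samples)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal sites+GT VCF v4.2.

    The effect allele is emitted as ALT and the other allele as REF, so a
    read-back reproduces the same dosage convention.  Heterozygotes are
    written unphased as ``0/1``.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (matrix.variants[j].chrom, matrix.variants[j].pos),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mirpgs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.variants[j].chrom for j in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j in order:
            v = matrix.variants[j]
            gts = [
                gt_map.get(g, "./.") if math.isfinite(g) else "./."
                for g in matrix.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.other_allele}\t"
                f"{v.effect_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Dosage TSV
# ---------------------------------------------------------------------------

def read_dosage_tsv(
    path: str | Path, variants: Sequence[VariantRecord] | None = None
) -> GenotypeMatrix:
    """Read a dosage table: first column ``sample_id``, one column per rsid.

    Cells must be 0, 1, 2 or ``NA``.  If ``variants`` is given it supplies
    allele/coordinate annotation (matched by rsid); otherwise placeholder
    records with A/G alleles are synthesised so the matrix is usable for
    purely numeric work.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise DosageValueError(f"{path}: first column must be 'sample_id'")
    rsids = list(df.columns[1:])
    n = len(df)
    dosages = np.full((n, len(rsids)), MISSING)
    for j, rsid in enumerate(rsids):
        for i, cell in enumerate(df[rsid]):
            if isinstance(cell, float) and math.isnan(cell):
                cell = "NA"
            cell = str(cell).strip()
            if cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise DosageValueError(
                    f"{path}: invalid dosage {cell!r} at row {i + 2}, column {rsid}"
                )
            dosages[i, j] = float(cell)

    if variants is not None:
        by_rsid = {v.rsid: v for v in variants}
        var_records = [by_rsid.get(r) or _placeholder_variant(r, j) for j, r in enumerate(rsids)]
    else:
        var_records = [_placeholder_variant(r, j) for j, r in enumerate(rsids)]
    samples = [SampleRecord(sample_id=s) for s in df["sample_id"]]
    return GenotypeMatrix(dosages, var_records, samples)


def _placeholder_variant(rsid: str, j: int) -> VariantRecord:
    return VariantRecord(rsid=rsid, chrom="0", pos=j + 1, effect_allele="A", other_allele="G")


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV; round-trips losslessly with :func:`read_dosage_tsv`."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.rsids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "NA" if not math.isfinite(g) else str(int(g))
                for g in matrix.dosages[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = ["sample_id", "status", "sex", "age", "ethnicity"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns sample_id, status, sex, age, ethnicity."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise DosageValueError(f"{path}: phenotype table lacks columns {missing}")
    return df[_PHENO_COLUMNS]


def write_phenotypes(matrix_or_df: GenotypeMatrix | pd.DataFrame, path: str | Path) -> None:
    if isinstance(matrix_or_df, GenotypeMatrix):
        df = pd.DataFrame(
            {
                "sample_id": matrix_or_df.sample_ids,
                "status": [s.status for s in matrix_or_df.samples],
                "sex": [s.sex for s in matrix_or_df.samples],
                "age": [s.age for s in matrix_or_df.samples],
                "ethnicity": [s.ethnicity for s in matrix_or_df.samples],
            }
        )
    else:
        df = matrix_or_df[_PHENO_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def attach_phenotypes(matrix: GenotypeMatrix, phenotypes: pd.DataFrame) -> GenotypeMatrix:
    """Return a matrix whose samples carry the phenotype columns.

    Every sample in the matrix must appear exactly once in ``phenotypes``
    and have a non-missing case/control status.
    """
    idx = phenotypes.set_index("sample_id")
    if idx.index.has_duplicates:
        raise DosageValueError("phenotype table has duplicate sample_ids")
    records = []
    for s in matrix.samples:
        if s.sample_id not in idx.index:
            raise DosageValueError(f"sample {s.sample_id} absent from phenotype table")
        row = idx.loc[s.sample_id]
        status = row["status"]
        if pd.isna(status):
            raise DosageValueError(f"sample {s.sample_id}: missing case/control status")
        age = None if pd.isna(row["age"]) else float(row["age"])
        records.append(
            SampleRecord(
                sample_id=s.sample_id,
                status=str(status),
                sex=None if pd.isna(row["sex"]) else str(row["sex"]),
                age=age,
                ethnicity=None if pd.isna(row["ethnicity"]) else str(row["ethnicity"]),
            )
        )
    return matrix.with_samples(records)


# ---------------------------------------------------------------------------
# Variant annotation table
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["gene_label", "chrom", "pos", "rsid", "effect_allele", "other_allele"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant annotation TSV (panel-table column layout)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise DosageValueError(f"{path}: variant table lacks columns {missing}")
    return [
        VariantRecord(
            rsid=row.rsid,
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            gene_label=getattr(row, "gene_label", "") or "",
        )
        for row in df.itertuples()
    ]


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_label": [v.gene_label for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "rsid": [v.rsid for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)
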