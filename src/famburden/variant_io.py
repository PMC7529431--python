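"""Readers and writers for the formats the pipeline touches.

Supported formats:

* VCF v4.2 subset — ``CHROM POS ID REF ALT QUAL FILTER INFO FORMAT`` plus
  sample columns; only the ``GT`` FORMAT field is used, and the INFO tags
  ``GENE=`` and ``CSQ=`` carry the gene symbol and consequence class.
  Multi-allelic records are split into bi-allelic variants on read and
  indels are reduced to minimal representation (suffix then prefix trim).
* PED — the six PLINK columns (family, sample, father, mother, sex,
  phenotype) with optional named extra columns (age, tier, group) declared
  in a sidecar header line beginning ``#extra:``.
* Annotation TSV — one row per variant with per-database MAFs, the nine
  predictor calls and an optional CADD score; missing values are ``"."``.
* Covariate TSV — sample_id, age, sex.

All writers round-trip losslessly through the corresponding readers.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MAF_DATABASES,
    MISSING,
    PREDICTORS,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    Variant,
)
from .exceptions import ParseError, PloidyError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_annotations",
    "write_annotations",
    "read_covariates",
    "write_covariates",
]

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf_1kg",
    "maf_uk10k",
    "maf_dbsnp144",
    "maf_nhlbi",
    "maf_exac",
    "dann",
    "gerp",
    "fathmm",
    "lrt",
    "metalr",
    "metasvm",
    "mutationassessor",
    "mutationtaster",
    "provean",
    "cadd",
)

# annotation column <-> canonical database / predictor names
_DB_COLUMNS = dict(
    zip(("maf_1kg", "maf_uk10k", "maf_dbsnp144", "maf_nhlbi", "maf_exac"), MAF_DATABASES)
)
_PRED_COLUMNS = {p.lower(): p for p in PREDICTORS}


def _open_text(path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_structure(path) -> None:
    """Cheap structural pass: header present, consistent column counts.

    Raises :class:`ParseError` naming the 1-based line number on failure.
    htslib is lenient about ragged records, so this guard runs first.
    """
    n_cols = None
    saw_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ] and fields[:8] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                ]:
                    raise ParseError(f"{path}: malformed #CHROM header at line {lineno}")
                n_cols = len(fields)
                saw_header = True
                continue
            if not saw_header:
                raise ParseError(f"{path}: record before #CHROM header at line {lineno}")
            if len(line.split("\t")) != n_cols:
                raise ParseError(
                    f"{path}: ragged record at line {lineno} "
                    f"({len(line.split(chr(9)))} columns, expected {n_cols})"
                )
    if not saw_header:
        raise ParseError(f"{path}: no #CHROM header line found")


def read_vcf(path) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a VCF into variants and an alternate-allele dosage matrix.

    Multi-allelic records are split into one :class:`Variant` per ALT
    allele; for each split variant, GT alleles equal to that ALT count
    toward the dosage and all other alleles count as reference.  Genotypes
    with any missing allele (``./.`` and half-calls) map to missing.
    """
    _validate_vcf_structure(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib raises bare exceptions
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        gts = record.genotypes  # [a0, a1, phased] per sample
        alleles = []
        for s, gt in enumerate(gts):
            if len(gt) != 3:
                raise PloidyError(
                    f"{path}: non-diploid GT for sample {samples[s]} at "
                    f"{record.CHROM}:{record.POS}"
                )
            alleles.append(gt[:2])
        allele_arr = np.asarray(alleles, dtype=np.int16)  # (n_samples, 2)
        missing = (allele_arr < 0).any(axis=1)
        info = dict(record.INFO) if record.INFO else {}
        gene = str(info.get("GENE", "") or "")
        csq = str(info.get("CSQ", "other") or "other")
        for alt_index, alt in enumerate(record.ALT, start=1):
            try:
                variant = Variant.normalized(
                    record.CHROM, record.POS, record.REF, alt, gene=gene, consequence=csq
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: {exc}") from exc
            dose = (allele_arr == alt_index).sum(axis=1).astype(np.int8)
            dose[missing] = MISSING
            variants.append(variant)
            columns.append(dose)
    dosage = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return variants, GenotypeMatrix(samples, [v.key for v in variants], dosage)


def write_vcf(
    variants: Sequence[Variant], genotypes: GenotypeMatrix, path
) -> None:
    """Write bi-allelic variants with GT-only FORMAT; re-readable by :func:`read_vcf`.

    Dosage 1 is written ``0/1``, 2 as ``1/1``, missing as ``./.``.
    """
    keys = {v.key: v for v in variants}
    contigs = sorted({v.chrom for v in variants}, key=str)
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, key in enumerate(genotypes.variants):
        v = keys.get(tuple(key))
        if v is None:
            raise ValidationError(f"no Variant object for matrix key {key}")
        info_parts = []
        if v.gene:
            info_parts.append(f"GENE={v.gene}")
        info_parts.append(f"CSQ={v.consequence}")
        gts = "\t".join(gt_map[int(d)] for d in genotypes.dosage[:, j])
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"{';'.join(info_parts)}\tGT\t{gts}"
        )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_FROM_CODE = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_PHENO_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0"}


def read_ped(path) -> list[SampleRecord]:
    """Read a 6-column PLINK PED-style pedigree with optional extra columns.

    A sidecar header line ``#extra: age tier group`` (any subset, any
    order) declares columns 7+.  Affection coding: 2 affected, 1
    unaffected, 0/-9 unknown; parent id ``0`` becomes empty.
    """
    extra_cols: list[str] = []
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#extra:"):
                extra_cols = line[len("#extra:"):].split()
                unknown = set(extra_cols) - {"age", "tier", "group"}
                if unknown:
                    raise ParseError(
                        f"{path}: unknown extra column(s) {sorted(unknown)} at line {lineno}"
                    )
                continue
            if line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + len(extra_cols):
                raise ParseError(
                    f"{path}: expected {6 + len(extra_cols)} columns at line "
                    f"{lineno}, found {len(fields)}"
                )
            fam, sid, father, mother, sex_code, pheno_code = fields[:6]
            if sid in seen:
                raise ParseError(f"{path}: duplicated sample_id {sid!r} at line {lineno}")
            seen.add(sid)
            if sex_code not in _SEX_FROM_CODE:
                raise ParseError(
                    f"{path}: sex code {sex_code!r} outside {{1,2,0}} at line {lineno}"
                )
            if pheno_code not in _PHENO_FROM_CODE:
                raise ParseError(
                    f"{path}: phenotype code {pheno_code!r} at line {lineno}"
                )
            extras = dict(zip(extra_cols, fields[6:]))
            age = extras.get("age", ".")
            phenotype = _PHENO_FROM_CODE[pheno_code]
            # bare 6-column files carry no tier; affected samples default
            # to tier1 to satisfy the affected-implies-tiered invariant
            tier = extras.get("tier", "none")
            if tier in (".", "none") and phenotype == "affected":
                tier = "tier1"
            try:
                record = SampleRecord(
                    sample_id=sid,
                    family_id="" if fam == "0" else fam,
                    father_id="" if father == "0" else father,
                    mother_id="" if mother == "0" else mother,
                    sex=_SEX_FROM_CODE[sex_code],
                    phenotype=phenotype,
                    age=None if age == "." else float(age),
                    tier=tier,
                    group=extras.get("group", "family"),
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(record)
    return records


def write_ped(samples: Sequence[SampleRecord], path) -> None:
    """Write samples as PLINK PED with ``#extra: age tier group`` columns."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#extra: age tier group\n")
        for s in samples:
            age = "." if s.age is None else format(s.age, ".17g")
            fh.write(
                "\t".join(
                    [
                        s.family_id or "0",
                        s.sample_id,
                        s.father_id or "0",
                        s.mother_id or "0",
                        _SEX_TO_CODE[s.sex],
                        _PHENO_TO_CODE[s.phenotype],
                        age,
                        s.tier,
                        s.group,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(path) -> list[AnnotationRecord]:
    """Read the per-variant annotation table (MAFs, predictor calls, CADD)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing annotation column(s) {missing_cols}")
    extra = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown annotation column(s) %s", path, extra)
    records: list[AnnotationRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        maf: dict[str, float | None] = {}
        for col, db in _DB_COLUMNS.items():
            raw = row[col]
            maf[db] = None if raw == "." else float(raw)
        calls: dict[str, str] = {}
        for col, pred in _PRED_COLUMNS.items():
            raw = row[col]
            calls[pred] = "missing" if raw == "." else raw
        cadd = None if row["cadd"] == "." else float(row["cadd"])
        try:
            records.append(
                AnnotationRecord(
                    variant_key=key, maf_by_db=maf, predictor_calls=calls, cadd=cadd
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {row_number}: {exc}") from exc
    return records


def write_annotations(
    records: Sequence[AnnotationRecord],
    path,
    variants: Sequence[Variant] | None = None,
) -> None:
    """Write annotation records as TSV (``"."`` for missing values).

    ``variants`` supplies gene/consequence columns; keys without a matching
    variant get empty gene and ``other``.
    """
    by_key = {v.key: v for v in variants} if variants else {}

    def fmt(x) -> str:
        return "." if x is None else format(x, ".17g")

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            chrom, pos, ref, alt = rec.variant_key
            v = by_key.get(tuple(rec.variant_key))
            row = [chrom, str(pos), ref, alt, v.gene if v else "", v.consequence if v else "other"]
            row += [fmt(rec.maf_by_db[db]) for db in MAF_DATABASES]
            row += [
                "." if rec.predictor_calls[p] == "missing" else rec.predictor_calls[p]
                for p in PREDICTORS
            ]
            row.append(fmt(rec.cadd))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def read_covariates(path) -> pd.DataFrame:
    """Read a sample covariate table (sample_id, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "age", "sex"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing covariate column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated sample_id in covariate table")
    bad_sex = ~df["sex"].isin(["male", "female", "unknown"])
    if bad_sex.any():
        raise ValidationError(f"{path}: sex values outside vocabulary")
    return df.set_index("sample_id", drop=False)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
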