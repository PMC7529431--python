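"""Core in-memory data model.

The pipeline works on four object kinds: :class:`Variant` (one normalized
alternate allele at a genomic position), :class:`AnnotationRecord`
(population frequencies and in-silico pathogenicity calls for a variant),
:class:`SampleRecord` (an individual with pedigree links, affection status
and covariates) and :class:`GenotypeMatrix` (samples x variants alternate
allele dosages with missingness).

Coordinates are 1-based throughout, as in VCF. A variant is uniquely keyed
by ``(chrom, pos, ref, alt)``; multi-allelic records never appear here —
they are split into bi-allelic variants at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "CONSEQUENCE_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "MAF_DATABASES",
    "PREDICTORS",
    "Variant",
    "AnnotationRecord",
    "SampleRecord",
    "GenotypeMatrix",
    "MISSING",
]

#: Recognised functional consequence classes.
CONSEQUENCE_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "frameshift",
        "splice_site",
        "synonymous",
        "other",
    }
)

#: The protein-altering classes retained by the default cascade.
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "stop_gained", "stop_lost", "frameshift", "splice_site"}
)

#: Population frequency databases, in cascade order.
MAF_DATABASES = ("1KG", "UK10K", "dbSNP144", "NHLBI", "ExAC")

#: The nine in-silico pathogenicity predictors used for the consensus verdict.
PREDICTORS = (
    "DANN",
    "GERP",
    "FATHMM",
    "LRT",
    "MetaLR",
    "MetaSVM",
    "MutationAssessor",
    "MutationTaster",
    "PROVEAN",
)

_ALLELE_ALPHABET = frozenset("ACGT")

#: Sentinel dosage for a missing genotype call.
MISSING = -1


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-trim a shared suffix then prefix (minimal-representation indels)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized alternate allele at a genomic position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_ALPHABET:
                raise ValidationError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not over ACGT"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} < 1 on {self.chrom}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """The unique variant key ``(chrom, pos, ref, alt)``."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def normalized(
        cls, chrom: str, pos: int, ref: str, alt: str, gene: str = "", consequence: str = "other"
    ) -> "Variant":
        """Build a variant with minimal allele representation (suffix then prefix trim)."""
        pos, ref, alt = _trim_alleles(pos, ref.upper(), alt.upper())
        return cls(chrom, pos, ref, alt, gene, consequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """Population MAFs and pathogenicity predictor calls for one variant.

    ``maf_by_db`` maps each of :data:`MAF_DATABASES` to a frequency in [0, 1]
    or ``None`` (absent from the database).  ``predictor_calls`` maps each of
    the nine :data:`PREDICTORS` to ``"pathogenic"``, ``"benign"`` or
    ``"missing"``.  ``cadd`` is a non-negative scaled score or ``None``.
    """

    variant_key: tuple[str, int, str, str]
    maf_by_db: Mapping[str, float | None] = field(default_factory=dict)
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    cadd: float | None = None

    def __post_init__(self) -> None:
        maf = {db: self.maf_by_db.get(db) for db in MAF_DATABASES}
        unknown = set(self.maf_by_db) - set(MAF_DATABASES)
        if unknown:
            raise ValidationError(f"unknown MAF database(s) {sorted(unknown)}")
        for db, freq in maf.items():
            if freq is not None and not (0.0 <= freq <= 1.0):
                raise ValidationError(
                    f"{db} frequency {freq} outside [0,1] for {self.variant_key}"
                )
        calls = {p: self.predictor_calls.get(p, "missing") for p in PREDICTORS}
        unknown = set(self.predictor_calls) - set(PREDICTORS)
        if unknown:
            raise ValidationError(f"unknown predictor(s) {sorted(unknown)}")
        for pred, call in calls.items():
            if call not in ("pathogenic", "benign", "missing"):
                raise ValidationError(
                    f"predictor {pred} call {call!r} outside vocabulary for {self.variant_key}"
                )
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"negative CADD score for {self.variant_key}")
        object.__setattr__(self, "maf_by_db", maf)
        object.__setattr__(self, "predictor_calls", calls)


@dataclass(frozen=True)
class SampleRecord:
    """An individual with pedigree links, affection status and covariates."""

    sample_id: str
    family_id: str = ""
    father_id: str = ""
    mother_id: str = ""
    sex: str = "unknown"  # male / female / unknown
    age: float | None = None
    phenotype: str = "unknown"  # affected / unaffected / unknown
    tier: str = "none"  # tier1 / tier2 / tier3 / control / none
    group: str = "family"  # family / cohort_case / cohort_control

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"sample {self.sample_id}: bad sex {self.sex!r}")
        if self.phenotype not in ("affected", "unaffected", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id}: bad phenotype {self.phenotype!r}"
            )
        if self.tier not in ("tier1", "tier2", "tier3", "control", "none"):
            raise ValidationError(f"sample {self.sample_id}: bad tier {self.tier!r}")
        if self.group not in ("family", "cohort_case", "cohort_control"):
            raise ValidationError(f"sample {self.sample_id}: bad group {self.group!r}")
        if self.phenotype == "affected" and self.tier not in ("tier1", "tier2", "tier3"):
            raise ValidationError(
                f"sample {self.sample_id}: affected individuals need a tier, got {self.tier!r}"
            )
        if self.group == "cohort_control" and self.phenotype != "unaffected":
            raise ValidationError(
                f"sample {self.sample_id}: cohort controls must be unaffected"
            )

    def with_(self, **kwargs) -> "SampleRecord":
        return replace(self, **kwargs)


class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Dosages are stored as ``int8`` with values in ``{0, 1, 2}`` and
    :data:`MISSING` (-1) for missing calls.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[tuple[str, int, str, str]],
        dosage: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.variants = [tuple(v) for v in variants]
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosage values must be 0, 1, 2 or missing (-1)")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant keys")
        self.dosage = dosage
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v: j for j, v in enumerate(self.variants)}

    # -- accessors -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.dosage[self._sample_index[sample_id]]

    def variant_column(self, key: tuple[str, int, str, str]) -> np.ndarray:
        return self.dosage[:, self._variant_index[tuple(key)]]

    def subset_variants(self, keys: Iterable[tuple[str, int, str, str]]) -> "GenotypeMatrix":
        keys = [tuple(k) for k in keys]
        cols = [self._variant_index[k] for k in keys]
        return GenotypeMatrix(self.samples, keys, self.dosage[:, cols])

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(sample_ids)
        rows = [self._sample_index[s] for s in ids]
        return GenotypeMatrix(ids, self.variants, self.dosage[rows, :])

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"
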