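"""The multiplex-tremor family that motivates the package defaults.

A 16-member, three-generation pedigree: ten members affected by
essential tremor and six unaffected controls.  Nine of the ten affected
members carry a heterozygous missense candidate variant in the *TUB*
gene; the tenth (III-6, with a history of thyroidectomy — a recognised
non-genetic cause of tremor) does not carry it and is interpreted as a
phenocopy.  None of the six controls carry the variant.  This is the
pattern the phenocopy-tolerant segregation filter (k = 9 of 10 affected,
0 control carriers) is designed to retain.

Individual ids, affection tiers, ages and genotypes reproduce the
published clinical table of the study family.  The *pedigree links*
(who is whose parent) are a synthetic reconstruction: the full pedigree
was not published, so a plausible acyclic structure consistent with the
generation labels is declared here for simulation and kinship checks.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    MAF_DATABASES,
    PREDICTORS,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    Variant,
)

__all__ = [
    "tremor_candidate_variant",
    "tremor_candidate_annotation",
    "tremor_pedigree",
    "tremor_genotypes",
    "PHENOCOPY_ID",
]

#: The affected member who does not carry the candidate (thyroidectomy).
PHENOCOPY_ID = "III-6"

# id, father, mother, sex, age, phenotype, tier, carrier(GA=1)
_MEMBERS = [
    ("II-1", "", "", "male", 100, "affected", "tier1", 1),
    ("II-2", "", "", "female", 93, "affected", "tier2", 1),
    ("III-2", "II-1", "", "female", 75, "affected", "tier1", 1),
    ("III-3", "II-1", "", "male", 66, "affected", "tier1", 1),
    ("III-6", "II-1", "", "male", 64, "affected", "tier2", 0),
    ("III-7", "II-1", "", "female", 62, "unaffected", "control", 0),
    ("III-9", "II-1", "", "male", 65, "unaffected", "control", 0),
    ("III-8", "", "", "female", 60, "unaffected", "control", 0),
    ("III-10", "", "", "female", 68, "unaffected", "control", 0),
    ("III-12", "", "II-2", "male", 78, "unaffected", "control", 0),
    ("III-15", "", "II-2", "female", 71, "unaffected", "control", 0),
    ("III-17", "", "II-2", "male", 69, "affected", "tier2", 1),
    ("III-18", "", "II-2", "female", 79, "affected", "tier2", 1),
    ("III-19", "", "II-2", "male", 71, "affected", "tier1", 1),
    ("IV-19", "III-3", "III-8", "female", 48, "affected", "tier1", 1),
    ("IV-28", "III-19", "III-10", "male", 39, "affected", "tier2", 1),
]


def tremor_candidate_variant() -> Variant:
    """The heterozygous missense candidate in *TUB* (chr11, G>A)."""
    return Variant("11", 8075543, "G", "A", gene="TUB", consequence="missense")


def tremor_candidate_annotation() -> AnnotationRecord:
    """Annotation profile of the candidate: rare everywhere, 8-vs-1 pathogenic.

    Population frequencies are below 0.01 in every database except ExAC,
    where the maximum (Finnish) frequency 0.0114 is used; eight of the
    nine predictors call the variant pathogenic and PROVEAN calls it
    benign, so the consensus verdict is deleterious.
    """
    v = tremor_candidate_variant()
    maf = dict(zip(MAF_DATABASES, (0.009, 0.0094, 0.009, 0.008, 0.0114)))
    calls = {p: "pathogenic" for p in PREDICTORS}
    calls["PROVEAN"] = "benign"
    return AnnotationRecord(
        variant_key=v.key, maf_by_db=maf, predictor_calls=calls, cadd=22.7
    )


def tremor_pedigree() -> list[SampleRecord]:
    """The 16 genotyped family members (10 affected, 6 controls)."""
    return [
        SampleRecord(
            sample_id=sid,
            family_id="FAM1",
            father_id=father,
            mother_id=mother,
            sex=sex,
            age=float(age),
            phenotype=phenotype,
            tier=tier,
        )
        for sid, father, mother, sex, age, phenotype, tier, _ in _MEMBERS
    ]


def tremor_genotypes() -> tuple[Variant, GenotypeMatrix]:
    """Candidate-variant dosages for the 16 members (GA = 1, GG = 0)."""
    v = tremor_candidate_variant()
    samples = [m[0] for m in _MEMBERS]
    dosage = np.array([[m[7]] for m in _MEMBERS], dtype=np.int8)
    return v, GenotypeMatrix(samples, [v.key], dosage)
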