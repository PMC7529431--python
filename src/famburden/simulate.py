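"""Synthetic family and cohort generators with known ground truth.

The generators produce datasets with the statistical structure the
analysis assumes, written in the standard formats the pipeline reads:

* :func:`simulate_family` — Mendelian gene-dropping of background exome
  variants down a three-generation pedigree, with a rare deleterious
  candidate variant planted in one founder lineage.  By default the
  candidate's carrier states and the affection statuses follow the
  motivating family's observed template (nine affected carriers, one
  affected non-carrier phenocopy, six unaffected non-carriers); a
  stochastic mode instead drops the candidate at random and assigns
  affection by penetrance and phenocopy rate.
* :func:`simulate_cohort` — a case-control resequencing cohort for one
  gene.  Carrier status for predicted-deleterious variants is simulated
  at the person level (so the carrier table can be calibrated exactly),
  then materialised as heterozygous genotypes at individual sites;
  synonymous and benign background sites are independent of phenotype.

Both generators are deterministic given their seed, and both return a
truth record listing everything that was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MAF_DATABASES,
    PREDICTORS,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    Variant,
)
from .datasets import (
    PHENOCOPY_ID,
    tremor_candidate_annotation,
    tremor_candidate_variant,
    tremor_pedigree,
)
from .exceptions import ValidationError
from . import variant_io

__all__ = [
    "PedigreeMember",
    "FamilySimConfig",
    "CohortSimConfig",
    "FamilyTruth",
    "CohortTruth",
    "simulate_family",
    "simulate_cohort",
    "truth_compare",
    "default_pedigree_spec",
]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class PedigreeMember:
    """One pedigree position; founders have empty parent ids."""

    sample_id: str
    father_id: str
    mother_id: str
    sex: str
    generation: int
    sampled: bool = True


def default_pedigree_spec() -> list[PedigreeMember]:
    """The study-family pedigree, completed with unsampled spouses/founders.

    The published material identifies the 16 genotyped members and their
    generations but not the full structure, so the connecting founders
    (I-1, I-2) and married-in spouses are synthetic.  The candidate
    variant enters through founder I-1.
    """
    return [
        PedigreeMember("I-1", "", "", "male", 1, sampled=False),
        PedigreeMember("I-2", "", "", "female", 1, sampled=False),
        PedigreeMember("II-1", "I-1", "I-2", "male", 2),
        PedigreeMember("II-2", "I-1", "I-2", "female", 2),
        PedigreeMember("II-3", "", "", "female", 2, sampled=False),
        PedigreeMember("II-4", "", "", "male", 2, sampled=False),
        PedigreeMember("III-2", "II-1", "II-3", "female", 3),
        PedigreeMember("III-3", "II-1", "II-3", "male", 3),
        PedigreeMember("III-6", "II-1", "II-3", "male", 3),
        PedigreeMember("III-7", "II-1", "II-3", "female", 3),
        PedigreeMember("III-9", "II-1", "II-3", "male", 3),
        # married-in founders, genotyped as controls in the study table
        PedigreeMember("III-8", "", "", "female", 3),
        PedigreeMember("III-10", "", "", "female", 3),
        PedigreeMember("III-12", "II-4", "II-2", "male", 3),
        PedigreeMember("III-15", "II-4", "II-2", "female", 3),
        PedigreeMember("III-17", "II-4", "II-2", "male", 3),
        PedigreeMember("III-18", "II-4", "II-2", "female", 3),
        PedigreeMember("III-19", "II-4", "II-2", "male", 3),
        PedigreeMember("IV-19", "III-3", "III-8", "female", 4),
        PedigreeMember("IV-28", "III-19", "III-10", "male", 4),
    ]


def _observed_carrier_template() -> dict[str, int]:
    """Candidate dosage per sampled member in the observed family pattern."""
    template = {}
    for s in tremor_pedigree():
        carrier = s.phenotype == "affected" and s.sample_id != PHENOCOPY_ID
        template[s.sample_id] = 1 if carrier else 0
    # transmission path: the candidate enters through I-1, so both
    # generation-II sibs are carriers; unsampled spouses are not.
    template.update({"I-1": 1, "I-2": 0, "II-3": 0, "II-4": 0})
    return template


@dataclass
class FamilySimConfig:
    """Conditions of the family simulation.

    ``phenotype_mode='observed'`` (default) reproduces the study family's
    carrier and affection pattern exactly; ``'stochastic'`` gene-drops
    the candidate from its founder and assigns affection with the given
    penetrance and phenocopy rate.
    """

    pedigree_spec: list[PedigreeMember] = field(default_factory=default_pedigree_spec)
    causal_variant: Variant = field(default_factory=tremor_candidate_variant)
    causal_annotation: AnnotationRecord = field(
        default_factory=tremor_candidate_annotation
    )
    causal_founder: str = "I-1"
    penetrance: float = 0.9
    phenocopy_rate: float = 0.05
    n_background_variants: int = 5000
    common_fraction: float = 0.7
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    rare_maf_range: tuple[float, float] = (0.0005, 0.02)
    phenotype_mode: str = "observed"  # observed | stochastic
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.penetrance, self.phenocopy_rate, self.common_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0,1]")
        if self.phenotype_mode not in ("observed", "stochastic"):
            raise ValidationError(f"bad phenotype_mode {self.phenotype_mode!r}")
        ids = [m.sample_id for m in self.pedigree_spec]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pedigree ids")
        seen: set[str] = set()
        for m in self.pedigree_spec:
            for parent in (m.father_id, m.mother_id):
                if parent and parent not in seen:
                    raise ValidationError(
                        f"parent {parent!r} of {m.sample_id} does not precede it"
                    )
            seen.add(m.sample_id)


@dataclass
class FamilyTruth:
    dataset_id: str
    causal_key: VariantKey
    carrier_state: dict[str, int]  # candidate dosage per sampled member
    phenotype: dict[str, str]
    haplotypes: dict[str, np.ndarray] | None = None  # per member, (2, n_sites)
    site_mafs: np.ndarray | None = None  # background-site frequencies drawn

    def to_json_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "causal_key": list(self.causal_key),
            "carrier_state": self.carrier_state,
            "phenotype": self.phenotype,
        }


def _background_annotation(
    rng: np.random.Generator, key: VariantKey, maf: float, consequence: str
) -> AnnotationRecord:
    jitter = np.clip(maf * np.exp(rng.normal(0.0, 0.15, len(MAF_DATABASES))), 0.0, 1.0)
    calls = {}
    for p in PREDICTORS:
        u = rng.random()
        if u < 0.15:
            calls[p] = "missing"
        elif u < 0.25:
            calls[p] = "pathogenic"
        else:
            calls[p] = "benign"
    return AnnotationRecord(
        variant_key=key,
        maf_by_db=dict(zip(MAF_DATABASES, jitter)),
        predictor_calls=calls,
        cadd=float(rng.uniform(0, 25)),
    )


def simulate_family(
    config: FamilySimConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Generate a family dataset; optionally write vcf/ped/annotations/truth.

    Returns a dict with ``variants``, ``genotypes`` (sampled members
    only), ``samples``, ``annotations`` and ``truth``.
    """
    config = config or FamilySimConfig()
    rng = np.random.default_rng(config.seed)
    members = config.pedigree_spec
    n_bg = config.n_background_variants

    # background site frequencies from the common/rare mixture
    is_common = rng.random(n_bg) < config.common_fraction
    mafs = np.where(
        is_common,
        rng.uniform(*config.common_maf_range, n_bg),
        rng.uniform(*config.rare_maf_range, n_bg),
    )

    # gene-drop haplotypes: per member a (2, n_bg) 0/1 array
    haplo: dict[str, np.ndarray] = {}
    for m in members:
        if not m.father_id:  # founder (both parents empty by construction)
            h = (rng.random((2, n_bg)) < mafs).astype(np.int8)
        else:
            fh = haplo[m.father_id]
            mh = haplo[m.mother_id]
            pick_f = rng.integers(0, 2, n_bg)
            pick_m = rng.integers(0, 2, n_bg)
            h = np.stack([fh[pick_f, np.arange(n_bg)], mh[pick_m, np.arange(n_bg)]])
        haplo[m.sample_id] = h

    # candidate variant carrier states
    template = _observed_carrier_template()
    carrier: dict[str, int] = {}
    if config.phenotype_mode == "observed":
        for m in members:
            carrier[m.sample_id] = template.get(m.sample_id, 0)
    else:
        for m in members:
            if not m.father_id:
                carrier[m.sample_id] = 1 if m.sample_id == config.causal_founder else 0
            else:
                transmitted = sum(
                    rng.random() < 0.5 * carrier[p] for p in (m.father_id, m.mother_id)
                )
                carrier[m.sample_id] = min(transmitted, 2)

    # affection status
    observed_pheno = {s.sample_id: s.phenotype for s in tremor_pedigree()}
    observed_tier = {s.sample_id: s.tier for s in tremor_pedigree()}
    observed_age = {s.sample_id: s.age for s in tremor_pedigree()}
    phenotype: dict[str, str] = {}
    for m in members:
        if not m.sampled:
            phenotype[m.sample_id] = "unknown"
        elif config.phenotype_mode == "observed" and m.sample_id in observed_pheno:
            phenotype[m.sample_id] = observed_pheno[m.sample_id]
        else:
            rate = config.penetrance if carrier[m.sample_id] else config.phenocopy_rate
            phenotype[m.sample_id] = "affected" if rng.random() < rate else "unaffected"

    sampled = [m for m in members if m.sampled]
    sampled_ids = [m.sample_id for m in sampled]

    # assemble variants: candidate first, then background sites
    causal = config.causal_variant
    variants: list[Variant] = [causal]
    annotations: dict[VariantKey, AnnotationRecord] = {
        causal.key: config.causal_annotation
    }
    chrom_pool = [str(c) for c in range(1, 23)]
    consequences = rng.choice(
        ["synonymous", "missense", "other", "splice_site", "stop_gained", "frameshift"],
        p=[0.40, 0.44, 0.10, 0.02, 0.02, 0.02],
        size=n_bg,
    )
    positions = rng.choice(10_000_000, size=n_bg, replace=False) + 1
    ref_alt = np.array([["A", "C"], ["C", "T"], ["G", "A"], ["T", "G"]])
    ra = ref_alt[rng.integers(0, 4, n_bg)]
    for j in range(n_bg):
        v = Variant(
            chrom=str(chrom_pool[j % len(chrom_pool)]),
            pos=int(positions[j]),
            ref=str(ra[j][0]),
            alt=str(ra[j][1]),
            gene=f"BG{j % 500}",
            consequence=str(consequences[j]),
        )
        variants.append(v)
        annotations[v.key] = _background_annotation(rng, v.key, float(mafs[j]), v.consequence)

    dosage = np.empty((len(sampled_ids), n_bg + 1), dtype=np.int8)
    for i, sid in enumerate(sampled_ids):
        dosage[i, 0] = carrier[sid]
        dosage[i, 1:] = haplo[sid].sum(axis=0)
    genotypes = GenotypeMatrix(sampled_ids, [v.key for v in variants], dosage)

    samples = []
    for m in sampled:
        pheno = phenotype[m.sample_id]
        if config.phenotype_mode == "observed" and m.sample_id in observed_tier:
            tier = observed_tier[m.sample_id]
        else:
            tier = "tier1" if pheno == "affected" else "control"
        father = m.father_id if any(x.sample_id == m.father_id and x.sampled for x in members) else ""
        mother = m.mother_id if any(x.sample_id == m.mother_id and x.sampled for x in members) else ""
        samples.append(
            SampleRecord(
                sample_id=m.sample_id,
                family_id="FAM1",
                father_id=father,
                mother_id=mother,
                sex=m.sex,
                age=observed_age.get(m.sample_id, 60.0),
                phenotype=pheno,
                tier=tier,
                group="family",
            )
        )

    truth = FamilyTruth(
        dataset_id=f"family-seed{config.seed}",
        causal_key=causal.key,
        carrier_state={sid: int(carrier[sid]) for sid in sampled_ids},
        phenotype={sid: phenotype[sid] for sid in sampled_ids},
        haplotypes=haplo,
        site_mafs=mafs,
    )
    result = {
        "variants": variants,
        "genotypes": genotypes,
        "samples": samples,
        "annotations": annotations,
        "truth": truth,
    }
    if out_dir is not None:
        _write_dataset(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Conditions of the case-control resequencing cohort simulation.

    Defaults reproduce the study cohort: 820 cases and 630 controls with
    deleterious-carrier probabilities 159/820 and 55/630; exact-count
    mode plants exactly ``round(n * p)`` carriers per group.
    """

    n_cases: int = 820
    n_controls: int = 630
    n_sites: int = 60
    carrier_prob_case: float = 159 / 820
    carrier_prob_control: float = 55 / 630
    fraction_deleterious: float = 0.35
    fraction_synonymous: float = 0.35
    predictor_error_rate: float = 0.0
    syn_carrier_prob_case: float | None = None  # defaults to control value (null)
    syn_carrier_prob_control: float = 0.12
    exact_counts: bool = True
    age_mean: float = 65.0
    age_sd: float = 10.0
    sex_prob_female: float = 0.5
    gene: str = "TUB"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.carrier_prob_case,
            self.carrier_prob_control,
            self.fraction_deleterious,
            self.fraction_synonymous,
            self.predictor_error_rate,
            self.sex_prob_female,
            self.syn_carrier_prob_control,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0,1]")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.fraction_deleterious + self.fraction_synonymous > 1.0:
            raise ValidationError("site-class fractions exceed 1")
        if self.fraction_deleterious <= 0:
            raise ValidationError("need at least one deleterious site class")


@dataclass
class CohortTruth:
    dataset_id: str
    carrier: dict[str, bool]
    site_class: dict[str, str]  # key_str -> deleterious | synonymous | benign
    planted_case_carriers: int
    planted_control_carriers: int

    def to_json_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "carrier": {k: bool(v) for k, v in self.carrier.items()},
            "site_class": self.site_class,
            "planted_case_carriers": self.planted_case_carriers,
            "planted_control_carriers": self.planted_control_carriers,
        }


def _choose_carriers(
    rng: np.random.Generator, n: int, prob: float, exact: bool
) -> np.ndarray:
    if exact:
        k = int(round(n * prob))
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=k, replace=False)] = True
        return flags
    return rng.random(n) < prob


def simulate_cohort(
    config: CohortSimConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Generate a case-control cohort; optionally write the standard files.

    Returns a dict with ``variants``, ``genotypes``, ``samples``,
    ``annotations``, ``covariates`` and ``truth``.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"case{i+1}" for i in range(config.n_cases)] + [
        f"ctrl{i+1}" for i in range(config.n_controls)
    ]
    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)

    # site classes and frequencies
    n_del = max(1, int(round(config.n_sites * config.fraction_deleterious)))
    n_syn = int(round(config.n_sites * config.fraction_synonymous))
    n_ben = max(config.n_sites - n_del - n_syn, 0)
    classes = ["deleterious"] * n_del + ["synonymous"] * n_syn + ["benign"] * n_ben
    site_maf = np.concatenate(
        [
            rng.uniform(2e-4, 0.01, n_del),
            rng.uniform(2e-4, 0.015, n_syn),
            rng.uniform(2e-4, 0.015, n_ben),
        ]
    )

    positions = np.sort(rng.choice(20_000, size=config.n_sites, replace=False)) + 8_060_000
    ref_alt = np.array([["A", "C"], ["C", "T"], ["G", "A"], ["T", "G"]])
    ra = ref_alt[rng.integers(0, 4, config.n_sites)]
    variants: list[Variant] = []
    annotations: dict[VariantKey, AnnotationRecord] = {}
    for j, cls in enumerate(classes):
        consequence = "synonymous" if cls == "synonymous" else "missense"
        v = Variant(
            chrom="11",
            pos=int(positions[j]),
            ref=str(ra[j][0]),
            alt=str(ra[j][1]),
            gene=config.gene,
            consequence=consequence,
        )
        variants.append(v)
        jitter = np.clip(
            site_maf[j] * np.exp(rng.normal(0.0, 0.1, len(MAF_DATABASES))), 0.0, 1.0
        )
        truth_call = "pathogenic" if cls == "deleterious" else "benign"
        calls = {}
        for p in PREDICTORS:
            flip = rng.random() < config.predictor_error_rate
            call = truth_call
            if flip:
                call = "benign" if call == "pathogenic" else "pathogenic"
            calls[p] = call
        annotations[v.key] = AnnotationRecord(
            variant_key=v.key,
            maf_by_db=dict(zip(MAF_DATABASES, jitter)),
            predictor_calls=calls,
            cadd=float(rng.uniform(15, 35)) if cls == "deleterious" else float(rng.uniform(0, 15)),
        )

    dosage = np.zeros((n, config.n_sites), dtype=np.int8)

    # deleterious carriers: person-level status, then one het site per carrier
    carrier = np.empty(n, dtype=bool)
    carrier[is_case] = _choose_carriers(
        rng, config.n_cases, config.carrier_prob_case, config.exact_counts
    )
    carrier[~is_case] = _choose_carriers(
        rng, config.n_controls, config.carrier_prob_control, config.exact_counts
    )
    del_idx = np.arange(n_del)
    del_weights = site_maf[:n_del] / site_maf[:n_del].sum()
    assigned = rng.choice(del_idx, size=int(carrier.sum()), p=del_weights)
    dosage[np.flatnonzero(carrier), assigned] = 1

    # synonymous sites: person-level carrier status independent of the
    # deleterious signal, with configurable (default equal) group rates
    syn_case = (
        config.syn_carrier_prob_case
        if config.syn_carrier_prob_case is not None
        else config.syn_carrier_prob_control
    )
    if n_syn:
        syn_carrier = np.empty(n, dtype=bool)
        syn_carrier[is_case] = rng.random(config.n_cases) < syn_case
        syn_carrier[~is_case] = rng.random(config.n_controls) < config.syn_carrier_prob_control
        syn_idx = np.arange(n_del, n_del + n_syn)
        syn_weights = site_maf[syn_idx] / site_maf[syn_idx].sum()
        syn_assigned = rng.choice(syn_idx, size=int(syn_carrier.sum()), p=syn_weights)
        dosage[np.flatnonzero(syn_carrier), syn_assigned] = 1

    # benign background sites: Hardy-Weinberg draws independent of phenotype
    if n_ben:
        ben_idx = np.arange(n_del + n_syn, config.n_sites)
        dosage[:, ben_idx] = rng.binomial(2, site_maf[ben_idx], size=(n, n_ben)).astype(
            np.int8
        )

    genotypes = GenotypeMatrix(sample_ids, [v.key for v in variants], dosage)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 30, 95).round(1)
    sex = np.where(rng.random(n) < config.sex_prob_female, "female", "male")
    covariates = pd.DataFrame(
        {"sample_id": sample_ids, "age": age, "sex": sex}
    ).set_index("sample_id", drop=False)

    samples = [
        SampleRecord(
            sample_id=sid,
            sex=s,
            age=float(a),
            phenotype="affected" if c else "unaffected",
            tier="tier1" if c else "none",
            group="cohort_case" if c else "cohort_control",
        )
        for sid, c, a, s in zip(sample_ids, is_case, age, sex)
    ]

    truth = CohortTruth(
        dataset_id=f"cohort-seed{config.seed}",
        carrier={sid: bool(c) for sid, c in zip(sample_ids, carrier)},
        site_class={v.key_str: cls for v, cls in zip(variants, classes)},
        planted_case_carriers=int(carrier[is_case].sum()),
        planted_control_carriers=int(carrier[~is_case].sum()),
    )
    result = {
        "variants": variants,
        "genotypes": genotypes,
        "samples": samples,
        "annotations": annotations,
        "covariates": covariates,
        "truth": truth,
    }
    if out_dir is not None:
        _write_dataset(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# Output and truth comparison
# ---------------------------------------------------------------------------

def _write_dataset(result: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variant_io.write_vcf(result["variants"], result["genotypes"], out / "dataset.vcf")
    variant_io.write_ped(result["samples"], out / "dataset.ped")
    variant_io.write_annotations(
        list(result["annotations"].values()), out / "annotations.tsv", result["variants"]
    )
    if "covariates" in result:
        variant_io.write_covariates(result["covariates"], out / "covariates.tsv")
    with open(out / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(result["truth"].to_json_dict(), fh, indent=2)


def truth_compare(truth, output, output_dataset_id: str | None = None) -> dict:
    """Compare pipeline output against the generator's truth record.

    ``truth`` is a :class:`FamilyTruth` or :class:`CohortTruth`;
    ``output`` a cascade result (family) or burden result (cohort).
    Raises on mismatched dataset ids when both declare one.
    """
    if output_dataset_id is not None and output_dataset_id != truth.dataset_id:
        raise ValidationError(
            f"dataset id mismatch: truth {truth.dataset_id!r} vs output "
            f"{output_dataset_id!r}"
        )
    if isinstance(truth, FamilyTruth):
        candidates = [tuple(k) for k in output.candidates]
        return {
            "dataset_id": truth.dataset_id,
            "causal_recovered": tuple(truth.causal_key) in candidates,
            "n_candidates": len(candidates),
        }
    if isinstance(truth, CohortTruth):
        table = output.carrier_table
        return {
            "dataset_id": truth.dataset_id,
            "case_carrier_error": table.case_carriers - truth.planted_case_carriers,
            "control_carrier_error": table.control_carriers
            - truth.planted_control_carriers,
            "enrichment_flagged": output.fisher_p < 0.05,
            "fisher_p": output.fisher_p,
            "skato_p": output.skato_p,
        }
    raise TypeError(f"unsupported truth record {type(truth).__name__}")
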