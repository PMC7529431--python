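"""Variant-prioritization cascade for a dominant-tremor pedigree.

The cascade mirrors the standard exome-prioritization recipe for an
autosomal-dominant trait in a multiplex family:

1. five population-frequency filters (1KG, UK10K, dbSNP144, NHLBI, ExAC),
   each retaining variants with MAF strictly below a threshold (default
   0.02, chosen because the trait is common in the population);
2. a consequence filter retaining protein-altering classes (missense,
   stop gained/lost, frameshift, splice site);
3. a dominant segregation filter retaining variants carried by at least
   *k* affected members (default 9 of 10, tolerating one phenocopy) and
   by no unaffected member.

A consensus deleteriousness verdict over nine in-silico predictors
(majority vote of pathogenic vs benign calls) is also provided; it is
used by the cohort burden analysis rather than by the family cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import (
    MAF_DATABASES,
    NONSYNONYMOUS_CLASSES,
    AnnotationRecord,
    GenotypeMatrix,
    SampleRecord,
    Variant,
)
from .exceptions import ConfigurationError

__all__ = [
    "FilterConfig",
    "CascadeResult",
    "maf_filter",
    "consequence_filter",
    "segregation_filter",
    "consensus_verdict",
    "run_cascade",
]

VariantKey = tuple[str, int, str, str]


@dataclass
class FilterConfig:
    """Configuration of the prioritization cascade.

    ``min_affected_carriers`` is the phenocopy-tolerant segregation
    threshold *k*: a candidate must be carried by at least *k* affected
    members.  ``max_control_carriers`` bounds carriers among unaffected
    members (0 = strict absence from controls).
    """

    maf_threshold: float = 0.02
    databases: tuple[str, ...] = MAF_DATABASES
    consequence_classes: frozenset[str] = NONSYNONYMOUS_CLASSES
    min_affected_carriers: int = 9
    max_affected: int = 10
    max_control_carriers: int = 0
    missing_maf_policy: str = "keep"  # keep | drop
    missing_genotype_policy: str = "neutral"  # neutral | as_noncarrier

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ConfigurationError(f"maf_threshold {self.maf_threshold} outside [0,1]")
        if self.min_affected_carriers < 0:
            raise ConfigurationError("min_affected_carriers must be >= 0")
        if self.missing_maf_policy not in ("keep", "drop"):
            raise ConfigurationError(f"bad missing_maf_policy {self.missing_maf_policy!r}")
        if self.missing_genotype_policy not in ("neutral", "as_noncarrier"):
            raise ConfigurationError(
                f"bad missing_genotype_policy {self.missing_genotype_policy!r}"
            )
        unknown = set(self.databases) - set(MAF_DATABASES)
        if unknown:
            raise ConfigurationError(f"unknown database(s) {sorted(unknown)}")


@dataclass
class CascadeResult:
    """Ordered per-step survivor counts and the final candidate list."""

    n_input: int = 0
    steps: list[tuple[str, str, int, list[VariantKey]]] = field(default_factory=list)
    candidates: list[VariantKey] = field(default_factory=list)

    def add_step(self, name: str, config_fragment: str, survivors: Sequence[VariantKey]) -> None:
        survivors = list(survivors)
        previous = self.steps[-1][2] if self.steps else self.n_input
        if len(survivors) > previous:
            raise ValueError("survivor count increased along the cascade")
        self.steps.append((name, config_fragment, len(survivors), survivors))

    @property
    def counts(self) -> list[int]:
        return [n for _, _, n, _ in self.steps]

    def to_table(self) -> list[dict]:
        return [
            {"step_name": name, "threshold": frag, "surviving_count": n}
            for name, frag, n, _ in self.steps
        ]


def _order_preserving(
    variants: Sequence[Variant | VariantKey], keep: set[VariantKey]
) -> list[VariantKey]:
    out = []
    for v in variants:
        key = v.key if isinstance(v, Variant) else tuple(v)
        if key in keep:
            out.append(key)
    return out


def _as_keys(variants: Iterable[Variant | VariantKey]) -> list[VariantKey]:
    return [v.key if isinstance(v, Variant) else tuple(v) for v in variants]


def maf_filter(
    variants: Sequence[Variant | VariantKey],
    annotations: Mapping[VariantKey, AnnotationRecord],
    database: str,
    threshold: float,
    missing_maf_policy: str = "keep",
) -> list[VariantKey]:
    """Retain variants with ``MAF < threshold`` in one population database.

    The comparison is strict (a frequency equal to the threshold is
    removed).  A variant absent from the database is retained under the
    default ``keep`` policy — absence from a population catalogue is
    evidence of rarity, not of commonness.
    """
    if database not in MAF_DATABASES:
        raise ConfigurationError(f"unknown database {database!r}")
    keys = _as_keys(variants)
    survivors = []
    for key in keys:
        rec = annotations.get(key)
        freq = rec.maf_by_db.get(database) if rec is not None else None
        if freq is None:
            if missing_maf_policy == "keep":
                survivors.append(key)
        elif freq < threshold:
            survivors.append(key)
    return survivors


def consequence_filter(
    variants: Sequence[Variant], classes: Iterable[str]
) -> list[VariantKey]:
    """Retain exactly the variants whose consequence class is in ``classes``."""
    classes = frozenset(classes)
    if not classes:
        raise ConfigurationError("empty consequence class set")
    return [v.key for v in variants if v.consequence in classes]


def segregation_filter(
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    config: FilterConfig,
    variants: Sequence[Variant | VariantKey] | None = None,
) -> tuple[list[VariantKey], dict[VariantKey, tuple[int, int]]]:
    """Dominant segregation filter with phenocopy tolerance.

    A variant survives iff at least ``config.min_affected_carriers``
    affected samples carry it (dosage >= 1) and at most
    ``config.max_control_carriers`` unaffected samples do.  Under the
    default ``neutral`` policy a missing genotype contributes to neither
    count.  Returns the surviving keys plus per-variant
    ``(affected_carriers, unaffected_carriers)`` counts for every variant
    considered.
    """
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    affected_rows = [
        sample_index[s.sample_id] for s in samples if s.phenotype == "affected"
    ]
    unaffected_rows = [
        sample_index[s.sample_id] for s in samples if s.phenotype == "unaffected"
    ]
    if not affected_rows:
        raise ConfigurationError("segregation filter needs at least one affected sample")

    if variants is None:
        keys = [tuple(k) for k in genotypes.variants]
        matrix = genotypes
    else:
        keys = _as_keys(variants)
        matrix = genotypes.subset_variants(keys)

    dos = matrix.dosage
    carrier = dos >= 1
    if config.missing_genotype_policy == "neutral":
        # missing (-1) is already non-carrier in `carrier`; nothing more needed
        pass
    aff_counts = carrier[affected_rows].sum(axis=0)
    ctrl_counts = carrier[unaffected_rows].sum(axis=0)

    counts = {
        key: (int(a), int(c)) for key, a, c in zip(keys, aff_counts, ctrl_counts)
    }
    survivors = [
        key
        for key, a, c in zip(keys, aff_counts, ctrl_counts)
        if a >= config.min_affected_carriers and c <= config.max_control_carriers
    ]
    return survivors, counts


def consensus_verdict(calls: Mapping[str, str]) -> str:
    """Majority vote over the nine predictor calls.

    ``deleterious`` iff pathogenic calls strictly outnumber benign calls
    among non-missing predictors; ``benign`` for the reverse; ``unknown``
    on a tie or when every predictor is missing.  ``unknown`` is never
    treated as deleterious downstream.
    """
    n_path = sum(1 for c in calls.values() if c == "pathogenic")
    n_benign = sum(1 for c in calls.values() if c == "benign")
    if n_path > n_benign:
        return "deleterious"
    if n_benign > n_path:
        return "benign"
    return "unknown"


def run_cascade(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, AnnotationRecord] | Sequence[AnnotationRecord],
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    config: FilterConfig | None = None,
) -> CascadeResult:
    """Run the full prioritization cascade and record per-step survivors.

    Step order: the five database MAF filters, the consequence filter,
    then the segregation filter reported as its two clauses (affected
    carriers, then control carriers).
    """
    config = config or FilterConfig()
    if not isinstance(annotations, Mapping):
        annotations = {tuple(rec.variant_key): rec for rec in annotations}
    by_key = {v.key: v for v in variants}

    current = [v.key for v in variants]
    result = CascadeResult(n_input=len(current))

    for db in config.databases:
        survivors = set(
            maf_filter(
                current, annotations, db, config.maf_threshold, config.missing_maf_policy
            )
        )
        current = _order_preserving(current, survivors)
        result.add_step(f"maf_{db}", f"MAF < {config.maf_threshold:g}", current)

    survivors = set(
        consequence_filter([by_key[k] for k in current], config.consequence_classes)
    )
    current = _order_preserving(current, survivors)
    result.add_step(
        "consequence", ",".join(sorted(config.consequence_classes)), current
    )

    # segregation filter, reported clause by clause
    _, counts = segregation_filter(genotypes, samples, config, variants=current)
    k = config.min_affected_carriers
    current = [key for key in current if counts[key][0] >= k]
    result.add_step("affected_carriers", f">= {k} affected carriers", current)
    m = config.max_control_carriers
    current = [key for key in current if counts[key][1] <= m]
    result.add_step("control_carriers", f"<= {m} control carriers", current)

    result.candidates = list(current)
    return result
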