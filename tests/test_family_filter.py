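"""Prioritization cascade: filter semantics, oracles, and the study pedigree."""

import itertools

import numpy as np
import pytest

from famburden.datasets import (
    PHENOCOPY_ID,
    tremor_candidate_annotation,
    tremor_genotypes,
    tremor_pedigree,
)
from famburden.datatypes import (
    MAF_DATABASES,
    NONSYNONYMOUS_CLASSES,
    PREDICTORS,
    AnnotationRecord,
    GenotypeMatrix,
    Variant,
)
from famburden.exceptions import ConfigurationError
from famburden.family_filter import (
    CascadeResult,
    FilterConfig,
    consensus_verdict,
    consequence_filter,
    maf_filter,
    run_cascade,
    segregation_filter,
)
from famburden.simulate import FamilySimConfig, simulate_family


def random_annotated_variants(rng, n=1000, missing_rate=0.15):
    """Fixture generator: variants with random MAFs and consequences."""
    consequences = list(NONSYNONYMOUS_CLASSES) + ["synonymous", "other"]
    variants, annotations = [], {}
    for j in range(n):
        v = Variant(
            "1", j + 1, "G", "A", gene=f"G{j}",
            consequence=consequences[rng.integers(len(consequences))],
        )
        maf = {}
        for db in MAF_DATABASES:
            if rng.random() < missing_rate:
                maf[db] = None
            else:
                # spectrum straddling the 0.02 threshold
                maf[db] = float(rng.choice([rng.uniform(0, 0.02), rng.uniform(0.02, 0.5)]))
        variants.append(v)
        annotations[v.key] = AnnotationRecord(v.key, maf_by_db=maf)
    return variants, annotations


class TestMafFilter:
    def test_above_threshold_removed(self):
        v = Variant("1", 1, "G", "A")
        ann = {v.key: AnnotationRecord(v.key, maf_by_db={"1KG": 0.05})}
        assert maf_filter([v], ann, "1KG", 0.02) == []

    def test_threshold_comparison_is_strict(self):
        v = Variant("1", 1, "G", "A")
        ann = {v.key: AnnotationRecord(v.key, maf_by_db={"1KG": 0.02})}
        assert maf_filter([v], ann, "1KG", 0.02) == []

    def test_missing_maf_policy(self):
        v = Variant("1", 1, "G", "A")
        ann = {v.key: AnnotationRecord(v.key)}
        assert maf_filter([v], ann, "ExAC", 0.02) == [v.key]
        assert maf_filter([v], ann, "ExAC", 0.02, missing_maf_policy="drop") == []

    def test_unknown_database(self):
        with pytest.raises(ConfigurationError):
            maf_filter([], {}, "gnomAD", 0.02)

    def test_brute_force_oracle(self, rng):
        variants, annotations = random_annotated_variants(rng)
        for db in MAF_DATABASES:
            survivors = maf_filter(variants, annotations, db, 0.02)
            expected = [
                v.key
                for v in variants
                if annotations[v.key].maf_by_db[db] is None
                or annotations[v.key].maf_by_db[db] < 0.02
            ]
            assert survivors == expected

    def test_database_order_commutes_on_sets(self, rng):
        variants, annotations = random_annotated_variants(rng, n=300)
        reference = None
        for order in itertools.islice(itertools.permutations(MAF_DATABASES), 6):
            keys = [v.key for v in variants]
            for db in order:
                keys = maf_filter(keys, annotations, db, 0.02)
            if reference is None:
                reference = set(keys)
            assert set(keys) == reference


class TestConsequenceFilter:
    def test_default_classes(self):
        syn = Variant("1", 1, "G", "A", consequence="synonymous")
        fs = Variant("1", 2, "G", "A", consequence="frameshift")
        assert consequence_filter([syn, fs], NONSYNONYMOUS_CLASSES) == [fs.key]

    def test_empty_class_set(self):
        with pytest.raises(ConfigurationError):
            consequence_filter([], set())

    def test_brute_force_oracle(self, rng):
        variants, _ = random_annotated_variants(rng, n=500)
        survivors = consequence_filter(variants, NONSYNONYMOUS_CLASSES)
        assert survivors == [v.key for v in variants if v.consequence in NONSYNONYMOUS_CLASSES]


class TestSegregationFilter:
    def test_study_pedigree_nine_of_ten(self):
        """The printed family genotype table: 9/10 affected carriers, 0 controls."""
        variant, genotypes = tremor_genotypes()
        samples = tremor_pedigree()
        survivors, counts = segregation_filter(genotypes, samples, FilterConfig())
        assert survivors == [variant.key]
        assert counts[variant.key] == (9, 0)
        # the affected non-carrier is the thyroidectomy phenocopy
        noncarrier_affected = [
            s.sample_id
            for s in samples
            if s.phenotype == "affected"
            and genotypes.sample_row(s.sample_id)[0] == 0
        ]
        assert noncarrier_affected == [PHENOCOPY_ID]

    def test_full_cosegregation_required_removes(self):
        _, genotypes = tremor_genotypes()
        cfg = FilterConfig(min_affected_carriers=10)
        survivors, _ = segregation_filter(genotypes, tremor_pedigree(), cfg)
        assert survivors == []

    def test_zero_affected_raises(self):
        _, genotypes = tremor_genotypes()
        controls = [s for s in tremor_pedigree() if s.phenotype == "unaffected"]
        with pytest.raises(ConfigurationError):
            segregation_filter(genotypes, controls, FilterConfig())

    def test_missing_genotype_is_neutral(self):
        variant, genotypes = tremor_genotypes()
        dosage = genotypes.dosage.copy()
        dosage[0, 0] = -1  # II-1 (affected carrier) becomes missing
        gm = GenotypeMatrix(genotypes.samples, genotypes.variants, dosage)
        _, counts = segregation_filter(gm, tremor_pedigree(), FilterConfig())
        assert counts[variant.key] == (8, 0)

    def test_brute_force_recount(self, rng):
        """Random 500-variant fixture at the relaxed k=6 criterion."""
        samples = tremor_pedigree()
        n, m = len(samples), 500
        dosage = rng.choice([0, 1, 2, -1], p=[0.55, 0.25, 0.1, 0.1], size=(n, m))
        keys = [("1", j + 1, "G", "A") for j in range(m)]
        gm = GenotypeMatrix([s.sample_id for s in samples], keys, dosage)
        cfg = FilterConfig(min_affected_carriers=6)
        survivors, counts = segregation_filter(gm, samples, cfg)
        affected = {s.sample_id for s in samples if s.phenotype == "affected"}
        expected = []
        for j, key in enumerate(keys):
            aff = sum(
                1 for i, sid in enumerate(gm.samples)
                if sid in affected and dosage[i, j] >= 1
            )
            ctl = sum(
                1 for i, sid in enumerate(gm.samples)
                if sid not in affected and dosage[i, j] >= 1
            )
            assert counts[key] == (aff, ctl)
            if aff >= 6 and ctl == 0:
                expected.append(key)
        assert survivors == expected


class TestConsensusVerdict:
    def test_eight_vs_one_is_deleterious(self):
        calls = tremor_candidate_annotation().predictor_calls
        assert sum(1 for c in calls.values() if c == "pathogenic") == 8
        assert consensus_verdict(calls) == "deleterious"

    @pytest.mark.parametrize(
        "n_path,n_benign,n_missing,expected",
        [
            (0, 9, 0, "benign"),
            (4, 4, 1, "unknown"),
            (0, 0, 9, "unknown"),
            (5, 4, 0, "deleterious"),
            (1, 0, 8, "deleterious"),
        ],
    )
    def test_majority_rule(self, n_path, n_benign, n_missing, expected):
        calls = dict(
            zip(
                PREDICTORS,
                ["pathogenic"] * n_path + ["benign"] * n_benign + ["missing"] * n_missing,
            )
        )
        assert consensus_verdict(calls) == expected


class TestCascade:
    def test_planted_causal_is_sole_candidate(self):
        for seed in range(5):
            fam = simulate_family(FamilySimConfig(n_background_variants=400, seed=seed))
            res = run_cascade(
                fam["variants"], fam["annotations"], fam["genotypes"],
                fam["samples"], FilterConfig(),
            )
            assert res.candidates == [fam["truth"].causal_key]

    def test_counts_monotone_and_consistent(self, family_dataset):
        res = run_cascade(
            family_dataset["variants"],
            family_dataset["annotations"],
            family_dataset["genotypes"],
            family_dataset["samples"],
            FilterConfig(),
        )
        counts = res.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] <= res.n_input
        assert len(res.steps) == 8
        for _, _, n, keys in res.steps:
            assert n == len(keys)

    def test_single_filter_idempotent(self, rng):
        variants, annotations = random_annotated_variants(rng, n=300)
        once = maf_filter(variants, annotations, "1KG", 0.02)
        twice = maf_filter(once, annotations, "1KG", 0.02)
        assert once == twice

    def test_zero_threshold(self, rng):
        """At threshold 0 only variants with no recorded frequency survive MAF steps."""
        variants, annotations = random_annotated_variants(rng, n=200)
        res = run_cascade(
            variants, annotations,
            GenotypeMatrix(
                [s.sample_id for s in tremor_pedigree()],
                [v.key for v in variants],
                np.ones((16, 200), dtype=np.int8),
            ),
            tremor_pedigree(),
            FilterConfig(maf_threshold=0.0, min_affected_carriers=0,
                         max_control_carriers=16),
        )
        after_maf = set(res.steps[4][3])
        expected = {
            v.key for v in variants
            if all(annotations[v.key].maf_by_db[db] is None for db in MAF_DATABASES)
        }
        assert after_maf == expected

    def test_empty_variant_list(self):
        affected = tremor_pedigree()[0]  # II-1, affected
        res = run_cascade(
            [], {},
            GenotypeMatrix([affected.sample_id], [], np.empty((1, 0), dtype=np.int8)),
            [affected],
            FilterConfig(),
        )
        assert res.counts == [0] * 8
        assert res.candidates == []

    def test_survivor_count_cannot_increase(self):
        res = CascadeResult(n_input=1)
        res.add_step("a", "", [])
        with pytest.raises(ValueError):
            res.add_step("b", "", [("1", 1, "G", "A")])
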