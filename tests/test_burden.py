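"""Cohort association: Fisher, subsampling, null model, SKAT/SKAT-O."""

import numpy as np
import pytest
from scipy.stats import chi2, fisher_exact, hypergeom

from famburden.burden import (
    BurdenConfig,
    CarrierTable,
    CohortDataset,
    bootstrap_carriers,
    carrier_status,
    fisher_two_tailed,
    fit_null_model,
    run_burden,
    skat_pvalue,
    skat_statistic,
    skato,
    synonymous_control,
    _kernel_matrix,
    _weighted_genotypes,
)
from famburden.datatypes import GenotypeMatrix
from famburden.exceptions import (
    ConfigurationError,
    ConvergenceError,
    DegenerateStatisticError,
    SeparationError,
)
from famburden.simulate import CohortSimConfig, simulate_cohort


class TestCarrierStatus:
    def make_matrix(self, dosage):
        dosage = np.asarray(dosage, dtype=np.int8)
        samples = [f"s{i}" for i in range(dosage.shape[0])]
        keys = [("1", j + 1, "G", "A") for j in range(dosage.shape[1])]
        return GenotypeMatrix(samples, keys, dosage)

    def test_het_at_one_site_is_carrier(self):
        gm = self.make_matrix([[0, 1, 0], [0, 0, 0]])
        carrier, excluded = carrier_status(gm, gm.variants)
        assert carrier.tolist() == [True, False]
        assert excluded == []

    def test_all_missing_sample_excluded(self):
        gm = self.make_matrix([[-1, -1], [0, 1]])
        carrier, excluded = carrier_status(gm, gm.variants)
        assert excluded == ["s0"]
        assert carrier.tolist()[1] is True

    def test_empty_set_rejected(self):
        gm = self.make_matrix([[0]])
        with pytest.raises(ConfigurationError):
            carrier_status(gm, [])


class TestFisherTwoTailed:
    def test_study_carrier_table_upper_bound(self):
        """159/820 vs 55/630 carriers: at least as significant as 5.30e-07."""
        p = fisher_two_tailed(CarrierTable(159, 661, 55, 575))
        assert p <= 5.30e-07

    def test_balanced_table_p_one(self):
        assert fisher_two_tailed(CarrierTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_small_table_exact_enumeration(self):
        # hypergeometric enumeration: p = (4 + 16 + 4 + 4 + 4 + 2*1)/70 = 34/70
        assert fisher_two_tailed(CarrierTable(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_zero_margin_gives_one(self):
        assert fisher_two_tailed(CarrierTable(0, 10, 0, 10)) == 1.0

    @pytest.mark.parametrize("table", [(5, 9, 2, 14), (1, 7, 6, 3), (12, 2, 4, 9)])
    def test_matches_scipy_and_swap_invariance(self, table):
        a, b, c, d = table
        p = fisher_two_tailed(CarrierTable(a, b, c, d))
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], rel=1e-9)
        assert p == pytest.approx(fisher_two_tailed(CarrierTable(c, d, a, b)), rel=1e-12)
        assert p == pytest.approx(fisher_two_tailed(CarrierTable(b, a, d, c)), rel=1e-12)

    def test_p_decreases_away_from_expectation(self):
        # fixed margins 20/20, 16 carriers; mode at a=8
        support = range(max(0, 16 - 20), min(20, 16) + 1)
        ps = {a: fisher_two_tailed(CarrierTable(a, 20 - a, 16 - a, 20 - (16 - a)))
              for a in support}
        for a in range(9, 17):
            assert ps[a] <= ps[a - 1] + 1e-12
        for a in range(7, -1, -1):
            assert ps[a] <= ps[a + 1] + 1e-12


class TestBootstrap:
    def test_exhaustive_small_case_matches_hypergeometric(self):
        # N=4 pool with K=2 carriers, draws of 2: P(0)=1/6, P(1)=4/6, P(2)=1/6
        summary = bootstrap_carriers(4, 2, 2, 30000, seed=7)
        freqs = {k: v / 30000 for k, v in summary.histogram.items()}
        assert freqs[0] == pytest.approx(1 / 6, abs=0.01)
        assert freqs[1] == pytest.approx(4 / 6, abs=0.01)
        assert freqs[2] == pytest.approx(1 / 6, abs=0.01)

    def test_no_carriers_all_zero(self):
        summary = bootstrap_carriers(820, 0, 630, 100, seed=0)
        assert summary.minimum == summary.maximum == 0

    def test_mean_and_variance_match_hypergeometric_law(self):
        n_pool, k, n_draw, reps = 820, 159, 630, 1000
        summary = bootstrap_carriers(n_pool, k, n_draw, reps, seed=3)
        mean = n_draw * k / n_pool
        var = n_draw * (k / n_pool) * (1 - k / n_pool) * (n_pool - n_draw) / (n_pool - 1)
        assert summary.mean == pytest.approx(mean, abs=3 * np.sqrt(var / reps))
        counts = np.repeat(
            list(summary.histogram.keys()), list(summary.histogram.values())
        )
        assert counts.var() == pytest.approx(var, rel=0.15)

    def test_deterministic_given_seed(self):
        a = bootstrap_carriers(820, 159, 630, 200, seed=42)
        b = bootstrap_carriers(820, 159, 630, 200, seed=42)
        assert a == b

    def test_with_replacement_is_binomial(self):
        reps = 20000
        s = bootstrap_carriers(820, 159, 630, reps, seed=1, with_replacement=True)
        p = 159 / 820
        var = 630 * p * (1 - p)  # binomial variance exceeds hypergeometric
        assert s.mean == pytest.approx(630 * p, abs=3 * np.sqrt(var / reps))

    def test_oversized_resample_rejected(self):
        with pytest.raises(ConfigurationError):
            bootstrap_carriers(100, 10, 200, 10, seed=0)


class TestNullModel:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(820), np.zeros(630)]
        null = fit_null_model(y)
        assert null.params[0] == pytest.approx(np.log(820 / 630), rel=1e-8)
        assert null.mu == pytest.approx(np.full(1450, 820 / 1450), rel=1e-8)

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.normal(0, 1, n)
        beta = 0.7
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + beta * x)))).astype(float)
        null = fit_null_model(y, x)
        se = 3 / np.sqrt(n * 0.2)  # generous 3-SE band
        assert null.params[1] == pytest.approx(beta, abs=se)

    def test_complete_separation_raises(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), -np.ones(20)]
        with pytest.raises((SeparationError, ConvergenceError)):
            fit_null_model(y, x)

    def test_constant_phenotype_raises(self):
        with pytest.raises(ConvergenceError):
            fit_null_model(np.ones(30))


def simulated_test_data(rng, n=400, m=12, beta_scale=0.0):
    maf = rng.uniform(0.01, 0.1, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    age = rng.normal(0, 1, n)
    sex = rng.integers(0, 2, n).astype(float)
    beta = rng.normal(0, beta_scale, m)
    logit = -0.3 + 0.2 * age + 0.1 * sex + G @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    return G, y, np.column_stack([age, sex])


class TestSkat:
    def test_single_variant_reduces_to_score_test(self, rng):
        G, y, X = simulated_test_data(rng, m=1)
        null = fit_null_model(y, X)
        p, _ = skat_pvalue(G, null)
        Z = _weighted_genotypes(G, None, (1.0, 25.0))
        score = float(Z[:, 0] @ null.residuals)
        sigma = _kernel_matrix(Z, null)[0, 0]
        assert p == pytest.approx(chi2.sf(score**2 / sigma, 1), rel=1e-10)

    def test_q_matches_dense_quadratic_form(self, rng):
        G, y, X = simulated_test_data(rng)
        null = fit_null_model(y, X)
        q, lam = skat_statistic(G, None, null)
        Z = _weighted_genotypes(G, None, (1.0, 25.0))
        r = null.residuals
        assert q == pytest.approx(float(r @ Z @ Z.T @ r), rel=1e-10)
        # eigenvalues must sum to the kernel trace
        assert lam.sum() == pytest.approx(np.trace(_kernel_matrix(Z, null)), rel=1e-8)

    def test_monomorphic_set_rejected(self, rng):
        _, y, X = simulated_test_data(rng)
        null = fit_null_model(y, X)
        with pytest.raises(DegenerateStatisticError):
            skat_statistic(np.zeros((400, 3)), None, null)

    def test_variant_reordering_invariance(self, rng):
        G, y, X = simulated_test_data(rng)
        null = fit_null_model(y, X)
        p1, _ = skat_pvalue(G, null)
        perm = rng.permutation(G.shape[1])
        p2, _ = skat_pvalue(G[:, perm], null)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_covariate_affine_rescaling_invariance(self, rng):
        G, y, X = simulated_test_data(rng)
        p1, _ = skat_pvalue(G, fit_null_model(y, X))
        p2, _ = skat_pvalue(G, fit_null_model(y, 3.0 * X + 7.0))
        assert p1 == pytest.approx(p2, rel=1e-6)


class TestSkatO:
    def test_rho_one_equals_weighted_burden(self, rng):
        G, y, X = simulated_test_data(rng)
        null = fit_null_model(y, X)
        res = skato(G, config=BurdenConfig(rho_grid=(1.0,)), null=null)
        Z = _weighted_genotypes(G, None, (1.0, 25.0))
        score = Z.T @ null.residuals
        q_burden = float(score.sum() ** 2)
        sigma = _kernel_matrix(Z, null)
        var_burden = float(np.ones(Z.shape[1]) @ sigma @ np.ones(Z.shape[1]))
        assert res["p"] == pytest.approx(chi2.sf(q_burden / var_burden, 1), rel=1e-6)

    def test_rho_zero_equals_skat(self, rng):
        G, y, X = simulated_test_data(rng)
        null = fit_null_model(y, X)
        res = skato(G, config=BurdenConfig(rho_grid=(0.0,)), null=null)
        p_skat, _ = skat_pvalue(G, null)
        assert res["p"] == pytest.approx(p_skat, rel=1e-9)

    def test_omnibus_p_bounded_by_bonferroni(self, rng):
        G, y, X = simulated_test_data(rng, beta_scale=0.4)
        null = fit_null_model(y, X)
        res = skato(G, config=BurdenConfig(), null=null)
        assert res["p"] <= min(res["p_per_rho"]) * len(res["rho_grid"]) + 1e-12
        assert res["p"] >= min(res["p_per_rho"]) * 0.999  # selection is accounted for
        assert res["rho_hat"] in res["rho_grid"]

    def test_rho_grid_requires_endpoints(self):
        with pytest.raises(ConfigurationError):
            BurdenConfig(rho_grid=(0.0, 0.5))


class TestSynonymousControl:
    def test_identical_groups_p_one(self):
        """All-synonymous fixture with identical genotypes in both groups."""
        from famburden.datatypes import AnnotationRecord, Variant

        variants = [
            Variant("11", 100 + j, "G", "A", gene="TUB", consequence="synonymous")
            for j in range(4)
        ]
        annotations = {v.key: AnnotationRecord(v.key) for v in variants}
        rng = np.random.default_rng(0)
        block = rng.choice([0, 1], p=[0.8, 0.2], size=(50, 4)).astype(np.int8)
        dosage = np.vstack([block, block])  # cases mirror controls exactly
        samples = [f"s{i}" for i in range(100)]
        gm = GenotypeMatrix(samples, [v.key for v in variants], dosage)
        y = np.r_[np.ones(50, dtype=bool), np.zeros(50, dtype=bool)]
        p = synonymous_control(variants, annotations, gm, y, BurdenConfig())
        assert p == pytest.approx(1.0)

    def test_planted_enrichment_monotone(self):
        ps = []
        for syn_case in (0.12, 0.25, 0.45):
            coh = simulate_cohort(
                CohortSimConfig(seed=9, syn_carrier_prob_case=syn_case)
            )
            y = np.array([s.group == "cohort_case" for s in coh["samples"]])
            ps.append(
                synonymous_control(
                    coh["variants"], coh["annotations"], coh["genotypes"], y,
                    BurdenConfig(),
                )
            )
        assert ps[0] > ps[1] > ps[2]
        assert ps[2] < 1e-6

    def test_null_p_values_approximately_uniform(self):
        """With no planted synonymous differential, control p-values over
        200 simulated cohorts are consistent with uniformity (KS at 0.01)."""
        from scipy.stats import kstest

        ps = []
        for rep in range(200):
            coh = simulate_cohort(CohortSimConfig(seed=5000 + rep))
            y = np.array([s.group == "cohort_case" for s in coh["samples"]])
            ps.append(
                synonymous_control(
                    coh["variants"], coh["annotations"], coh["genotypes"], y,
                    BurdenConfig(),
                )
            )
        _, ks_p = kstest(np.asarray(ps, dtype=float), "uniform")
        assert ks_p > 0.01

    def test_no_synonymous_variants_returns_none(self):
        coh = simulate_cohort(
            CohortSimConfig(seed=1, n_sites=10, fraction_deleterious=0.5,
                            fraction_synonymous=0.0)
        )
        y = np.array([s.group == "cohort_case" for s in coh["samples"]])
        p = synonymous_control(
            coh["variants"], coh["annotations"], coh["genotypes"], y, BurdenConfig()
        )
        assert p is None


class TestRunBurden:
    def test_planted_carrier_table_recovered(self, cohort_burden_result):
        assert cohort_burden_result.carrier_table.as_tuple() == (159, 661, 55, 575)
        assert cohort_burden_result.fisher_p <= 5.30e-07
        assert 0 < cohort_burden_result.skato_p <= 1

    def test_bootstrap_summary_shape(self, cohort_burden_result):
        b = cohort_burden_result.bootstrap_summary
        assert b.n_resamples == 1000
        assert b.minimum <= b.mean <= b.maximum
        assert sum(b.histogram.values()) == 1000

    def test_deterministic_given_seed(self, cohort_as_dataset):
        r1 = run_burden(cohort_as_dataset, BurdenConfig(seed=11))
        r2 = run_burden(cohort_as_dataset, BurdenConfig(seed=11))
        assert r1.to_dict() == r2.to_dict()

    def test_deleterious_only_flag_equivalent_when_all_deleterious(self):
        coh = simulate_cohort(
            CohortSimConfig(seed=4, n_sites=20, fraction_deleterious=1.0,
                            fraction_synonymous=0.0)
        )
        ds = CohortDataset(
            coh["variants"], coh["annotations"], coh["genotypes"],
            coh["samples"], coh["covariates"],
        )
        r_true = run_burden(ds, BurdenConfig(seed=1, deleterious_only=True))
        r_false = run_burden(ds, BurdenConfig(seed=1, deleterious_only=False))
        assert r_true.deleterious_variants == r_false.deleterious_variants
        assert r_true.to_dict() == r_false.to_dict()
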