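import math

import numpy as np
import pytest
from scipy import stats

from ampliscreen.fixtures import cohort_table_from_table1
from ampliscreen.popstats import (
    DegenerateInputError,
    allele_frequency,
    association_scan,
    carrier_summary,
    concordance,
    concordance_from_table,
    display_percent,
    format_frequency,
    genotype_pca,
)


class TestAlleleFrequency:
    def test_modes_coincide_when_het_equals_hom(self):
        f = allele_frequency(9, 9, 41, mode="printed")
        assert f == allele_frequency(9, 9, 41, mode="standard") == 27 / 82

    def test_printed_formula(self):
        assert allele_frequency(8, 6, 41, mode="printed") == 22 / 82

    def test_standard_estimator(self):
        assert allele_frequency(14, 6, 41, mode="standard") == 26 / 82

    def test_zero_counts(self):
        assert allele_frequency(0, 0, 41) == 0.0

    def test_scale_invariance(self):
        for mode in ("printed", "standard"):
            a = allele_frequency(4, 3, 20, mode=mode)
            b = allele_frequency(12, 9, 60, mode=mode)
            assert a == pytest.approx(b)

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 100))
            het = int(rng.integers(0, n + 1))
            hom = int(rng.integers(0, n - het + 1))
            for mode in ("printed", "standard"):
                assert 0 <= allele_frequency(het, hom, n, mode=mode) <= 1

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(30, 20, 41)
        with pytest.raises(ValueError):
            allele_frequency(0, 0, 0)

    def test_formatting_modes(self):
        assert format_frequency(27 / 82, 4, "truncate") == 0.3292
        assert format_frequency(22 / 82, 4, "round") == 0.2683
        assert format_frequency(26 / 82, 4, "truncate") == 0.3170
        assert display_percent(20 / 41) == 49


class TestConcordance:
    def test_table1_fixture(self):
        result = concordance_from_table(cohort_table_from_table1(), "taqman", "kmer")
        assert (result.n_concordant, result.n_total) == (30, 41)
        assert len(result.discrepancies) == 11
        assert display_percent(result.rate) == 73

    def test_identical_and_disjoint(self):
        same = concordance(["SS", "Sr"], ["SS", "Sr"])
        assert same.rate == 1.0 and same.discrepancies == ()
        disjoint = concordance(["SS", "Sr"], ["rr", "rr"])
        assert disjoint.rate == 0.0

    def test_symmetry(self):
        a = ["SS", "Sr", "rr", "SS"]
        b = ["SS", "rr", "rr", "Sr"]
        assert concordance(a, b).rate == concordance(b, a).rate

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            concordance(["SS"], ["SS", "Sr"])


class TestCarrierSummary:
    def test_lajas_taqman(self):
        summary = carrier_summary(cohort_table_from_table1(), "taqman")
        lajas = summary.loc["Lajas"]
        assert lajas["n"] == 15
        assert (lajas["pct_carriers"], lajas["pct_hom"], lajas["pct_het"]) == (
            53,
            33,
            20,
        )

    def test_santa_isabel_taqman(self):
        row = carrier_summary(cohort_table_from_table1(), "taqman").loc["Santa Isabel"]
        assert (row["pct_hom"], row["pct_het"]) == (21, 0)

    def test_all_susceptible_location(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "location": ["X", "X"],
                "method": ["kmer", "kmer"],
                "call": ["SS", "SS"],
            }
        )
        row = carrier_summary(table, "kmer").loc["X"]
        assert (row["pct_carriers"], row["pct_hom"], row["pct_het"]) == (0, 0, 0)

    def test_unknown_method(self):
        with pytest.raises(KeyError):
            carrier_summary(cohort_table_from_table1(), "pyrosequencing")


class TestGenotypePca:
    def test_two_clusters_separate_on_pc1(self):
        X = np.array([[0, 0, 0, 0]] * 5 + [[2, 2, 2, 2]] * 5, dtype=float)
        proj, explained = genotype_pca(X)
        assert explained[0] == pytest.approx(1.0)
        pc1 = proj[:, 0]
        assert np.ptp(pc1[:5]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(pc1[5:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[0] - pc1[5]) > 1.0

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(20, 50)).astype(float)
        _proj, explained = genotype_pca(X)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1 + 1e-9

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(15, 30)).astype(float)
        perm = rng.permutation(15)
        proj, _ = genotype_pca(X)
        proj_perm, _ = genotype_pca(X[perm])
        assert np.allclose(proj_perm, proj[perm], atol=1e-8)

    def test_column_shift_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(12, 8)).astype(float)
        shifted = X + np.arange(8)[None, :]
        a, _ = genotype_pca(X)
        b, _ = genotype_pca(shifted)
        assert np.allclose(a, b, atol=1e-8)

    def test_missing_values_mean_imputed(self):
        X = np.array([[0, 2], [2, 0], [np.nan, 1], [1, np.nan]], dtype=float)
        proj, _ = genotype_pca(X)
        assert np.isfinite(proj).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            genotype_pca(np.ones((5, 4)))


class TestAssociationScan:
    def test_identical_allele_counts_p_one(self):
        X = np.array([[1], [1], [1], [1]], dtype=float)
        y = [0, 0, 1, 1]
        out = association_scan(X, y)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeometric_oracle(self):
        n = 20
        X = np.array([[0]] * n + [[2]] * n, dtype=float)
        y = [0] * n + [1] * n
        p = association_scan(X, y).loc[0, "p_value"]
        assert p < 1e-5
        # independent oracle: two-sided Fisher p from the hypergeometric pmf
        M, K, N = 4 * n, 2 * n, 2 * n  # alleles total, alt alleles, class-0 draws
        pmf = stats.hypergeom(M, K, N).pmf(np.arange(0, 2 * n + 1))
        observed = pmf[0]  # class 0 carries zero alt alleles
        oracle = pmf[pmf <= observed * (1 + 1e-9)].sum()
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_sorted_by_position(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(10, 5)).astype(float)
        out = association_scan(X, [0] * 5 + [1] * 5, positions=[50, 10, 30, 20, 40])
        assert list(out["position"]) == [10, 20, 30, 40, 50]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            association_scan(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_type_one_error_bounded_under_permutation(self):
        """Fisher's exact test on allele counts is valid (conservative) for
        Hardy-Weinberg genotypes: under permuted (null) labels the rejection
        rate at alpha=0.05 must not exceed 0.05 + 3 SE.  (Allele-count tests
        assume binomial allele dosage; overdispersed genotype matrices would
        not be calibrated.)"""
        rng = np.random.default_rng(6)
        n, n_sites, n_perm = 40, 10, 60
        p = rng.uniform(0.1, 0.9, size=n_sites)
        X = rng.binomial(2, p, size=(n, n_sites)).astype(float)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        alpha = 0.05
        rejections = trials = 0
        for _ in range(n_perm):
            y = rng.permutation(labels)
            out = association_scan(X, y)
            rejections += int((out["p_value"] <= alpha).sum())
            trials += n_sites
        rate = rejections / trials
        se = math.sqrt(alpha * (1 - alpha) / trials)
        assert rate <= alpha + 3 * se
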