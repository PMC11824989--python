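from __future__ import annotations

import math

import numpy as np
import pytest

from rarepop.genotype_io import GenotypeMatrix
from rarepop import popgen_stats as ps

from conftest import make_aft, random_matrix
from oracles import (
    o_detected,
    o_freqs,
    o_fst,
    o_he,
    o_ho,
    o_mean_freq_diff,
    o_nei,
    o_rogers,
)


def matrix_from_genotypes(genotypes, missing_code=0):
    """One-locus matrix from a list of (a, b) genotype pairs."""
    alleles = np.array(genotypes)[:, None, :]
    return GenotypeMatrix(
        [f"i{k}" for k in range(len(genotypes))], ["L1"], alleles, missing_code
    )


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "genotypes,expected",
        [
            ([(1, 1), (1, 2), (2, 2)], {1: 0.5, 2: 0.5}),
            ([(3, 3), (3, 3)], {3: 1.0}),
            ([(1, 2), (0, 0), (2, 2)], {1: 0.25, 2: 0.75}),  # missing excluded
        ],
    )
    def test_hand_counts(self, genotypes, expected):
        F = ps.allele_frequencies(matrix_from_genotypes(genotypes))
        assert F.freqs[0] == pytest.approx(expected)

    def test_half_missing_genotype_contributes_one_copy(self):
        F = ps.allele_frequencies(matrix_from_genotypes([(1, 0), (2, 2)]))
        assert F.copy_counts[0] == 3
        assert F.freqs[0] == pytest.approx({1: 1 / 3, 2: 2 / 3})

    def test_all_missing_locus_is_empty(self):
        F = ps.allele_frequencies(matrix_from_genotypes([(0, 0), (0, 0)]))
        assert F.freqs[0] == {}
        assert F.copy_counts[0] == 0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            F = ps.allele_frequencies(random_matrix(rng))
            for f, c in zip(F.freqs, F.copy_counts):
                if c:
                    assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "genotypes,expected",
        [
            ([(1, 1), (2, 2), (3, 3)], 0.0),
            ([(1, 2), (2, 3), (1, 3)], 1.0),
            ([(1, 2), (1, 1), (2, 2), (3, 3)], 0.25),
        ],
    )
    def test_observed(self, genotypes, expected):
        ho = ps.observed_heterozygosity(matrix_from_genotypes(genotypes))
        assert ho[0] == pytest.approx(expected)

    def test_observed_undefined_without_complete_genotypes(self):
        ho = ps.observed_heterozygosity(matrix_from_genotypes([(1, 0), (0, 2)]))
        assert np.isnan(ho[0])

    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({3: 1.0}, 0.0),
            ({1: 0.5, 2: 0.5}, 0.5),
            ({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}, 0.75),
        ],
    )
    def test_expected(self, freqs, expected):
        he = ps.expected_heterozygosity(make_aft(freqs))
        assert he[0] == pytest.approx(expected)

    def test_he_bounded_by_allele_count(self):
        """He <= 1 - 1/k for k observed alleles (equality at uniformity)."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            G = random_matrix(rng)
            F = ps.allele_frequencies(G)
            he = ps.expected_heterozygosity(F)
            for l, f in enumerate(F.freqs):
                if f:
                    assert 0.0 <= he[l] <= 1.0 - 1.0 / len(f) + 1e-12


class TestPairwiseDistances:
    def test_identity_gives_zero_everywhere(self):
        F = make_aft({1: 0.5, 2: 0.5}, {3: 0.2, 4: 0.8})
        assert ps.fst_pair(F, F) == 0.0
        assert ps.nei_distance(F, F) == pytest.approx(0.0, abs=1e-12)
        assert ps.rogers_distance(F, F) == 0.0

    def test_fst_disjoint_fixed_pools(self):
        assert ps.fst_pair(make_aft({1: 1.0}), make_aft({2: 1.0})) == pytest.approx(1.0)

    def test_fst_excludes_jointly_monomorphic_loci(self):
        F_a = make_aft({1: 0.5, 2: 0.5}, {1: 1.0})
        F_b = make_aft({1: 0.5, 2: 0.5}, {1: 1.0})
        assert ps.fst_pair(F_a, F_b) == 0.0

    def test_fst_no_polymorphic_locus_returns_zero(self):
        assert ps.fst_pair(make_aft({1: 1.0}), make_aft({1: 1.0})) == 0.0

    def test_nei_disjoint_pools_infinite(self):
        assert ps.nei_distance(make_aft({1: 1.0}), make_aft({2: 1.0})) == math.inf

    def test_nei_hand_value(self):
        d = ps.nei_distance(make_aft({1: 0.8, 2: 0.2}), make_aft({1: 0.2, 2: 0.8}))
        assert d == pytest.approx(-math.log(0.32 / 0.68))

    def test_rogers_disjoint_pools(self):
        assert ps.rogers_distance(make_aft({1: 1.0}), make_aft({2: 1.0})) == pytest.approx(1.0)

    def test_rogers_hand_value(self):
        d = ps.rogers_distance(make_aft({1: 0.8, 2: 0.2}), make_aft({1: 0.2, 2: 0.8}))
        assert d == pytest.approx(0.6)

    def test_mismatched_locus_sets_rejected(self):
        F1, F2 = make_aft({1: 1.0}), make_aft({1: 1.0}, {2: 1.0})
        for fn in (ps.fst_pair, ps.nei_distance, ps.rogers_distance,
                   ps.mean_freq_difference):
            with pytest.raises(ValueError, match="locus"):
                fn(F1, F2)

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            Fa = ps.allele_frequencies(random_matrix(rng))
            Fb = ps.allele_frequencies(random_matrix(rng))
            assert ps.fst_pair(Fa, Fb) == pytest.approx(ps.fst_pair(Fb, Fa))
            assert ps.rogers_distance(Fa, Fb) == pytest.approx(ps.rogers_distance(Fb, Fa))
            na, nb = ps.nei_distance(Fa, Fb), ps.nei_distance(Fb, Fa)
            assert na == nb or na == pytest.approx(nb)


class TestClassification:
    def test_threshold_split(self):
        cls = ps.classify_alleles(make_aft({1: 0.9, 2: 0.06, 3: 0.04}), 0.05)
        assert cls.common == {(0, 1), (0, 2)}
        assert cls.rare == {(0, 3)}

    def test_no_rare_alleles(self):
        cls = ps.classify_alleles(make_aft({1: 0.5, 2: 0.5}), 0.05)
        assert cls.rare == set()
        assert cls.common == {(0, 1), (0, 2)}

    def test_global_extremes(self):
        cls = ps.classify_alleles(make_aft({1: 0.9, 2: 0.1}, {5: 0.7, 6: 0.3}), 0.05)
        assert cls.most_common == (0, 1, 0.9)
        assert cls.least_common == (0, 2, 0.1)

    def test_tie_break_by_locus_then_code(self):
        cls = ps.classify_alleles(make_aft({2: 0.5, 1: 0.5}, {7: 0.5, 8: 0.5}), 0.05)
        assert cls.most_common == (0, 1, 0.5)
        assert cls.least_common == (0, 1, 0.5)


class TestDetectionAndFreqDiff:
    def test_full_set_detected_in_itself(self):
        F = make_aft({1: 0.5, 2: 0.5}, {3: 1.0})
        assert ps.detected_fraction(F.allele_set(), F) == 1.0

    def test_partial_detection(self):
        full = make_aft({1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1})
        sub = make_aft({1: 0.5, 2: 0.25, 3: 0.25})
        assert ps.detected_fraction(full.allele_set(), sub) == 0.75

    def test_disjoint_detection_zero(self):
        assert ps.detected_fraction({(0, 9)}, make_aft({1: 1.0})) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ps.detected_fraction(set(), make_aft({1: 1.0}))

    @pytest.mark.parametrize(
        "full,sub,expected",
        [
            ({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}, 0.0),
            ({1: 0.5, 2: 0.5}, {1: 1.0}, 0.5),
            ({1: 0.75, 2: 0.25}, {1: 0.5, 2: 0.5}, 0.25),
        ],
    )
    def test_mean_freq_difference(self, full, sub, expected):
        d = ps.mean_freq_difference(make_aft(sub), make_aft(full))
        assert d.mean == pytest.approx(expected)

    def test_per_allele_values(self):
        d = ps.mean_freq_difference(make_aft({1: 1.0}), make_aft({1: 0.5, 2: 0.5}))
        assert d.per_allele == pytest.approx({(0, 1): 0.5, (0, 2): 0.5})


class TestOracleEquivalence:
    """Every statistic agrees with explicit brute-force counting on random
    6-individual, 3-locus matrices (including missing data)."""

    @pytest.mark.parametrize("missing_code", [0, -9])
    def test_against_brute_force(self, missing_code):
        rng = np.random.default_rng(2024 + missing_code)
        for _ in range(120):
            G_sub = random_matrix(rng, missing_code)
            G_full = random_matrix(rng, missing_code)
            of_sub, oc_sub = o_freqs(G_sub.alleles, missing_code)
            of_full, _ = o_freqs(G_full.alleles, missing_code)

            F_sub = ps.allele_frequencies(G_sub)
            F_full = ps.allele_frequencies(G_full)
            for l in range(3):
                assert F_sub.freqs[l] == pytest.approx(of_sub[l])
                assert F_sub.copy_counts[l] == oc_sub[l]

            np.testing.assert_allclose(
                ps.observed_heterozygosity(G_sub), o_ho(G_sub.alleles, missing_code)
            )
            np.testing.assert_allclose(
                ps.expected_heterozygosity(F_sub), o_he(of_sub)
            )
            assert ps.fst_pair(F_sub, F_full) == pytest.approx(o_fst(of_sub, of_full))
            assert ps.rogers_distance(F_sub, F_full) == pytest.approx(
                o_rogers(of_sub, of_full)
            )
            nei = ps.nei_distance(F_sub, F_full)
            onei = o_nei(of_sub, of_full)
            assert nei == onei or nei == pytest.approx(onei)
            assert ps.mean_freq_difference(F_sub, F_full).mean == pytest.approx(
                o_mean_freq_diff(of_sub, of_full)
            )
            all_full = F_full.allele_set()
            assert ps.detected_fraction(all_full, F_sub) == pytest.approx(
                o_detected(all_full, of_sub)
            )
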