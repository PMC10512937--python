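"""Diversity measures: worked examples, hand-enumerated values, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialdiv.alignment import Alignment, AlignmentError, collapse_alleles
from spatialdiv.diversity import (
    calc_diversity,
    expected_heterozygosity,
    expected_heterozygosity_unbiased,
    nucleotide_diversity,
    pairwise_rate_matrix,
    pairwise_substitution_rate,
    segregating_sites,
    sigma_n_oracle,
    sigma_tilde,
    watterson_theta,
)


class TestPairwiseRate:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("AAA", "GGG", 1.0),
            ("ACGT", "ACGT", 0.0),
            ("AAT", "AAA", 1 / 3),
        ],
    )
    def test_values(self, s1, s2, expected):
        assert pairwise_substitution_rate(s1, s2) == pytest.approx(expected)
        assert pairwise_substitution_rate(s2, s1) == pytest.approx(expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            pairwise_substitution_rate("AA", "AAA")

    def test_matrix_matches_scalar(self):
        seqs = ["ACGT", "ACGA", "TCGA"]
        R = pairwise_rate_matrix(seqs)
        for i in range(3):
            for j in range(3):
                assert R[i, j] == pytest.approx(
                    pairwise_substitution_rate(seqs[i], seqs[j])
                )
        assert np.allclose(R, R.T)
        assert np.diagonal(R).tolist() == [0, 0, 0]

    def test_matrix_large_input_path(self):
        # force the matmul branch and compare against the broadcast branch
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 500)) for _ in range(150)]
        R_big = pairwise_rate_matrix(seqs)
        R_ref = pairwise_rate_matrix(seqs[:20])
        assert np.allclose(R_big[:20, :20], R_ref)


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.2] * 5, 0.8)],
    )
    def test_expected(self, freqs, expected):
        assert expected_heterozygosity(freqs) == pytest.approx(expected)

    def test_unbiased_small_sample(self):
        # 2n/(2n-1) factor at n=2
        assert expected_heterozygosity_unbiased([0.5, 0.5], 2) == pytest.approx(2 / 3)

    def test_unbiased_tends_to_plain(self):
        he = expected_heterozygosity([0.5, 0.5])
        corrected = expected_heterozygosity_unbiased([0.5, 0.5], 10**7)
        assert corrected == pytest.approx(he, rel=1e-6)

    def test_monomorphic_zero(self):
        assert expected_heterozygosity_unbiased([1.0], 5) == 0.0

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            expected_heterozygosity([1.2, -0.2])


class TestNucleotideDiversity:
    def test_monomorphic(self):
        assert nucleotide_diversity([1.0], np.zeros((1, 1))) == 0.0

    def test_two_alleles_half(self):
        R = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert nucleotide_diversity([0.5, 0.5], R) == pytest.approx(0.5)
        assert nucleotide_diversity([0.5, 0.5], R, corrected=True, n=2) == pytest.approx(1.0)

    def test_hand_enumerated_triple(self):
        # {AAA, AAT, AAA}: pi_hat = 2*(2/3)(1/3)(1/3) = 4/27, pi_tilde = 2/9
        aln = Alignment.from_sequences(["AAA", "AAT", "AAA"])
        alleles = collapse_alleles(aln)
        R = pairwise_rate_matrix(alleles.haplotypes)
        pi_hat = nucleotide_diversity(alleles.freqs, R)
        assert pi_hat == pytest.approx(4 / 27)
        assert nucleotide_diversity(
            alleles.freqs, R, corrected=True, n=3
        ) == pytest.approx(2 / 9)

    def test_corrected_requires_n(self):
        with pytest.raises(ValueError):
            nucleotide_diversity([1.0], np.zeros((1, 1)), corrected=True, n=1)


class TestWattersonTheta:
    def test_no_segregating_sites(self):
        aln = Alignment.from_sequences(["AAAA", "AAAA", "AAAA"])
        assert watterson_theta(aln) == 0.0

    def test_equals_K_at_n2(self):
        rng = np.random.default_rng(3)
        s1 = "".join(rng.choice(list("ACGT"), 1000))
        s2 = list(s1)
        for pos in rng.choice(1000, size=7, replace=False):
            s2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[pos]]
        aln = Alignment.from_sequences([s1, "".join(s2)])
        assert segregating_sites(aln) == 7
        assert watterson_theta(aln) == pytest.approx(7.0)
        assert watterson_theta(aln, per_site=True) == pytest.approx(0.007)

    def test_harmonic_denominator(self):
        # n=4, K=11 -> 11 / (1 + 1/2 + 1/3) = 6
        seqs = ["A" * 11, "C" * 11, "G" * 11, "T" * 11]
        aln = Alignment.from_sequences(seqs)
        assert segregating_sites(aln) == 11
        assert watterson_theta(aln) == pytest.approx(6.0)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            watterson_theta(Alignment.from_sequences(["AAA"]))


class TestSigma:
    def test_three_distinct_max(self, toy_three):
        assert sigma_tilde(collapse_alleles(toy_three)) == pytest.approx(1.0)

    def test_duplicate_leaves_value(self, toy_four):
        assert sigma_tilde(collapse_alleles(toy_four)) == pytest.approx(1.0)

    def test_single_allele_zero(self):
        aln = Alignment.from_sequences(["AAA", "AAA"])
        assert sigma_tilde(collapse_alleles(aln)) == 0.0

    def test_two_alleles_single_pair(self):
        aln = Alignment.from_sequences(["AAA", "AAT"])
        assert sigma_tilde(collapse_alleles(aln)) == pytest.approx(1 / 3)

    def test_frequency_independent(self):
        a = Alignment.from_sequences(["AAT", "GGA", "AAT"])
        b = Alignment.from_sequences(["AAT"] * 9 + ["GGA"])
        assert sigma_tilde(collapse_alleles(a)) == sigma_tilde(collapse_alleles(b))


class TestSigmaNOracle:
    def test_pair_attains_max(self):
        pop = Alignment.from_sequences(["AAA", "AAA", "GGG"])
        assert sigma_n_oracle(pop, 2) == pytest.approx(1.0)

    def test_toy_worked_example(self, toy_three):
        assert sigma_n_oracle(toy_three, 2) == pytest.approx(1.0)
        assert sigma_n_oracle(toy_three, 3) == pytest.approx(1.0)

    def test_equals_sigma_at_full_size(self, random_population):
        pop = random_population(7, 12, seed=5)
        full = sigma_n_oracle(pop, pop.n)
        assert full == pytest.approx(sigma_tilde(collapse_alleles(pop)))

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_non_increasing(self, random_population, seed):
        pop = random_population(8, 6, seed=seed)
        values = [sigma_n_oracle(pop, n) for n in range(2, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_combination_cap(self, random_population):
        pop = random_population(10, 4, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            sigma_n_oracle(pop, 5, max_combinations=10)


class TestCalcDiversity:
    def test_toy_three_all_measures(self, toy_three):
        s = calc_diversity(toy_three)
        assert s.sigma_hat == pytest.approx(1.0)
        assert s.pi_tilde == pytest.approx(1.0)  # m = n so the two agree
        assert s.m == s.n == 3
        assert s.K == 3

    def test_monomorphic_all_zero(self):
        s = calc_diversity(Alignment.from_sequences(["ACGT", "ACGT", "ACGT"]))
        assert (
            s.He, s.He_hat, s.pi_hat, s.pi_tilde, s.theta_w, s.theta_w_site,
            s.sigma_hat,
        ) == (0,) * 7

    def test_hand_enumerated(self):
        s = calc_diversity(Alignment.from_sequences(["AAA", "AAT", "AAA"]))
        assert s.pi_tilde == pytest.approx(2 / 9)
        assert s.sigma_hat == pytest.approx(1 / 3)

    def test_sigma_equals_pi_tilde_when_all_distinct(self, random_population):
        pop = random_population(10, 40, seed=11)
        assert collapse_alleles(pop).m == pop.n
        s = calc_diversity(pop)
        assert s.sigma_hat == pytest.approx(s.pi_tilde, abs=1e-12)

    def test_reorder_invariance(self, random_population):
        pop = random_population(8, 20, seed=2)
        rng = np.random.default_rng(9)
        perm = rng.permutation(pop.n)
        shuffled = pop.subset(perm.tolist())
        a, b = calc_diversity(pop), calc_diversity(shuffled)
        for key in ("He", "He_hat", "pi_hat", "pi_tilde", "theta_w", "sigma_hat"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), abs=1e-12)

    def test_refuses_dirty_alignment(self):
        with pytest.raises(AlignmentError):
            calc_diversity(Alignment.from_sequences(["A-", "AA"]))


@settings(deadline=None, max_examples=50)
@given(
    counts=st.lists(st.integers(1, 6), min_size=1, max_size=5),
)
def test_sigma_larger_than_pi_for_equal_distinct_alleles(counts):
    """With all alleles distinct and equally frequent, the unweighted mean
    substitution rate exceeds the frequency-weighted one by N/(N-1)."""
    rng = np.random.default_rng(sum(counts))
    m = len(counts)
    seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(m)]
    if len(set(seqs)) != m:
        return
    aln = Alignment.from_sequences(seqs)
    alleles = collapse_alleles(aln)
    R = pairwise_rate_matrix(alleles.haplotypes)
    pi = nucleotide_diversity(alleles.freqs, R)
    sig = sigma_tilde(alleles, R)
    if m >= 2:
        assert sig == pytest.approx(pi * m / (m - 1))
        assert sig >= pi
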