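"""The seven genetic diversity measures and the exhaustive subset oracle.

Measures
--------
Let a sample of ``n`` aligned sequences collapse into ``m`` allele types
(haplotypes) with frequencies ``p_i`` and per-site substitution rates
``pi_ij`` (p-distances) between types.  The package computes:

- expected heterozygosity            ``He = 1 - sum p_i^2``
- its unbiased estimator             ``He_hat = 2n/(2n-1) * He``
- nucleotide diversity (plug-in)     ``pi_hat = sum_i sum_j p_i p_j pi_ij``
- bias-corrected nucleotide diversity ``pi_tilde = n/(n-1) * pi_hat``
- Watterson's theta                  ``theta_w = K / H_{n-1}`` (K segregating
  sites, ``H_{n-1}`` the harmonic number), and its per-site value
- the frequency-independent average substitution rate among allele types
  ``sigma_tilde = (1/(m(m-1))) sum_{i != j} pi_ij`` (0 when ``m = 1``)

``sigma_tilde`` weighs every allele type equally — rare, phylogenetically
distant alleles count as much as common ones — which is what makes it the
natural companion of one-individual-per-location spatial sampling.  On a
whole statistical population the same formula over all ``M`` allele types
is the population parameter ``sigma``; the auxiliary quantity
``sigma_n = max`` of ``sigma_tilde`` over all size-n subsets is provided
by the brute-force :func:`sigma_n_oracle` for enumerable toy populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from spatialdiv.alignment import Alignment, AlleleSet, AlignmentError, collapse_alleles

__all__ = [
    "DiversitySummary",
    "pairwise_substitution_rate",
    "pairwise_rate_matrix",
    "expected_heterozygosity",
    "expected_heterozygosity_unbiased",
    "nucleotide_diversity",
    "watterson_theta",
    "segregating_sites",
    "sigma_tilde",
    "sigma_n_oracle",
    "calc_diversity",
]


@dataclass(frozen=True)
class DiversitySummary:
    """The seven diversity measures of one sample, plus n, m and K."""

    He: float
    He_hat: float
    pi_hat: float
    pi_tilde: float
    theta_w: float
    theta_w_site: float
    sigma_hat: float
    n: int
    m: int
    K: int

    def as_dict(self) -> dict[str, float]:
        return {
            "He": self.He,
            "He_hat": self.He_hat,
            "pi_hat": self.pi_hat,
            "pi_tilde": self.pi_tilde,
            "theta_w": self.theta_w,
            "theta_w_site": self.theta_w_site,
            "sigma_hat": self.sigma_hat,
            "n": self.n,
            "m": self.m,
            "K": self.K,
        }


def pairwise_substitution_rate(s1: str, s2: str) -> float:
    """Per-site substitution rate (p-distance) between two sequences.

    The number of mismatching sites divided by the sequence length.  No
    multiple-hit correction is applied.
    """
    if len(s1) != len(s2):
        raise AlignmentError("sequences must have equal length")
    if len(s1) == 0:
        raise AlignmentError("sequences must have length >= 1")
    diff = sum(c1 != c2 for c1, c2 in zip(s1, s2))
    return diff / len(s1)


def pairwise_rate_matrix(seqs: tuple[str, ...] | list[str]) -> np.ndarray:
    """Symmetric matrix of p-distances between the given sequences.

    Diagonal is 0.  Vectorised over an (n, L) byte matrix.
    """
    n = len(seqs)
    if n == 0:
        return np.zeros((0, 0))
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise AlignmentError("sequences must have equal length")
    if L == 0:
        raise AlignmentError("sequences must have length >= 1")
    mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, L)
    if n * n * L <= 8_000_000:
        diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        return diffs / L
    # large inputs: count matches via per-base indicator matmuls, O(4 n^2 L)
    # flops but O(n^2) memory
    matches = np.zeros((n, n))
    for base in b"ACGT":
        ind = (mat == base).astype(np.float32)
        matches += ind @ ind.T
    diffs = L - matches
    np.fill_diagonal(diffs, 0.0)
    return diffs / L


def expected_heterozygosity(freqs) -> float:
    """Expected heterozygosity ``He = 1 - sum p_i^2``."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - (p**2).sum())


def expected_heterozygosity_unbiased(freqs, n: int) -> float:
    """Finite-sample corrected heterozygosity ``2n/(2n-1) * (1 - sum p_i^2)``.

    The correction factor is the one conventional for haplotype data in
    this scheme; it tends to ``He`` as n grows.
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    return 2 * n / (2 * n - 1) * expected_heterozygosity(freqs)


def nucleotide_diversity(
    freqs, rates: np.ndarray, *, corrected: bool = False, n: int | None = None
) -> float:
    """Nucleotide diversity ``pi = sum_i sum_j p_i p_j pi_ij``.

    With ``corrected=True`` the ``n/(n-1)`` bias correction is applied
    (requires the sample size ``n >= 2``).
    """
    p = np.asarray(freqs, dtype=float)
    R = np.asarray(rates, dtype=float)
    if R.shape != (p.size, p.size):
        raise ValueError("rate matrix not conformable with frequencies")
    pi = float(p @ R @ p)
    if corrected:
        if n is None or n < 2:
            raise ValueError("corrected nucleotide diversity requires n >= 2")
        pi *= n / (n - 1)
    return pi


def segregating_sites(a: Alignment) -> int:
    """Number of columns with more than one distinct base (K)."""
    if not a.is_clean():
        raise AlignmentError("segregating_sites requires a cleaned alignment")
    if a.length == 0:
        return 0
    mat = a.to_matrix()
    return int((mat != mat[0]).any(axis=0).sum())


def watterson_theta(a: Alignment, *, per_site: bool = False) -> float:
    """Watterson's theta ``K / sum_{i=1}^{n-1} 1/i``.

    ``per_site=True`` divides by the alignment length (e.g., by 1,000
    for 1,000-bp sequences).
    """
    if a.n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    K = segregating_sites(a)
    harmonic = sum(1.0 / i for i in range(1, a.n))
    theta = K / harmonic
    if per_site:
        if a.length == 0:
            return 0.0
        theta /= a.length
    return theta


def sigma_tilde(alleles: AlleleSet, rates: np.ndarray | None = None) -> float:
    """Average substitution rate among the m distinct allele types.

    ``(1/(m(m-1))) * sum over ordered pairs i != j of pi_ij``; defined as
    0 for a monomorphic sample (m = 1).  Frequency-independent: haplotype
    counts play no role.  On a whole population this is the parameter
    ``sigma``; on a sample it is the statistic ``sigma_hat``.
    """
    m = alleles.m
    if m <= 1:
        return 0.0
    if rates is None:
        rates = pairwise_rate_matrix(alleles.haplotypes)
    R = np.asarray(rates, dtype=float)
    if R.shape != (m, m):
        raise ValueError("rate matrix must be over the m distinct haplotypes")
    return float(R.sum() / (m * (m - 1)))


def sigma_from_alignment(a: Alignment) -> float:
    """Convenience: collapse an alignment and return its sigma value."""
    return sigma_tilde(collapse_alleles(a))


def sigma_n_oracle(
    population: Alignment, n: int, *, max_combinations: int = 2_000_000
) -> float:
    """Brute-force ``sigma_n``: the maximum sigma over all size-n subsets.

    Exhaustively enumerates every size-n subset of the population's
    sequences, evaluates the average pairwise substitution rate of each
    subset's distinct haplotypes, and returns the maximum.  Only feasible
    on small populations; the enumeration refuses to start when
    ``C(N, n)`` exceeds ``max_combinations`` (combination explosion).
    """
    N = population.n
    if not 2 <= n <= N:
        raise ValueError("subset size n must satisfy 2 <= n <= N")
    n_comb = comb(N, n)
    if n_comb > max_combinations:
        raise ValueError(
            f"C({N}, {n}) = {n_comb} subsets exceeds the enumeration cap "
            f"({max_combinations})"
        )
    rates = pairwise_rate_matrix(population.seqs)
    best = 0.0
    for subset in combinations(range(N), n):
        # collapse to distinct haplotypes within the subset
        distinct: dict[str, int] = {}
        for i in subset:
            distinct.setdefault(population.seqs[i], i)
        idx = list(distinct.values())
        m = len(idx)
        if m == 1:
            val = 0.0
        else:
            sub = rates[np.ix_(idx, idx)]
            val = float(sub.sum() / (m * (m - 1)))
        if val > best:
            best = val
    return best


def calc_diversity(a: Alignment) -> DiversitySummary:
    """Compute all seven diversity measures of a cleaned alignment.

    Mirrors a one-stop summary for an aligned FASTA sample: expected
    heterozygosity and its corrected form, plug-in and corrected
    nucleotide diversity, whole-locus and per-site Watterson's theta,
    and the frequency-independent average substitution rate, together
    with n, m and the number of segregating sites K.
    """
    if a.n < 2:
        raise ValueError("calc_diversity requires n >= 2")
    if not a.is_clean():
        raise AlignmentError(
            "calc_diversity requires a cleaned (ACGT-only) alignment; "
            "apply remove_gap_unknown_columns first"
        )
    alleles = collapse_alleles(a)
    rates = pairwise_rate_matrix(alleles.haplotypes) if a.length else np.zeros(
        (alleles.m, alleles.m)
    )
    freqs = alleles.freqs
    He = expected_heterozygosity(freqs)
    He_hat = expected_heterozygosity_unbiased(freqs, a.n)
    pi_hat = nucleotide_diversity(freqs, rates)
    pi_tilde = nucleotide_diversity(freqs, rates, corrected=True, n=a.n)
    K = segregating_sites(a)
    harmonic = sum(1.0 / i for i in range(1, a.n))
    theta_w = K / harmonic
    theta_w_site = theta_w / a.length if a.length else 0.0
    sigma_hat = sigma_tilde(alleles, rates)
    return DiversitySummary(
        He=He,
        He_hat=He_hat,
        pi_hat=pi_hat,
        pi_tilde=pi_tilde,
        theta_w=theta_w,
        theta_w_site=theta_w_site,
        sigma_hat=sigma_hat,
        n=a.n,
        m=alleles.m,
        K=K,
    )
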