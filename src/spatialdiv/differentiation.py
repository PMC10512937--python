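"""Between-deme differentiation indices Gst and Nst.

Gst is the classical H-based decomposition (Ht - Hs) / Ht over haplotype
frequencies: Hs the sample-size-weighted mean within-deme expected
heterozygosity, Ht the expected heterozygosity of the pooled frequencies.
Nst is the nucleotide-level analogue built from nucleotide diversity
(which weighs haplotype pairs by their per-site substitution rate)
instead of heterozygosity.  Gst therefore ignores how different two
haplotypes are, Nst does not — the pair is reported side by side in the
simulation experiments as a differentiation diagnostic.

Division by a zero total diversity (all demes monomorphic for the same
allele) returns 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from spatialdiv.alignment import Alignment, collapse_alleles
from spatialdiv.diversity import (
    expected_heterozygosity,
    nucleotide_diversity,
    pairwise_rate_matrix,
)

__all__ = ["SubdividedSample", "gst", "nst"]


@dataclass(frozen=True)
class SubdividedSample:
    """One alignment per deme, sharing a common sequence length."""

    groups: tuple[Alignment, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("differentiation requires at least two demes")
        lengths = {g.length for g in self.groups}
        if len(lengths) != 1:
            raise ValueError("all demes must share the sequence length")

    @classmethod
    def from_alignments(cls, groups: Sequence[Alignment]) -> "SubdividedSample":
        return cls(groups=tuple(groups))

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(g.n for g in self.groups)


def _pooled_haplotypes(s: SubdividedSample):
    """Global haplotype list, per-deme count matrix and deme sizes."""
    order: dict[str, int] = {}
    per_deme_counts: list[dict[int, int]] = []
    for g in s.groups:
        alleles = collapse_alleles(g)
        counts: dict[int, int] = {}
        for hap, c in zip(alleles.haplotypes, alleles.counts):
            idx = order.setdefault(hap, len(order))
            counts[idx] = c
        per_deme_counts.append(counts)
    H = len(order)
    count_mat = np.zeros((len(s.groups), H))
    for d, counts in enumerate(per_deme_counts):
        for idx, c in counts.items():
            count_mat[d, idx] = c
    return tuple(order), count_mat, np.array(s.sizes, dtype=float)


def gst(s: SubdividedSample) -> float:
    """Nei's Gst = (Ht - Hs) / Ht over haplotype frequencies.

    Demes are weighted by sample size; returns 0 when Ht = 0.
    """
    _, counts, sizes = _pooled_haplotypes(s)
    deme_freqs = counts / sizes[:, None]
    Hs_per_deme = np.array([expected_heterozygosity(f) for f in deme_freqs])
    weights = sizes / sizes.sum()
    Hs = float(weights @ Hs_per_deme)
    pooled = counts.sum(axis=0) / sizes.sum()
    Ht = expected_heterozygosity(pooled)
    if Ht == 0.0:
        return 0.0
    return (Ht - Hs) / Ht


def nst(s: SubdividedSample) -> float:
    """Nucleotide-level differentiation (vT - vS) / vT.

    vS is the size-weighted mean within-deme nucleotide diversity, vT
    the nucleotide diversity of the pooled sample; returns 0 when
    vT = 0.
    """
    haplotypes, counts, sizes = _pooled_haplotypes(s)
    rates = pairwise_rate_matrix(list(haplotypes))
    deme_freqs = counts / sizes[:, None]
    vS_per_deme = np.array(
        [nucleotide_diversity(f, rates) for f in deme_freqs]
    )
    weights = sizes / sizes.sum()
    vS = float(weights @ vS_per_deme)
    pooled = counts.sum(axis=0) / sizes.sum()
    vT = nucleotide_diversity(pooled, rates)
    if vT == 0.0:
        return 0.0
    return (vT - vS) / vT
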