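"""Aligned-sequence containers, FASTA I/O, cleaning and haplotype collapsing.

All diversity measures in this package consume an :class:`Alignment` of
equal-length nucleotide sequences (one per individual).  Columns holding
gaps, unknown bases or IUPAC ambiguity codes carry no per-site
substitution information for the measures computed here, so they are
removed wholesale by :func:`remove_gap_unknown_columns` before any
statistic is calculated.  Distinct sequences ("allele types" or
haplotypes) are obtained by exact string identity via
:func:`collapse_alleles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlleleSet",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "remove_gap_unknown_columns",
    "collapse_alleles",
]

#: The only characters retained by the column cleaner.
CANONICAL_BASES = frozenset("ACGT")

# numeric codes used internally (A,C,G,T -> 0..3)
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, empty input, ...)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences, one per individual.

    Parameters
    ----------
    ids:
        Unique sequence identifiers.
    seqs:
        Uppercase nucleotide strings, all of identical length.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(self.seqs) == 0:
            raise AlignmentError("alignment must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids must be unique")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise AlignmentError("all sequences must have identical length")

    @classmethod
    def from_sequences(
        cls, seqs: Sequence[str], ids: Iterable[str] | None = None
    ) -> "Alignment":
        seqs = tuple(s.upper() for s in seqs)
        if ids is None:
            ids = tuple(f"seq{i}" for i in range(len(seqs)))
        return cls(ids=tuple(ids), seqs=seqs)

    @property
    def n(self) -> int:
        """Number of sequences (sample size n, or N for a whole population)."""
        return len(self.seqs)

    @property
    def length(self) -> int:
        """Number of aligned sites per sequence."""
        return len(self.seqs[0])

    def is_clean(self) -> bool:
        """True iff every character is one of A, C, G, T."""
        return all(set(s) <= CANONICAL_BASES for s in self.seqs)

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an (n, length) uint8 matrix of ASCII codes."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)

    def to_codes(self) -> np.ndarray:
        """Return an (n, length) matrix of base codes A,C,G,T -> 0..3.

        Requires a cleaned alignment.
        """
        if not self.is_clean():
            raise AlignmentError(
                "alignment contains non-ACGT characters; apply "
                "remove_gap_unknown_columns first"
            )
        lut = np.zeros(256, dtype=np.uint8)
        for b, c in _BASE_TO_CODE.items():
            lut[ord(b)] = c
        return lut[self.to_matrix()]

    def subset(self, indices: Sequence[int]) -> "Alignment":
        """Row subset, preserving the given order."""
        return Alignment(
            ids=tuple(self.ids[i] for i in indices),
            seqs=tuple(self.seqs[i] for i in indices),
        )


@dataclass(frozen=True)
class AlleleSet:
    """The distinct haplotypes of an alignment with their sample frequencies.

    ``m`` (number of allele types in a sample; ``M`` when computed on a
    whole statistical population) is ``len(haplotypes)``.
    """

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    n: int
    #: indices mapping each original sequence to its haplotype
    membership: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("haplotype counts must be >= 1")
        if sum(self.counts) != self.n:
            raise ValueError("counts must sum to the sample size n")

    @property
    def m(self) -> int:
        """Number of distinct allele types."""
        return len(self.haplotypes)

    @property
    def freqs(self) -> np.ndarray:
        """Relative haplotype frequencies p_i = counts / n."""
        return np.asarray(self.counts, dtype=float) / self.n


def read_fasta(path: str | Path) -> Alignment:
    """Read a multi-record FASTA file into an :class:`Alignment`.

    Sequences are uppercased; ragged record lengths raise
    :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    if any(len(s) == 0 for s in seqs):
        raise AlignmentError("empty sequence record in FASTA input")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"sequences are not aligned: lengths {sorted(lengths)} differ"
        )
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(a: Alignment, path: str | Path) -> None:
    """Write an alignment as unwrapped multi-record FASTA."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.seqs)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def remove_gap_unknown_columns(a: Alignment) -> Alignment:
    """Delete every column containing any character outside {A, C, G, T}.

    Gaps, N and all IUPAC ambiguity codes are treated alike: the whole
    column is discarded.  Row order and ids are preserved.  If every
    column is dirty a length-0 alignment is returned with a warning.
    """
    mat = a.to_matrix()
    ok = np.zeros(256, dtype=bool)
    for b in CANONICAL_BASES:
        ok[ord(b)] = True
    keep = ok[mat].all(axis=0)
    if not keep.any():
        warnings.warn(
            "all alignment columns contained gaps/unknown bases; "
            "returning a length-0 alignment",
            stacklevel=2,
        )
    cleaned = mat[:, keep]
    seqs = tuple(row.tobytes().decode("ascii") for row in cleaned)
    # bypass the length>=1 invariant check path: zero-length rows are a
    # legal (degenerate) outcome of cleaning
    return Alignment(ids=a.ids, seqs=seqs)


def collapse_alleles(a: Alignment) -> AlleleSet:
    """Collapse an alignment into its distinct haplotypes.

    Identity is exact string equality (run the cleaner first).
    Haplotypes are listed in order of first occurrence.
    """
    if not a.is_clean():
        raise AlignmentError(
            "collapse_alleles requires a cleaned (ACGT-only) alignment"
        )
    order: dict[str, int] = {}
    counts: list[int] = []
    membership: list[int] = []
    for s in a.seqs:
        idx = order.get(s)
        if idx is None:
            idx = len(order)
            order[s] = idx
            counts.append(0)
        counts[idx] += 1
        membership.append(idx)
    return AlleleSet(
        haplotypes=tuple(order),
        counts=tuple(counts),
        n=a.n,
        membership=tuple(membership),
    )
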