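"""Core domain types shared by every analysis module.

All internal coordinates are 0-based, half-open ``[start, end)``. Formats
that use other conventions (VCF's 1-based positions) are converted exactly
once, at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

# full IUPAC complement so ambiguity patterns reverse-complement correctly
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA/IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


class PreconditionError(ValueError):
    """Raised when an operation's stated precondition is violated."""


@dataclass
class GenomeSequence:
    """Named chromosomes of upper-case DNA text over {A,C,G,T,N}.

    Parameters
    ----------
    seq
        Mapping from chromosome name to sequence. Order of insertion is
        preserved as the canonical chromosome order.
    """

    seq: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("genome must contain at least one chromosome")
        for name, s in self.seq.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not s:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if not set(s) <= DNA_ALPHABET:
                bad = sorted(set(s) - DNA_ALPHABET)
                raise ValueError(f"chromosome {name!r} contains non-ACGTN characters {bad}")

    @property
    def chrom_names(self) -> List[str]:
        return list(self.seq)

    def length(self, chrom: str) -> int:
        return len(self.seq[chrom])

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.seq.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seq

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` clipped to the chromosome bounds."""
        s = self.seq[chrom]
        return s[max(0, start):min(len(s), end)]


def chrom_sizes(genome_or_sizes) -> Dict[str, int]:
    """Normalize a GenomeSequence or a plain ``{chrom: length}`` mapping."""
    if isinstance(genome_or_sizes, GenomeSequence):
        return genome_or_sizes.lengths
    return dict(genome_or_sizes)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# Breakend sides: which flank of the junction the sample retains.
LEFT_RETAINED = "left_retained"
RIGHT_RETAINED = "right_retained"


@dataclass(frozen=True)
class Breakend:
    """One side of a structural-variant junction.

    ``pos`` is the 0-based breakend base; ``side`` says whether the
    sequence to the left (upstream, through ``pos``) or to the right
    (``pos`` onward) of the junction is retained in the rearranged allele.
    """

    chrom: str
    pos: int
    side: str = RIGHT_RETAINED

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("breakend position must be >= 0")
        if self.side not in (LEFT_RETAINED, RIGHT_RETAINED):
            raise ValueError(f"invalid breakend side {self.side!r}")


@dataclass(frozen=True)
class BreakpointPair:
    """A pair of breakends forming one structural-variant junction."""

    breakend_a: Breakend
    breakend_b: Breakend
    id: str = ""
    sample: str = ""

    def swapped(self) -> "BreakpointPair":
        return BreakpointPair(self.breakend_b, self.breakend_a, self.id, self.sample)


@dataclass(frozen=True)
class VariantCall:
    """A biallelic single-nucleotide substitution; ``pos1`` is 1-based."""

    chrom: str
    pos1: int
    ref: str
    alt: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT" or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos1 < 1:
            raise ValueError("pos1 is 1-based and must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos1 - 1

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos1, self.ref, self.alt)


class SignalTrack:
    """Fixed-bin numeric track over a genome, optionally stranded.

    ``values[chrom]`` is a float array of length ``ceil(L / bin_width)``.
    A stranded track carries ``plus`` and ``minus`` component tracks and
    its own ``values`` holds their sum.
    """

    def __init__(
        self,
        bin_width: int,
        values: Mapping[str, np.ndarray],
        plus: Optional["SignalTrack"] = None,
        minus: Optional["SignalTrack"] = None,
    ) -> None:
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.bin_width = int(bin_width)
        self.values: Dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in track for {chrom!r}")
            self.values[chrom] = a
        self.plus = plus
        self.minus = minus

    @property
    def stranded(self) -> bool:
        return self.plus is not None and self.minus is not None

    @classmethod
    def stranded_from(cls, plus: "SignalTrack", minus: "SignalTrack") -> "SignalTrack":
        if plus.bin_width != minus.bin_width:
            raise ValueError("strand components must share bin_width")
        values = {
            c: plus.values.get(c, 0) + minus.values.get(c, 0)
            for c in set(plus.values) | set(minus.values)
        }
        return cls(plus.bin_width, values, plus=plus, minus=minus)

    @classmethod
    def zeros(cls, bin_width: int, sizes: Mapping[str, int]) -> "SignalTrack":
        values = {
            c: np.zeros(int(np.ceil(L / bin_width))) for c, L in sizes.items()
        }
        return cls(bin_width, values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def group_by_chrom(intervals: Iterable[GenomicInterval]) -> Dict[str, List[GenomicInterval]]:
    out: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out
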