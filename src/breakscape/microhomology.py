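"""Junction microhomology at structural-variant breakpoint pairs.

Microhomology is measured as junction shift-ambiguity: the number of
bases by which the junction could slide left (``left_shift``) or right
(``right_shift``) while keeping both partner sequences identical —
the standard breakend-homology semantics of SV callers. Exact matches
only; long homology tracts are capped at ``max_scan``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .core import (
    Breakend,
    BreakpointPair,
    GenomeSequence,
    LEFT_RETAINED,
    PreconditionError,
    RIGHT_RETAINED,
    revcomp,
)
from .stats import TestResult, wilcoxon_rank_sum


@dataclass
class MicrohomologyRecord:
    pair_id: str
    left_shift: int
    right_shift: int
    capped: bool

    @property
    def total(self) -> int:
        return self.left_shift + self.right_shift


def _donor_context(genome: GenomeSequence, be: Breakend, k: int) -> Tuple[str, str]:
    """(retained tail, continuation) for a breakend used as the 5' junction side.

    The retained sequence reads 5'->3' into the junction; the
    continuation is what would follow the breakend had it not broken,
    in the same orientation. Both are clipped at chromosome edges.
    """
    s = genome.seq[be.chrom]
    if be.pos >= len(s):
        raise PreconditionError(f"breakend at {be.pos} beyond chromosome {be.chrom!r}")
    if be.side == LEFT_RETAINED:
        retained = s[max(0, be.pos + 1 - k): be.pos + 1]
        continuation = s[be.pos + 1: be.pos + 1 + k]
    else:
        retained = revcomp(s[be.pos: be.pos + k])
        continuation = revcomp(s[max(0, be.pos - k): be.pos])
    return retained, continuation


def _acceptor_context(genome: GenomeSequence, be: Breakend, k: int) -> Tuple[str, str]:
    """(retained head, upstream context) for a breakend used as the 3' side."""
    s = genome.seq[be.chrom]
    if be.pos >= len(s):
        raise PreconditionError(f"breakend at {be.pos} beyond chromosome {be.chrom!r}")
    if be.side == RIGHT_RETAINED:
        retained = s[be.pos: be.pos + k]
        upstream = s[max(0, be.pos - k): be.pos]
    else:
        retained = revcomp(s[max(0, be.pos + 1 - k): be.pos + 1])
        upstream = revcomp(s[be.pos + 1: be.pos + 1 + k])
    return retained, upstream


def _shared_suffix(a: str, b: str) -> int:
    k = 0
    while k < len(a) and k < len(b) and a[-1 - k] == b[-1 - k]:
        k += 1
    return k


def _shared_prefix(a: str, b: str) -> int:
    k = 0
    while k < len(a) and k < len(b) and a[k] == b[k]:
        k += 1
    return k


def junction_microhomology(
    pair: BreakpointPair,
    genome: GenomeSequence,
    max_scan: int = 50,
) -> MicrohomologyRecord:
    """Microhomology of one junction.

    With D the retained sequence ending at breakend_a and A the retained
    sequence starting at breakend_b (reverse-complemented as needed so
    both read 5'->3' across the junction):

    * ``left_shift``: longest shared suffix of D and the sequence
      immediately upstream of A's start (bases the acceptor lost);
    * ``right_shift``: longest shared prefix of A and the continuation
      past breakend_a (bases the donor lost).

    ``capped`` is set when a shift reaches ``max_scan`` or the scan was
    truncated by a chromosome edge.
    """
    d_ret, d_cont = _donor_context(genome, pair.breakend_a, max_scan)
    a_ret, a_up = _acceptor_context(genome, pair.breakend_b, max_scan)
    left = _shared_suffix(d_ret, a_up)
    right = _shared_prefix(a_ret, d_cont)
    truncated = (
        left == min(len(d_ret), len(a_up))
        and min(len(d_ret), len(a_up)) < max_scan
    ) or (
        right == min(len(a_ret), len(d_cont))
        and min(len(a_ret), len(d_cont)) < max_scan
    )
    capped = left >= max_scan or right >= max_scan or truncated
    return MicrohomologyRecord(pair.id, left, right, capped)


@dataclass
class GroupSummary:
    group: str
    n: int
    median: float
    mean: float
    histogram: Dict[int, int]


@dataclass
class MicrohomologySummary:
    groups: List[GroupSummary]
    pairwise: List[Tuple[str, str, TestResult]]


def microhomology_distribution_summary(
    records_by_group: Mapping[str, Sequence[MicrohomologyRecord]],
) -> MicrohomologySummary:
    """Histogram, median and mean of total microhomology per group, with
    pairwise two-sided Wilcoxon rank-sum comparisons between groups."""
    groups: List[GroupSummary] = []
    totals: Dict[str, List[int]] = {}
    for name, recs in records_by_group.items():
        if not recs:
            raise PreconditionError(f"group {name!r} is empty")
        t = [r.total for r in recs]
        totals[name] = t
        hist: Dict[int, int] = {}
        for v in t:
            hist[v] = hist.get(v, 0) + 1
        groups.append(
            GroupSummary(name, len(t), float(np.median(t)), float(np.mean(t)), hist)
        )
    pairwise = [
        (g1, g2, wilcoxon_rank_sum(totals[g1], totals[g2], "two"))
        for g1, g2 in combinations(totals, 2)
    ]
    return MicrohomologySummary(groups, pairwise)
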