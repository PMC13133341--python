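"""Breakpoint region preparation, breakpoint-centered meta-profiles and
proximity statistics against shuffled-coordinate null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    BreakpointPair,
    GenomicInterval,
    PreconditionError,
    SignalTrack,
    chrom_sizes,
    group_by_chrom,
    sort_intervals,
)
from .stats import TestResult, chi_square_gof, wilcoxon_rank_sum


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome.

    Output is sorted and strand-less (strand is dropped, as merged loci
    may combine features of both strands).
    """
    merged: List[GenomicInterval] = []
    for chrom, ivs in sorted(group_by_chrom(intervals).items()):
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def filter_pairs_by_region(
    pairs: Iterable[BreakpointPair], region: GenomicInterval
) -> List[BreakpointPair]:
    """Pairs with either breakend inside ``region`` (half-open)."""

    def inside(be) -> bool:
        return be.chrom == region.chrom and region.start <= be.pos < region.end

    return [p for p in pairs if inside(p.breakend_a) or inside(p.breakend_b)]


def sample_random_intervals(
    intervals: Sequence[GenomicInterval],
    genome_or_sizes,
    n_draws: int,
    seed: int,
) -> List[List[GenomicInterval]]:
    """Shuffle intervals uniformly within their own chromosomes.

    Each draw preserves, per chromosome, both the number and the lengths
    of the input intervals (the "preserve chromosomal distribution"
    shuffle); start positions are uniform over valid placements.
    """
    sizes = chrom_sizes(genome_or_sizes)
    by_chrom = group_by_chrom(intervals)
    for chrom, ivs in by_chrom.items():
        if chrom not in sizes:
            raise PreconditionError(f"interval on unknown chromosome {chrom!r}")
        for iv in ivs:
            if len(iv) > sizes[chrom]:
                raise PreconditionError(
                    f"interval of length {len(iv)} exceeds chromosome {chrom!r}"
                )
    rng = np.random.default_rng(seed)
    draws: List[List[GenomicInterval]] = []
    for _ in range(n_draws):
        draw: List[GenomicInterval] = []
        for chrom, ivs in by_chrom.items():
            L = sizes[chrom]
            for iv in ivs:
                start = int(rng.integers(0, L - len(iv) + 1))
                draw.append(GenomicInterval(chrom, start, start + len(iv)))
        draws.append(draw)
    return draws


@dataclass
class MetaProfile:
    """Mean signal around anchor midpoints, offset-binned.

    ``offsets`` are bin-center offsets in bp relative to the anchor
    midpoint, from -half_window to +half_window.
    """

    half_window: int
    bin_width: int
    offsets: np.ndarray
    mean_signal: np.ndarray
    background_mean: Optional[np.ndarray]
    n_anchors: int
    n_background: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_anchors < 1:
            raise ValueError("meta-profile needs at least one usable anchor")
        if len(self.offsets) != len(self.mean_signal):
            raise ValueError("offsets and mean_signal must align")


def _profile_means(
    anchors: Sequence[GenomicInterval],
    track: SignalTrack,
    K: int,
) -> Tuple[np.ndarray, int, int]:
    """Mean track value at offsets -K..K bins around anchor midpoints."""
    acc = np.zeros(2 * K + 1)
    used = dropped = 0
    for iv in anchors:
        if iv.chrom not in track.values:
            dropped += 1
            continue
        arr = track.values[iv.chrom]
        b0 = iv.midpoint // track.bin_width
        if b0 - K < 0 or b0 + K >= len(arr):
            dropped += 1
            continue
        acc += arr[b0 - K: b0 + K + 1]
        used += 1
    if used:
        acc /= used
    return acc, used, dropped


def meta_profile(
    anchors: Sequence[GenomicInterval],
    track: SignalTrack,
    half_window: int,
    background: Optional[Sequence[Sequence[GenomicInterval]]] = None,
) -> MetaProfile:
    """Anchor-centered meta-profile of a binned signal track.

    Anchors are reduced to their midpoints; anchors whose window does
    not fit their chromosome are dropped (and counted). The optional
    ``background`` draws (e.g. from :func:`sample_random_intervals`) are
    pooled and profiled identically.
    """
    bw = track.bin_width
    if half_window % bw:
        raise PreconditionError("half_window must be a multiple of the track bin_width")
    K = half_window // bw
    mean_signal, used, dropped = _profile_means(anchors, track, K)
    if used == 0:
        raise PreconditionError("no anchor window fits its chromosome")
    bg_mean = None
    n_bg = 0
    if background is not None:
        pooled = [iv for draw in background for iv in draw]
        bg_mean, n_bg, _ = _profile_means(pooled, track, K)
    offsets = np.arange(-K, K + 1) * bw
    return MetaProfile(half_window, bw, offsets, mean_signal, bg_mean, used, n_bg, dropped)


def distance_to_nearest(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
) -> List[int]:
    """Distance from each query to its nearest same-chromosome feature.

    0 when overlapping (or book-ended); queries on feature-free
    chromosomes are excluded (their count is available on the returned
    list's ``n_missing`` attribute).
    """
    feats = group_by_chrom(features)
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for chrom, ivs in feats.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])
    out: List[int] = []
    n_missing = 0
    for q in queries:
        if q.chrom not in starts:
            n_missing += 1
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        gaps = np.maximum(s - q.end, q.start - e)
        out.append(int(max(0, gaps.min())))
    if not out:
        raise PreconditionError("all queries lie on feature-free chromosomes")
    result = _IntListWithMeta(out)
    result.n_missing = n_missing
    return result


class _IntListWithMeta(list):
    n_missing = 0


@dataclass
class DistanceTestResult:
    observed_distances: List[int]
    null_distances: List[int]
    wilcoxon: TestResult
    observed_median: float
    null_median: float


def proximity_null_test(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    genome_or_sizes,
    n_draws: int = 100,
    seed: int = 0,
) -> DistanceTestResult:
    """Observed nearest-feature distances vs a shuffled-coordinate null.

    The null pools the distances of ``n_draws`` chromosome-preserving
    shuffles of the queries; the two distance samples are compared with
    a two-sided Wilcoxon rank-sum test.
    """
    observed = distance_to_nearest(queries, features)
    draws = sample_random_intervals(queries, genome_or_sizes, n_draws, seed)
    null: List[int] = []
    for draw in draws:
        null.extend(distance_to_nearest(draw, features))
    test = wilcoxon_rank_sum(observed, null, tails="two")
    return DistanceTestResult(
        list(observed),
        null,
        test,
        float(np.median(observed)),
        float(np.median(null)),
    )


@dataclass
class RelDistResult:
    bin_edges: np.ndarray
    observed_freq: np.ndarray
    expected_freq: np.ndarray
    chi2: TestResult
    n_used: int
    n_excluded: int
    reldists: np.ndarray = field(default_factory=lambda: np.array([]))


def relative_distance_test(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    n_bins: int = 10,
) -> RelDistResult:
    """Relative-distance statistic of queries within the feature grid.

    For each query midpoint q between flanking feature midpoints
    L <= q < R, reldist = min(q-L, R-q)/(R-L) in [0, 0.5]; under
    independence reldist is uniform, which is tested with Pearson's
    chi-square against equal bin counts.
    """
    feat_mids: Dict[str, np.ndarray] = {}
    for chrom, ivs in group_by_chrom(features).items():
        mids = np.unique(np.array(sorted(iv.midpoint for iv in ivs)))
        if len(mids) >= 2:
            feat_mids[chrom] = mids
    if not feat_mids:
        raise PreconditionError("need >= 2 features on at least one chromosome")
    vals: List[float] = []
    n_excluded = 0
    for q in queries:
        mids = feat_mids.get(q.chrom)
        qm = q.midpoint
        if mids is None or qm < mids[0] or qm >= mids[-1]:
            n_excluded += 1
            continue
        i = int(np.searchsorted(mids, qm, side="right")) - 1
        L, R = int(mids[i]), int(mids[i + 1])
        vals.append(min(qm - L, R - qm) / (R - L))
    if not vals:
        raise PreconditionError("no query lies within the feature span")
    arr = np.asarray(vals)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    # np.histogram closes the last bin on the right, so reldist == 0.5
    # (query exactly midway) lands in the last bin as intended
    counts, _ = np.histogram(arr, bins=edges)
    expected = np.full(n_bins, len(arr) / n_bins)
    test = chi_square_gof(counts, expected)
    return RelDistResult(
        edges,
        counts / len(arr),
        expected / len(arr),
        test,
        len(arr),
        n_excluded,
        reldists=arr,
    )


def pairs_to_intervals(pairs: Iterable[BreakpointPair], width: int = 1) -> List[GenomicInterval]:
    """Breakends of each pair as width-bp intervals (both ends emitted)."""
    out: List[GenomicInterval] = []
    for p in pairs:
        for be in (p.breakend_a, p.breakend_b):
            out.append(GenomicInterval(be.chrom, be.pos, be.pos + width, name=p.id or None))
    return out
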