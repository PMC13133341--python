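"""DamID-seq quantification over DpnI (GATC) restriction fragments.

Reads from Dam-fusion and Dam-only samples are counted onto the GATC
fragment grid, library-size corrected to counts per million, and the
averaged Dam-only background is subtracted to leave fusion-specific
occupancy. Region-level occupancy and enrichment tests operate on the
corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GenomeSequence,
    GenomicInterval,
    PreconditionError,
    group_by_chrom,
)
from .stats import TestResult, moods_median_test

FUSION = "fusion"
DAM_ONLY = "dam_only"


@dataclass
class FragmentMap:
    """Per-chromosome fragments tiling [0, length) without gaps/overlaps."""

    fragments: Dict[str, List[GenomicInterval]]

    def __post_init__(self) -> None:
        for chrom, frags in self.fragments.items():
            pos = 0
            for f in frags:
                if f.start != pos:
                    raise ValueError(f"fragment map does not tile {chrom!r} at {pos}")
                pos = f.end
        # flat index for table rows
        self._flat: List[GenomicInterval] = [
            f for chrom in self.fragments for f in self.fragments[chrom]
        ]
        self._offsets: Dict[str, int] = {}
        off = 0
        for chrom, frags in self.fragments.items():
            self._offsets[chrom] = off
            off += len(frags)

    @property
    def flat(self) -> List[GenomicInterval]:
        return self._flat

    def n_fragments(self) -> int:
        return len(self._flat)

    def fragment_index(self, chrom: str, pos: int) -> int:
        """Flat index of the fragment containing ``pos`` on ``chrom``."""
        frags = self.fragments[chrom]
        ends = np.array([f.end for f in frags])
        i = int(np.searchsorted(ends, pos, side="right"))
        if i >= len(frags) or not frags[i].contains(pos):
            raise KeyError(f"position {chrom}:{pos} outside fragment map")
        return self._offsets[chrom] + i


def gatc_fragment_map(genome: GenomeSequence) -> FragmentMap:
    """DpnI fragments: cuts at +2 inside every plus-strand GATC (GA^TC).

    A chromosome without GATC yields a single full-length fragment.
    """
    fragments: Dict[str, List[GenomicInterval]] = {}
    for chrom, seq in genome.seq.items():
        cuts: List[int] = []
        start = 0
        while True:
            i = seq.find("GATC", start)
            if i == -1:
                break
            cuts.append(i + 2)
            start = i + 1  # GATC occurrences cannot overlap, but stay safe
        bounds = [0] + cuts + [len(seq)]
        frags = [
            GenomicInterval(chrom, a, b)
            for a, b in zip(bounds[:-1], bounds[1:])
            if b > a
        ]
        fragments[chrom] = frags
    return FragmentMap(fragments)


def count_reads_to_fragments(
    reads_per_sample: Mapping[str, object],
    fragment_map: FragmentMap,
) -> Tuple[np.ndarray, List[str], Dict[str, int]]:
    """Count reads onto fragments by read midpoint.

    Reads per sample are either a sequence of GenomicInterval or the
    compact form {chrom: (starts, ends)} of numpy arrays. Returns (raw
    count matrix fragments x samples, sample order, per-sample
    skipped-read counts for unknown chromosomes).
    """
    samples = list(reads_per_sample)
    raw = np.zeros((fragment_map.n_fragments(), len(samples)), dtype=np.int64)
    skipped: Dict[str, int] = {s: 0 for s in samples}
    # vectorized midpoint -> fragment lookup per chromosome
    ends_by_chrom = {
        chrom: np.array([f.end for f in frags])
        for chrom, frags in fragment_map.fragments.items()
    }
    for si, sample in enumerate(samples):
        reads = reads_per_sample[sample]
        mids: Dict[str, np.ndarray] = {}
        if isinstance(reads, Mapping):
            for chrom, (starts, ends) in reads.items():
                if chrom not in fragment_map.fragments:
                    skipped[sample] += len(starts)
                    continue
                mids[chrom] = (np.asarray(starts) + np.asarray(ends)) // 2
        else:
            acc: Dict[str, List[int]] = {}
            for r in reads:
                if r.chrom not in fragment_map.fragments:
                    skipped[sample] += 1
                    continue
                acc.setdefault(r.chrom, []).append(r.midpoint)
            mids = {c: np.asarray(v) for c, v in acc.items()}
        for chrom, ms in mids.items():
            ends = ends_by_chrom[chrom]
            idx = np.searchsorted(ends, ms, side="right")
            off = fragment_map._offsets[chrom]
            np.add.at(raw[:, si], off + idx, 1)
    return raw, samples, skipped


@dataclass
class OccupancyTable:
    """Raw, normalized and background-corrected fragment counts."""

    fragments: FragmentMap
    samples: List[str]
    sample_roles: Dict[str, str]
    raw: np.ndarray
    normalized: np.ndarray = field(init=False)
    corrected: np.ndarray = field(init=False)
    background: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.raw.shape != (self.fragments.n_fragments(), len(self.samples)):
            raise ValueError("raw matrix shape mismatch")
        roles = set(self.sample_roles.get(s) for s in self.samples)
        if not roles <= {FUSION, DAM_ONLY}:
            raise PreconditionError("sample roles must be 'fusion' or 'dam_only'")
        normalize_and_subtract_background(self)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def corrected_for(self, sample: str) -> np.ndarray:
        return self.corrected[:, self.sample_index(sample)]


def normalize_and_subtract_background(table: OccupancyTable) -> np.ndarray:
    """CPM-normalise every sample, then subtract the mean Dam-only track.

    Per sample, counts are scaled to counts-per-million of that sample's
    total; the background is the per-fragment mean over Dam-only samples
    (in the same normalized units) and is subtracted from every sample.
    Corrected values may be negative.
    """
    dam_idx = [
        i for i, s in enumerate(table.samples)
        if table.sample_roles.get(s) == DAM_ONLY
    ]
    if not dam_idx:
        raise PreconditionError("need at least one dam_only sample")
    totals = table.raw.sum(axis=0).astype(float)
    if np.any(totals == 0):
        zero = [s for s, t in zip(table.samples, totals) if t == 0]
        raise PreconditionError(f"zero-total samples: {zero}")
    table.normalized = table.raw / totals * 1e6
    table.background = table.normalized[:, dam_idx].mean(axis=1)
    table.corrected = table.normalized - table.background[:, None]
    return table.corrected


def build_prompt_regions(
    tss: Sequence[GenomicInterval],
    genome_or_sizes,
    span: int = 3000,
) -> List[GenomicInterval]:
    """Putative promoter-upstream-transcript regions.

    For each transcription start site the ``span`` bp upstream and
    antisense of it: a plus-strand TSS at t gives [t-span, t) on "-",
    a minus-strand TSS at t gives [t, t+span) on "+"; clipped at
    chromosome bounds.
    """
    from .core import chrom_sizes

    sizes = chrom_sizes(genome_or_sizes)
    out: List[GenomicInterval] = []
    for iv in tss:
        if iv.strand not in ("+", "-"):
            raise PreconditionError("TSS intervals must carry strand")
        L = sizes[iv.chrom]
        if iv.strand == "+":
            t = iv.start
            start, end, strand = max(0, t - span), t, "-"
        else:
            t = iv.end - 1
            start, end, strand = t, min(L, t + span), "+"
        if start < end:
            out.append(GenomicInterval(iv.chrom, start, end, strand, iv.name))
    return out


def region_occupancy(
    table: OccupancyTable,
    regions: Sequence[GenomicInterval],
    sample: Optional[str] = None,
) -> np.ndarray:
    """Overlap-length-weighted mean corrected occupancy per region.

    Returns an array regions x samples (or a 1-D vector for one sample).
    """
    cols = (
        table.corrected
        if sample is None
        else table.corrected[:, [table.sample_index(sample)]]
    )
    out = np.zeros((len(regions), cols.shape[1]))
    for ri, region in enumerate(regions):
        frags = table.fragments.fragments.get(region.chrom)
        if frags is None:
            raise PreconditionError(f"region on unknown chromosome {region.chrom!r}")
        ends = np.array([f.end for f in frags])
        starts = np.array([f.start for f in frags])
        i0 = int(np.searchsorted(ends, region.start, side="right"))
        i1 = int(np.searchsorted(starts, region.end, side="left"))
        assert i1 > i0, "tiling guarantees at least one overlapping fragment"
        off = table.fragments._offsets[region.chrom]
        w = (
            np.minimum(ends[i0:i1], region.end)
            - np.maximum(starts[i0:i1], region.start)
        ).astype(float)
        out[ri] = (cols[off + np.arange(i0, i1)] * w[:, None]).sum(axis=0) / w.sum()
    return out[:, 0] if sample is not None else out


def occupancy_enrichment_test(
    table: OccupancyTable,
    target_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
    sample: str,
) -> TestResult:
    """Mood's median test of per-region occupancy, targets vs background."""
    if not target_regions or not background_regions:
        raise PreconditionError("both region sets must be non-empty")
    t = region_occupancy(table, target_regions, sample)
    b = region_occupancy(table, background_regions, sample)
    return moods_median_test(t, b)
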