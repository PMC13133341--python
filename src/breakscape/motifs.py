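"""Sequence-level annotation: IUPAC motif scans, G-quadruplex annotation,
GC content.

The default motif set holds the classic AID hotspot patterns (RGYW and
friends); G-quadruplexes are annotated by the G-run rule (at least four
runs of at least three G, separated by short loops), with a stringent
(loops up to 7 nt) and a relaxed (up to 30 nt) parameterization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GenomeSequence,
    GenomicInterval,
    PreconditionError,
    SignalTrack,
    revcomp,
)

# IUPAC ambiguity codes -> concrete base sets. N in the *sequence* never
# matches (conservative behavior in assembly gaps), so no code expands to N.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# AID hotspot / off-target motifs used throughout the analyses
DEFAULT_MOTIFS: Dict[str, str] = {
    "RGYW": "RGYW",
    "GAGCT": "GAGCT",
    "GGGGW": "GGGGW",
    "GGGCT": "GGGCT",
}


@dataclass(frozen=True)
class MotifSet:
    """Named IUPAC patterns to scan for."""

    patterns: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("motif set must be non-empty")
        for name, pat in self.patterns.items():
            _validate_iupac(pat)


@dataclass(frozen=True)
class G4Params:
    """G-quadruplex annotation rule parameters.

    ``max_loop`` = 7 gives the stringent annotation, 30 the relaxed one.
    """

    min_run_length: int = 3
    min_runs: int = 4
    max_loop: int = 7

    def __post_init__(self) -> None:
        if min(self.min_run_length, self.min_runs, self.max_loop) < 1:
            raise ValueError("all G4 parameters must be >= 1")


STRINGENT_G4 = G4Params(max_loop=7)
RELAXED_G4 = G4Params(max_loop=30)


def _validate_iupac(pattern: str) -> None:
    if not pattern:
        raise PreconditionError("empty IUPAC pattern")
    bad = [c for c in pattern.upper() if c not in IUPAC]
    if bad:
        raise PreconditionError(f"invalid IUPAC codes {bad} in pattern {pattern!r}")


def iupac_to_regex(pattern: str) -> str:
    parts = []
    for c in pattern.upper():
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_iupac_motifs(
    genome: GenomeSequence,
    pattern: str,
    strands: str = "+-",
    name: Optional[str] = None,
) -> List[GenomicInterval]:
    """All (possibly overlapping) matches of an IUPAC pattern.

    Minus-strand matches are found by matching the reverse complement of
    the pattern against the plus-strand text and are reported in plus
    coordinates with strand "-". Windows containing N never match.
    """
    _validate_iupac(pattern)
    label = name or pattern
    out: List[GenomicInterval] = []
    k = len(pattern)
    searches: List[Tuple[str, re.Pattern]] = []
    if "+" in strands:
        searches.append(("+", re.compile(f"(?=({iupac_to_regex(pattern)}))")))
    if "-" in strands:
        searches.append(("-", re.compile(f"(?=({iupac_to_regex(revcomp(pattern.upper()))}))")))
    for chrom, seq in genome.seq.items():
        for strand, rx in searches:
            for m in rx.finditer(seq):
                out.append(GenomicInterval(chrom, m.start(), m.start() + k, strand, label))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return out


def motif_density_track(
    genome: GenomeSequence,
    motif_set: MotifSet,
    bin_width: int,
    strands: str = "+-",
    collapse: bool = False,
) -> Dict[str, SignalTrack]:
    """Per-motif match-density tracks (matches per bp).

    Each match is counted once, in the bin of its start; per-bin counts
    are divided by ``bin_width`` so that sum(track) * bin_width equals
    the total match count. ``collapse=True`` merges overlapping matches
    per strand before counting (off by default).
    """
    if bin_width < 1:
        raise PreconditionError("bin_width must be >= 1")
    sizes = genome.lengths
    tracks: Dict[str, SignalTrack] = {}
    for mname, pattern in motif_set.patterns.items():
        matches = scan_iupac_motifs(genome, pattern, strands=strands, name=mname)
        if collapse:
            from .breakpoints import merge_intervals

            per_strand: List[GenomicInterval] = []
            for s in set(iv.strand for iv in matches):
                per_strand.extend(
                    merge_intervals([iv for iv in matches if iv.strand == s])
                )
            matches = per_strand
        track = SignalTrack.zeros(bin_width, sizes)
        for iv in matches:
            track.values[iv.chrom][iv.start // bin_width] += 1.0 / bin_width
        tracks[mname] = track
    return tracks


_G_RUN_RE = {}


def _runs(seq: str, base: str, min_len: int) -> List[Tuple[int, int]]:
    """Maximal runs of ``base`` of length >= min_len, as (start, end)."""
    key = (base, min_len)
    rx = _G_RUN_RE.get(key)
    if rx is None:
        rx = _G_RUN_RE[key] = re.compile(f"{base}{{{min_len},}}")
    return [(m.start(), m.end()) for m in rx.finditer(seq)]


def scan_g_quadruplexes(
    genome: GenomeSequence,
    params: G4Params = STRINGENT_G4,
) -> List[GenomicInterval]:
    """Maximal non-overlapping G-quadruplex-forming intervals per strand.

    A match is >= ``min_runs`` runs of >= ``min_run_length`` consecutive
    G separated by loops of 1..``max_loop`` bases, extended greedily
    left-to-right to the longest valid span. Minus-strand quadruplexes
    are found as C-runs on the plus text and reported with strand "-".
    """
    out: List[GenomicInterval] = []
    for chrom, seq in genome.seq.items():
        for strand, base in (("+", "G"), ("-", "C")):
            runs = _runs(seq, base, params.min_run_length)
            # chain consecutive runs while the loop between them is short
            # enough; a maximal chain of >= min_runs runs is one match.
            i = 0
            while i < len(runs):
                j = i
                while (
                    j + 1 < len(runs)
                    and 1 <= runs[j + 1][0] - runs[j][1] <= params.max_loop
                ):
                    j += 1
                if j - i + 1 >= params.min_runs:
                    out.append(
                        GenomicInterval(chrom, runs[i][0], runs[j][1], strand, "G4")
                    )
                i = j + 1
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return out


def gc_content_track(genome: GenomeSequence, bin_width: int) -> SignalTrack:
    """Per-bin GC fraction over non-N bases; all-N bins get 0 and a mask.

    The returned track carries a ``mask`` attribute: dict of boolean
    arrays flagging bins with no informative (non-N) base.
    """
    if bin_width < 1:
        raise PreconditionError("bin_width must be >= 1")
    values: Dict[str, np.ndarray] = {}
    mask: Dict[str, np.ndarray] = {}
    for chrom, seq in genome.seq.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n_bins = int(np.ceil(len(arr) / bin_width))
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        gc = np.zeros(n_bins)
        informative = np.zeros(n_bins)
        idx = np.arange(len(arr)) // bin_width
        np.add.at(gc, idx, is_gc.astype(float))
        np.add.at(informative, idx, (~is_n).astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(informative > 0, gc / np.maximum(informative, 1), 0.0)
        values[chrom] = frac
        mask[chrom] = informative == 0
    track = SignalTrack(bin_width, values)
    track.mask = mask  # type: ignore[attr-defined]
    return track
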