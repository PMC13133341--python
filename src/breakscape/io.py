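"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are normalized strictly at this boundary: BED,
BEDPE and bedGraph are already 0-based half-open and are kept as-is; VCF
positions stay 1-based inside :class:`~breakscape.core.VariantCall` and
are converted through its ``pos0`` property.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .core import (
    Breakend,
    BreakpointPair,
    FormatError,
    GenomeSequence,
    GenomicInterval,
    LEFT_RETAINED,
    RIGHT_RETAINED,
    SignalTrack,
    VariantCall,
    chrom_sizes,
)

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are mapped
    to N and the substitution count is logged.
    """
    seqs: Dict[str, str] = {}
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        s = str(rec.seq).upper()
        bad = [c for c in set(s) if c not in _VALID]
        if bad:
            for c in bad:
                n_subst += s.count(c)
                s = s.replace(c, "N")
        seqs[rec.id] = s
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    if n_subst:
        logger.info("read_fasta: mapped %d non-ACGTN characters to N", n_subst)
    genome = GenomeSequence(seqs)
    genome.n_substituted = n_subst  # type: ignore[attr-defined]
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, s in genome.seq.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals (kept 0-based half-open)."""
    out: List[GenomicInterval] = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        out.append(GenomicInterval(f[0], start, end, strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_bedpe(
    path,
    side_a: str = RIGHT_RETAINED,
    side_b: str = LEFT_RETAINED,
) -> List[BreakpointPair]:
    """Read BEDPE breakpoint pairs; breakend position = interval start.

    The retained-side annotation is not part of BEDPE, so defaults are
    applied (configurable per caller).
    """
    out: List[BreakpointPair] = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        try:
            s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if s1 < 0 or s2 < 0 or s1 >= e1 or s2 >= e2:
            raise FormatError(f"{path}:{lineno}: malformed BEDPE coordinates")
        name = f[6] if len(f) > 6 else f"pair{len(out) + 1}"
        out.append(
            BreakpointPair(
                Breakend(f[0], s1, side_a),
                Breakend(f[3], s2, side_b),
                id=name,
            )
        )
    return out


def write_bedpe(pairs: Sequence[BreakpointPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.breakend_a, p.breakend_b
            fh.write(
                f"{a.chrom}\t{a.pos}\t{a.pos + 1}\t{b.chrom}\t{b.pos}\t{b.pos + 1}"
                f"\t{p.id or '.'}\n"
            )


def read_vcf_snvs(path, sample: str = "") -> List[VariantCall]:
    """Read biallelic single-base substitutions from a VCF v4 text file.

    Only CHROM/POS/REF/ALT are consumed; indels and multiallelic records
    are skipped and the skip count is logged (also returned on the list
    as the ``n_skipped`` attribute).
    """
    out: List[VariantCall] = []
    n_skipped = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#CHROM"):
                    saw_header = True
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}:{lineno}: VCF needs >= 5 columns")
            chrom, pos_s, _id, ref, alt = f[0], f[1], f[2], f[3].upper(), f[4].upper()
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer POS") from exc
            if (
                len(ref) != 1
                or len(alt) != 1
                or ref not in "ACGT"
                or alt not in "ACGT"
                or ref == alt
            ):
                n_skipped += 1
                continue
            out.append(VariantCall(chrom, pos1, ref, alt, sample=sample))
    if n_skipped:
        logger.info("read_vcf_snvs: skipped %d non-SNV records in %s", n_skipped, path)
    out_list = out
    # attach skip count without changing the return type contract
    out_list = _ListWithMeta(out_list)
    out_list.n_skipped = n_skipped
    return out_list


class _ListWithMeta(list):
    """Plain list that can carry side-channel counters (n_skipped etc.)."""


def write_vcf_snvs(variants: Sequence[VariantCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def read_bedgraph_track(
    paths: Sequence,
    bin_width: int,
    genome_or_sizes,
) -> SignalTrack:
    """Bin one (unstranded) or two (plus, minus) bedGraph files.

    Interval values are averaged into fixed bins weighted by overlap
    length; uncovered bases contribute 0.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    sizes = chrom_sizes(genome_or_sizes)
    if len(paths) == 1:
        return _read_one_bedgraph(paths[0], bin_width, sizes)
    if len(paths) == 2:
        plus = _read_one_bedgraph(paths[0], bin_width, sizes)
        minus = _read_one_bedgraph(paths[1], bin_width, sizes)
        return SignalTrack.stranded_from(plus, minus)
    raise ValueError("read_bedgraph_track takes one path or a (plus, minus) pair")


def _read_one_bedgraph(path, bin_width: int, sizes: Dict[str, int]) -> SignalTrack:
    track = SignalTrack.zeros(bin_width, sizes)
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
        if chrom not in sizes:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or start >= end or end > sizes[chrom]:
            raise FormatError(
                f"{path}:{lineno}: interval [{start}, {end}) outside {chrom!r}"
            )
        arr = track.values[chrom]
        b0, b1 = start // bin_width, (end - 1) // bin_width
        for b in range(b0, b1 + 1):
            lo, hi = max(start, b * bin_width), min(end, (b + 1) * bin_width)
            arr[b] += value * (hi - lo) / bin_width
    return track


def write_bedgraph(track: SignalTrack, path, chroms: Optional[Sequence[str]] = None) -> None:
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in chroms or track.values:
            arr = track.values[chrom]
            for b, v in enumerate(arr):
                if v != 0.0:
                    fh.write(f"{chrom}\t{b * bw}\t{(b + 1) * bw}\t{v:g}\n")


def read_contact_triples(path, bin_width: int, chrom: str, n_bins: Optional[int] = None):
    """Read ``pos1 pos2 count`` triples into a dense symmetric ContactMatrix.

    Positions must be multiples of ``bin_width`` (the juicer dump dialect).
    Duplicate triples for the same bin pair are summed.
    """
    from .contacts import ContactMatrix

    entries: List[Tuple[int, int, float]] = []
    max_bin = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: need 'pos1 pos2 count'")
            p1, p2, cnt = int(f[0]), int(f[1]), float(f[2])
            if p1 % bin_width or p2 % bin_width:
                raise FormatError(
                    f"{path}:{lineno}: position not a multiple of bin_width {bin_width}"
                )
            i, j = p1 // bin_width, p2 // bin_width
            entries.append((i, j, cnt))
            max_bin = max(max_bin, i, j)
    n = n_bins if n_bins is not None else max_bin + 1
    if n < 1:
        raise FormatError(f"no contact triples in {path}")
    M = np.zeros((n, n))
    for i, j, cnt in entries:
        M[i, j] += cnt
        if i != j:
            M[j, i] += cnt
    return ContactMatrix(chrom=chrom, bin_width=bin_width, M=M)


def write_contact_triples(matrix, path) -> None:
    bw = matrix.bin_width
    with open(path, "w") as fh:
        n = matrix.M.shape[0]
        for i in range(n):
            for j in range(i, n):
                v = matrix.M[i, j]
                if v != 0.0:
                    fh.write(f"{i * bw}\t{j * bw}\t{v:g}\n")
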