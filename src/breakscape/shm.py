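"""Somatic-variant filtering, mutated-cytidine strand assignment and
transcriptional strand-asymmetry statistics.

AID deaminates cytosines on single-stranded DNA; during transcription the
non-template (coding) strand is preferentially exposed, so somatic
hypermutation shows a strand bias: mutated cytidines accumulate on the
non-template strand of transcribed units. This module quantifies that
bias from caller output and a stranded gene model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GenomicInterval,
    PreconditionError,
    SignalTrack,
    VariantCall,
    group_by_chrom,
)
from .breakpoints import MetaProfile, _profile_means
from .stats import TestResult, binomial_test


def filter_somatic_variants(
    per_sample_variants: Mapping[str, Sequence[VariantCall]],
    controls: Optional[Mapping[str, Sequence[VariantCall]]] = None,
) -> Dict[str, List[VariantCall]]:
    """Keep variants uniquely present in a single tumor sample.

    A variant (chrom, pos, ref, alt) is somatic for a sample iff it
    occurs in no other tumor sample and in no control sample (variants
    seen in any control are treated as germline).
    """
    if not per_sample_variants or (
        len(per_sample_variants) < 2 and not controls
    ):
        raise PreconditionError(
            "somatic filtering needs >= 2 tumor samples or >= 1 control"
        )
    germline = set()
    if controls:
        for vs in controls.values():
            germline.update(v.key() for v in vs)
    counts: Dict[Tuple, int] = {}
    for vs in per_sample_variants.values():
        for k in {v.key() for v in vs}:
            counts[k] = counts.get(k, 0) + 1
    out: Dict[str, List[VariantCall]] = {}
    for sample, vs in per_sample_variants.items():
        out[sample] = [
            v for v in vs if counts[v.key()] == 1 and v.key() not in germline
        ]
    return out


# alt bases compatible with a mutated cytidine: any substitution of C is a
# cytidine mutation; on the minus strand a mutated C appears as ref G.
def select_cytidine_mutations(
    variants: Iterable[VariantCall],
) -> List[Tuple[VariantCall, str]]:
    """Variants whose mutated base is a cytidine, with its strand.

    Ref C -> the mutated C lies on the plus strand (c_strand "+");
    ref G -> the mutated C lies on the minus strand (c_strand "-").
    All C>T/G/A (and complement G>A/C/T) substitutions qualify.
    """
    out: List[Tuple[VariantCall, str]] = []
    for v in variants:
        if v.ref == "C":
            out.append((v, "+"))
        elif v.ref == "G":
            out.append((v, "-"))
    return out


@dataclass
class StrandAsymmetryResult:
    n_nontemplate: int
    n_template: int
    n_unassigned: int
    bias: float
    binomial: Optional[TestResult]

    @property
    def n_total(self) -> int:
        return self.n_nontemplate + self.n_template + self.n_unassigned


def assign_transcriptional_strand(
    cytidine_mutations: Sequence[Tuple[VariantCall, str]],
    genes: Sequence[GenomicInterval],
) -> StrandAsymmetryResult:
    """Classify each mutated cytidine as template / non-template.

    A mutation inside genes of exactly one strand is non-template when
    its c_strand equals the gene strand (the coding strand carries the
    C that AID hit) and template otherwise. Mutations outside all genes,
    or inside overlapping genes of both strands, are unassigned.
    """
    for g in genes:
        if g.strand not in ("+", "-"):
            raise PreconditionError("genes must carry strand")
    by_chrom = group_by_chrom(genes)
    sorted_genes: Dict[str, Tuple[np.ndarray, np.ndarray, List[str]]] = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        sorted_genes[chrom] = (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
            [g.strand for g in gs],
        )
    n_nt = n_t = n_un = 0
    for v, c_strand in cytidine_mutations:
        entry = sorted_genes.get(v.chrom)
        strands = set()
        if entry is not None:
            starts, ends, gstrands = entry
            pos = v.pos0
            hit = (starts <= pos) & (pos < ends)
            strands = {gstrands[i] for i in np.nonzero(hit)[0]}
        if len(strands) != 1:
            n_un += 1
        elif c_strand in strands:
            n_nt += 1
        else:
            n_t += 1
    denom = n_nt + n_t
    bias = n_nt / denom if denom else float("nan")
    test = binomial_test(n_nt, denom, 0.5, "two") if denom else None
    return StrandAsymmetryResult(n_nt, n_t, n_un, bias, test)


@dataclass
class DirectionalProfiles:
    """Sense/antisense meta-profiles around mutated cytidines.

    Offsets read 5'->3' along the mutated-C strand; profiles of the
    minus-strand class are reversed before averaging so orientation is
    uniform.
    """

    sense: MetaProfile
    antisense: MetaProfile
    per_class: Dict[str, Tuple[MetaProfile, MetaProfile]]


def _oriented_means(
    positions: Sequence[Tuple[str, int]],
    track: SignalTrack,
    K: int,
    reverse: bool,
) -> Tuple[np.ndarray, int]:
    acc = np.zeros(2 * K + 1)
    used = 0
    for chrom, pos in positions:
        if chrom not in track.values:
            continue
        arr = track.values[chrom]
        b0 = pos // track.bin_width
        if b0 - K < 0 or b0 + K >= len(arr):
            continue
        window = arr[b0 - K: b0 + K + 1]
        acc += window[::-1] if reverse else window
        used += 1
    if used:
        acc /= used
    return acc, used


def directional_signal_profile(
    cytidine_mutations: Sequence[Tuple[VariantCall, str]],
    stranded_track: SignalTrack,
    half_window: int,
) -> DirectionalProfiles:
    """Strand-aware signal aggregation over mutated cytidines.

    For each mutation the sense component is the track strand matching
    its c_strand and the antisense component the opposite strand;
    offsets are oriented 5'->3' along the c_strand.
    """
    if not stranded_track.stranded:
        raise PreconditionError("directional profiles require a stranded track")
    bw = stranded_track.bin_width
    if half_window % bw:
        raise PreconditionError("half_window must be a multiple of the track bin_width")
    K = half_window // bw
    offsets = np.arange(-K, K + 1) * bw
    plus, minus = stranded_track.plus, stranded_track.minus

    by_class: Dict[str, List[Tuple[str, int]]] = {"+": [], "-": []}
    for v, c_strand in cytidine_mutations:
        by_class[c_strand].append((v.chrom, v.pos0))

    per_class: Dict[str, Tuple[MetaProfile, MetaProfile]] = {}
    acc = {}
    for c_strand, positions in by_class.items():
        sense_comp = plus if c_strand == "+" else minus
        anti_comp = minus if c_strand == "+" else plus
        reverse = c_strand == "-"
        s_mean, s_n = _oriented_means(positions, sense_comp, K, reverse)
        a_mean, a_n = _oriented_means(positions, anti_comp, K, reverse)
        acc[c_strand] = (s_mean, a_mean, s_n)
        if s_n:
            per_class[c_strand] = (
                MetaProfile(half_window, bw, offsets, s_mean, None, s_n),
                MetaProfile(half_window, bw, offsets, a_mean, None, a_n),
            )
    total = sum(v[2] for v in acc.values())
    if total == 0:
        raise PreconditionError("no mutation window fits its chromosome")
    s_all = sum(v[0] * v[2] for v in acc.values()) / total
    a_all = sum(v[1] * v[2] for v in acc.values()) / total
    return DirectionalProfiles(
        MetaProfile(half_window, bw, offsets, s_all, None, total),
        MetaProfile(half_window, bw, offsets, a_all, None, total),
        per_class,
    )
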