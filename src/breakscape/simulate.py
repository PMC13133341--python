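"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its configuration and the master
seed: each derives its own random stream from ``(seed, label)`` so adding
one generator never perturbs another's output. Planted elements never
overlap each other and are returned as truth tables alongside the data.

Defaults emulate the study conditions the analyses are calibrated
against: a mammalian-like GC fraction, kilobase-scale transcription
units, half-normal breakpoint proximity bias (sigma 1 kb), signature
mixtures over 96-class spectra, 4-fold DamID enrichment at deep
coverage, and 2-kb contact matrices with power-law distance decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Breakend,
    BreakpointPair,
    GenomeSequence,
    GenomicInterval,
    LEFT_RETAINED,
    RIGHT_RETAINED,
    VariantCall,
    chrom_sizes,
)
from .contacts import ContactMatrix
from .damid import FragmentMap
from .motifs import IUPAC, G4Params, STRINGENT_G4
from .signatures import CLASS_LABELS, SUBSTITUTIONS, SignatureCatalog

# stable stream labels (never reorder: they define the seed derivation)
_STREAMS = {
    "genome": 1,
    "transcription_units": 2,
    "breakpoints": 3,
    "snvs": 4,
    "damid": 5,
    "contacts": 6,
    "catalog": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class PlantedMotif:
    pattern: str
    count: int


@dataclass
class PlantedG4:
    params: G4Params = field(default_factory=lambda: STRINGENT_G4)
    count: int = 0
    n_runs: int = 4
    run_length: int = 3
    loop_length: int = 2


@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.42
    motif_clusters: List[PlantedMotif] = field(default_factory=list)
    g4s: Optional[PlantedG4] = None


@dataclass
class TranscriptionConfig:
    n_units: int = 40
    min_length: int = 2_000
    max_length: int = 20_000
    p_plus: float = 0.5


@dataclass
class BreakpointConfig:
    n_pairs: int = 50
    sigma: float = 1_000.0  # half-normal proximity bias, bp
    biased: bool = True


@dataclass
class SnvConfig:
    n: int = 2_000
    mixture_weights: Tuple[float, ...] = (0.6, 0.3, 0.1)
    p_nontemplate: float = 0.7
    n_samples: int = 1
    n_shared: int = 0  # identical variants planted in every sample
    max_tries: int = 200


@dataclass
class DamidConfig:
    reads_per_sample: int = 1_000_000
    n_fusion: int = 2
    n_dam_only: int = 3
    fold: float = 4.0
    n_enriched_fragments: int = 200
    read_length: int = 50


@dataclass
class ContactConfig:
    n_bins: int = 200
    bin_width: int = 2_000
    decay_exponent: float = 1.0
    scale: float = 100.0
    noise_sigma: float = 0.2  # lognormal sigma
    box_rows: Tuple[int, int] = (40, 50)  # planted box, bin range [lo, hi)
    box_cols: Tuple[int, int] = (120, 130)
    fold: float = 3.0


@dataclass
class SynthConfig:
    """Master configuration bundling every generator's parameters."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    transcription: TranscriptionConfig = field(default_factory=TranscriptionConfig)
    breakpoints: BreakpointConfig = field(default_factory=BreakpointConfig)
    snv: SnvConfig = field(default_factory=SnvConfig)
    damid: DamidConfig = field(default_factory=DamidConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in pattern.upper())


def _place_nonoverlapping(
    occupied: List[Tuple[int, int]],
    length: int,
    chrom_len: int,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> int:
    """Uniform start for a length-bp element avoiding existing placements."""
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start
    raise RuntimeError("could not place element without overlap; genome too crowded")


def generate_genome(
    config: SynthConfig,
) -> Tuple[GenomeSequence, Dict[str, List[GenomicInterval]]]:
    """I.i.d. background genome with planted motifs and G-quadruplexes.

    Returns the genome and a truth table mapping element names
    ("motif:<pattern>", "g4") to their planted coordinates.
    """
    g = config.genome
    rng = _rng(config.seed, "genome")
    p = np.array(
        [(1 - g.gc_fraction) / 2, g.gc_fraction / 2, g.gc_fraction / 2,
         (1 - g.gc_fraction) / 2]
    )
    seqs: Dict[str, str] = {}
    arrays: Dict[str, np.ndarray] = {}
    for i in range(g.n_chroms):
        chrom = f"chr{i + 1}"
        arrays[chrom] = _BASES[rng.choice(4, size=g.chrom_length, p=p)]
    truth: Dict[str, List[GenomicInterval]] = {}
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in arrays}

    def plant(element: str, label: str) -> None:
        chrom = f"chr{int(rng.integers(g.n_chroms)) + 1}"
        start = _place_nonoverlapping(
            occupied[chrom], len(element), g.chrom_length, rng
        )
        arrays[chrom][start:start + len(element)] = np.frombuffer(
            element.encode(), dtype=np.uint8
        )
        truth.setdefault(label, []).append(
            GenomicInterval(chrom, start, start + len(element), "+", label)
        )

    for cluster in g.motif_clusters:
        for _ in range(cluster.count):
            plant(_concrete_motif(cluster.pattern, rng), f"motif:{cluster.pattern}")
    if g.g4s is not None and g.g4s.count:
        plan = g.g4s
        for _ in range(plan.count):
            runs = ["G" * plan.run_length] * plan.n_runs
            loops = [
                "".join(rng.choice(list("ACT"), size=plan.loop_length))
                for _ in range(plan.n_runs - 1)
            ]
            element = runs[0] + "".join(l + r for l, r in zip(loops, runs[1:]))
            plant(element, "g4")
    for chrom, arr in arrays.items():
        seqs[chrom] = arr.tobytes().decode("ascii")
    return GenomeSequence(seqs), truth


def generate_transcription_units(
    config: SynthConfig, genome_or_sizes
) -> List[GenomicInterval]:
    """Non-overlapping stranded gene intervals ("transcription units")."""
    t = config.transcription
    sizes = chrom_sizes(genome_or_sizes)
    rng = _rng(config.seed, "transcription_units")
    chroms = list(sizes)
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    out: List[GenomicInterval] = []
    for i in range(t.n_units):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(t.min_length, t.max_length + 1))
        length = min(length, sizes[chrom])
        start = _place_nonoverlapping(occupied[chrom], length, sizes[chrom], rng)
        strand = "+" if rng.random() < t.p_plus else "-"
        out.append(GenomicInterval(chrom, start, start + length, strand, f"tu{i + 1}"))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def generate_breakpoints(
    config: SynthConfig,
    genome_or_sizes,
    features: Optional[Sequence[GenomicInterval]] = None,
) -> Tuple[List[BreakpointPair], List[float]]:
    """Breakpoint pairs with controllable proximity bias to a feature set.

    In biased mode, breakend A is placed |N(0, sigma)| bp from a random
    feature edge; in null mode it is uniform over the genome. Partner
    breakends are always uniform. Returns the pairs and the truth
    distances of breakend A to its chosen feature edge.
    """
    b = config.breakpoints
    sizes = chrom_sizes(genome_or_sizes)
    rng = _rng(config.seed, "breakpoints")
    if b.biased and not features:
        raise ValueError("biased breakpoint placement needs a feature set")
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    def uniform_pos() -> Tuple[str, int]:
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        return c, int(rng.integers(0, sizes[c]))

    pairs: List[BreakpointPair] = []
    truth: List[float] = []
    for i in range(b.n_pairs):
        if b.biased:
            f = features[int(rng.integers(len(features)))]
            edge = f.start if rng.random() < 0.5 else f.end - 1
            offset = abs(rng.normal(0.0, b.sigma))
            offset = offset if rng.random() < 0.5 else -offset
            pos = int(np.clip(round(edge + offset), 0, sizes[f.chrom] - 1))
            chrom_a = f.chrom
            truth.append(abs(pos - edge))
        else:
            chrom_a, pos = uniform_pos()
            truth.append(float("nan"))
        chrom_b, pos_b = uniform_pos()
        pairs.append(
            BreakpointPair(
                Breakend(chrom_a, pos, LEFT_RETAINED),
                Breakend(chrom_b, pos_b, RIGHT_RETAINED),
                id=f"bp{i + 1}",
            )
        )
    return pairs, truth


def random_catalog(
    n_signatures: int,
    seed: int,
    max_cosine: float = 0.3,
    concentration: float = 0.15,
    max_tries: int = 500,
) -> SignatureCatalog:
    """Random near-orthogonal synthetic signature catalog.

    Sparse Dirichlet profiles are drawn until all pairwise cosine
    similarities fall below ``max_cosine``.
    """
    rng = np.random.default_rng([int(seed) % (2**31), _STREAMS["catalog"]])
    for _ in range(max_tries):
        profiles = rng.dirichlet(np.full(96, concentration), size=n_signatures)
        norms = np.linalg.norm(profiles, axis=1)
        cos = (profiles @ profiles.T) / np.outer(norms, norms)
        np.fill_diagonal(cos, 0.0)
        if cos.max() < max_cosine:
            names = [f"SBS_synth{i + 1}" for i in range(n_signatures)]
            return SignatureCatalog(names, profiles)
    raise RuntimeError("could not draw a catalog with the requested separation")


@dataclass
class SnvTruth:
    """Per-variant ground truth from the signature/strand generator."""

    exposures: np.ndarray
    signature_of: List[int]
    class_of: List[int]
    c_strand_of: List[str]
    nontemplate: List[Optional[bool]]


# byte codes for vectorized context classification
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _context_pools(
    genome: GenomeSequence,
    genes: Optional[Sequence[GenomicInterval]],
) -> Dict[Tuple[int, int, str], Dict[str, np.ndarray]]:
    """Candidate positions per (pyrimidine kind, context16, pool).

    pyrimidine kind: 0 = C-centred classes, 1 = T-centred. Pools are
    "nontemplate"/"template" (position inside genes of exactly one
    strand, classified by the pyrimidine strand) and "outside".
    Positions are encoded as (chrom_index, pos0).
    """
    chroms = list(genome.seq)
    pools: Dict[Tuple[int, int, str], List[np.ndarray]] = {}
    for ci, chrom in enumerate(chroms):
        arr = _CODE[np.frombuffer(genome.seq[chrom].encode(), dtype=np.uint8)]
        L = len(arr)
        if L < 3:
            continue
        b5, b0, b3 = arr[:-2], arr[1:-1], arr[2:]
        valid = (b5 != 255) & (b0 != 255) & (b3 != 255)
        pos = np.arange(1, L - 1)
        # pyrimidine strand: '+' when the central base is C/T
        is_pyr = (b0 == 1) | (b0 == 3)
        kind = np.where((b0 == 1) | (b0 == 2), 0, 1)  # C/G -> 0, T/A -> 1
        ctx_plus = b5.astype(np.int64) * 4 + b3
        ctx_minus = (3 - b3.astype(np.int64)) * 4 + (3 - b5)
        ctx = np.where(is_pyr, ctx_plus, ctx_minus)
        # gene-strand state: 0 none, 1 plus-only, 2 minus-only, 3 both
        state = np.zeros(L, dtype=np.uint8)
        if genes:
            for g in genes:
                if g.chrom != chrom:
                    continue
                state[g.start:g.end] |= 1 if g.strand == "+" else 2
        st = state[1:-1]
        pyr_plus = is_pyr
        for kind_v in (0, 1):
            for ctx_v in range(16):
                sel = valid & (kind == kind_v) & (ctx == ctx_v)
                if not np.any(sel):
                    continue
                base = sel
                nontemp = base & (
                    (pyr_plus & (st == 1)) | (~pyr_plus & (st == 2))
                )
                temp = base & ((pyr_plus & (st == 2)) | (~pyr_plus & (st == 1)))
                outside = base & ~nontemp & ~temp
                for pool_name, mask in (
                    ("nontemplate", nontemp),
                    ("template", temp),
                    ("outside", outside),
                ):
                    idx = pos[mask]
                    if len(idx):
                        key = (kind_v, ctx_v, pool_name)
                        pools.setdefault(key, []).append(
                            np.stack([np.full(len(idx), ci), idx], axis=1)
                        )
    return {
        k: {"pos": np.concatenate(v, axis=0)} for k, v in pools.items()
    }


def generate_snvs_from_signatures(
    config: SynthConfig,
    genome: GenomeSequence,
    catalog: SignatureCatalog,
    genes: Optional[Sequence[GenomicInterval]] = None,
) -> Tuple[Dict[str, List[VariantCall]], SnvTruth]:
    """Somatic SNVs drawn from a signature mixture, with strand bias.

    Each mutation draws a signature by the mixture weights and a
    96-class by that signature's profile, then a genome position whose
    plus-strand trinucleotide matches the class (or its complement).
    Cytidine-class mutations falling in the gene model are placed on the
    non-template strand with probability ``p_nontemplate``. Every
    generated variant's ref matches the genome by construction.
    """
    s = config.snv
    weights = np.asarray(s.mixture_weights, dtype=float)
    if len(weights) != len(catalog.names):
        raise ValueError("mixture weights must match catalog size")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = _rng(config.seed, "snvs")
    chroms = list(genome.seq)
    pools = _context_pools(genome, genes)
    used: set = set()
    per_sample: Dict[str, List[VariantCall]] = {
        f"sample{i + 1}": [] for i in range(s.n_samples)
    }
    truth = SnvTruth(weights, [], [], [], [])

    def draw_position(cls: int, want_pool: Optional[str]) -> Optional[Tuple[str, int]]:
        kind = 0 if cls // 16 < 3 else 1
        ctx = cls % 16
        order = (
            [want_pool, "outside", "nontemplate", "template"]
            if want_pool
            else ["outside", "nontemplate", "template"]
        )
        for pool_name in dict.fromkeys(order):
            entry = pools.get((kind, ctx, pool_name))
            if entry is None:
                continue
            arr = entry["pos"]
            for _ in range(s.max_tries):
                ci, p = arr[int(rng.integers(len(arr)))]
                key = (int(ci), int(p))
                if key not in used:
                    used.add(key)
                    return chroms[int(ci)], int(p)
        return None

    def make_variant(cls: int, chrom: str, pos0: int, sample: str) -> Tuple[VariantCall, str]:
        ref = genome.seq[chrom][pos0]
        sub = SUBSTITUTIONS[cls // 16]  # e.g. "C>T" in pyrimidine frame
        pyr_ref, pyr_alt = sub[0], sub[2]
        if ref == pyr_ref:  # pyrimidine on plus strand
            alt = pyr_alt
            c_strand = "+"
        else:  # complementary purine on plus strand
            alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[pyr_alt]
            c_strand = "-"
        return VariantCall(chrom, pos0 + 1, ref, alt, sample=sample), c_strand

    samples = list(per_sample)
    # shared (germline-like) variants present in every sample
    for _ in range(s.n_shared):
        sig = int(rng.choice(len(weights), p=weights))
        cls = int(rng.choice(96, p=catalog.profiles[sig]))
        found = draw_position(cls, None)
        if found is None:
            raise RuntimeError("no free position matching the drawn context")
        chrom, pos0 = found
        for sample in samples:
            v, _ = make_variant(cls, chrom, pos0, sample)
            per_sample[sample].append(v)
    for i in range(s.n):
        sample = samples[i % len(samples)]
        sig = int(rng.choice(len(weights), p=weights))
        cls = int(rng.choice(96, p=catalog.profiles[sig]))
        is_cytidine = cls // 16 < 3
        want: Optional[str] = None
        nontemplate: Optional[bool] = None
        if is_cytidine and genes:
            nontemplate = bool(rng.random() < s.p_nontemplate)
            want = "nontemplate" if nontemplate else "template"
        found = draw_position(cls, want)
        if found is None:
            raise RuntimeError("no free position matching the drawn context")
        chrom, pos0 = found
        v, c_strand = make_variant(cls, chrom, pos0, sample)
        per_sample[sample].append(v)
        truth.signature_of.append(sig)
        truth.class_of.append(cls)
        truth.c_strand_of.append(c_strand)
        truth.nontemplate.append(nontemplate)
    return per_sample, truth


def generate_damid_reads(
    config: SynthConfig,
    fragment_map: FragmentMap,
    as_arrays: bool = False,
) -> Tuple[Dict[str, object], Dict[str, str], np.ndarray]:
    """Reads over GATC fragments with planted fusion enrichment.

    Dam-only samples draw reads multinomially over fragments
    proportional to length; fusion samples multiply the enriched
    fragments' probabilities by ``fold`` before renormalisation. Read
    positions are uniform within their fragment. Returns (reads per
    sample, sample roles, truth enriched fragment indices). With
    ``as_arrays=True`` reads are {chrom: (starts, ends)} arrays, the
    compact form accepted by count_reads_to_fragments.
    """
    d = config.damid
    rng = _rng(config.seed, "damid")
    frags = fragment_map.flat
    lengths = np.array([len(f) for f in frags], dtype=float)
    base_p = lengths / lengths.sum()
    n_enr = min(d.n_enriched_fragments, len(frags))
    enriched = rng.choice(len(frags), size=n_enr, replace=False)
    fusion_p = base_p.copy()
    fusion_p[enriched] *= d.fold
    fusion_p /= fusion_p.sum()

    roles: Dict[str, str] = {}
    reads: Dict[str, object] = {}
    for kind, n_samples, p in (
        ("fusion", d.n_fusion, fusion_p),
        ("dam_only", d.n_dam_only, base_p),
    ):
        for r in range(n_samples):
            sample = f"{kind}{r + 1}"
            roles[sample] = kind
            counts = rng.multinomial(d.reads_per_sample, p)
            starts_by_chrom: Dict[str, List[np.ndarray]] = {}
            ends_by_chrom: Dict[str, List[np.ndarray]] = {}
            for fi in np.nonzero(counts)[0]:
                f = frags[fi]
                n = counts[fi]
                span = max(1, len(f) - d.read_length)
                starts = f.start + rng.integers(0, span, size=n)
                ends = np.minimum(starts + d.read_length, f.end)
                starts_by_chrom.setdefault(f.chrom, []).append(starts)
                ends_by_chrom.setdefault(f.chrom, []).append(ends)
            arr = {
                chrom: (
                    np.concatenate(starts_by_chrom[chrom]),
                    np.concatenate(ends_by_chrom[chrom]),
                )
                for chrom in starts_by_chrom
            }
            if as_arrays:
                reads[sample] = arr
            else:
                reads[sample] = [
                    GenomicInterval(chrom, int(s0), int(e0))
                    for chrom, (ss, ee) in arr.items()
                    for s0, e0 in zip(ss, ee)
                ]
    return reads, roles, np.sort(enriched)


def generate_contact_matrix(
    config: SynthConfig,
) -> Tuple[ContactMatrix, Tuple[np.ndarray, np.ndarray]]:
    """Distance-decay contact matrix with a planted interaction box.

    M[i,j] = scale * (|i-j|+1)^(-alpha) * lognormal noise, symmetrised;
    entries of the planted box (and its transpose) are multiplied by
    ``fold``. Returns the matrix and the truth (row bins, col bins).
    """
    c = config.contact
    if c.n_bins < 4:
        raise ValueError("need at least 4 bins")
    rng = _rng(config.seed, "contacts")
    idx = np.arange(c.n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    M = c.scale * (dist + 1.0) ** (-c.decay_exponent)
    noise = rng.lognormal(0.0, c.noise_sigma, size=M.shape)
    noise = np.sqrt(noise * noise.T)  # symmetric noise field
    M = M * noise
    rows = np.arange(*c.box_rows)
    cols = np.arange(*c.box_cols)
    M[np.ix_(rows, cols)] *= c.fold
    M[np.ix_(cols, rows)] *= c.fold
    return (
        ContactMatrix("chrS", c.bin_width, M),
        (rows, cols),
    )
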