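"""96-class trinucleotide mutation spectra and non-negative signature
exposure fitting.

Spectra follow the standard pyrimidine-centred convention: substitution
classes C>A, C>G, C>T, T>A, T>C, T>G, each over 16 flanking contexts with
the 5' base cycling slowest, both flanks in A,C,G,T order. Variants with
a purine reference are reverse-complemented into this frame. Exposures
are fitted by non-negative least squares against a signature catalog and
normalised to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls

from .core import (
    GenomeSequence,
    GenomicInterval,
    PreconditionError,
    VariantCall,
    group_by_chrom,
    revcomp,
)

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"

#: the 96 class labels, e.g. "A[C>A]A", in canonical order
CLASS_LABELS: List[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

_CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def class_index(five: str, ref: str, alt: str, three: str) -> int:
    """Index of a substitution in the 96-class order (pyrimidine frame).

    Purine-reference substitutions are complement-mapped, mirroring the
    flanks, before lookup.
    """
    if ref in "AG":
        five, ref, alt, three = _COMP[three], _COMP[ref], _COMP[alt], _COMP[five]
    return _CLASS_INDEX[f"{five}[{ref}>{alt}]{three}"]


@dataclass
class TrinucSpectrum:
    """96-class mutation counts plus bookkeeping of skipped variants."""

    counts: np.ndarray
    n_used: int
    n_skipped: int
    errors: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 classes")
        if abs(self.counts.sum() - self.n_used) > 1e-6:
            raise ValueError("sum of counts must equal n_used")

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise PreconditionError("empty spectrum")
        return self.counts / total


@dataclass
class SignatureCatalog:
    """Named signature profiles; each row is a distribution over 96 classes."""

    names: List[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape != (len(self.names), 96):
            raise ValueError("profiles must be n_signatures x 96")
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature rows must sum to 1")

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        """Read a catalog TSV: first column class label, one column per
        signature; rows may come in any class order."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CLASS_LABELS) - set(df.index)
        if missing:
            raise PreconditionError(f"catalog missing {len(missing)} classes")
        df = df.loc[CLASS_LABELS]
        return cls(list(df.columns), df.to_numpy().T)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.profiles.T, index=CLASS_LABELS, columns=self.names
        ).rename_axis("class").to_csv(path, sep="\t")


def trinucleotide_spectrum(
    variants: Iterable[VariantCall],
    genome: GenomeSequence,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> TrinucSpectrum:
    """Build a 96-class spectrum, optionally restricted to a region set.

    Variants outside the regions, at chromosome edges (no flank), or
    with N in their context are skipped and counted; variants whose ref
    disagrees with the genome are skipped and reported in ``errors``.
    """
    region_idx: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None
    if regions is not None:
        region_idx = {}
        for chrom, ivs in group_by_chrom(regions).items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            region_idx[chrom] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
            )
    counts = np.zeros(96)
    n_used = n_skipped = 0
    errors: List[str] = []
    for v in variants:
        if v.chrom not in genome.seq:
            n_skipped += 1
            continue
        if region_idx is not None:
            entry = region_idx.get(v.chrom)
            if entry is None:
                n_skipped += 1
                continue
            starts, ends = entry
            if not np.any((starts <= v.pos0) & (v.pos0 < ends)):
                n_skipped += 1
                continue
        s = genome.seq[v.chrom]
        p = v.pos0
        if p - 1 < 0 or p + 1 >= len(s):
            n_skipped += 1
            continue
        tri = s[p - 1: p + 2]
        if "N" in tri:
            n_skipped += 1
            continue
        if tri[1] != v.ref:
            errors.append(
                f"{v.chrom}:{v.pos1} ref {v.ref} != genome {tri[1]}"
            )
            n_skipped += 1
            continue
        counts[class_index(tri[0], v.ref, v.alt, tri[2])] += 1
        n_used += 1
    return TrinucSpectrum(counts, n_used, n_skipped, errors)


@dataclass
class ExposureFit:
    names: List[str]
    weights: np.ndarray
    residual_norm: float
    n_mutations: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("exposure weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("exposure weights must sum to 1")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.weights))


def fit_signature_exposures(
    spectrum: TrinucSpectrum, catalog: SignatureCatalog
) -> ExposureFit:
    """Non-negative least-squares fit of a spectrum to a catalog.

    Solves min ||c/sum(c) - w.P||_2 with w >= 0, then normalises w to
    sum to 1; the reported residual is the minimised norm.
    """
    target = spectrum.normalized()
    w, resid = nnls(catalog.profiles.T, target)
    total = w.sum()
    if total <= 0:
        # NNLS can return all-zero only if the target is orthogonal to
        # every signature; fall back to uniform weights and report the
        # full residual.
        w = np.full(len(catalog.names), 1.0 / len(catalog.names))
        resid = float(np.linalg.norm(target))
    else:
        w = w / total
    return ExposureFit(list(catalog.names), w, float(resid), spectrum.n_used)
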