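"""Single-chromosome contact-matrix balancing and interval-pair ("box")
quantification.

Balancing uses iterative proportional fitting in its symmetric form:
rows and columns are rescaled together by the square root of the
marginal correction, so the matrix stays symmetric at every step and the
result equals F.M.F for a diagonal factor vector F. Bins with zero
marginal are masked before balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, PreconditionError
from .stats import TestResult, wilcoxon_rank_sum


class ConvergenceError(RuntimeError):
    """Balancing failed to reach tolerance; carries the last deviation."""

    def __init__(self, deviation: float, max_iter: int) -> None:
        super().__init__(
            f"IPF did not converge within {max_iter} iterations "
            f"(last relative marginal deviation {deviation:.3g})"
        )
        self.deviation = deviation


@dataclass
class ContactMatrix:
    """Dense symmetric contact matrix for one chromosome."""

    chrom: str
    bin_width: int
    M: np.ndarray
    origin: int = 0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = self.M.shape[0]
        if self.M.ndim != 2 or self.M.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if np.any(self.M < 0):
            raise ValueError("contact matrix must be non-negative")
        if not np.allclose(self.M, self.M.T, rtol=1e-9, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        self.M = 0.5 * (self.M + self.M.T)  # remove last-ulp asymmetry
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        # masked rows/cols are kept all-zero
        self.M[self.mask, :] = 0.0
        self.M[:, self.mask] = 0.0

    @property
    def n_bins(self) -> int:
        return self.M.shape[0]

    def bin_of(self, pos: int) -> int:
        return (pos - self.origin) // self.bin_width

    def bins_overlapping(self, interval: GenomicInterval) -> np.ndarray:
        if interval.chrom != self.chrom:
            raise PreconditionError(
                f"interval on {interval.chrom!r}, matrix on {self.chrom!r}"
            )
        b0 = max(0, (interval.start - self.origin) // self.bin_width)
        b1 = min(self.n_bins, -(-(interval.end - self.origin) // self.bin_width))
        if b0 >= b1:
            raise PreconditionError("interval outside the matrix grid")
        return np.arange(b0, b1)


def ipf_balance(
    matrix: ContactMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> Tuple[ContactMatrix, np.ndarray]:
    """Balance a contact matrix so all unmasked marginals are equal.

    The marginal target is the mean unmasked marginal of the input (not
    1), keeping values on the raw scale. Returns the balanced matrix and
    the per-bin factor vector F with balanced = F.M.F (masked bins get
    factor 0).
    """
    M = matrix.M.copy()
    mask = matrix.mask | (M.sum(axis=1) == 0)
    M[mask, :] = 0.0
    M[:, mask] = 0.0
    free = ~mask
    if not np.any(free):
        raise PreconditionError("all bins masked; nothing to balance")
    target = M[free].sum() / free.sum()
    factors = np.zeros(matrix.n_bins)
    factors[free] = 1.0
    deviation = np.inf
    for _ in range(max_iter):
        marg = M.sum(axis=1)
        deviation = float(np.max(np.abs(marg[free] / target - 1.0)))
        if deviation < tol:
            balanced = ContactMatrix(
                matrix.chrom, matrix.bin_width, M, matrix.origin, mask
            )
            return balanced, factors
        d = np.zeros_like(factors)
        d[free] = np.sqrt(target / marg[free])
        M = M * d[:, None] * d[None, :]
        factors *= d
    raise ConvergenceError(deviation, max_iter)


def sum_replicates(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Elementwise sum of replicate matrices on the same grid; masks unite.

    Summation precedes balancing in the analysis recipe.
    """
    if not matrices:
        raise PreconditionError("need at least one matrix")
    first = matrices[0]
    M = first.M.copy()
    mask = first.mask.copy()
    for m in matrices[1:]:
        if (
            m.chrom != first.chrom
            or m.bin_width != first.bin_width
            or m.origin != first.origin
            or m.n_bins != first.n_bins
        ):
            raise PreconditionError("replicate matrices must share the bin grid")
        M += m.M
        mask |= m.mask
    return ContactMatrix(first.chrom, first.bin_width, M, first.origin, mask)


@dataclass
class BoxSignal:
    """Normalized entries linking two intervals of the same chromosome."""

    row_interval: GenomicInterval
    col_interval: GenomicInterval
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def box_signal(
    balanced: ContactMatrix,
    row_interval: GenomicInterval,
    col_interval: GenomicInterval,
) -> BoxSignal:
    """All unmasked entries (i, j) with bin i over ``row_interval`` and
    bin j over ``col_interval``."""
    rows = balanced.bins_overlapping(row_interval)
    cols = balanced.bins_overlapping(col_interval)
    rows = rows[~balanced.mask[rows]]
    cols = cols[~balanced.mask[cols]]
    if len(rows) == 0 or len(cols) == 0:
        raise PreconditionError("box is empty after masking")
    values = balanced.M[np.ix_(rows, cols)].ravel()
    return BoxSignal(row_interval, col_interval, values)


def compare_box_signals(
    boxes_by_group: Mapping[str, Sequence[BoxSignal]],
) -> List[Tuple[str, str, TestResult]]:
    """Two-sided Wilcoxon rank-sum on pooled box entries, all group pairs."""
    if len(boxes_by_group) < 2:
        raise PreconditionError("need at least two groups")
    pooled: Dict[str, np.ndarray] = {}
    for name, boxes in boxes_by_group.items():
        if not boxes:
            raise PreconditionError(f"group {name!r} is empty")
        pooled[name] = np.concatenate([b.values for b in boxes])
    return [
        (g1, g2, wilcoxon_rank_sum(pooled[g1], pooled[g2], "two"))
        for g1, g2 in combinations(pooled, 2)
    ]
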