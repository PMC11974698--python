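"""Population-genetic summary statistics of a haplotype matrix.

These are the quantities the shuffle levels are designed to target:
the allele frequency spectrum (AFS), nucleotide diversity pi, segregating
site count S, the singleton fraction, Garud's H1 haplotype homozygosity,
and linkage disequilibrium summarized as pairwise r-squared (its multiset /
mean for "long-scale" LD, and its rank correlation with inter-site distance
for "short-scale" LD decay). They double as verification oracles for the
shuffles and as features for statistic-threshold stand-in classifiers.

All statistics are computed over the non-padding columns only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .matrix import HaplotypeMatrix, require_valid

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStatistics",
    "afs",
    "pairwise_pi",
    "garud_h1",
    "seg_sites",
    "singleton_fraction",
    "ld_r2",
    "mean_r2",
    "r2_distance_corr",
    "summarize",
]


@dataclass
class SummaryStatistics:
    """Bundle of all summary statistics for one matrix.

    ``afs`` holds counts of sites with derived-allele count k for
    k = 1..n_hap-1 (index 0 is the singleton class); monomorphic-ancestral
    and fixed-derived columns are tallied separately. ``r2_distance_corr``
    is ``None`` when positions are absent or fewer than three polymorphic
    sites exist; ``mean_r2`` is NaN with fewer than two polymorphic sites.
    """

    afs: np.ndarray
    n_monomorphic_zero: int
    n_fixed_derived: int
    pi: float
    seg_sites: int
    total_derived: int
    singleton_fraction: float
    h1: float
    mean_r2: float
    r2_distance_corr: Optional[float] = None

    FIELDS = (
        "pi",
        "seg_sites",
        "total_derived",
        "singleton_fraction",
        "h1",
        "mean_r2",
        "r2_distance_corr",
    )


def _counts(m: HaplotypeMatrix) -> np.ndarray:
    """Derived-allele count per non-padding column."""
    return m.data_region().sum(axis=0)


def afs(m: HaplotypeMatrix) -> tuple[np.ndarray, int, int]:
    """Unfolded allele frequency spectrum over the non-padding columns.

    Returns ``(counts, n_monomorphic_zero, n_fixed_derived)`` where
    ``counts[k-1]`` is the number of sites with derived-allele count k,
    k = 1..n_hap-1. Columns with no derived allele or fixed for the
    derived allele are reported apart from the polymorphic classes.
    """
    require_valid(m, check_positions=False)
    d = _counts(m)
    n = m.n_hap
    counts = np.bincount(d, minlength=n + 1)
    return counts[1:n].copy(), int(counts[0]), int(counts[n])


def pairwise_pi(m: HaplotypeMatrix) -> float:
    """Nucleotide diversity pi: mean pairwise difference between haplotypes.

    Closed form over columns: pi = sum_j d_j (n - d_j) / C(n, 2), with
    d_j the derived count at site j and n the number of haplotypes.
    Fixed-derived columns contribute 0; padding is excluded.
    """
    require_valid(m, check_positions=False)
    d = _counts(m).astype(np.int64)
    n = m.n_hap
    return float(np.sum(d * (n - d)) / (n * (n - 1) // 2))


def garud_h1(m: HaplotypeMatrix) -> float:
    """Garud's H1 haplotype homozygosity: sum of squared haplotype-class
    frequencies, high when one haplotype dominates (as after a sweep)."""
    require_valid(m, check_positions=False)
    region = np.ascontiguousarray(m.data_region())
    _, counts = np.unique(region, axis=0, return_counts=True)
    # integer sum of squared class counts: exact and independent of the
    # (column-order-dependent) order in which classes are enumerated
    n = m.n_hap
    return float(np.sum(counts.astype(np.int64) ** 2) / (n * n))


def seg_sites(m: HaplotypeMatrix) -> int:
    """Number of polymorphic (segregating) non-padding columns."""
    require_valid(m, check_positions=False)
    d = _counts(m)
    return int(np.sum((d > 0) & (d < m.n_hap)))


def singleton_fraction(m: HaplotypeMatrix) -> float:
    """Fraction of polymorphic sites carrying exactly one derived allele
    (0.0 when there are no polymorphic sites)."""
    require_valid(m, check_positions=False)
    d = _counts(m)
    s = np.sum((d > 0) & (d < m.n_hap))
    if s == 0:
        return 0.0
    return float(np.sum(d == 1) / s)


def _polymorphic_region(m: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    region = m.data_region()
    d = region.sum(axis=0)
    poly = np.nonzero((d > 0) & (d < m.n_hap))[0]
    return region[:, poly], poly


def ld_r2(m: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise r-squared over polymorphic non-padding columns.

    r^2(j,k) = (P11 - p_j p_k)^2 / (p_j (1-p_j) p_k (1-p_k)) with
    haplotype frequencies, equivalently the squared Pearson correlation of
    the two 0/1 columns. Returns ``(r2, poly)``: a symmetric matrix with
    unit diagonal over the polymorphic columns, and their column indices.
    With fewer than two polymorphic columns the matrix is empty.
    """
    require_valid(m, check_positions=False)
    sub, poly = _polymorphic_region(m)
    if len(poly) < 2:
        logger.info("ld_r2: fewer than 2 polymorphic columns")
        return np.zeros((len(poly), len(poly))), poly
    x = sub.astype(float)
    n = x.shape[0]
    p = x.mean(axis=0)
    p11 = (x.T @ x) / n
    d = p11 - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    r2 = (d * d) / denom
    np.fill_diagonal(r2, 1.0)
    return r2, poly


def mean_r2(m: HaplotypeMatrix) -> float:
    """Mean off-diagonal pairwise r-squared (NaN with < 2 polymorphic
    sites)."""
    r2, poly = ld_r2(m)
    k = len(poly)
    if k < 2:
        return float("nan")
    iu = np.triu_indices(k, 1)
    return float(r2[iu].mean())


def r2_distance_corr(m: HaplotypeMatrix) -> float:
    """Spearman rank correlation between inter-site distance and r-squared.

    Computed over all pairs of polymorphic columns, with average-rank tie
    handling; when either variable is completely tied (e.g. all r-squared
    equal) the correlation is 0 by convention. Requires positions and at
    least three polymorphic sites.
    """
    require_valid(m)
    if m.positions is None:
        raise ValueError("r2_distance_corr requires genomic positions")
    r2, poly = ld_r2(m)
    if len(poly) < 3:
        raise ValueError(
            "r2_distance_corr requires >= 3 polymorphic columns, "
            f"got {len(poly)}"
        )
    pos = m.positions[poly]
    iu = np.triu_indices(len(poly), 1)
    dist = np.abs(pos[iu[0]] - pos[iu[1]])
    vals = r2[iu]
    if np.all(vals == vals[0]) or np.all(dist == dist[0]):
        return 0.0
    rho = sps.spearmanr(dist, vals).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def summarize(m: HaplotypeMatrix) -> SummaryStatistics:
    """Compute all summary statistics for one matrix.

    ``r2_distance_corr`` is included only when positions are present and
    at least three polymorphic sites exist.
    """
    spectrum, n_zero, n_fixed = afs(m)
    s = seg_sites(m)
    rdc: Optional[float] = None
    if m.positions is not None and s >= 3:
        rdc = r2_distance_corr(m)
    return SummaryStatistics(
        afs=spectrum,
        n_monomorphic_zero=n_zero,
        n_fixed_derived=n_fixed,
        pi=pairwise_pi(m),
        seg_sites=s,
        total_derived=m.total_derived(),
        singleton_fraction=singleton_fraction(m),
        h1=garud_h1(m),
        mean_r2=mean_r2(m),
        r2_distance_corr=rdc,
    )
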