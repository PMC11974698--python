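"""The five haplotype-matrix disruption operations.

Each operation destroys one more class of population-genetic structure
while preserving the rest, so that a predictor's performance drop at each
level reveals which data features it exploits:

========================  ====================================================
level                     destroys (on top of previous levels)
========================  ====================================================
COLUMNS                   relation between genomic position and genotype
                          (short-scale LD); preserves AFS, pi, S, H1 and the
                          multiset of pairwise r-squared values
WITHIN_COLUMNS            haplotype identity, hence H1 and all LD; preserves
                          per-column allele counts (AFS, pi, S, singletons)
ALL_PIXELS                the allele frequency spectrum; preserves only the
                          total derived-allele count
BLOCK_KEEP_PADDING        all per-site structure, packing derived alleles
                          into one solid block anchored at the apparent
                          data/padding boundary, which it preserves
BLOCK_BREAK_PADDING       additionally the zero-padding boundary itself
========================  ====================================================

Randomized levels take an integer seed and are bit-reproducible; the block
groupings are deterministic. Padding columns never participate in the
randomized shuffles, and the genomic positions vector is never touched by
any level.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .matrix import (
    HaplotypeMatrix,
    ShuffleLevel,
    last_informative_column,
    require_valid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "shuffle_columns",
    "shuffle_within_columns",
    "shuffle_all",
    "block_group_keep_padding",
    "block_group_break_padding",
    "apply_level",
    "battery",
    "derive_seed",
]


def _check_nonempty(m: HaplotypeMatrix) -> bool:
    if m.data_width == 0:
        logger.warning("shuffle on all-padding matrix: identity returned")
        return False
    return True


def shuffle_columns(m: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Permute the non-padding columns uniformly at random.

    Column contents travel whole, so every per-column and per-row quantity
    (AFS, pi, segregating sites, H1, the r-squared multiset) is preserved;
    only the association between column content and genomic position is
    destroyed. Positions and padding are unchanged.
    """
    require_valid(m)
    out = m.copy()
    if not _check_nonempty(m):
        return out
    w = m.data_width
    perm = np.random.default_rng(seed).permutation(w)
    out.alleles[:, :w] = m.alleles[:, perm]
    return out


def shuffle_within_columns(m: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Shuffle columns, then independently permute entries within each column.

    The composite destroys haplotype identity (hence H1) and all linkage
    between sites, while preserving each column's derived-allele count —
    so the AFS, pi, S and the singleton fraction survive exactly.
    """
    require_valid(m)
    out = m.copy()
    if not _check_nonempty(m):
        return out
    w = m.data_width
    rng = np.random.default_rng(seed)
    region = m.alleles[:, rng.permutation(w)]
    # one independent uniform permutation per column, via per-column ranks
    # of iid uniform keys
    order = np.argsort(rng.random((m.n_hap, w)), axis=0)
    out.alleles[:, :w] = np.take_along_axis(region, order, axis=0)
    return out


def shuffle_all(m: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Uniformly permute every entry of the non-padding region.

    Scatters derived alleles over all data cells, destroying the allele
    frequency spectrum; only the total derived count survives. Padding is
    untouched.
    """
    require_valid(m)
    out = m.copy()
    if not _check_nonempty(m):
        return out
    w = m.data_width
    flat = m.alleles[:, :w].ravel()
    perm = np.random.default_rng(seed).permutation(flat.size)
    out.alleles[:, :w] = flat[perm].reshape(m.n_hap, w)
    return out


def _packed(m: HaplotypeMatrix, anchor: int, direction: int) -> np.ndarray:
    """All-zero alleles array with T derived alleles packed as a block.

    Columns fill starting at ``anchor`` moving by ``direction`` (+1 right,
    -1 left), top-to-bottom within each column.
    """
    n = m.n_hap
    t = m.total_derived()
    alleles = np.zeros_like(m.alleles)
    col = anchor
    while t > 0:
        fill = min(t, n)
        alleles[:fill, col] = 1
        t -= fill
        col += direction
    return alleles


def block_group_keep_padding(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Pack all derived alleles into one solid block, keeping the boundary.

    Deterministic: the T derived alleles of the data region are packed
    column-by-column right-to-left, anchored at the last informative
    column, filling top-to-bottom within each column. The total derived
    count, the data width, the padding and (for T > 0) the apparent
    data/padding boundary (:func:`last_informative_column`) are all
    preserved; every per-site pattern is destroyed.
    """
    require_valid(m)
    out = m.copy()
    lic = last_informative_column(m)
    if lic is None:
        return out
    out.alleles = _packed(m, lic, -1)
    return out


def block_group_break_padding(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Pack all derived alleles from the left edge over the full width.

    Deterministic: the T derived alleles are packed column-by-column
    left-to-right starting at column 0, over data and padding columns
    alike, top-to-bottom within each column. Only the total derived count
    survives; the zero-padding boundary no longer exists, so the output
    carries ``padding_width = 0`` (the positions vector is still carried
    through untouched, per the rule that no shuffle modifies it).
    """
    require_valid(m)
    out = m.copy()
    out.padding_width = 0
    if m.total_derived() == 0:
        return out
    out.alleles = _packed(m, 0, +1)
    return out


def apply_level(
    m: HaplotypeMatrix, level: ShuffleLevel, seed: int = 0
) -> HaplotypeMatrix:
    """Dispatch to the operation for ``level`` (seed ignored where
    the level is deterministic)."""
    level = ShuffleLevel(level)
    if level is ShuffleLevel.IDENTITY:
        require_valid(m)
        return m.copy()
    if level is ShuffleLevel.COLUMNS:
        return shuffle_columns(m, seed)
    if level is ShuffleLevel.WITHIN_COLUMNS:
        return shuffle_within_columns(m, seed)
    if level is ShuffleLevel.ALL_PIXELS:
        return shuffle_all(m, seed)
    if level is ShuffleLevel.BLOCK_KEEP_PADDING:
        return block_group_keep_padding(m)
    if level is ShuffleLevel.BLOCK_BREAK_PADDING:
        return block_group_break_padding(m)
    raise ValueError(f"unknown shuffle level {level!r}")


def derive_seed(master_seed: int, index: int, level: ShuffleLevel) -> int:
    """Per-(matrix, level) seed from a master seed.

    Counter-based derivation through :class:`numpy.random.SeedSequence`
    keyed on ``(master_seed, index, level)``: the seed for one matrix at
    one level never depends on which other matrices or levels are being
    shuffled in the same run.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index), int(level)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def battery(
    dataset: Sequence[HaplotypeMatrix],
    levels: Iterable[ShuffleLevel],
    master_seed: int,
) -> dict[ShuffleLevel, list[HaplotypeMatrix]]:
    """Apply each requested level to every matrix of a dataset.

    Per-matrix seeds derive deterministically from
    ``(master_seed, matrix index, level)``, so identical calls reproduce
    bit-exactly and each level's randomness is independent of the set of
    other levels requested. The input dataset is never modified.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("battery requires a non-empty dataset")
    levels = [ShuffleLevel(l) for l in levels]
    result: dict[ShuffleLevel, list[HaplotypeMatrix]] = {}
    for level in levels:
        result[level] = [
            apply_level(m, level, derive_seed(master_seed, i, level))
            for i, m in enumerate(dataset)
        ]
    return result
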