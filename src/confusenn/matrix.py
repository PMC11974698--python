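"""Haplotype-matrix data model.

Population-genetic CNNs consume genetic variation data as a binary "image":
one row per sampled haplotype, one column per segregating site, entries
0 (ancestral) / 1 (derived), with columns ordered by genomic position.
Variable-width inputs are typically right-padded with all-zero columns to a
fixed image width; the padding boundary itself encodes the number of
segregating sites in the window.

This module defines :class:`HaplotypeMatrix`, the :class:`ShuffleLevel`
enumeration of disruption depths, and the structural queries every other
module builds on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "ShuffleLevel",
    "ValidationResult",
    "InvalidMatrixError",
    "validate",
    "require_valid",
    "data_width",
    "last_informative_column",
]


class ShuffleLevel(enum.IntEnum):
    """The six disruption levels, ordered by disruption depth.

    IDENTITY leaves the matrix untouched. COLUMNS permutes whole columns
    (destroys the relation between position and genotype, i.e. short-scale
    LD). WITHIN_COLUMNS additionally permutes entries within each column
    (destroys haplotype identity and all LD). ALL_PIXELS permutes every
    entry of the data region (destroys the allele frequency spectrum).
    BLOCK_KEEP_PADDING packs all derived alleles into one solid block while
    preserving the zero-padding boundary; BLOCK_BREAK_PADDING packs them
    from the left edge across the full width, destroying the boundary too.
    """

    IDENTITY = 0
    COLUMNS = 1
    WITHIN_COLUMNS = 2
    ALL_PIXELS = 3
    BLOCK_KEEP_PADDING = 4
    BLOCK_BREAK_PADDING = 5

    @classmethod
    def from_token(cls, token: str) -> "ShuffleLevel":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown shuffle level {token!r}; expected one of "
                + ", ".join(l.name for l in cls)
            ) from None


@dataclass(eq=False)
class HaplotypeMatrix:
    """A binary haplotype-by-site matrix with optional trailing zero-padding.

    Parameters
    ----------
    alleles
        ``(n_hap, n_col)`` array of 0/1 allele states
        (0 = ancestral, 1 = derived). Stored as ``int8``.
    padding_width
        Number of trailing all-zero columns that are zero-padding rather
        than data. Padding shares the ancestral value 0, so it is
        distinguishable from data only through this metadata field —
        exactly what a padding-blind consumer (a CNN) sees.
    positions
        Optional monotone non-decreasing genomic coordinates for the
        ``n_col - padding_width`` data columns (base pairs, or scaled
        [0, 1) as in coalescent-simulator output). Positions are metadata:
        no operation in this package ever reorders or rewrites them.
    """

    alleles: np.ndarray
    padding_width: int = 0
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D array")
        self.padding_width = int(self.padding_width)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)

    # -- structural properties -------------------------------------------

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_col(self) -> int:
        return self.alleles.shape[1]

    @property
    def data_width(self) -> int:
        """Number of non-padding columns."""
        return self.n_col - self.padding_width

    def data_region(self) -> np.ndarray:
        """View of the non-padding columns."""
        return self.alleles[:, : self.data_width]

    def total_derived(self) -> int:
        """Total count of derived alleles in the data region."""
        return int(self.data_region().sum())

    def copy(self) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles.copy(),
            self.padding_width,
            None if self.positions is None else self.positions.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        if self.alleles.shape != other.alleles.shape:
            return False
        if not np.array_equal(self.alleles, other.alleles):
            return False
        if self.padding_width != other.padding_width:
            return False
        if (self.positions is None) != (other.positions is None):
            return False
        if self.positions is not None:
            return np.array_equal(self.positions, other.positions)
        return True


@dataclass
class ValidationResult:
    """Verdict of :func:`validate`: ``ok`` or a list of violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


class InvalidMatrixError(ValueError):
    """Raised when an operation receives a structurally invalid matrix."""

    def __init__(self, result: ValidationResult):
        self.result = result
        super().__init__("invalid haplotype matrix: " + "; ".join(result.violations))


def validate(m: HaplotypeMatrix, check_positions: bool = True) -> ValidationResult:
    """Check every structural invariant of a :class:`HaplotypeMatrix`.

    Returns an ``ok`` verdict iff all invariants hold; otherwise each
    violated invariant is reported with the offending row/column indices.

    ``check_positions=False`` skips the positions-length/-sortedness
    invariants: the boundary-breaking shuffle legitimately produces
    matrices whose (untouched) positions vector no longer matches the
    collapsed padding metadata, and consumers that never read positions
    may accept such matrices.
    """
    v: list[str] = []
    if m.n_hap < 2:
        v.append(f"n_hap must be >= 2, got {m.n_hap}")
    if m.n_col < 1:
        v.append(f"n_col must be >= 1, got {m.n_col}")
    if m.padding_width < 0:
        v.append(f"padding_width must be >= 0, got {m.padding_width}")
    if m.padding_width > m.n_col:
        v.append(
            f"padding_width {m.padding_width} exceeds n_col {m.n_col}"
        )
    bad = np.argwhere((m.alleles != 0) & (m.alleles != 1))
    for r, c in bad[:20]:
        v.append(f"non-binary entry at ({r}, {c})")
    if len(bad) > 20:
        v.append(f"... and {len(bad) - 20} more non-binary entries")
    if 0 < m.padding_width <= m.n_col:
        pad = m.alleles[:, m.n_col - m.padding_width:]
        bad_cols = np.nonzero(pad.any(axis=0))[0]
        for c in bad_cols:
            v.append(
                f"padding column {m.n_col - m.padding_width + c} "
                "contains a derived allele"
            )
    if check_positions and m.positions is not None:
        expected = max(m.n_col - max(m.padding_width, 0), 0)
        if len(m.positions) != expected:
            v.append(
                f"positions length {len(m.positions)} != "
                f"n_col - padding_width = {expected}"
            )
        if len(m.positions) > 1 and np.any(np.diff(m.positions) < 0):
            i = int(np.nonzero(np.diff(m.positions) < 0)[0][0])
            v.append(f"positions not sorted: decrease at index {i}")
    return ValidationResult(v)


def require_valid(m: HaplotypeMatrix, check_positions: bool = True) -> None:
    """Raise :class:`InvalidMatrixError` unless ``m`` is valid."""
    result = validate(m, check_positions=check_positions)
    if not result.ok:
        raise InvalidMatrixError(result)


def data_width(m: HaplotypeMatrix) -> int:
    """Number of non-padding columns (``n_col - padding_width``)."""
    require_valid(m)
    return m.data_width


def last_informative_column(m: HaplotypeMatrix) -> Optional[int]:
    """Largest column index holding at least one derived allele.

    This is the "apparent width" a padding-blind consumer perceives: the
    rightmost column distinguishable from the zero-padded region. Returns
    ``None`` for an all-zero matrix.
    """
    any_derived = m.alleles.any(axis=0)
    idx = np.nonzero(any_derived)[0]
    if len(idx) == 0:
        return None
    return int(idx[-1])
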