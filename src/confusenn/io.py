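"""Reading and writing haplotype matrices.

Three input routes are supported:

* ms-style coalescent simulator text (``//`` replicate blocks with
  ``segsites:`` and ``positions:`` lines followed by 0/1 haplotype rows);
* VCF with phased genotypes (biallelic SNP records; via pysam);
* a plain-text matrix archive defined by this package, which round-trips
  a :class:`~confusenn.matrix.HaplotypeMatrix` bit-exactly.

Plus :func:`pad_to_width`, which appends the all-zero padding columns used
to bring variable-width matrices to a fixed image width.
"""

from __future__ import annotations

import io as _io
import logging
import os
from typing import IO, Iterator, Optional, Sequence, Union

import numpy as np

from .matrix import HaplotypeMatrix, require_valid

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_ms",
    "read_vcf",
    "read_archive",
    "write_archive",
    "pad_to_width",
]

ARCHIVE_MAGIC = "#confusenn v1"


class ParseError(ValueError):
    """Malformed input file or stream."""


# ---------------------------------------------------------------------------
# ms-style simulator output
# ---------------------------------------------------------------------------

def read_ms(stream: Union[str, IO[str]]) -> list[HaplotypeMatrix]:
    """Parse ms-style simulator output into one matrix per replicate.

    Replicates are delimited by ``//``; each carries ``segsites: <k>``, a
    ``positions:`` line with ``k`` floats in [0, 1), and one 0/1 string per
    haplotype. Matrices are returned with ``padding_width`` 0. A replicate
    with ``segsites: 0`` yields a zero-width matrix which fails validation;
    callers decide how to handle such empty windows.
    """
    if isinstance(stream, str):
        if "\n" not in stream and os.path.exists(stream):
            with open(stream) as fh:
                return read_ms(fh)
        stream = _io.StringIO(stream)
    lines = stream.read().splitlines()

    matrices: list[HaplotypeMatrix] = []
    i = 0
    rep = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        rep += 1
        i += 1
        # segsites line
        while i < len(lines) and not lines[i].startswith("segsites:"):
            if lines[i].strip() == "//":
                raise ParseError(f"replicate {rep}: missing 'segsites:' line")
            i += 1
        if i >= len(lines):
            raise ParseError(f"replicate {rep}: missing 'segsites:' line")
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except (IndexError, ValueError):
            raise ParseError(
                f"replicate {rep}: malformed segsites line {lines[i]!r}"
            ) from None
        i += 1
        positions: Optional[np.ndarray] = None
        rows: list[np.ndarray] = []
        if segsites > 0:
            while i < len(lines) and not lines[i].startswith("positions:"):
                if lines[i].strip() in ("//", ""):
                    raise ParseError(f"replicate {rep}: missing 'positions:' line")
                i += 1
            if i >= len(lines):
                raise ParseError(f"replicate {rep}: missing 'positions:' line")
            try:
                positions = np.array(
                    [float(x) for x in lines[i].split(":", 1)[1].split()]
                )
            except ValueError:
                raise ParseError(
                    f"replicate {rep}: malformed positions line"
                ) from None
            if len(positions) != segsites:
                raise ParseError(
                    f"replicate {rep}: {len(positions)} positions for "
                    f"{segsites} segsites"
                )
            i += 1
            while i < len(lines) and lines[i].strip() not in ("", "//"):
                row = lines[i].strip()
                if len(row) != segsites:
                    raise ParseError(
                        f"replicate {rep}, line {i + 1}: row length "
                        f"{len(row)} != segsites {segsites}"
                    )
                if set(row) - {"0", "1"}:
                    raise ParseError(
                        f"replicate {rep}, line {i + 1}: non-0/1 character "
                        f"in haplotype row {row!r}"
                    )
                rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
                i += 1
        if segsites == 0:
            alleles = np.zeros((0, 0), dtype=np.int8)
        else:
            alleles = np.array(rows, dtype=np.int8)
        matrices.append(HaplotypeMatrix(alleles, 0, positions))
    return matrices


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    samples: Optional[Sequence[str]] = None,
    allow_unphased: bool = False,
    polarization: str = "as-given",
) -> HaplotypeMatrix:
    """Build a haplotype matrix from phased genotypes in a VCF.

    Each diploid sample contributes two rows (haploid samples one); columns
    are the biallelic SNP records in POS order, with ``positions`` set to
    the 1-based POS values verbatim. Non-biallelic or non-SNP records are
    skipped and counted in a log message. Unphased genotypes (``/``
    separator) and missing alleles are ingestion errors unless
    ``allow_unphased`` is set (which treats ``/`` as ``|`` at the user's
    own risk).

    ``polarization`` controls the 0/1 encoding: ``"as-given"`` (default)
    keeps REF=0/ALT=1 as polarized in the file; ``"minor"`` folds each
    column so 1 marks the minor allele.
    """
    import pysam

    if polarization not in ("as-given", "minor"):
        raise ValueError(f"unknown polarization {polarization!r}")
    columns: list[np.ndarray] = []
    positions: list[float] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        if samples is not None:
            missing = set(samples) - set(vf.header.samples)
            if missing:
                raise ParseError(f"samples not in VCF: {sorted(missing)}")
            use = list(samples)
        else:
            use = list(vf.header.samples)
        if not use:
            raise ParseError("VCF has no samples")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped += 1
                continue
            col: list[int] = []
            for s in use:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    raise ParseError(
                        f"missing allele in GT for sample {s} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                if len(gt) > 1 and not call.phased and not allow_unphased:
                    raise ParseError(
                        f"unphased genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}; pass allow_unphased=True "
                        "to treat '/' as '|'"
                    )
                col.extend(int(a) for a in gt)
            columns.append(np.array(col, dtype=np.int8))
            positions.append(float(rec.pos))
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not columns:
        raise ParseError("no biallelic SNP records found in VCF")
    order = np.argsort(positions, kind="stable")
    alleles = np.column_stack([columns[j] for j in order])
    pos = np.array([positions[j] for j in order])
    if polarization == "minor":
        n = alleles.shape[0]
        flip = alleles.sum(axis=0) > n / 2
        alleles[:, flip] = 1 - alleles[:, flip]
    return HaplotypeMatrix(alleles, 0, pos)


# ---------------------------------------------------------------------------
# MatrixArchive
# ---------------------------------------------------------------------------

def write_archive(m: HaplotypeMatrix, path: Union[str, IO[str]]) -> None:
    """Write ``m`` as a plain-text matrix archive.

    Format: a header line ``#confusenn v1 n_hap=<int> n_col=<int>
    padding_width=<int>``, an optional ``#positions`` line, then one row of
    ``n_col`` contiguous 0/1 characters per haplotype. Reading the archive
    back reproduces ``m`` field-for-field.
    """
    require_valid(m)
    own = isinstance(path, (str, os.PathLike))
    fh = open(path, "w") if own else path
    try:
        fh.write(
            f"{ARCHIVE_MAGIC} n_hap={m.n_hap} n_col={m.n_col} "
            f"padding_width={m.padding_width}\n"
        )
        if m.positions is not None:
            fh.write("#positions " + " ".join(repr(float(p)) for p in m.positions) + "\n")
        for row in m.alleles:
            fh.write("".join("1" if a else "0" for a in row) + "\n")
    finally:
        if own:
            fh.close()


def read_archive(path: Union[str, IO[str]]) -> HaplotypeMatrix:
    """Read a matrix archive written by :func:`write_archive`."""
    own = isinstance(path, (str, os.PathLike))
    fh = open(path) if own else path
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()
    if not lines or not lines[0].startswith(ARCHIVE_MAGIC):
        raise ParseError("not a matrix archive: bad or missing header")
    header = dict(
        kv.split("=", 1) for kv in lines[0][len(ARCHIVE_MAGIC):].split()
    )
    try:
        n_hap = int(header["n_hap"])
        n_col = int(header["n_col"])
        padding_width = int(header["padding_width"])
    except (KeyError, ValueError):
        raise ParseError(f"malformed archive header {lines[0]!r}") from None
    i = 1
    positions: Optional[np.ndarray] = None
    if i < len(lines) and lines[i].startswith("#positions"):
        positions = np.array([float(x) for x in lines[i].split()[1:]])
        i += 1
    rows = [l for l in lines[i:] if l.strip()]
    if len(rows) != n_hap:
        raise ParseError(f"expected {n_hap} rows, found {len(rows)}")
    alleles = np.zeros((n_hap, n_col), dtype=np.int8)
    for r, row in enumerate(rows):
        if len(row) != n_col:
            raise ParseError(
                f"row {r}: length {len(row)} != n_col {n_col}"
            )
        if set(row) - {"0", "1"}:
            raise ParseError(f"row {r}: non-0/1 character")
        alleles[r] = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
    return HaplotypeMatrix(alleles, padding_width, positions)


# ---------------------------------------------------------------------------
# Padding
# ---------------------------------------------------------------------------

def pad_to_width(m: HaplotypeMatrix, target_width: int) -> HaplotypeMatrix:
    """Right-pad ``m`` with all-zero columns to ``target_width``.

    ``m`` must be unpadded; the result records
    ``padding_width = target_width - n_col`` and keeps positions unchanged.
    """
    require_valid(m)
    if m.padding_width != 0:
        raise ValueError("pad_to_width requires an unpadded matrix")
    if target_width < m.n_col:
        raise ValueError(
            f"target_width {target_width} < matrix width {m.n_col}"
        )
    extra = target_width - m.n_col
    if extra == 0:
        return m.copy()
    alleles = np.concatenate(
        [m.alleles, np.zeros((m.n_hap, extra), dtype=np.int8)], axis=1
    )
    return HaplotypeMatrix(
        alleles, extra, None if m.positions is None else m.positions.copy()
    )
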