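"""Alignment input and the read-inclusion policy.

Every downstream per-base quantity (depth, low-MAPQ mass) is computed from
the stream of records this module yields.  The policy mirrors common pileup
practice: unmapped, secondary, duplicate, and QC-fail records never count;
supplementary records count only when the run explicitly opts in.  Secondary
alignments are excluded in *both* modes, because a secondary record is an
alternative placement of a read whose primary placement is already counted,
whereas a supplementary record covers reference bases its primary does not
(a chimeric piece of a split read).
"""

from __future__ import annotations

import enum
import logging
import os
from typing import Iterable, Iterator, List, Set, Tuple

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentMode",
    "passes_filter",
    "reference_covered_positions",
    "covered_blocks",
    "open_alignment",
    "filtered_records",
]


class AlignmentMode(enum.Enum):
    """Which alignment records participate in pileup.

    ``PRIMARY_ONLY`` excludes both secondary and supplementary records;
    ``PRIMARY_PLUS_SUPPLEMENTARY`` excludes only secondary records, letting
    the split pieces of chimeric reads (e.g. reads spanning an inversion
    breakpoint) contribute coverage.
    """

    PRIMARY_ONLY = "primary"
    PRIMARY_PLUS_SUPPLEMENTARY = "primary+supplementary"

    @classmethod
    def from_string(cls, s: str) -> "AlignmentMode":
        for m in cls:
            if m.value == s or m.name.lower() == s.lower():
                return m
        raise ValueError(
            f"unknown alignment mode {s!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


# CIGAR operation codes (pysam numeric encoding).
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S, _CIGAR_H, _CIGAR_P = range(7)
_CIGAR_EQ, _CIGAR_X = 7, 8
#: ops that consume reference positions *and* place a read base there
_ALIGNED_OPS = frozenset({_CIGAR_M, _CIGAR_EQ, _CIGAR_X})
#: ops that consume reference positions without placing a read base
_REF_SKIP_OPS = frozenset({_CIGAR_D, _CIGAR_N})
#: ops that consume only the query (or nothing)
_QUERY_ONLY_OPS = frozenset({_CIGAR_I, _CIGAR_S, _CIGAR_H, _CIGAR_P})
_KNOWN_OPS = _ALIGNED_OPS | _REF_SKIP_OPS | _QUERY_ONLY_OPS


def passes_filter(
    record: pysam.AlignedSegment,
    mode: AlignmentMode,
    *,
    exclude_duplicates: bool = True,
    exclude_qcfail: bool = True,
) -> bool:
    """Return True iff *record* participates in pileup under *mode*.

    A record passes when it is mapped, not secondary, not duplicate
    (configurable), not QC-fail (configurable), and either not supplementary
    or the mode admits supplementary records.  The filter is monotone in the
    mode: every record passing ``PRIMARY_ONLY`` also passes
    ``PRIMARY_PLUS_SUPPLEMENTARY``.
    """
    if record.is_unmapped:
        return False
    if record.is_secondary:
        return False
    if exclude_duplicates and record.is_duplicate:
        return False
    if exclude_qcfail and record.is_qcfail:
        return False
    if record.is_supplementary and mode is AlignmentMode.PRIMARY_ONLY:
        return False
    return True


def covered_blocks(record: pysam.AlignedSegment) -> List[Tuple[int, int]]:
    """Half-open reference blocks covered by aligned bases (M/=/X).

    Deletions and reference skips advance the reference cursor without
    producing a block; insertions and clips touch no reference position.
    Raises ``ValueError`` on an unknown CIGAR operation.
    """
    cigar = record.cigartuples
    if cigar is None:
        return []
    blocks: List[Tuple[int, int]] = []
    pos = record.reference_start
    for op, length in cigar:
        if op in _ALIGNED_OPS:
            if length > 0:
                blocks.append((pos, pos + length))
            pos += length
        elif op in _REF_SKIP_OPS:
            pos += length
        elif op in _QUERY_ONLY_OPS:
            continue
        else:
            raise ValueError(
                f"unknown CIGAR op code {op} in record {record.query_name!r}"
            )
    return blocks


def reference_covered_positions(record: pysam.AlignedSegment) -> Set[int]:
    """The exact set of 0-based reference positions covered by *record*.

    Set form of :func:`covered_blocks`; its size always equals the summed
    M/=/X lengths because alignment blocks cannot overlap.
    """
    out: Set[int] = set()
    for start, end in covered_blocks(record):
        out.update(range(start, end))
    return out


def open_alignment(path: str | os.PathLike) -> pysam.AlignmentFile:
    """Open a coordinate-sorted SAM/BAM/CRAM file, requiring an index for
    binary formats (random access is how regions are classified; an absent
    index is an error, never an implicit sort)."""
    path = os.fspath(path)
    af = pysam.AlignmentFile(path)
    if af.format in ("BAM", "CRAM") and not af.has_index():
        af.close()
        raise FileNotFoundError(
            f"{path}: no index found (.bai/.crai); sort and index the file "
            "first (samtools sort && samtools index)"
        )
    return af


def filtered_records(
    alignment: pysam.AlignmentFile,
    chrom: str,
    start: int | None = None,
    end: int | None = None,
    mode: AlignmentMode = AlignmentMode.PRIMARY_ONLY,
    *,
    exclude_duplicates: bool = True,
    exclude_qcfail: bool = True,
) -> Iterator[pysam.AlignedSegment]:
    """Stream records overlapping ``chrom[:start-end]`` that pass the filter.

    Records are yielded in coordinate order (the file's order).  Zero-length
    alignments are skipped with a debug log line.  Raises ``ValueError`` if
    *chrom* is absent from the header, listing the available names.
    """
    if chrom not in alignment.references:
        raise ValueError(
            f"sequence {chrom!r} not in alignment header; available: "
            f"{list(alignment.references)}"
        )
    for rec in alignment.fetch(chrom, start, end):
        if not passes_filter(
            rec,
            mode,
            exclude_duplicates=exclude_duplicates,
            exclude_qcfail=exclude_qcfail,
        ):
            continue
        if rec.reference_length is None or rec.reference_length == 0:
            logger.debug("skipping zero-length alignment %s", rec.query_name)
            continue
        yield rec
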