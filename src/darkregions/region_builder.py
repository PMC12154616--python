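"""Merge classified loci into maximal intervals and summarise them.

Intervals are BED-style 0-based half-open.  Each dark class yields
maximal runs of consecutive same-class bases; the *all-dark* track is the
union of the two dark classes, so a depth run abutting a MAPQ run fuses
into a single all-dark region.  Region statistics mirror the standard
per-class summary: total bases, region count, mean and median region
length.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import IO, Dict, Iterable, Iterator, List, Sequence, Tuple

from .locus_classifier import DarkClass

__all__ = [
    "DarkInterval",
    "RegionStats",
    "ALL_DARK",
    "merge_loci",
    "region_stats",
    "filter_min_length",
    "write_bed",
    "read_bed",
    "write_stats_tsv",
    "read_stats_tsv",
]

#: pseudo-class label for the fused union track
ALL_DARK = "all_dark"


@dataclass(frozen=True, order=True)
class DarkInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    dark_class: str  # "dark_by_depth" | "dark_by_mapq" | "all_dark"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionStats:
    """Summary of one class's intervals: bases, regions, mean/median length."""

    dark_class: str
    n_bases: int
    n_regions: int
    mean_len: float
    median_len: float


def merge_loci(
    loci: Iterable[Tuple[str, int, DarkClass]],
) -> Dict[str, List[DarkInterval]]:
    """Collapse a sorted ``(chrom, pos, class)`` stream into maximal runs.

    Returns a dict with keys ``dark_by_depth``, ``dark_by_mapq`` and
    ``all_dark``; resolved positions separate runs.  Input must be sorted
    by (chrom, pos) with each chromosome contiguous; the first inversion
    raises ``ValueError``.
    """
    out: Dict[str, List[DarkInterval]] = {
        DarkClass.DARK_BY_DEPTH.value: [],
        DarkClass.DARK_BY_MAPQ.value: [],
        ALL_DARK: [],
    }
    # open run per track: (start, last_pos) or None
    open_runs: Dict[str, Tuple[int, int] | None] = {k: None for k in out}
    cur_chrom: str | None = None
    last_pos = -1
    seen_chroms: set[str] = set()

    def _flush(track: str, chrom: str) -> None:
        run = open_runs[track]
        if run is not None:
            out[track].append(DarkInterval(chrom, run[0], run[1] + 1, track))
            open_runs[track] = None

    def _flush_all(chrom: str) -> None:
        for track in out:
            _flush(track, chrom)

    for chrom, pos, cls in loci:
        if chrom != cur_chrom:
            if chrom in seen_chroms:
                raise ValueError(
                    f"unsorted input: chromosome {chrom!r} seen twice"
                )
            if cur_chrom is not None:
                _flush_all(cur_chrom)
            seen_chroms.add(chrom)
            cur_chrom = chrom
            last_pos = -1
        elif pos <= last_pos:
            raise ValueError(
                f"unsorted input at {chrom}:{pos} (previous {last_pos})"
            )
        for track in (
            DarkClass.DARK_BY_DEPTH.value,
            DarkClass.DARK_BY_MAPQ.value,
        ):
            if cls.value == track:
                run = open_runs[track]
                if run is not None and pos == run[1] + 1:
                    open_runs[track] = (run[0], pos)
                else:
                    _flush(track, chrom)
                    open_runs[track] = (pos, pos)
            else:
                _flush(track, chrom)
        if cls is not DarkClass.RESOLVED:
            run = open_runs[ALL_DARK]
            if run is not None and pos == run[1] + 1:
                open_runs[ALL_DARK] = (run[0], pos)
            else:
                _flush(ALL_DARK, chrom)
                open_runs[ALL_DARK] = (pos, pos)
        else:
            _flush(ALL_DARK, chrom)
        last_pos = pos
    if cur_chrom is not None:
        _flush_all(cur_chrom)
    return out


def region_stats(
    intervals: Sequence[DarkInterval], dark_class: str | None = None
) -> RegionStats:
    """Compute bases/regions/mean/median over *intervals*.

    Empty input yields all-zero stats (mean and median reported as 0).
    """
    if dark_class is None:
        dark_class = intervals[0].dark_class if intervals else "none"
    lengths = [iv.length for iv in intervals]
    if not lengths:
        return RegionStats(dark_class, 0, 0, 0.0, 0.0)
    n_bases = sum(lengths)
    n = len(lengths)
    return RegionStats(
        dark_class,
        n_bases,
        n,
        n_bases / n,
        float(statistics.median(lengths)),
    )


def filter_min_length(
    intervals: Iterable[DarkInterval], min_len: int
) -> List[DarkInterval]:
    """Keep intervals of length >= *min_len* (order preserved)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [iv for iv in intervals if iv.length >= min_len]


def write_bed(intervals: Iterable[DarkInterval], fh: IO[str]) -> int:
    """Write BED4 (chrom, start, end, class); returns rows written."""
    n = 0
    for iv in intervals:
        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.dark_class}\n")
        n += 1
    return n


def read_bed(fh: IO[str]) -> List[DarkInterval]:
    """Read BED3/BED4 produced by :func:`write_bed` (column 4 optional)."""
    out: List[DarkInterval] = []
    for line in fh:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        cls = parts[3] if len(parts) > 3 else ALL_DARK
        out.append(DarkInterval(parts[0], int(parts[1]), int(parts[2]), cls))
    return out


_STATS_COLS = ("dark_class", "n_bases", "n_regions", "mean_len", "median_len")


def write_stats_tsv(stats: Iterable[RegionStats], fh: IO[str]) -> None:
    """Write one summary row per class, means/medians to 2 decimals."""
    fh.write("\t".join(_STATS_COLS) + "\n")
    for s in stats:
        fh.write(
            f"{s.dark_class}\t{s.n_bases}\t{s.n_regions}"
            f"\t{s.mean_len:.2f}\t{s.median_len:.2f}\n"
        )


def read_stats_tsv(fh: IO[str]) -> List[RegionStats]:
    out: List[RegionStats] = []
    header = fh.readline()
    if header.strip() and header.split("\t")[0] != "dark_class":
        raise ValueError("not a region-stats TSV (missing header)")
    for line in fh:
        if not line.strip():
            continue
        cls, nb, nr, mean, med = line.rstrip("\n").split("\t")
        out.append(RegionStats(cls, int(nb), int(nr), float(mean), float(med)))
    return out
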