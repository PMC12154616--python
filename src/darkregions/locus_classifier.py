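"""Per-base depth/MAPQ profiling and dark-class assignment.

A reference base is *dark-by-depth* when fewer than ``depth_threshold``
filtered reads cover it (default < 5x): whatever variation the sample
carries there is invisible for lack of data.  A base is *dark-by-MAPQ*
when it has enough reads but at least ``low_mapq_fraction`` of them
(default 90%) map with MAPQ below ``mapq_threshold`` (default 10): reads
are present but cannot be assigned confidently among near-identical loci.
Depth takes precedence, so every base gets exactly one class.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pysam

from .alignment_io import AlignmentMode, covered_blocks, filtered_records

__all__ = [
    "ClassificationConfig",
    "LocusProfile",
    "DarkClass",
    "CombinePolicy",
    "pileup_profile",
    "classify_locus",
    "classify_profiles",
    "combine_samples",
    "write_profiles",
    "read_profiles",
]


class DarkClass(enum.Enum):
    RESOLVED = "resolved"
    DARK_BY_DEPTH = "dark_by_depth"
    DARK_BY_MAPQ = "dark_by_mapq"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the per-base classification.

    depth_threshold
        A base is dark-by-depth when depth < this many reads (default 5).
    mapq_threshold
        A read is low-MAPQ when MAPQ < this value (default 10).
    low_mapq_fraction
        A base is dark-by-MAPQ when low-MAPQ reads make up at least this
        fraction of its depth (default 0.90, compared with >=).
    locus_read_cap
        At most this many reads accumulate per locus (default 10,000);
        later-arriving reads in coordinate order are dropped at loci
        already at the cap, which bounds memory in collapsed repeats.
    min_region_len
        Minimum contiguous dark run, in bases, for a gene to count as
        containing a dark region (default 20; applied at the
        gene-counting stage, never to genome-wide totals).
    """

    depth_threshold: int = 5
    mapq_threshold: int = 10
    low_mapq_fraction: float = 0.90
    locus_read_cap: int = 10_000
    min_region_len: int = 20

    def __post_init__(self) -> None:
        if self.depth_threshold < 1:
            raise ValueError("depth_threshold must be >= 1")
        if not (0 < self.low_mapq_fraction <= 1):
            raise ValueError("low_mapq_fraction must be in (0, 1]")
        if not (0 <= self.mapq_threshold <= 255):
            raise ValueError("mapq_threshold must be in [0, 255]")
        if self.locus_read_cap < self.depth_threshold:
            raise ValueError("locus_read_cap must be >= depth_threshold")
        if self.min_region_len < 1:
            raise ValueError("min_region_len must be >= 1")


@dataclass(frozen=True)
class LocusProfile:
    """Depth and low-MAPQ read count at one reference base."""

    chrom: str
    pos: int  # 0-based
    depth: int
    low_mapq_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.low_mapq_count <= self.depth):
            raise ValueError(
                f"invalid profile at {self.chrom}:{self.pos}: "
                f"low_mapq_count {self.low_mapq_count} > depth {self.depth}"
            )

    @property
    def low_mapq_fraction(self) -> float:
        return self.low_mapq_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class CombinePolicy:
    """How per-sample profiles merge into one track.

    ``pooled`` (default): combined depth is the rounded mean of per-sample
    depths and the combined low-MAPQ count is that mean scaled by the
    pooled low-MAPQ fraction (sum of counts over sum of depths) — i.e. the
    samples are treated as one pooled library at average depth.
    ``quorum``: a position is emitted as dark of class *c* iff at least
    ``quorum`` of the samples classify it as *c* individually; a sentinel
    profile realising that class is synthesised.
    """

    mode: str = "pooled"
    quorum: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "quorum"):
            raise ValueError(f"unknown combine mode {self.mode!r}")
        if not (0 < self.quorum <= 1):
            raise ValueError("quorum must be in (0, 1]")


def pileup_profile(
    alignment: pysam.AlignmentFile,
    chrom: str,
    start: int,
    end: int,
    config: ClassificationConfig = ClassificationConfig(),
    mode: AlignmentMode = AlignmentMode.PRIMARY_ONLY,
    *,
    exclude_duplicates: bool = True,
    exclude_qcfail: bool = True,
) -> Iterator[LocusProfile]:
    """Stream one :class:`LocusProfile` per position of ``chrom:[start,end)``.

    Depth counts the filtered reads whose aligned bases (M/=/X CIGAR ops)
    include the position; deletions and clips contribute nothing.  A read
    is counted at a locus only while the locus is under ``locus_read_cap``,
    so overflow reads are dropped per-locus in stream (coordinate) order.
    """
    if end <= start or start < 0:
        raise ValueError(f"bad region {chrom}:{start}-{end}")
    n = end - start
    depth = np.zeros(n, dtype=np.int32)
    low = np.zeros(n, dtype=np.int32)
    cap = config.locus_read_cap
    for rec in filtered_records(
        alignment,
        chrom,
        start,
        end,
        mode,
        exclude_duplicates=exclude_duplicates,
        exclude_qcfail=exclude_qcfail,
    ):
        is_low = rec.mapping_quality < config.mapq_threshold
        for bstart, bend in covered_blocks(rec):
            s = max(bstart, start) - start
            e = min(bend, end) - start
            if e <= s:
                continue
            room = depth[s:e] < cap
            depth[s:e] += room
            if is_low:
                low[s:e] += room
    for i in range(n):
        yield LocusProfile(chrom, start + i, int(depth[i]), int(low[i]))


def classify_locus(
    profile: LocusProfile, config: ClassificationConfig = ClassificationConfig()
) -> DarkClass:
    """Assign one dark class to a profiled base; total on valid profiles.

    Depth takes precedence: a base under the depth threshold is
    dark-by-depth regardless of its MAPQ composition, so the three classes
    partition every region exactly.
    """
    if profile.depth < config.depth_threshold:
        return DarkClass.DARK_BY_DEPTH
    if profile.low_mapq_count / profile.depth >= config.low_mapq_fraction:
        return DarkClass.DARK_BY_MAPQ
    return DarkClass.RESOLVED


def classify_profiles(
    profiles: Iterable[LocusProfile],
    config: ClassificationConfig = ClassificationConfig(),
) -> Iterator[Tuple[str, int, DarkClass]]:
    """Map a profile stream to a ``(chrom, pos, DarkClass)`` stream."""
    for p in profiles:
        yield p.chrom, p.pos, classify_locus(p, config)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def combine_samples(
    samples: Sequence[Iterable[LocusProfile]],
    policy: CombinePolicy = CombinePolicy(),
    config: ClassificationConfig = ClassificationConfig(),
) -> Iterator[LocusProfile]:
    """Merge per-sample profile streams over identical positions.

    All streams must cover the same positions in the same order; the first
    discordant position raises ``ValueError``.  See :class:`CombinePolicy`
    for the two merge rules.  With a single sample both rules reduce to
    (a re-classification-equivalent of) the identity.
    """
    iters = [iter(s) for s in samples]
    if not iters:
        return
    if len(iters) == 1:
        yield from iters[0]
        return
    n_samples = len(iters)
    for rows in zip(*iters, strict=True):
        first = rows[0]
        for r in rows[1:]:
            if (r.chrom, r.pos) != (first.chrom, first.pos):
                raise ValueError(
                    f"sample position mismatch: {first.chrom}:{first.pos} "
                    f"vs {r.chrom}:{r.pos}"
                )
        if policy.mode == "pooled":
            total_depth = sum(r.depth for r in rows)
            total_low = sum(r.low_mapq_count for r in rows)
            mean_depth = total_depth / n_samples
            frac = (total_low / total_depth) if total_depth else 0.0
            depth = _round_half_up(mean_depth)
            low = min(depth, _round_half_up(mean_depth * frac))
            yield LocusProfile(first.chrom, first.pos, depth, low)
        else:  # quorum
            votes = {c: 0 for c in DarkClass}
            for r in rows:
                votes[classify_locus(r, config)] += 1
            needed = policy.quorum * n_samples
            cls = DarkClass.RESOLVED
            for c in (DarkClass.DARK_BY_DEPTH, DarkClass.DARK_BY_MAPQ):
                if votes[c] >= needed:
                    cls = c
                    break
            yield _sentinel_profile(first.chrom, first.pos, cls, config)


def _sentinel_profile(
    chrom: str, pos: int, cls: DarkClass, config: ClassificationConfig
) -> LocusProfile:
    """A minimal profile that classify_locus maps back to *cls*."""
    if cls is DarkClass.DARK_BY_DEPTH:
        return LocusProfile(chrom, pos, 0, 0)
    if cls is DarkClass.DARK_BY_MAPQ:
        d = config.depth_threshold
        return LocusProfile(chrom, pos, d, d)
    return LocusProfile(chrom, pos, config.depth_threshold, 0)


_PROFILE_HEADER = "#chrom\tpos\tdepth\tlow_mapq_count\tlow_mapq_fraction"


def write_profiles(profiles: Iterable[LocusProfile], fh: IO[str]) -> int:
    """Write the per-locus TSV (one row per base); returns rows written."""
    fh.write(_PROFILE_HEADER + "\n")
    n = 0
    for p in profiles:
        fh.write(
            f"{p.chrom}\t{p.pos}\t{p.depth}\t{p.low_mapq_count}"
            f"\t{p.low_mapq_fraction:.6g}\n"
        )
        n += 1
    return n


def read_profiles(fh: IO[str]) -> Iterator[LocusProfile]:
    """Read the per-locus TSV written by :func:`write_profiles`."""
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        chrom, pos, depth, low = line.rstrip("\n").split("\t")[:4]
        yield LocusProfile(chrom, int(pos), int(depth), int(low))
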