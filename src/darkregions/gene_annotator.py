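"""Gene-level dark and camouflage reporting.

Overlaps dark/camouflage interval tracks with *gene bodies* — the full
annotated gene extent, introns included, which is the denominator for all
per-gene percentages — and derives the threshold flags used for gene
counting: any dark run of at least ``min_region_len`` contiguous in-gene
bases per class, gene at least 5% dark (of either type), at least 5%
dark-by-MAPQ / dark-by-depth / camouflaged, 100% camouflaged, and
containing both dark classes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Dict, Iterable, List, Sequence, Tuple

import gffutils

from .locus_classifier import ClassificationConfig, DarkClass
from .region_builder import DarkInterval

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneDarkReport",
    "read_gff3",
    "gene_dark_report",
    "count_genes",
    "COUNT_CRITERIA",
    "write_gene_reports",
]

#: fraction of the gene body above which a gene counts as "5% dark"
DARK_GENE_FRACTION = 0.05


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    biotype: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneDarkReport:
    gene: GeneModel
    dark_depth_bases: int
    dark_mapq_bases: int
    camo_bases: int
    has_depth_region_ge_min_len: bool
    has_mapq_region_ge_min_len: bool

    @property
    def has_dark_region_ge_min_len(self) -> bool:
        """Gene contains a qualifying run of either class.

        Defined as the disjunction of the per-class flags so that gene
        counts satisfy inclusion-exclusion exactly:
        |any| = |depth| + |mapq| - |both|.
        """
        return self.has_depth_region_ge_min_len or self.has_mapq_region_ge_min_len

    @property
    def gene_len(self) -> int:
        return self.gene.length

    @property
    def f_depth(self) -> float:
        return self.dark_depth_bases / self.gene_len

    @property
    def f_mapq(self) -> float:
        return self.dark_mapq_bases / self.gene_len

    @property
    def f_dark(self) -> float:
        # dark-by-depth and dark-by-MAPQ are disjoint, so fractions add
        return self.f_depth + self.f_mapq

    @property
    def f_camo(self) -> float:
        return self.camo_bases / self.gene_len

    @property
    def is_ge5pct_dark(self) -> bool:
        return self.f_dark >= DARK_GENE_FRACTION

    @property
    def is_ge5pct_mapq(self) -> bool:
        return self.f_mapq >= DARK_GENE_FRACTION

    @property
    def is_ge5pct_depth(self) -> bool:
        return self.f_depth >= DARK_GENE_FRACTION

    @property
    def is_ge5pct_camo(self) -> bool:
        return self.f_camo >= DARK_GENE_FRACTION

    @property
    def is_100pct_camo(self) -> bool:
        return self.camo_bases == self.gene_len

    @property
    def has_both_classes(self) -> bool:
        return self.dark_depth_bases > 0 and self.dark_mapq_bases > 0


def read_gff3(
    path: str | os.PathLike, feature_type: str = "gene"
) -> List[GeneModel]:
    """Parse gene features from a GFF3 file into sorted :class:`GeneModel`s.

    GFF3 1-based inclusive coordinates become 0-based half-open.  The
    biotype is taken from the first present of the ``gene_biotype`` /
    ``biotype`` attribute keys (empty string if neither).  A feature of the
    requested type without an ID raises ``ValueError`` naming the feature.
    Output is sorted by (chrom, start) regardless of file order.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(
                f"{path}: {feature_type} feature at {feat.seqid}:{feat.start}"
                f"-{feat.end} has no ID attribute"
            )
        attrs = feat.attributes
        biotype = (attrs.get("gene_biotype") or attrs.get("biotype") or [""])[0]
        name = (attrs.get("Name") or attrs.get("gene_name") or ids)[0]
        genes.append(
            GeneModel(
                gene_id=ids[0],
                name=name,
                biotype=biotype,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _clip_and_merge(
    intervals: Iterable[DarkInterval], chrom: str, start: int, end: int
) -> List[Tuple[int, int]]:
    """Clip intervals to ``chrom:[start,end)`` and re-merge touching runs.

    Re-merging makes downstream length flags invariant to how callers may
    have split a maximal run into abutting pieces.
    """
    clipped = sorted(
        (max(iv.start, start), min(iv.end, end))
        for iv in intervals
        if iv.chrom == chrom and iv.start < end and iv.end > start
    )
    merged: List[Tuple[int, int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def gene_dark_report(
    gene: GeneModel,
    depth_intervals: Sequence[DarkInterval],
    mapq_intervals: Sequence[DarkInterval],
    camo_intervals: Sequence[DarkInterval] = (),
    config: ClassificationConfig = ClassificationConfig(),
) -> GeneDarkReport:
    """Overlap one gene body with the class tracks.

    Base counts are total in-gene overlap per class; the per-class
    >=min_region_len flag asks whether any single merged in-gene run
    reaches ``config.min_region_len`` bases *after clipping to the gene*,
    so a long interval with under 20 in-gene bases does not count.  Genes
    on chromosomes absent from the interval universe get zero-filled
    reports (alt-contig robustness), not errors.
    """
    runs_depth = _clip_and_merge(depth_intervals, gene.chrom, gene.start, gene.end)
    runs_mapq = _clip_and_merge(mapq_intervals, gene.chrom, gene.start, gene.end)
    runs_camo = _clip_and_merge(camo_intervals, gene.chrom, gene.start, gene.end)
    ml = config.min_region_len
    depth_bases = sum(e - s for s, e in runs_depth)
    mapq_bases = sum(e - s for s, e in runs_mapq)
    camo_bases = sum(e - s for s, e in runs_camo)
    if depth_bases == mapq_bases == camo_bases == 0:
        logger.debug("gene %s has no dark overlap", gene.gene_id)
    return GeneDarkReport(
        gene=gene,
        dark_depth_bases=depth_bases,
        dark_mapq_bases=mapq_bases,
        camo_bases=camo_bases,
        has_depth_region_ge_min_len=any(e - s >= ml for s, e in runs_depth),
        has_mapq_region_ge_min_len=any(e - s >= ml for s, e in runs_mapq),
    )


#: criterion name -> predicate on a report
COUNT_CRITERIA = {
    "any_dark": lambda r: r.has_dark_region_ge_min_len,
    "any_mapq": lambda r: r.has_mapq_region_ge_min_len,
    "any_depth": lambda r: r.has_depth_region_ge_min_len,
    "both_classes": lambda r: (
        r.has_mapq_region_ge_min_len and r.has_depth_region_ge_min_len
    ),
    "ge5pct_dark": lambda r: r.is_ge5pct_dark,
    "ge5pct_mapq": lambda r: r.is_ge5pct_mapq,
    "ge5pct_depth": lambda r: r.is_ge5pct_depth,
    "ge5pct_camo": lambda r: r.is_ge5pct_camo,
    "camo_100pct": lambda r: r.is_100pct_camo,
}


def count_genes(
    reports: Iterable[GeneDarkReport],
    criterion: str,
    biotype: str | None = None,
) -> int:
    """Count reports satisfying *criterion*, optionally within one biotype.

    ``any_*``/``both_classes`` criteria require a contiguous in-gene run of
    at least the configured minimum length (the gene-counting rule);
    ``ge5pct_*``/``camo_100pct`` compare gene-body fractions.
    """
    try:
        pred = COUNT_CRITERIA[criterion]
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; valid: "
            f"{sorted(COUNT_CRITERIA)}"
        ) from None
    return sum(
        1
        for r in reports
        if (biotype is None or r.gene.biotype == biotype) and pred(r)
    )


_REPORT_COLS = (
    "gene_id name biotype chrom start end gene_len "
    "dark_depth_bases dark_mapq_bases camo_bases "
    "f_depth f_mapq f_dark f_camo "
    "has_depth_region_ge_min_len has_mapq_region_ge_min_len "
    "has_dark_region_ge_min_len is_ge5pct_dark is_ge5pct_mapq "
    "is_ge5pct_depth is_ge5pct_camo is_100pct_camo has_both_classes"
).split()


def write_gene_reports(reports: Iterable[GeneDarkReport], fh: IO[str]) -> int:
    """Write the per-gene TSV; returns rows written."""
    fh.write("\t".join(_REPORT_COLS) + "\n")
    n = 0
    for r in reports:
        g = r.gene
        row = [
            g.gene_id, g.name, g.biotype, g.chrom, str(g.start), str(g.end),
            str(g.length),
            str(r.dark_depth_bases), str(r.dark_mapq_bases), str(r.camo_bases),
            f"{r.f_depth:.6f}", f"{r.f_mapq:.6f}", f"{r.f_dark:.6f}",
            f"{r.f_camo:.6f}",
            str(int(r.has_depth_region_ge_min_len)),
            str(int(r.has_mapq_region_ge_min_len)),
            str(int(r.has_dark_region_ge_min_len)),
            str(int(r.is_ge5pct_dark)), str(int(r.is_ge5pct_mapq)),
            str(int(r.is_ge5pct_depth)), str(int(r.is_ge5pct_camo)),
            str(int(r.is_100pct_camo)), str(int(r.has_both_classes)),
        ]
        fh.write("\t".join(row) + "\n")
        n += 1
    return n
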