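"""Cross-platform / cross-reference / cross-mode comparison arithmetic.

Small, exact operations over per-class region summaries: resolution
percentages (how much of a baseline platform's dark content another
platform recovers), fold changes, and the signed base/region deltas that
quantify the effect of admitting supplementary alignments (negative =
supplementary inclusion resolved dark content).  Also renders and parses
the wide per-platform/per-reference summary table.

The published genome-scale summary statistics that these operations were
designed around (ten ~30x human WGS samples per platform against four
references, primary-only and primary+supplementary) ship as package data
and load via :func:`load_published_stats`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .alignment_io import AlignmentMode
from .region_builder import ALL_DARK, RegionStats

__all__ = [
    "ComparisonCell",
    "resolution_pct",
    "fold_change",
    "mode_delta",
    "render_table",
    "parse_table",
    "load_published_stats",
    "get_cell",
    "write_delta_tsv",
    "PLATFORM_ORDER",
    "REFERENCE_ORDER",
    "PUBLISHED_GENE_BODY_MAPQ_BASES",
]

#: canonical row orders: platforms within a reference, references by
#: assembly completeness
PLATFORM_ORDER = ("Illumina100", "Illumina250", "PacBio", "ONT")
REFERENCE_ORDER = ("HG19", "HG38_noalt", "HG38_alt", "CHM13")

_CLASS_ORDER = ("dark_by_depth", "dark_by_mapq", ALL_DARK)

#: published gene-body dark-by-MAPQ base totals on CHM13 (prose-reported,
#: not part of the genome-wide tables); used for the within-gene fold change
PUBLISHED_GENE_BODY_MAPQ_BASES = {"PacBio": 6_071_156, "ONT": 1_802_133}


@dataclass(frozen=True)
class ComparisonCell:
    platform: str
    reference: str
    mode: AlignmentMode
    stats: Mapping[str, RegionStats]  # dark_class -> RegionStats


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def resolution_pct(baseline: int, other: int) -> float:
    """Percent of *baseline*'s dark content absent from *other*.

    ``100 * (1 - other/baseline)``, rounded half-up to one decimal; equal
    counts give 0.0 and a fully resolved track gives 100.0.
    """
    if baseline <= 0:
        raise ValueError("baseline count must be > 0")
    if other < 0:
        raise ValueError("counts must be >= 0")
    return _round_half_up(100.0 * (1.0 - other / baseline), 1)


def fold_change(numerator: int, denominator: int) -> float:
    """Ratio of two counts, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return _round_half_up(numerator / denominator, 1)


def mode_delta(
    primary_stats: RegionStats, supp_stats: RegionStats
) -> Tuple[int, int]:
    """Signed (base, region) differences, supplementary minus primary.

    Negative values mean that admitting supplementary alignments resolved
    dark content.  Raises ``ValueError`` on mismatched classes.
    """
    if primary_stats.dark_class != supp_stats.dark_class:
        raise ValueError(
            f"class mismatch: {primary_stats.dark_class!r} vs "
            f"{supp_stats.dark_class!r}"
        )
    return (
        supp_stats.n_bases - primary_stats.n_bases,
        supp_stats.n_regions - primary_stats.n_regions,
    )


def _fmt_int(v: int) -> str:
    return f"{v:,}"


def _fmt_2dp(v: float) -> str:
    return f"{_round_half_up(v, 2):,.2f}"


_TABLE_COLS = ["platform", "reference"] + [
    f"{cls}.{col}"
    for cls in _CLASS_ORDER
    for col in ("n_bases", "n_regions", "mean_len", "median_len")
]


def render_table(
    cells: Sequence[ComparisonCell],
    platforms: Sequence[str] | None = None,
    references: Sequence[str] | None = None,
) -> str:
    """Render cells as a TSV in the wide summary layout.

    One row per (platform, reference) with 12 numeric columns (three
    classes x bases/regions/mean/median), grouped by reference in
    completeness order with platforms in canonical order; thousands
    separators on counts, two decimals on means and medians.  A missing
    cell or class raises ``KeyError`` naming the gap.
    """
    by_key = {(c.platform, c.reference): c for c in cells}
    if platforms is None:
        platforms = [p for p in PLATFORM_ORDER if any(c.platform == p for c in cells)]
    if references is None:
        references = [
            r for r in REFERENCE_ORDER if any(c.reference == r for c in cells)
        ]
    lines = ["\t".join(_TABLE_COLS)]
    for ref in references:
        for plat in platforms:
            if (plat, ref) not in by_key:
                raise KeyError(f"missing cell for platform={plat} reference={ref}")
            cell = by_key[(plat, ref)]
            row = [plat, ref]
            for cls in _CLASS_ORDER:
                if cls not in cell.stats:
                    raise KeyError(
                        f"cell {plat}/{ref} missing class {cls!r}"
                    )
                s = cell.stats[cls]
                row += [
                    _fmt_int(s.n_bases),
                    _fmt_int(s.n_regions),
                    _fmt_2dp(s.mean_len),
                    _fmt_2dp(s.median_len),
                ]
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def parse_table(text: str, mode: AlignmentMode = AlignmentMode.PRIMARY_ONLY) -> List[ComparisonCell]:
    """Parse a TSV produced by :func:`render_table` back into cells."""
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header != _TABLE_COLS:
        raise ValueError("not a rendered comparison table")
    cells: List[ComparisonCell] = []
    for line in lines[1:]:
        parts = line.split("\t")
        plat, ref = parts[0], parts[1]
        stats: Dict[str, RegionStats] = {}
        for ci, cls in enumerate(_CLASS_ORDER):
            base = 2 + 4 * ci
            stats[cls] = RegionStats(
                cls,
                int(parts[base].replace(",", "")),
                int(parts[base + 1].replace(",", "")),
                float(parts[base + 2].replace(",", "")),
                float(parts[base + 3].replace(",", "")),
            )
        cells.append(ComparisonCell(plat, ref, mode, stats))
    return cells


def load_published_stats(
    mode: AlignmentMode = AlignmentMode.PRIMARY_ONLY,
) -> List[ComparisonCell]:
    """Load the bundled published summary statistics for *mode*.

    Returns the full 4-platform x 4-reference grid of
    :class:`ComparisonCell`s with all three dark classes per cell.
    """
    name = (
        "published_stats_primary.tsv"
        if mode is AlignmentMode.PRIMARY_ONLY
        else "published_stats_supplementary.tsv"
    )
    ref = importlib.resources.files("darkregions.data").joinpath(name)
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    cells: List[ComparisonCell] = []
    for (plat, refname), grp in df.groupby(["platform", "reference"], sort=False):
        stats = {
            row.dark_class: RegionStats(
                row.dark_class,
                int(row.n_bases),
                int(row.n_regions),
                float(row.mean_len),
                float(row.median_len),
            )
            for row in grp.itertuples()
        }
        cells.append(ComparisonCell(str(plat), str(refname), mode, stats))
    return cells


def get_cell(
    cells: Iterable[ComparisonCell], platform: str, reference: str
) -> ComparisonCell:
    """Convenience lookup; raises ``KeyError`` when absent."""
    for c in cells:
        if c.platform == platform and c.reference == reference:
            return c
    raise KeyError(f"no cell for platform={platform} reference={reference}")


def write_delta_tsv(
    primary_cells: Sequence[ComparisonCell],
    supp_cells: Sequence[ComparisonCell],
    fh: IO[str],
) -> int:
    """Write signed supplementary-minus-primary deltas for every cell/class.

    Returns rows written.  Cells present in one grid but not the other
    raise ``KeyError``.
    """
    fh.write("platform\treference\tdark_class\tdelta_bases\tdelta_regions\n")
    n = 0
    for pc in primary_cells:
        sc = get_cell(supp_cells, pc.platform, pc.reference)
        for cls in _CLASS_ORDER:
            db, dr = mode_delta(pc.stats[cls], sc.stats[cls])
            fh.write(f"{pc.platform}\t{pc.reference}\t{cls}\t{db}\t{dr}\n")
            n += 1
    return n
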