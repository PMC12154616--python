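"""Self-contained synthetic fixtures with analytic truth tracks.

Builds a toy reference whose structure plants each cause of darkness the
classifier must detect, together with rule-based alignments and the exact
intervals the pipeline should recover:

* ``duplication_copy`` blocks — a copy of an earlier block, optionally
  mutated at a per-copy rate.  Reads falling wholly inside a duplication
  family are assigned MAPQ 0 (ambiguous placement), so family interiors
  become dark-by-MAPQ; near-identical copies are additionally camouflaged.
* ``deletion_zone`` blocks — no reads are drawn from the zone, so it and
  its tiling-geometry flanks become dark-by-depth.
* ``low_depth_zone`` blocks — coverage is clamped to a stated low value.
* ``inversion_zone`` blocks — reads crossing a zone boundary are emitted
  as a soft-clipped primary on one side plus a reverse-strand
  supplementary record covering the other side, so the zone is a
  dark-by-depth hole under primary-only filtering that closes when
  supplementary records are admitted.

Alignments are *constructed*, not re-aligned: the phenomena of interest
(ambiguity, absence, breakpoint clipping) are properties of alignment
records, so a deterministic rule reproduces them exactly and makes the
expected classification derivable from tiling geometry alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pysam

from .locus_classifier import ClassificationConfig, DarkClass
from .alignment_io import AlignmentMode
from .region_builder import ALL_DARK, DarkInterval

__all__ = [
    "Block",
    "SyntheticGenomeSpec",
    "SyntheticReference",
    "TruthTracks",
    "default_spec",
    "build_reference",
    "simulate_alignments",
    "truth_dark_regions",
    "write_fixture",
    "sam_to_indexed_bam",
]

BLOCK_KINDS = (
    "unique",
    "duplication_copy",
    "deletion_zone",
    "inversion_zone",
    "low_depth_zone",
)


@dataclass(frozen=True)
class Block:
    name: str
    kind: str
    length: int
    copy_of: str | None = None  # duplication_copy: name of an earlier block
    mutation_rate: float = 0.0  # duplication_copy: per-base substitution rate
    low_depth: int = 2  # low_depth_zone: clamped coverage

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError(f"block {self.name}: length must be >= 1")
        if self.kind == "duplication_copy" and not self.copy_of:
            raise ValueError(f"block {self.name}: duplication_copy needs copy_of")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Ordered block layout + seed; the seed fixes every random draw."""

    blocks: Tuple[Block, ...]
    chrom_name: str = "chrT"
    seed: int = 0

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    def offsets(self) -> Dict[str, Tuple[int, int]]:
        out: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for b in self.blocks:
            out[b.name] = (pos, pos + b.length)
            pos += b.length
        return out


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class SyntheticReference:
    spec: SyntheticGenomeSpec
    sequence: str
    #: absolute positions mutated in each duplication copy
    mutated_positions: Dict[str, Tuple[int, ...]]
    genes: List[GeneSpec] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.spec.chrom_name


@dataclass
class TruthTracks:
    """Analytic expectations for one (config, mode, tiling) combination."""

    dark: Dict[str, List[DarkInterval]]  # class -> intervals (incl. all_dark)
    #: duplication family name -> (member loci, expected camouflaged?)
    camo_families: Dict[str, Tuple[List[Tuple[int, int]], bool]]


def default_spec(seed: int = 0) -> SyntheticGenomeSpec:
    """The standard ~42 kb fixture: every zone type, two duplication
    families (one exact -> camouflaged, one 5%-divergent -> dark but not
    camouflaged), a deletion, a low-coverage zone, and a short inversion."""
    return SyntheticGenomeSpec(
        blocks=(
            Block("u1", "unique", 6000),
            Block("dupA", "unique", 3000),
            Block("u2", "unique", 4000),
            Block("cpyA", "duplication_copy", 3000, copy_of="dupA"),
            Block("u3", "unique", 800),
            Block("del1", "deletion_zone", 1500),
            Block("u4", "unique", 4000),
            Block("low1", "low_depth_zone", 1200, low_depth=2),
            Block("u5", "unique", 4000),
            Block("inv1", "inversion_zone", 300),
            Block("u6", "unique", 4000),
            Block("dupB", "unique", 2000),
            Block("u7", "unique", 2500),
            Block("cpyB", "duplication_copy", 2000, copy_of="dupB",
                  mutation_rate=0.05),
            Block("u8", "unique", 4000),
        ),
        seed=seed,
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _default_genes(spec: SyntheticGenomeSpec) -> List[GeneSpec]:
    """Genes straddling truth boundaries of the default block layout."""
    off = spec.offsets()
    c = spec.chrom_name
    genes = [
        # fully resolved gene in unique sequence
        GeneSpec("GCLEAN", "protein_coding", c, off["u1"][0] + 1000,
                 off["u1"][0] + 2200),
        # overlaps the low-coverage zone's left tiling flank by exactly 19
        # bases (one under the 20-nt gene-counting rule)
        GeneSpec("G19NT", "lincRNA", c, off["low1"][0] - 1181,
                 off["low1"][0] - 181, "-"),
        # interior of the exact duplication copy: expect 100% camouflaged
        GeneSpec("GCAMO", "protein_coding", c, off["cpyA"][0] + 800,
                 off["cpyA"][1] - 800),
        # spans the copy's edge and the deletion zone: both dark classes
        GeneSpec("GBOTH", "protein_coding", c, off["cpyA"][1] - 600,
                 off["del1"][0] + 700, "-"),
        # ~6% overlap with the deletion's right tiling flank
        GeneSpec("G5PCT", "pseudogene", c, off["del1"][1] + 80,
                 off["del1"][1] + 2080),
        # on a contig absent from the alignment universe
        GeneSpec("GABSENT", "protein_coding", "chrUn", 100, 600),
    ]
    return genes


def build_reference(
    spec: SyntheticGenomeSpec, genes: Sequence[GeneSpec] | None = None
) -> SyntheticReference:
    """Deterministically synthesise the reference sequence for *spec*.

    Duplication copies replicate their source block's bases, substituted
    at ``mutation_rate`` (positions and replacement bases drawn from the
    spec seed; a substitution always changes the base).  A copy
    referencing a later or unknown block raises ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)
    parts: Dict[str, np.ndarray] = {}
    mutated: Dict[str, Tuple[int, ...]] = {}
    pos = 0
    for b in spec.blocks:
        if b.kind == "duplication_copy":
            if b.copy_of not in parts:
                raise ValueError(
                    f"block {b.name}: copy_of {b.copy_of!r} must name an "
                    "earlier block"
                )
            src = parts[b.copy_of]
            if len(src) != b.length:
                raise ValueError(
                    f"block {b.name}: length {b.length} != source length "
                    f"{len(src)}"
                )
            arr = src.copy()
            if b.mutation_rate > 0:
                n_mut = int(round(b.mutation_rate * b.length))
                sites = rng.choice(b.length, size=n_mut, replace=False)
                for s in sites:
                    choices = _BASES[_BASES != arr[s]]
                    arr[s] = rng.choice(choices)
                mutated[b.name] = tuple(sorted(int(s) + pos for s in sites))
            else:
                mutated[b.name] = ()
        else:
            arr = _BASES[rng.integers(0, 4, size=b.length)]
        parts[b.name] = arr
        pos += b.length
    seq = b"".join(p.tobytes() for p in (parts[b.name] for b in spec.blocks))
    ref = SyntheticReference(
        spec=spec,
        sequence=seq.decode("ascii"),
        mutated_positions=mutated,
    )
    ref.genes = list(genes) if genes is not None else _default_genes(spec)
    return ref


@dataclass(frozen=True)
class _LogicalRead:
    """Geometry-level read: what the SAM encodes and the truth counts."""

    qname: str
    primary: Tuple[int, int]  # reference span covered by the primary
    primary_clip: Tuple[int, int]  # (left, right) soft-clipped bases
    supplementary: Tuple[int, int] | None = None
    supp_clip: Tuple[int, int] = (0, 0)
    mapq: int = 60


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and a1 > b0


def _duplication_families(
    spec: SyntheticGenomeSpec,
) -> Dict[str, List[Tuple[int, int]]]:
    off = spec.offsets()
    fams: Dict[str, List[Tuple[int, int]]] = {}
    for b in spec.blocks:
        if b.kind == "duplication_copy":
            fams.setdefault(b.copy_of, [off[b.copy_of]]).append(off[b.name])
    return fams


def _logical_reads(
    spec: SyntheticGenomeSpec, read_len: int, depth_target: int
) -> List[_LogicalRead]:
    """The deterministic tiling that both the SAM writer and the truth use.

    Reads start every ``read_len // depth_target`` bases, including
    starts hanging off both genome ends (clipped to the genome), so a
    fully unique genome is covered at exactly ``depth_target`` at every
    locus.  Zone rules are applied in order: drop on deletion/low-depth
    overlap, split on inversion-boundary crossing, then the MAPQ rule
    (0 inside a duplication family, 60 elsewhere).  Low-depth zones are
    re-covered by ``low_depth`` zone-length reads so their interior depth
    is exact.
    """
    off = spec.offsets()
    total = spec.total_length
    if read_len >= total:
        raise ValueError("read_len must be smaller than the genome")
    step = read_len // depth_target
    if step < 1:
        raise ValueError("depth_target too high for read_len")
    del_zones = [off[b.name] for b in spec.blocks if b.kind == "deletion_zone"]
    low_zones = [
        (off[b.name], b.low_depth)
        for b in spec.blocks
        if b.kind == "low_depth_zone"
    ]
    inv_zones = [off[b.name] for b in spec.blocks if b.kind == "inversion_zone"]
    for z0, z1 in del_zones:
        if z1 - z0 < read_len:
            raise ValueError(
                f"deletion zone [{z0},{z1}) shorter than read length"
            )
    for (z0, z1), _ in low_zones:
        if z1 - z0 < read_len:
            raise ValueError(
                f"low-depth zone [{z0},{z1}) shorter than read length"
            )
    for z0, z1 in inv_zones:
        if z1 - z0 >= read_len:
            raise ValueError(
                f"inversion zone [{z0},{z1}) must be shorter than the read"
            )
    families = _duplication_families(spec)
    fam_spans = [span for spans in families.values() for span in spans]

    def _mapq(a: int, b: int) -> int:
        return 0 if any(a >= s and b <= e for s, e in fam_spans) else 60

    reads: List[_LogicalRead] = []
    for raw_a in range(-(read_len - step), total, step):
        a = max(raw_a, 0)
        b = min(raw_a + read_len, total)
        if b - a < 1:
            continue
        if any(_overlaps(a, b, z0, z1) for z0, z1 in del_zones):
            continue
        if any(_overlaps(a, b, z0, z1) for (z0, z1), _ in low_zones):
            continue
        inv = next(
            ((z0, z1) for z0, z1 in inv_zones if _overlaps(a, b, z0, z1)), None
        )
        if inv is not None:
            z0, z1 = inv
            if a < z0:
                # anchored left of the zone; the rest maps as a
                # reverse-strand supplementary starting at the breakpoint
                reads.append(
                    _LogicalRead(
                        qname=f"read{raw_a}",
                        primary=(a, z0),
                        primary_clip=(0, b - z0),
                        supplementary=(z0, b),
                        supp_clip=(z0 - a, 0),
                        mapq=60,
                    )
                )
            else:
                # starts inside the zone; anchored right of it
                reads.append(
                    _LogicalRead(
                        qname=f"read{raw_a}",
                        primary=(z1, b),
                        primary_clip=(z1 - a, 0),
                        supplementary=(a, z1),
                        supp_clip=(0, b - z1),
                        mapq=60,
                    )
                )
            continue
        reads.append(
            _LogicalRead(
                qname=f"read{raw_a}",
                primary=(a, b),
                primary_clip=(0, 0),
                mapq=_mapq(a, b),
            )
        )
    for (z0, z1), low in low_zones:
        for i in range(low):
            reads.append(
                _LogicalRead(
                    qname=f"lowzone{z0}_{i}",
                    primary=(z0, z1),
                    primary_clip=(0, 0),
                    mapq=60,
                )
            )
    return reads


def simulate_alignments(
    ref: SyntheticReference,
    sam_path: str | os.PathLike,
    depth_target: int = 10,
    read_len: int = 500,
    seed: int | None = None,
) -> int:
    """Write the rule-based alignments as a coordinate-sorted SAM file.

    Returns the number of records written.  *seed* is accepted for
    interface symmetry; the tiling itself is fully deterministic.
    """
    spec = ref.spec
    reads = _logical_reads(spec, read_len, depth_target)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref.chrom, "LN": spec.total_length}],
        }
    )
    records: List[pysam.AlignedSegment] = []
    seq = ref.sequence

    def _segment(
        qname: str,
        span: Tuple[int, int],
        clip: Tuple[int, int],
        mapq: int,
        supplementary: bool,
    ) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header)
        rec.query_name = qname
        rec.reference_id = 0
        rec.reference_start = span[0]
        rec.mapping_quality = mapq
        left, right = clip
        cigar = []
        if left:
            cigar.append((4, left))
        cigar.append((0, span[1] - span[0]))
        if right:
            cigar.append((4, right))
        rec.cigartuples = cigar
        rec.query_sequence = seq[span[0] - left : span[1] + right]
        rec.flag = (0x800 if supplementary else 0) | (0x10 if supplementary else 0)
        return rec

    for r in reads:
        records.append(_segment(r.qname, r.primary, r.primary_clip, r.mapq, False))
        if r.supplementary is not None:
            records.append(
                _segment(r.qname, r.supplementary, r.supp_clip, r.mapq, True)
            )
    records.sort(key=lambda rec: rec.reference_start)
    with pysam.AlignmentFile(os.fspath(sam_path), "w", header=header) as out:
        for rec in records:
            out.write(rec)
    return len(records)


def sam_to_indexed_bam(
    sam_path: str | os.PathLike, bam_path: str | os.PathLike
) -> str:
    """Convert a SAM file to a sorted, indexed BAM (pileup needs random
    access); returns the BAM path."""
    sam_path, bam_path = os.fspath(sam_path), os.fspath(bam_path)
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path


def truth_dark_regions(
    ref: SyntheticReference,
    config: ClassificationConfig = ClassificationConfig(),
    mode: AlignmentMode = AlignmentMode.PRIMARY_ONLY,
    depth_target: int = 10,
    read_len: int = 500,
) -> TruthTracks:
    """Expected dark intervals, from tiling geometry alone.

    Per-base depth and low-MAPQ mass are accumulated directly from the
    logical read spans (difference arrays — no alignment records, pileup
    engine, or interval merger involved), then thresholded with the same
    definitions the classifier implements.
    """
    spec = ref.spec
    n = spec.total_length
    depth_diff = np.zeros(n + 1, dtype=np.int64)
    low_diff = np.zeros(n + 1, dtype=np.int64)

    def _add(span: Tuple[int, int], mapq: int) -> None:
        depth_diff[span[0]] += 1
        depth_diff[span[1]] -= 1
        if mapq < config.mapq_threshold:
            low_diff[span[0]] += 1
            low_diff[span[1]] -= 1

    for r in _logical_reads(spec, read_len, depth_target):
        _add(r.primary, r.mapq)
        if (
            r.supplementary is not None
            and mode is AlignmentMode.PRIMARY_PLUS_SUPPLEMENTARY
        ):
            _add(r.supplementary, r.mapq)
    depth = np.cumsum(depth_diff[:-1])
    low = np.cumsum(low_diff[:-1])
    np.minimum(depth, config.locus_read_cap, out=depth)
    is_depth_dark = depth < config.depth_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, low / np.maximum(depth, 1), 0.0)
    is_mapq_dark = (~is_depth_dark) & (frac >= config.low_mapq_fraction)

    def _runs(mask: np.ndarray, cls: str) -> List[DarkInterval]:
        out: List[DarkInterval] = []
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(DarkInterval(spec.chrom_name, int(s), int(e), cls))
        return out

    dark = {
        DarkClass.DARK_BY_DEPTH.value: _runs(
            is_depth_dark, DarkClass.DARK_BY_DEPTH.value
        ),
        DarkClass.DARK_BY_MAPQ.value: _runs(
            is_mapq_dark, DarkClass.DARK_BY_MAPQ.value
        ),
        ALL_DARK: _runs(is_depth_dark | is_mapq_dark, ALL_DARK),
    }
    fams: Dict[str, Tuple[List[Tuple[int, int]], bool]] = {}
    off = spec.offsets()
    for src, spans in _duplication_families(spec).items():
        worst = 1.0
        for b in spec.blocks:
            if b.kind == "duplication_copy" and b.copy_of == src:
                n_mut = len(ref.mutated_positions.get(b.name, ()))
                worst = min(worst, 1.0 - n_mut / b.length)
        fams[src] = (spans, worst >= 0.98)
    return TruthTracks(dark=dark, camo_families=fams)


def write_fixture(
    ref: SyntheticReference,
    out_dir: str | os.PathLike,
    depth_target: int = 10,
    read_len: int = 500,
    config: ClassificationConfig = ClassificationConfig(),
) -> Dict[str, str]:
    """Write FASTA(+fai), SAM, sorted+indexed BAM, GFF3 and truth BEDs.

    Returns a dict of the paths written.
    """
    from pyfaidx import Faidx

    out = {}
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "reference.fa")
    with open(fasta, "w") as fh:
        fh.write(f">{ref.chrom}\n")
        seq = ref.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    Faidx(fasta)
    out["fasta"] = fasta
    sam = os.path.join(out_dir, "reads.sam")
    simulate_alignments(ref, sam, depth_target, read_len)
    out["sam"] = sam
    out["bam"] = sam_to_indexed_bam(sam, os.path.join(out_dir, "reads.bam"))
    gff = os.path.join(out_dir, "genes.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ref.genes:
            attrs = (
                f"ID={g.gene_id};Name={g.gene_id};gene_biotype={g.biotype}"
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
    out["gff3"] = gff
    for mode in AlignmentMode:
        truth = truth_dark_regions(ref, config, mode, depth_target, read_len)
        for cls, ivs in truth.dark.items():
            path = os.path.join(out_dir, f"truth_{cls}_{mode.name.lower()}.bed")
            with open(path, "w") as fh:
                for iv in ivs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\n")
            out[f"truth_{cls}_{mode.name.lower()}"] = path
    return out
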