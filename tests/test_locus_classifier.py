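"""Pileup profiling, per-base classification, and multi-sample combining."""

from __future__ import annotations

import io

import pysam
import pytest

from darkregions import (
    ClassificationConfig,
    CombinePolicy,
    DarkClass,
    LocusProfile,
    classify_locus,
    combine_samples,
    pileup_profile,
    read_profiles,
    write_profiles,
)
from darkregions.alignment_io import AlignmentMode

PRIMARY = AlignmentMode.PRIMARY_ONLY


def _write_bam(tmp_path, records_spec, chrom="chr1", length=10000):
    """records_spec: iterable of (start, cigar, mapq, flag)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    )
    sam = tmp_path / "mini.sam"
    with pysam.AlignmentFile(sam, "w", header=header) as out:
        for i, (start, cigar, mapq, flag) in enumerate(
            sorted(records_spec, key=lambda r: r[0])
        ):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"r{i}"
            rec.reference_id = 0
            rec.reference_start = start
            rec.cigarstring = cigar
            rec.mapping_quality = mapq
            rec.flag = flag
            rec.query_sequence = "A" * rec.infer_query_length()
            out.write(rec)
    bam = str(tmp_path / "mini.bam")
    pysam.sort("-o", bam, str(sam))
    pysam.index(bam)
    return pysam.AlignmentFile(bam)


def test_pileup_no_reads_gives_zero_depth(tmp_path):
    af = _write_bam(tmp_path, [(5000, "10M", 60, 0)])
    profiles = list(pileup_profile(af, "chr1", 0, 10))
    assert len(profiles) == 10
    assert all(p.depth == 0 and p.low_mapq_count == 0 for p in profiles)


def test_pileup_counts_low_mapq_subset(tmp_path):
    spec = [(100, "50M", 0, 0)] * 6 + [(100, "50M", 60, 0)]
    af = _write_bam(tmp_path, spec)
    (p,) = list(pileup_profile(af, "chr1", 120, 121))
    assert (p.depth, p.low_mapq_count) == (7, 6)


def test_pileup_read_cap_drops_overflow_deterministically(tmp_path):
    cfg = ClassificationConfig(locus_read_cap=10)
    af = _write_bam(tmp_path, [(100, "20M", 60, 0)] * 14)
    (p,) = list(pileup_profile(af, "chr1", 110, 111, cfg))
    assert p.depth == 10


def test_pileup_deletions_leave_coverage_gaps(tmp_path):
    af = _write_bam(tmp_path, [(0, "5M3D5M", 60, 0)])
    depths = [p.depth for p in pileup_profile(af, "chr1", 0, 13)]
    assert depths == [1] * 5 + [0] * 3 + [1] * 5


@pytest.mark.parametrize(
    "depth,low,expected",
    [
        (0, 0, DarkClass.DARK_BY_DEPTH),
        (4, 0, DarkClass.DARK_BY_DEPTH),  # depth precedence over MAPQ
        (4, 4, DarkClass.DARK_BY_DEPTH),
        (5, 4, DarkClass.RESOLVED),
        (10, 9, DarkClass.DARK_BY_MAPQ),  # 0.90 boundary is inclusive
        (10, 8, DarkClass.RESOLVED),
        (10, 10, DarkClass.DARK_BY_MAPQ),
    ],
)
def test_classify_locus_thresholds(depth, low, expected):
    assert classify_locus(LocusProfile("c", 0, depth, low)) is expected


def test_classification_partitions_every_locus(bamfile, synthetic_ref, config):
    """The three class counts must sum to the region length."""
    counts = {c: 0 for c in DarkClass}
    for p in pileup_profile(bamfile, synthetic_ref.chrom, 0, 5000, config):
        counts[classify_locus(p, config)] += 1
    assert sum(counts.values()) == 5000
    assert counts[DarkClass.RESOLVED] > 0


def test_profile_invariant_rejects_low_above_depth():
    with pytest.raises(ValueError):
        LocusProfile("c", 0, depth=3, low_mapq_count=4)


def _profiles(rows):
    return [LocusProfile("c", i, d, l) for i, (d, l) in enumerate(rows)]


def test_combine_single_sample_is_identity():
    rows = _profiles([(10, 2), (4, 0), (7, 7)])
    for mode in ("pooled", "quorum"):
        out = list(combine_samples([rows], CombinePolicy(mode=mode)))
        assert out == rows


def test_combine_pooled_unanimous_low_depth():
    samples = [_profiles([(4, 0)]) for _ in range(3)]
    (out,) = combine_samples(samples)
    assert out.depth == 4
    assert classify_locus(out) is DarkClass.DARK_BY_DEPTH


def test_combine_pooled_fraction_uses_pooled_counts():
    """Depths {10,10}, low {9,7}: pooled fraction 16/20 = 0.8 -> resolved."""
    samples = [_profiles([(10, 9)]), _profiles([(10, 7)])]
    (out,) = combine_samples(samples)
    assert (out.depth, out.low_mapq_count) == (10, 8)
    assert classify_locus(out) is DarkClass.RESOLVED


def test_combine_quorum_requires_enough_votes():
    dark = _profiles([(0, 0)])
    clean = _profiles([(10, 0)])
    policy = CombinePolicy(mode="quorum", quorum=0.5)
    (out,) = combine_samples([dark, dark, clean], policy)
    assert classify_locus(out) is DarkClass.DARK_BY_DEPTH
    (out,) = combine_samples([dark, clean, clean], policy)
    assert classify_locus(out) is DarkClass.RESOLVED


def test_combine_position_mismatch_is_an_error():
    a = [LocusProfile("c", 0, 5, 0)]
    b = [LocusProfile("c", 1, 5, 0)]
    with pytest.raises(ValueError, match="mismatch"):
        list(combine_samples([a, b]))


def test_profile_tsv_round_trip():
    rows = _profiles([(10, 2), (0, 0), (10000, 9999)])
    buf = io.StringIO()
    assert write_profiles(rows, buf) == 3
    buf.seek(0)
    assert list(read_profiles(buf)) == rows


def test_dark_depth_count_monotone_in_depth_threshold(bamfile, synthetic_ref):
    """Raising the depth threshold can only add dark-by-depth bases."""
    profiles = list(
        pileup_profile(bamfile, synthetic_ref.chrom, 15000, 20000)
    )
    counts = []
    for thr in (2, 5, 8):
        cfg = ClassificationConfig(depth_threshold=thr)
        counts.append(
            sum(
                classify_locus(p, cfg) is DarkClass.DARK_BY_DEPTH
                for p in profiles
            )
        )
    assert counts == sorted(counts)


def test_dark_mapq_count_antitone_in_fraction(bamfile, synthetic_ref):
    """Raising the low-MAPQ fraction can only remove dark-by-MAPQ bases."""
    profiles = list(
        pileup_profile(bamfile, synthetic_ref.chrom, 13000, 16500)
    )
    counts = []
    for frac in (0.5, 0.9, 1.0):
        cfg = ClassificationConfig(low_mapq_fraction=frac)
        counts.append(
            sum(
                classify_locus(p, cfg) is DarkClass.DARK_BY_MAPQ
                for p in profiles
            )
        )
    assert counts == sorted(counts, reverse=True)
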