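"""K-mer seeding, banded identity, and camouflage grouping."""

from __future__ import annotations

import random

import edlib
import pytest

from darkregions import (
    CamoConfig,
    DarkInterval,
    banded_identity,
    build_kmer_index,
    detect_camo,
    seeded_identity_search,
)
from darkregions.camo_detector import revcomp


def _random_seq(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(seq, n_subs, seed):
    rng = random.Random(seed)
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


# --- k-mer index -----------------------------------------------------------

def test_index_seed_count_is_length_minus_k_plus_one():
    seq = _random_seq(20, 1)
    idx = build_kmer_index({"c": seq}, k=15)
    forward = [hit for i in range(6) for hit in idx.lookup(seq[i : i + 15])
               if hit[2] == "+"]
    assert len(forward) >= 6  # every window retrievable


def test_index_absent_kmer_returns_nothing():
    idx = build_kmer_index({"c": "ACGT" * 10}, k=10)
    assert idx.lookup("A" * 10) == []


def test_index_finds_reverse_complement_occurrences():
    core = _random_seq(15, 2)
    seq = _random_seq(30, 3) + revcomp(core) + _random_seq(30, 4)
    idx = build_kmer_index({"c": seq}, k=15)
    hits = idx.lookup(core)
    assert ("c", 30, "-") in hits


def test_index_matches_brute_force_scan_on_both_strands():
    seq = _random_seq(300, 5)
    k = 12
    idx = build_kmer_index({"c": seq}, k=k)
    rng = random.Random(6)
    for _ in range(25):
        i = rng.randrange(len(seq) - k)
        probe = seq[i : i + k]
        expected = set()
        rc = revcomp(probe)
        for j in range(len(seq) - k + 1):
            window = seq[j : j + k]
            if window == probe:
                expected.add(("c", j, "+"))
            if window == rc:
                expected.add(("c", j, "-"))
        assert set(idx.lookup(probe)) == expected


def test_empty_reference_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        build_kmer_index({}, k=15)


# --- banded aligner vs full-alignment oracle -------------------------------

def full_dp_oracle(a, b):
    """Unbanded glocal DP: (min edit distance, max matches among optima).

    Independent O(n*m) reference for the banded implementation; the free
    b-ends convention matches (leading/trailing target bases cost nothing).
    """
    la, lb = len(a), len(b)
    prev = [(0, 0)] * (lb + 1)  # (distance, -matches); row 0 is free
    for i in range(1, la + 1):
        cur = [(prev[0][0] + 1, prev[0][1])] + [None] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            match = ai == b[j - 1]
            d, nm = prev[j - 1]
            best = (d + (not match), nm - match)
            d, nm = prev[j]
            if (d + 1, nm) < best:
                best = (d + 1, nm)
            d, nm = cur[j - 1]
            if (d + 1, nm) < best:
                best = (d + 1, nm)
            cur[j] = best
        prev = cur
    d, nm = min(prev)  # free suffix: end anywhere in b
    return d, -nm


@pytest.mark.parametrize("length", [60, 200, 450])
@pytest.mark.parametrize("n_subs", [0, 2, 10])
def test_banded_identity_equals_full_dp_oracle(length, n_subs):
    from darkregions.camo_detector import banded_alignment

    a = _random_seq(length, seed=length + n_subs)
    b_core = _mutate(a, n_subs, seed=n_subs + 1)
    b = _random_seq(30, 7) + b_core + _random_seq(30, 8)
    res = banded_alignment(a, b)
    d, m = full_dp_oracle(a, b)
    assert (res.distance, res.matches) == (d, m)
    assert res.identity == pytest.approx(m / (m + d), abs=1e-12)
    # external anchor: the minimum distance itself agrees with edlib
    assert res.distance == edlib.align(a, b, mode="HW")["editDistance"]


def test_banded_identity_handles_indels():
    from darkregions.camo_detector import banded_alignment

    a = _random_seq(300, 9)
    b = a[:100] + a[103:]  # 3-base deletion
    res = banded_alignment(a, b)
    d, m = full_dp_oracle(a, b)
    assert (res.distance, res.matches) == (d, m)
    assert res.distance == 3 and res.matches == 297


def test_identity_of_exact_copy_is_one():
    a = _random_seq(250, 10)
    identity, span = banded_identity(a, "TT" + a + "GG")
    assert identity == 1.0
    assert span == (2, 252)


# --- seeded search ---------------------------------------------------------

def _two_copy_reference(core_len=600, n_subs=0, seed=20):
    core = _random_seq(core_len, seed)
    copy = _mutate(core, n_subs, seed + 1) if n_subs else core
    seq = _random_seq(500, seed + 2) + core + _random_seq(800, seed + 3) + \
        copy + _random_seq(500, seed + 4)
    a = DarkInterval("c", 500, 500 + core_len, "dark_by_mapq")
    b = DarkInterval("c", 500 + core_len + 800,
                     500 + 2 * core_len + 800, "dark_by_mapq")
    return seq, a, b


def test_exact_copy_found_with_identity_one():
    seq, a, b = _two_copy_reference()
    idx = build_kmer_index({"c": seq}, k=15)
    hits = seeded_identity_search(seq[a.start : a.end], a, idx)
    assert len(hits) == 1
    h = hits[0]
    assert h.identity == 1.0 and h.orientation == "forward"
    assert (h.target_start, h.target_end) == (b.start, b.end)


def test_one_percent_divergence_kept_three_percent_dropped():
    for n_subs, expect_hit in ((6, True), (18, False)):  # of 600 bases
        seq, a, b = _two_copy_reference(n_subs=n_subs)
        idx = build_kmer_index({"c": seq}, k=15)
        hits = seeded_identity_search(seq[a.start : a.end], a, idx)
        assert bool(hits) is expect_hit
        if hits:
            assert hits[0].identity >= 0.98


def test_self_hit_is_suppressed():
    seq = _random_seq(2000, 30)
    iv = DarkInterval("c", 400, 1000, "dark_by_mapq")
    idx = build_kmer_index({"c": seq}, k=15)
    assert seeded_identity_search(seq[400:1000], iv, idx) == []


def test_hit_detection_is_symmetric_on_exact_copies():
    seq, a, b = _two_copy_reference()
    idx = build_kmer_index({"c": seq}, k=15)
    ab = seeded_identity_search(seq[a.start : a.end], a, idx)
    ba = seeded_identity_search(seq[b.start : b.end], b, idx)
    assert bool(ab) and bool(ba)
    assert (ab[0].target_start, ab[0].target_end) == (b.start, b.end)
    assert (ba[0].target_start, ba[0].target_end) == (a.start, a.end)


def test_reverse_complement_copy_is_found():
    core = _random_seq(600, 40)
    seq = _random_seq(400, 41) + core + _random_seq(700, 42) + \
        revcomp(core) + _random_seq(400, 43)
    iv = DarkInterval("c", 400, 1000, "dark_by_mapq")
    idx = build_kmer_index({"c": seq}, k=15)
    hits = seeded_identity_search(core, iv, idx)
    assert len(hits) == 1
    assert hits[0].orientation == "reverse-complement"
    assert hits[0].identity == 1.0
    assert (hits[0].target_start, hits[0].target_end) == (1700, 2300)


# --- grouping --------------------------------------------------------------

def test_three_mutual_copies_form_one_group():
    core = _random_seq(600, 50)
    gap1, gap2 = _random_seq(700, 51), _random_seq(900, 52)
    seq = _random_seq(300, 53) + core + gap1 + core + gap2 + core + \
        _random_seq(300, 54)
    starts = [300, 300 + 600 + 700, 300 + 600 + 700 + 600 + 900]
    ivs = [DarkInterval("c", s, s + 600, "dark_by_mapq") for s in starts]
    camo, groups, _ = detect_camo(ivs, {"c": seq})
    assert len(camo) == 3
    assert len(groups) == 1
    assert len(groups[0].members) == 3


def test_diverged_paralog_stays_dark_but_not_camo():
    seq, a, b = _two_copy_reference(n_subs=18)  # 97% identity
    camo, groups, _ = detect_camo([a, b], {"c": seq})
    assert camo == [] and groups == []


def test_camo_is_subset_of_mapq_track(synthetic_ref, config):
    from darkregions.synthetic_data import truth_dark_regions

    truth = truth_dark_regions(synthetic_ref, config)
    mapq = truth.dark["dark_by_mapq"]
    camo, _, _ = detect_camo(mapq, {synthetic_ref.chrom: synthetic_ref.sequence})
    camo_bases = sum(iv.length for iv in camo)
    mapq_bases = sum(iv.length for iv in mapq)
    assert camo_bases <= mapq_bases
    assert set(camo) <= set(mapq)


def test_interval_outside_reference_is_an_error():
    with pytest.raises(ValueError, match="outside"):
        detect_camo(
            [DarkInterval("c", 0, 100, "dark_by_mapq")], {"c": "ACGT" * 10}
        )
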