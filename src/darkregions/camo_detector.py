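"""Camouflaged-region detection.

A *camouflaged* region is a dark-by-MAPQ region whose sequence is at
least 98% identical to at least one other genomic locus — the reads are
present but cannot be apportioned among near-identical copies.  Detection
is a self-contained seed-and-extend pipeline: exact k-mer seeds on both
strands locate candidate copies, and a banded global aligner (unit
match/mismatch/gap costs) scores each candidate, with identity defined as
matches over alignment columns (gap columns count in the denominator).
Mutually similar regions are grouped into camo sets by connected
components of the query-target link graph, so three mutually similar
copies form one group of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .region_builder import DarkInterval

__all__ = [
    "CamoConfig",
    "SimilarityHit",
    "CamoGroup",
    "build_kmer_index",
    "KmerIndex",
    "AlignResult",
    "banded_alignment",
    "banded_identity",
    "seeded_identity_search",
    "detect_camo",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CamoConfig:
    """Similarity-search parameters.

    identity_threshold
        Minimum alignment-column identity for a hit (default 0.98).
    min_query_coverage
        Minimum fraction of the query that must align (default 0.90).
    kmer_size
        Exact seed length (default 15); smaller is more sensitive but
        slower.
    flank
        Bases of context added around each candidate target window before
        alignment so the banded path can anchor across interval edges
        (default 50); flank columns never enter the identity.
    min_seeds
        Minimum co-diagonal seeds for a candidate locus (default 3).
    """

    identity_threshold: float = 0.98
    min_query_coverage: float = 0.90
    kmer_size: int = 15
    flank: int = 50
    min_seeds: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.kmer_size < 8:
            raise ValueError("kmer_size must be >= 8")


@dataclass(frozen=True)
class SimilarityHit:
    query: DarkInterval
    target_chrom: str
    target_start: int
    target_end: int
    identity: float
    query_coverage: float
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class CamoGroup:
    group_id: int
    members: Tuple[Tuple[str, int, int], ...]  # merged (chrom, start, end)


class KmerIndex:
    """Exact k-mer -> occurrence index over a reference.

    Forward k-mers are stored; reverse-complement occurrences are found by
    looking up the reverse complement of the probe, so every occurrence on
    either strand is retrievable without double storage.  K-mers containing
    ambiguous bases are not indexed.
    """

    def __init__(self, sequences: Mapping[str, str], k: int):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty reference")
        self.k = k
        self.sequences = {c: str(s).upper() for c, s in sequences.items()}
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def lookup(self, kmer: str) -> List[Tuple[str, int, str]]:
        """All occurrences of *kmer* as ``(chrom, pos, strand)``.

        ``strand`` is ``+`` where the reference holds the k-mer itself and
        ``-`` where it holds its reverse complement.
        """
        kmer = kmer.upper()
        out = [(c, p, "+") for c, p in self._index.get(kmer, ())]
        out += [(c, p, "-") for c, p in self._index.get(revcomp(kmer), ())]
        return out


def build_kmer_index(
    sequences: Mapping[str, str], k: int = 15
) -> KmerIndex:
    """Build a :class:`KmerIndex`; *sequences* maps name -> sequence."""
    return KmerIndex(sequences, k)


_INF = np.int64(1) << 60


@dataclass(frozen=True)
class AlignResult:
    """Outcome of aligning a query globally into a target window.

    Among all minimum-edit-distance alignments the one with the most
    matches is reported, which makes ``identity`` a well-defined quantity
    (optimal edit paths can differ in their match counts).
    """

    identity: float  # matches / alignment columns (gaps count)
    distance: int  # in-alignment edits (mismatches + gaps)
    matches: int
    columns: int  # = matches + distance
    b_span: Tuple[int, int]  # half-open span of b used by the alignment


def _dp_end(a: str, b: str, band: int, free_b_ends: bool):
    """Banded DP; returns ``(score, j_end)`` or None when b is unreachable.

    Scores encode the lexicographic objective (minimise edit distance,
    then maximise matches) in one integer: ``v = distance * M - matches``
    with ``M`` larger than any achievable match count, so a plain integer
    minimum realises the lexicographic optimum and both components are
    recoverable from ``v``.
    """
    la, lb = len(a), len(b)
    M = 4 * (la + lb) + 8
    lo = min(0, lb - la) - band
    hi = max(0, lb - la) + band
    w = hi - lo + 1
    bv = np.frombuffer(b.encode("ascii"), dtype="S1")
    av = np.frombuffer(a.encode("ascii"), dtype="S1")
    ks = np.arange(w, dtype=np.int64)
    ramp = ks * M
    # row 0: entering at column j costs nothing (free prefix) or j gaps
    j0 = lo + ks
    prev = np.full(w, _INF, dtype=np.int64)
    valid0 = (j0 >= 0) & (j0 <= lb)
    prev[valid0] = 0 if free_b_ends else j0[valid0] * M
    for i in range(1, la + 1):
        j = i + lo + ks
        valid = (j >= 0) & (j <= lb)
        # diagonal: consume a[i-1] and b[j-1]
        jj = np.clip(j - 1, 0, lb - 1)
        match = bv[jj] == av[i - 1]
        diag = prev + np.where(match, -1, M)
        diag[(j < 1) | ~valid | (prev >= _INF)] = _INF
        # gap in b: consume a[i-1] only (predecessor is (i-1, j) = k+1)
        up = np.concatenate((prev[1:], [_INF])) + M
        up[~valid | (up >= _INF)] = _INF
        t = np.minimum(diag, up)
        # gap in a: consume b only; within-row prefix-min scan
        row = np.minimum.accumulate(t - ramp) + ramp
        row[~valid] = _INF
        prev = row
    j_last = la + lo + ks
    ok = (j_last >= 0) & (j_last <= lb) & (prev < _INF)
    if free_b_ends:
        if not ok.any():
            return None
        masked = np.where(ok, prev, _INF)
        k_best = int(np.argmin(masked))
        return int(masked[k_best]), int(j_last[k_best])
    k_end = lb - la - lo
    if not (0 <= k_end < w) or prev[k_end] >= _INF:
        return None
    return int(prev[k_end]), lb


def banded_alignment(
    a: str, b: str, *, free_b_ends: bool = True, band: int | None = None
) -> AlignResult:
    """Align *a* globally into *b* (free *b* ends by default).

    Unit mismatch/gap costs; among minimum-cost alignments the one with
    the most matches is scored.  The band starts near the length
    difference and doubles until the optimum provably fits inside it, so
    the result equals an unbanded dynamic program.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        return AlignResult(0.0, 0, 0, 0, (0, 0))
    la, lb = len(a), len(b)
    M = 4 * (la + lb) + 8
    cur = band or max(8, abs(la - lb) + 2)
    limit = la + lb + 2
    while True:
        res = _dp_end(a, b, cur, free_b_ends)
        if res is not None:
            v, j_end = res
            dist = -(-v // M)  # ceil: v = dist*M - matches, 0 <= matches < M
            matches = dist * M - v
            if dist < cur:
                # locate the start column by aligning the reversed strings
                rv, j_end_rev = _dp_end(a[::-1], b[::-1], cur, free_b_ends)
                j_start = lb - j_end_rev if free_b_ends else 0
                if j_start >= j_end:  # degenerate all-gap alignment
                    j_start, j_end = j_end, j_end
                columns = matches + dist
                identity = matches / columns if columns else 0.0
                return AlignResult(
                    identity, dist, matches, columns, (j_start, j_end)
                )
        if cur > limit:
            return AlignResult(0.0, la + lb, 0, la + lb, (0, lb))
        cur *= 2


def banded_identity(
    a: str, b: str, *, free_b_ends: bool = True, band: int | None = None
) -> Tuple[float, Tuple[int, int]]:
    """Alignment-column identity of *a* against *b* and the *b* span used.

    Identity is matches / alignment columns, counting gap columns in the
    denominator; see :func:`banded_alignment` for the exact objective.
    """
    res = banded_alignment(a, b, free_b_ends=free_b_ends, band=band)
    return res.identity, res.b_span


def _cluster_diagonals(
    positions: Sequence[int], gap: int
) -> List[List[int]]:
    """Group sorted diagonal values whose neighbours differ by <= gap."""
    clusters: List[List[int]] = []
    for v in sorted(positions):
        if clusters and v - clusters[-1][-1] <= gap:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def seeded_identity_search(
    query_seq: str,
    query: DarkInterval,
    index: KmerIndex,
    config: CamoConfig = CamoConfig(),
) -> List[SimilarityHit]:
    """Find loci whose sequence matches *query_seq* above the thresholds.

    Seeds are exact k-mers shared with the reference (both strands),
    clustered by alignment diagonal; each cluster with at least
    ``min_seeds`` seeds nominates a target window that is scored with the
    banded aligner.  Hits overlapping the query's own locus are suppressed.
    Zero hits is a valid result.
    """
    q = query_seq.upper()
    k = index.k
    if len(q) < k:
        return []
    # (chrom, strand) -> list of (diag, query_offset)
    seeds: Dict[Tuple[str, str], List[int]] = {}
    for i in range(len(q) - k + 1):
        kmer = q[i : i + k]
        if "N" in kmer:
            continue
        for chrom, pos, strand in index.lookup(kmer):
            # forward: target start of the full query ~ pos - i
            # reverse: anti-diagonal pos + i + k ~ target end of the query
            key = (chrom, strand)
            diag = pos - i if strand == "+" else pos + i + k
            seeds.setdefault(key, []).append(diag)
    hits: List[SimilarityHit] = []
    pad = config.flank + max(8, len(q) // 50)
    for (chrom, strand), diags in seeds.items():
        ref = index.sequences[chrom]
        for cluster in _cluster_diagonals(diags, gap=2 * k):
            if len(cluster) < config.min_seeds:
                continue
            if strand == "+":
                t0 = max(0, min(cluster) - pad)
                t1 = min(len(ref), max(cluster) + len(q) + pad)
            else:
                t0 = max(0, min(cluster) - len(q) - pad)
                t1 = min(len(ref), max(cluster) + pad)
            if chrom == query.chrom and t0 < query.end and t1 > query.start:
                continue  # self-hit
            window = ref[t0:t1]
            if strand == "-":
                window = revcomp(window)
            identity, (js, je) = banded_identity(q, window)
            if strand == "+":
                t_start, t_end = t0 + js, t0 + je
            else:
                t_start, t_end = t1 - je, t1 - js
            coverage = min(1.0, (je - js) / len(q)) if je > js else 0.0
            if (
                identity >= config.identity_threshold
                and coverage >= config.min_query_coverage
            ):
                hits.append(
                    SimilarityHit(
                        query=query,
                        target_chrom=chrom,
                        target_start=t_start,
                        target_end=t_end,
                        identity=identity,
                        query_coverage=coverage,
                        orientation="forward" if strand == "+" else "reverse-complement",
                    )
                )
    # deduplicate overlapping windows, keeping the best identity
    hits.sort(key=lambda h: (-h.identity, h.target_chrom, h.target_start))
    kept: List[SimilarityHit] = []
    for h in hits:
        if any(
            h.target_chrom == o.target_chrom
            and h.target_start < o.target_end
            and h.target_end > o.target_start
            for o in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.target_chrom, h.target_start))
    return kept


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[int, int] = {}

    def find(self, x: int) -> int:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def detect_camo(
    mapq_intervals: Sequence[DarkInterval],
    sequences: Mapping[str, str],
    config: CamoConfig = CamoConfig(),
) -> Tuple[List[DarkInterval], List[CamoGroup], List[SimilarityHit]]:
    """Classify dark-by-MAPQ intervals as camouflaged and group them.

    Returns ``(camo_intervals, groups, hits)``: the subset of inputs with
    at least one qualifying similarity hit, the connected components of
    the query-target link graph (targets merged with overlapping member
    loci), and the raw hits.  An interval outside the reference bounds
    raises ``ValueError``.
    """
    seqs = {c: str(s).upper() for c, s in sequences.items()}
    for iv in mapq_intervals:
        if iv.chrom not in seqs or iv.end > len(seqs[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside reference"
            )
    index = build_kmer_index(seqs, config.kmer_size)
    all_hits: List[SimilarityHit] = []
    camo: List[DarkInterval] = []
    # node universe: query intervals first, then novel target loci
    nodes: List[Tuple[str, int, int]] = [
        (iv.chrom, iv.start, iv.end) for iv in mapq_intervals
    ]

    def node_for(chrom: str, start: int, end: int) -> int:
        for idx, (c, s, e) in enumerate(nodes):
            if c == chrom and start < e and end > s:
                return idx
        nodes.append((chrom, start, end))
        return len(nodes) - 1

    uf = _UnionFind()
    for qi, iv in enumerate(mapq_intervals):
        hits = seeded_identity_search(
            seqs[iv.chrom][iv.start : iv.end], iv, index, config
        )
        if hits:
            camo.append(iv)
            all_hits.extend(hits)
            for h in hits:
                ti = node_for(h.target_chrom, h.target_start, h.target_end)
                uf.union(qi, ti)
    comp: Dict[int, List[int]] = {}
    for idx in range(len(nodes)):
        if idx in uf.parent:
            comp.setdefault(uf.find(idx), []).append(idx)
    groups: List[CamoGroup] = []
    gid = 0
    for root in sorted(comp, key=lambda r: min(comp[r])):
        members = sorted(nodes[i] for i in comp[root])
        if len(members) < 2:
            continue
        groups.append(CamoGroup(group_id=gid, members=tuple(members)))
        gid += 1
    return camo, groups, all_hits
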