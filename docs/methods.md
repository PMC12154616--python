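# Methods

## Per-base classification model

Every reference base in a region receives exactly one class from two
quantities accumulated over filtered alignment records: depth (number of
covering reads) and low-MAPQ count (covering reads with mapping quality
below `mapq_threshold`).  A read covers a base only through alignment
match columns (CIGAR M/=/X); deletions, reference skips, clips and
insertions contribute nothing.

* `depth < depth_threshold` (default 5) -> **dark-by-depth**;
* else `low_mapq_count / depth >= low_mapq_fraction` (default 0.90,
  inclusive) -> **dark-by-MAPQ**;
* else **resolved**.

Depth takes precedence, making the three classes a partition: per-class
base counts always sum to the region length, and all-dark totals are
exactly the sum of the two dark classes.  The depth and MAPQ cuts are
strict (`< 5`, `< 10`) while the fraction cut is inclusive (`>= 0.90`),
so a 9-of-10 low-MAPQ locus is dark and an 8-of-10 locus is not.

Record filtering: unmapped, secondary, duplicate-flagged and QC-fail
records are always excluded (the latter two configurable); supplementary
records are excluded under `primary` mode and admitted under
`primary+supplementary`.  Secondary alignments are never counted in any
mode because they re-place a read whose primary placement is already
counted, whereas a supplementary record covers reference bases its
primary does not.  Filtering is monotone in the mode, which yields a
provable invariant: switching to `primary+supplementary` can only add
coverage, so single-sample dark-by-depth content never grows.

At most `locus_read_cap` reads (default 10,000) accumulate per locus;
overflow reads are dropped at that locus in coordinate order.  The cap
bounds memory over collapsed repeats where supplementary inclusion can
multiply depth; capped loci are classified from the capped counts with
no rescaling.  The cap applies to total accumulated reads, before any
MAPQ partitioning.

## Multi-sample combination

Two rules are provided because the right pooling semantics are a
genuine design choice:

* **pooled** (default): combined depth is the rounded mean of
  per-sample depths; the combined low-MAPQ count is that mean scaled by
  the pooled fraction (sum of low counts over sum of depths), i.e. the
  samples are treated as one library sequenced at average depth.
  Rounding is half-up for determinism across platforms.
* **quorum**: a position is dark of class *c* iff at least a `quorum`
  fraction of samples classify it *c* individually; a minimal sentinel
  profile realising the class is emitted.

Both require identical position universes across samples; the first
discordant position is an error rather than a silent join.

## Interval construction and statistics

Classified loci are merged streamingly into maximal runs per class;
the all-dark track merges runs of any non-resolved class, so a depth run
abutting a MAPQ run fuses into one region (hence all-dark region counts
are subadditive while base counts are exactly additive).  Intervals are
BED 0-based half-open, sorted by (sequence, start); unsorted input fails
at the first inversion.  Summaries report total bases, region count,
mean length (bases/regions) and median length (midpoint-averaged for
even counts), printed to two decimals with full precision kept
internally.  The >= 20-contiguous-base rule is *not* applied to
genome-wide totals — only to gene counting — so genome-wide medians can
be small.

## Gene-body reporting

Gene bodies are the full annotated gene extent including introns; GFF3
1-based inclusive coordinates are converted to 0-based half-open on
read.  Per gene, each class's intervals are clipped to the gene body and
re-merged before evaluation, so the >= `min_region_len` (20) flag is
invariant to how callers may have split a maximal run, and a long
interval with fewer than 20 in-gene bases does not count.  Fraction
flags compare `bases/gene_len >= 0.05`; "100% camouflaged" requires the
camo overlap to equal the gene length exactly.  The "any dark region"
gene flag is defined as the disjunction of the per-class flags, which
makes gene counting satisfy inclusion-exclusion exactly:
`|depth genes| + |MAPQ genes| - |both| = |any dark genes|`.  Genes on
sequences absent from the classification universe produce zero-filled
reports (alt-contig robustness), not errors.  Overlapping genes are
reported independently; shared bases are not deduplicated.  Per-gene
percentages are computed against the combined (multi-sample) track.

## Camouflage detection

Camouflaged regions are dark-by-MAPQ intervals >= 98% identical to at
least one other locus.  Detection is a self-contained seed-and-extend
search rather than an external aligner dependency; the only
biologically fixed parameter is the 98% identity threshold.

1. **Seeding** — every exact k-mer (default k = 15) of the query is
   looked up in a forward-strand index of the reference; reverse-
   complement occurrences are found by probing the reverse complement of
   the k-mer.  Hits are clustered by alignment diagonal (anti-diagonal
   for the reverse strand); clusters with fewer than `min_seeds` (3)
   seeds are discarded as noise.
2. **Extension** — each cluster nominates a target window (padded by
   `flank`, default 50 bases, so the alignment can anchor across the
   interval edges; the padding is on the target side and never enters
   the identity).  The query is aligned globally into the window with
   free target ends, unit mismatch/gap costs, by a banded dynamic
   program whose band starts near the length difference and doubles
   until the optimum provably fits, so results equal an unbanded DP.
3. **Identity** — among all minimum-edit-distance alignments the one
   with the most matches is scored (optimal edit paths differ in match
   counts, so this tie-break is what makes "identity" well defined; it
   is implemented exactly via a lexicographic integer encoding, not
   heuristically).  Identity = matches / alignment columns, gap columns
   counted in the denominator — the stricter of the common conventions.
   Hits require identity >= 0.98 and query coverage >= 0.90, and a
   target overlapping the query's own locus is suppressed.
4. **Grouping** — camo groups are connected components of the
   query-target link graph (targets merged with overlapping member
   loci), so three mutually similar copies form one group of three.

Limitations: no translated search, no exhaustive tiling of very long
windows, and a target window wide enough to touch the query's own locus
is skipped with it (relevant only for near-adjacent tandem copies).

## Synthetic fixtures and what they show

The generator plants each cause of darkness with a deterministic rule
so the expected classification is derivable from tiling geometry alone,
without running the pipeline's alignment parsing, pileup, or merging:

* reads tile the genome every `read_len/depth` bases, with starts
  hanging off both ends clipped, so a fully unique genome is covered at
  exactly the target depth everywhere (empty truth);
* reads wholly inside a duplication family get MAPQ 0, others 60 — the
  footprint of ambiguity, not an aligner simulation;
* deletion and low-coverage zones drop or clamp overlapping reads, with
  flank effects that follow from the tiling arithmetic;
* reads crossing an inversion-zone boundary are emitted as a
  soft-clipped primary plus a reverse-strand supplementary record, so
  the zone is a dark-by-depth hole under primary-only filtering that
  closes exactly when supplementary records are admitted;
* duplication copies are substituted at a per-copy rate with recorded
  positions, so expected camo status (98% bar) is known by
  construction.

Default study conditions: a 42,300-base genome containing every zone
type, 500-base reads at 10x tiling, a 2x-clamped low-coverage zone, a
300-base inversion, and duplication families at 0% and 5% divergence;
planted genes straddle the truth boundaries (a clean gene, a 100%
camouflaged gene, a gene with both dark classes, a ~6% dark gene, a
19-base-overlap gene just under the 20-base rule, and a gene on an
absent contig).  These sizes exercise every code path in well under a
minute of test time.

What the fixtures do **not** emulate: sequencing errors and base
qualities, read-length and fragment-size distributions, diploid
genotypes, aligner-specific MAPQ calibration, or the scale of a real
genome.  Passing the truth-recovery tests therefore demonstrates that
the classification, merging, annotation and camouflage logic are exact
on alignments with known properties — not that any particular aligner
produces those properties on real data.

## Comparison layer

Resolution percent is `100 x (1 - other/baseline)` against the stated
baseline platform on the same reference and class; fold change is the
plain ratio.  Both round half-up to one decimal (two decimals for table
means/medians), matching conventional reporting precision.  Mode deltas
are supplementary-minus-primary, negative meaning supplementary
inclusion resolved dark content.  The published per-platform/
per-reference summary grids (primary-only and with-supplementary) ship
as package data; the bundled worked examples recompute from them at run
time — resolution 62.1% / 69.6% (PacBio / ONT vs Illumina100
dark-by-MAPQ bases on CHM13), fold changes 3.3x and 3.4x, and deltas
-15,533,421 / +1,911,880 bases.

## Numerical choices

* Half-up rounding everywhere a printed decimal is produced (banker's
  rounding would make printed values platform-lore dependent).
* Empty interval sets summarise as zeros (mean/median reported as 0).
* The banded aligner widens its band geometrically and only accepts a
  result whose distance is strictly inside the band, guaranteeing
  equality with the unbanded optimum.
* Degenerate inputs fail loudly: empty reference, unsorted loci,
  missing alignment index, unknown CIGAR op, position-discordant
  samples, unknown count criterion.
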