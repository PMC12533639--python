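# Methods

## The detection problem

Extrachromosomal circular DNA (eccDNA) consists of small circular elements
(typically hundreds of bp to a few kb) excised from chromosomal sequence.
Circle-enriched sequencing libraries are prepared by digesting linear DNA
with exonuclease, amplifying the surviving circles by rolling-circle
amplification (RCA), and paired-end sequencing the amplicons.  Because the
circular template has no ends, a sequenced fragment can span the circle's
start/end junction, producing two alignment signatures on the linear
reference that `eccpipe` detects:

1. **Split reads.** A read that crosses the junction aligns in two parts:
   its leading bases match at the circle end (right soft-clipped) and the
   clipped tail matches at the circle start (left-clipped supplementary on
   the same chromosome and strand).  If the circle occupies `[s, e)`, the
   left-clipped segment starts exactly at `s` and the right-clipped
   segment ends exactly at `e`, so split reads place both breakpoints at
   base resolution.  The mirror geometry (leading segment upstream) is the
   signature of a linear deletion, not a circle, and is discarded.
2. **Outward-facing pairs.** An FR (innie) Illumina pair whose fragment
   spans the junction without either read crossing it appears in RF
   orientation in linear coordinates: the leftmost mate (near the circle
   start) on the minus strand, the rightmost (near the circle end) on
   plus.  Such a pair bounds the junction to within one insert length;
   it corroborates a circle but cannot place breakpoints precisely.
3. **Coverage enrichment.** RCA concentrates reads on circle intervals;
   mean depth over a candidate interval is compared with the genome-wide
   background (median depth over 50-bp bins plus a pseudocount of
   0.01 reads/bp, so the background is defined even when most of the
   genome is read-free, as it is in a well-digested circle library).

## Coordinate conventions

All intervals are 0-based half-open internally, so `length = end − start`.
GFF3 I/O converts to/from the on-disk 1-based inclusive convention; BED
output is 0-based half-open, so BED `end − start` equals the reported
length directly.

## Calling procedure

Split-read junction evidence is grouped per chromosome and single-linkage
clustered: two junctions are linked when both their start and their end
coordinates agree within the tolerance ε (default 5 bp).  The clustering
is implemented as a sorted sweep over starts with a union-find, which is
exactly the transitive closure of the ε-link relation (verified against a
brute-force O(n²) closure in the tests).  Each cluster's candidate
breakpoints are the integer medians of its members' coordinates.

A discordant pair is assigned to a candidate when its evidence interval
sits inside the candidate within the expected geometry: its start within
`[candidate start − ε, candidate start + max_insert + ε]` and its end
within `[candidate end − max_insert − ε, candidate end + ε]`, where
`max_insert` (default 1000 bp) is the upper truncation of the library
insert distribution.

A candidate becomes a call iff

* `split_support ≥ min_split` (default 2), **or**
  `split_support ≥ 1` and `discordant_support ≥ 2`; and
* enrichment = mean depth / background ≥ `min_enrichment` (default 2.0); and
* `min_circle_len ≤ length ≤ max_circle_len` (defaults 200 bp, 10 Mb).

Discordant pairs alone never produce a call: their breakpoint resolution
is limited by the insert size, and letting them call would inflate counts
of "unique" circles with poorly localized duplicates.  Calls agreeing
within ε on both breakpoints are merged with supports summed.  Every
rejection is tallied by reason in the QC output.  The defaults are
deliberately split-read-driven: in a circle-enriched library almost all
coverage is on circles, so depth separates circles from background poorly
while clip geometry separates them exactly.

Multi-segment circles (junctions joining distant loci) are out of scope:
cross-chromosome and cross-strand split pairs are tallied, not called.
Hard clips are treated as soft clips for geometry; insertions/deletions
within a segment are accepted and only reference-consuming ops contribute
to segment spans.

## The simulator

The simulator is the package's source of ground truth and emulates the
library, not the machine:

* **Circle lengths** follow a log-normal with median 1500 bp and shape
  σ=0.8, truncated to [300, 10000] bp.  The analytic mass of this
  distribution on [400, 6000) is 0.94, matching the observation that the
  large majority of circles in circle-enriched libraries fall in that
  band.  Lengths are drawn by inverse-CDF sampling, so the sampled
  distribution is exact up to bp rounding.
* **Origin classes** default to intergenic 60%, partial-gene 39.6%,
  full-gene 0.4%: real catalogs are overwhelmingly intergenic/partial with
  full-gene circles at the level of a few per thousand.  Class placement
  is by rejection sampling against the gene annotation; circles are
  placed mutually non-overlapping with a 1 kb separation guard so that
  every call can be attributed to exactly one truth circle when
  benchmarking.
* **RCA** is modeled as tandem concatemerization: each fragment is drawn
  from a concatemer of `k` copies of the circle, `k = 1 + Geometric(p)`
  with mean ≈ `rca_fold` (default 10) and minimum 2, then fragmented
  uniformly with normal insert sizes (350 ± 50, truncated to
  [200, 1000] bp).  No strand-displacement branching is modeled: tandem
  repetition already produces both diagnostic signatures, and branching
  parameters would be unidentifiable from short reads anyway.
* **Reads** are 150 bp from fragment ends in FR orientation; which
  physical end is "read 1" is random.  Sequencing error is
  substitution-only at rate 0.001/base by default (no indels, all
  qualities Q30): the caller's evidence is clip- and orientation-based,
  so indel/quality realism would add parameters without exercising any
  decision path.
* **Background**: a binomial fraction (default 1%) of pairs are uniform
  linear genomic fragments, standing in for incomplete exonuclease
  digestion.  They produce proper FR pairs and no junction evidence.
* **Truth SAM**: the simulator emits its own alignments (flags,
  CIGARs, SA tags, mate fields) since template positions are known
  exactly.  This removes the external aligner from the test loop; FASTQ
  is also written for users who want to run a real aligner, whose output
  feeds the same caller provided it emits supplementary alignments.

What passing tests on this simulator do **not** show: robustness to
mapping ambiguity in repeats, chimeric artifacts between different
circles, PCR duplicates, GC coverage bias, or indel-containing junctions.
On real data those effects make both recall and precision worse than the
synthetic benchmarks; the thresholds are configurable for that reason.

## Synthetic reference

Reference chromosomes are i.i.d. bases at a target GC (no repeats, no N),
and gene models are non-overlapping and single-transcript with features
(5′UTR, exons, introns, 3′UTR) exactly tiling the gene span.  Non-overlap
keeps the content classification single-valued; alternative isoforms
would make the full/partial/intergenic trichotomy ambiguous without
adding information at this scale.

## Annotation layer

Gene content of a call: `full_gene` iff ≥1 gene span is fully contained
in the call (containment wins over any partial overlaps); `intergenic`
iff no gene span is overlapped; otherwise `partial_gene` subtyped by the
feature kind with the largest overlapped base count, ties broken
intronic > exonic > 5′UTR > 3′UTR (the dominant-overlap rule is the least
arbitrary single-label rule; the tie order favors the empirically
dominant intronic class).  "Intergenic" is defined against gene spans
(UTR to UTR), not exons.  Percentages are rendered at 2 significant
figures.  Length histograms use half-open 200-bp bins, and the
400–6000 bp band fraction is likewise half-open `[400, 6000)`; boundary
inclusion is a declared convention, not an inference.

The chromosome-of-origin check compares observed per-chromosome counts
with expectations proportional to chromosome length via a chi-square
goodness-of-fit test, flagging cells with expected count < 1.

## Cohort layer

Two-group comparisons use the classical pooled-variance unpaired
two-sided Student's t test (Welch available behind a flag); more than two
groups use one-way ANOVA.  When both groups have zero variance the
statistic is defined directly (0 with equal means, ±∞ otherwise) rather
than propagating a 0/0.  Fold change is the ratio of arithmetic group
means.  Correlations are Pearson's r with R² and the two-sided p from the
t transform.  No multiple-testing correction is applied by default;
Benjamini–Hochberg can be applied downstream by the user if many markers
are tested.

Median stratification labels samples strictly above the median
circle-high and strictly below circle-low; samples exactly at the median
are assigned alternately low-then-high in row order, each tie going to
the currently smaller side, which keeps `|high| − |low| ≤ 1` even when
many samples tie.  An all-identical column is rejected as a degenerate
split.

The expression co-simulator generates marker expression as
`x_gs = α_g + β·burden_s + N(0, σ²)`; with σ=0 the sample correlation is
exactly 1, and the (β, σ) pairs used in validation are chosen to give
known population correlations so that recovery can be checked against
Fisher-z sampling intervals computed before the runs.

## Problem sizes and numerical choices

The validation workflow uses a 3 Mb two-chromosome genome with 40 genes,
50-circle libraries at ~40× per-circle coverage (about 10–12k read
pairs), chosen so the full simulate–call–annotate–compare loop and all
oracle comparisons complete in seconds while every evidence path (splits,
outward pairs, enrichment, background rejection) is exercised with
comfortable margins.  Integer medians (floor at half-integers) make
cluster breakpoints deterministic; catalog TSVs store float fields with
`repr` so round-trips are exact; all random draws flow from a single
`numpy` `default_rng` seed per component, making every artifact
byte-reproducible.

## Known limitations

* The caller requires an aligner that emits supplementary alignments
  (SA-tag style) when run on real FASTQ; soft-clipped tails are not
  realigned internally.
* No cross-sample deduplication: "unique eccDNA" is a per-sample notion.
* Breakpoint homology (microhomology at the junction making the split
  position ambiguous by a few bp) is not simulated; on real data it
  widens breakpoint scatter and is absorbed by ε.
* Copy-number estimation of amplified circles and reconstruction of
  multi-fragment circles are out of scope.
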