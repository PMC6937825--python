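# Methods

## The model system

*Oxytricha trifallax* and related ciliates keep two genomes: a silent
germline and a working somatic genome consisting of ~20,000 distinct
"nanochromosomes" averaging ~3.2 kb, each capped by telomeric repeats
(C4A4 on the 5' strand, G4T4 on the 3' strand) and amplified to a mean
copy number around 2000n with order-of-magnitude heterogeneity. Because
a single long read can span an entire nanochromosome, a read carrying
telomeric tracts at both termini *is* a complete chromosome, and most of
the genome can be sequenced without assembly. Two complications make the
analysis interesting: roughly a quarter of chromosomes exist as
alternative-fragmentation isoforms (different breakpoint / telomere-
addition choices over the same germline region, sometimes recombining
segments from two paralogous germline loci), and the extreme copy-number
spread starves low-abundance chromosomes of coverage.

This package implements that capture strategy end to end, driven by a
synthetic-data generator so every stage is testable without the original
sequencing data.

## Pipeline

1. **Telomere detection** (`telomere`). Terminal tracts are found by an
   approximate motif scan: four 12-mer cores of the telomeric repeat
   (`TTTTGGGGTTTT`, `GGGGTTTTGGGG`, `AAAACCCCAAAA`, `CCCCAAAACCCC`) at
   unit-cost edit distance ≤ 2 within a 100-bp terminal window. The
   flanking homopolymeric classes (`[TG]*` / `[AC]*`) extend the reported
   span at zero cost but never absorb edits — a literal reading would let
   long homopolymers soak up the mismatch budget. A terminal match must
   additionally reach within `anchor_slack` (16 bp) of the read end:
   a telomere is a terminal structure, and anchoring is what drives the
   false two-telomere rate on motif-free 3-kb sequence to 0/10,000
   (unanchored, the measured rate is ~0.15%: 12-mer edit-2 neighborhoods
   are not rare). Internal (chimera-diagnostic) patterns use the two
   embedded-tract cores at edit distance 1 and the two fused junction
   cores at edit distance 3, excluded from the terminal windows.

   The scan itself is a semi-global DP over all end positions with start
   recovery (numba-compiled); edlib serves as the independent oracle in
   tests, never as the implementation of this primitive.

   Note on orientation: the C-rich and G-rich pattern families are mutual
   reverse complements, so a complete chromosome reads C-rich at 5' and
   G-rich at 3' on *either* strand. Orientation of a two-telomere read is
   therefore representation-neutral; strand is canonicalized at alignment
   time (both strands tried everywhere), and `orient_read` only matters
   for partial reads.

2. **QC** (`qc`). Reads are dropped, with one first-triggered reason each,
   in the fixed order: shorter than 300 bp; homopolymer run strictly
   longer than 10 bp; any internal telomere match (chimeras); telomere-
   only (masking leaves < 50 bp of core). The order is a package choice —
   first-trigger attribution keeps the report additive.

3. **Capture** (`capture`). Two-telomere reads become chromosome records
   (telomeres retained in `bases`, trimmed `core` stored alongside).
   Exact duplicates and exact substrings on either strand collapse onto
   the longest survivor, summing support. Greedy centroid clustering at
   90% identity runs on telomere-trimmed cores, longest record first
   (then support, then id); identity is computed with the shorter
   sequence aligned as an infix of the centroid and terminal gaps
   excluded from the denominator, the convention of centroid-clustering
   tools. This matters: a shorter isoform is a sub-span of its
   full-length family and must join that cluster rather than found a new
   "chromosome". Within the alignment, identity is matches over all
   alignment columns, so indels dilute identity everywhere in the
   package.

4. **Isoform detection** (`isoforms`). Masked records map against the
   centroid set (best = longest reference span; ties by identity then
   ref id; accepted at ≥ 80% identity). Hits on one reference group by
   endpoints: the first unassigned hit (sorted by start, end, id) anchors
   a group and others join iff both endpoints are within 50 bp of the
   anchors — seed-anchored rather than single-linkage, so group diameter
   is bounded at 100 bp and chaining cannot occur. Each group's members
   are clustered at 97% identity; clusters supported by ≥ 2 reads
   (deduplicated records count with their multiplicity) emit a
   majority-vote consensus variant.

5. **Attribution** (`attribution`). Each variant is partitioned into
   100-bp windows; each window is scored against every germline locus by
   infix edit distance. Strict ties mark a window ambiguous (the
   paralogs are locally identical there); a best hit below 70% identity
   marks it unassigned — e.g. windows straddling a segment junction that
   does not exist in the germline pay the spacer cost against *every*
   locus, and attributing them to the least-bad one would manufacture
   spurious multi-locus calls. Adjacent same-call windows merge; a
   variant whose unambiguous segments name ≥ 2 loci is multi-locus, and
   a group is multi-locus when any of its variants is.

6. **Hybrid merge** (`merge`). Per published contig, in order: (R1)
   two-telomere and core < 600 bp → rescue; (R2) no long-read analog
   (≥ 90% infix identity of the shorter core in the longer) → rescue;
   (R3) longest analog ≥ 75 bp shorter → add the published contig,
   keeping a two-telomere long-read analog as an isoform and dropping a
   sub-two-telomere one; (R4) otherwise the long-read contig stands.
   Length comparisons use telomere-trimmed cores (tract length is a
   property of the run, not the chromosome). Afterwards, contigs ≥ 50%
   covered by repeat annotations are removed, and contigs with no
   telomeres *and* < 20% germline coverage are removed as contaminants.

7. **Correction benchmark** (`bench`). One pileup majority-vote corrector
   serves both strategies, differing only in evidence: other long reads
   (self) or short reads (hybrid). Evidence is pre-screened by shared
   13-mers, aligned on its better strand, and votes per target column;
   positions with depth < 2 stay untouched. The target's telomeric
   tracts are excluded from correction and reattached unchanged: the
   8-bp-periodic tract is shared genome-wide, so evidence alignments
   inside it are phase-ambiguous and would vote in a shifted frame near
   the tract/core junction (the trimmed tract is discarded by masking
   downstream anyway). Completeness of a corrected read set is the
   number of reference chromosomes ≥ 80% covered by a *single* unit at
   ≥ 90% identity — the identity floor stands in for the mapper the
   original comparison delegated this to; without it, an uncorrected
   13%-error read would "recover" a chromosome and the strategy
   comparison would be vacuous. Copy-number capture bias uses Welch's
   one-sided unequal-variance t-test (scipy).

## Consensus and polishing

Cluster consensus star-aligns members to the centroid and votes per
column: majority base wins, ties keep the centroid base, gap majority
deletes, and an insertion is emitted when more than half of the covering
members carry one (most common string, ties lexicographic). Consensus
output keeps only columns observed by at least half of the members
("majority span"): the centroid is by construction the longest member —
the one with the most residual junk at its ends — and infix-aligned
clean members never cover those columns, so without the rule the
centroid's private ends would survive every vote. Short-read polishing
reuses the same pileup with depth ≥ 1 and runs to fixpoint (default two
rounds).

## The synthetic-data generator

`SimParams` defaults are the study conditions: mean chromosome length
3200 bp (sd 600), five copies of the 8-mer telomeric repeat per end,
copy numbers log-normal with mean 2000 and log-sd 1.0 (the distribution
family is a package choice; only the mean and the orders-of-magnitude
spread are given facts), long-read errors at 13% with an indel-dominant
(0.15 sub, 0.45 ins, 0.40 del) mix, short reads of 150 bp at 0.5%
substitution error, paralog divergence 5% (substitutions only), and a
quarter of families carrying 1–3 alternative isoforms. Germline loci are
the somatic segments in order with 30–80 bp spacers; scrambled or
inverted segment orders and IES removal are deliberately not modelled —
the pipeline never sees unrearranged germline molecules. Generated
sequence caps homopolymer runs at 8 bp and keeps piece boundaries out of
runs: genic nanochromosome sequence is homopolymer-poor, and uncapped
uniform sequence would occasionally trip the >10 bp artifact filter on
legitimate chromosomes. All generators are pure functions of
(params, seed).

What passing tests on this generator do **not** show: real somatic
genomes have biased composition, non-uniform error profiles along reads,
length-dependent capture efficiency, and germline architecture
(scrambling, IESs) far richer than ordered segments with spacers.
Results here validate the machinery, not the biology of any particular
dataset.

The deterministic worked example (`make_worked_example`) encodes a
two-locus family whose six 350-bp segments rearrange into nine
endpoint-distinct isoform groups (pairwise endpoint separation ≥ 350 bp
≫ the 50-bp tolerance); groups A, B, D and I carry an extra variant
mixing both loci, with enough segments from the other locus that the
within-group variant divergence exceeds 3% and the 97% clustering
separates them. Diagnostic substitutions sit every 20 bp (17 per
segment, ~4.9% divergence). Three error-free reads per variant, one of
each trio reverse-complemented.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study design,
chosen as the smallest sizes at which each claim is statistically
meaningful: 50 error-free chromosomes at depth 10 for exact recovery;
20 chromosomes × depth 20 with 50× short reads for the noisy consensus
check (≥ 95% of ~20 variants within 2 edits needs at least 20 trials);
10 chromosomes × depth grid {2, 5, 10} × 3 seeds for the correction
ordering. Ties everywhere break deterministically (toward the forward
strand, then leftmost; lexicographic ids last). Edit-distance bounds
passed to the aligner are derived from identity thresholds
(edits ≤ len·(1−t)/t) so threshold decisions are exact, never
approximated by the early-exit.

## Known limitations

* The side list (reads with ≤ 1 telomere) is exported, not assembled:
  overlap-layout-consensus assembly is out of scope, and the headline
  path is deliberately the assembly-free one.
* `align(mode="local")` reports the single best +1/−1 segment; chained
  HSP tiling is not implemented (attribution uses windowed infix
  scoring instead).
* The corrector is a majority-vote stand-in preserving the evidence-set
  contrast between strategies; it does not reproduce any external
  correction tool's behaviour in detail.
* Quality scores are parsed but ignored throughout.
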