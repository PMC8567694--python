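# Methods

## Coordinate model

All intervals are 0-based half-open on a named sequence. RepeatMasker
`.out` rows (1-based inclusive) and VCF deletions (1-based, POS anchored on
the base before the event) are converted on read; BED passes through.
Strand is carried on intervals but ignored by every overlap computation —
none of the procedures here are strand-sensitive except the promoter-window
construction, which uses the gene's transcription direction.

**Mutual overlap** of two intervals is the shared length divided by the
*longer* of the two. This is the strictest of the common readings of
"reciprocal overlap" and makes "mutual overlap ≥ f" equivalent to the
overlap covering ≥ f of both intervals. Under it, an insertion-style
deletion that coincides with a TE passes the 90% match threshold even with
several bp of call jitter, while a deletion spilling > L/9 bp into the
flanks of an L bp TE cannot.

## Human-specificity filter

An instance is human-specific when its mapped fraction is ≤ 0.20 in every
genome of the primate panel ("no more than 20%" read inclusively). Mapped
fractions are consumed as a TSV rather than computed: chain-alignment
parameters are genome-build decisions that belong to the caller, and a
sparse table (missing genome = fraction 0) is accepted. Instances fully
contained in a tandem repeat are discarded as potential duplications;
partial overlap is kept. Both filters commute.

## Deletion catalogue

Deletions < 50 bp are discarded (shorter events are very unlikely to be
mobile-element insertions, whose active families are ≥ ~300 bp). Redundancy
is resolved on an overlap graph: edges connect pairs at ≥ 50% mutual
overlap, and the highest-degree node is removed repeatedly — updating
neighbour degrees — until no edges remain. The removal order for tied
degrees is fixed at the lexicographically smallest (chrom, start, end, id),
which makes the retained set independent of input row order; pruning is
idempotent and the retained set provably contains no edge. Discarded
records are kept with `retained=False` because the expanded pMEI scan
rescues TE matches hidden behind a discarded duplicate.

## Pseudo-indel null

Each retained deletion of length L is complemented with `n_total` tiles of
length L (default 500, split 250 per flank; the even split is the natural
symmetric choice). The step between same-side neighbours is L − ⌊L/2⌋, so
adjacent tiles share ⌊L/2⌋ bp — exactly 50% for even L, floored for odd L.
The innermost tiles sit flush against the deletion boundaries. Tiles
protruding past either chromosome end are dropped, never reflected, and the
contingency table uses the *actual* generated total N_pseudo so that
boundary clipping cannot bias the null. Pseudo-indels are not screened for
overlap with true indels or each other: the null deliberately measures the
chance of a TE match at a nearby position of identical size.

The per-subfamily p-value is the one-sided Fisher exact probability
P(X ≥ T_TE) for the table [[T_TE, N_true − T_TE], [P_TE, N_pseudo − P_TE]],
computed as a hypergeometric survival function (scipy); an exact-rational
enumeration oracle in the test suite bounds its relative error at ~5e-15 on
tables with margins up to 10,000. A log10-p column accompanies the raw
p-value because extreme subfamilies underflow doubles. BH correction runs
over every subfamily with ≥ 1 human-specific instance; the RMS threshold
Q ≤ 0.001 is inclusive.

## Enrichment, annotation, chromatin post-processing

*Set enrichment* uses the same one-sided Fisher machinery on subfamily
sets; obsolete catalogue names are first remapped onto the working
annotation (e.g. AluYb11 → AluYb9) with validation that remap targets exist.
*Gene proximity* uses edge-to-edge distance (0 when overlapping) with a
strict `< 50 kb` window, a universe of expressed genes, and ASE status as
the target.

*Context classification* is a fixed precedence — exonic (≥ 5 bp exon
overlap) > promoter (≥ 50 bp overlap with the strand-aware window 2 kb
upstream to 1 kb downstream of the TSS) > intronic (any gene-body overlap)
> intergenic — chosen because the four context counts must partition the
pMEI set. When several genes compete for "nearest", the nearest TSS wins,
ties broken lexicographically. cCRE labels attach on ≥ 1 bp overlap with the
element slopped by 50 bp on both sides (compensating the poor short-read
mappability of young TE copies); labels are monotone in the slop.

*Chromatin post-processing*: the genome is tiled at 151 bp / 75 bp step
(76 bp shared between consecutive tiles; the trailing partial tile is
dropped). Tiles scoring ≥ 1 are merged greedily left-to-right while they
overlap and the span stays within 601 bp (= a run of 7 tiles); each merged
region keeps its best member score and is trimmed symmetrically back to
151 bp, with the odd extra base removed from the right. Regions are then
ranked by score and cut at the measured-DHS count of the same cell line, so
predicted and measured hypersensitive fractions are directly comparable.
A subfamily's hypersensitive fraction counts instances overlapping a DHS by
≥ 50 bp over *all* genomic instances; fold enrichment divides each cell
line's fraction by the row mean (missing when the mean is 0), and the
ancient-subfamily reference set is parameterised as ≥ 20% average divergence
with ≥ 1000 instances.

## Synthetic genomes

The generator emulates the interval-level structure the screen exploits; it
produces no sequence, no reads and no caller error model beyond boundary
jitter. Reference conditions (the `default_config`): one 10 Mb chromosome;
40 subfamilies × 100 instances with Gaussian lengths (mean 300 bp, sd 30,
floor 150 — Alu-like); 3 mobile subfamilies, each with 15 planted pMEIs;
5,000 background deletions with log-normal sizes (median ~200 bp, floored
at 50 bp) placed uniformly and independently of TEs; 500 pseudo-indels per
deletion downstream.

TE placement is uniform without overlap (sorted uniform gaps in the free
space), with no insertion-site preference — consistent with evidence that
L1 integration is largely insensitive to local chromatin state. Each
subfamily gets a human-specific fraction of instances (default 0.2) whose
mapped fractions are drawn U(0, 0.15); the remainder are ancestral,
U(0.85, 1). This gives null subfamilies a tested human-specific cohort, so
calibration can be measured across a realistic testing universe rather than
only at the planted subfamilies. Planted pMEIs pair a mobile subfamily's
human-specific instance (mapped fractions exactly 0) with a deletion whose
boundaries are jittered by ≤ 5 bp per side; the config validator enforces
2·jitter ≤ 0.1·L_min so every planted pair keeps ≥ 90% mutual overlap by
construction. A `pmed_rate` fraction (default 0.02) of ancestral instances
receives a deletion spilling 50–200 bp into each flank, which arithmetically
guarantees mutual overlap < 0.9 whenever the total spill exceeds L/9.

What passing recovery tests show — and what they do not: the synthetic
truth exercises matching, pruning, the null construction and the FDR
machinery end to end, but real call sets add caller-specific boundary
biases, size-dependent sensitivity, segmental duplications and reference
errors that the generator does not model; recovery on synthetic genomes is
a correctness check of the statistic, not a sensitivity estimate for any
particular cohort.

## Numerical and scale choices

Matching uses a start-sorted per-chromosome index: a query of length M can
only achieve f-reciprocal overlap with targets whose start lies within
(1−f)/f·M of its own, so a binary search plus a vectorised check on that
narrow window is exact and keeps the genome-wide screen near-linear.
Acceptance-level simulations run 20 seeds at the reference conditions
(~0.7 s per seed end to end); the exact-rational Fisher oracle is evaluated
on tables with cells ≤ 2,500 (margins ≤ 10,000), comparing in log10 space
once tails drop below the smallest normal double, where linear-scale
relative error is no longer representable.

## Known limitations

* The screen consumes mapped fractions, remap tables and tile scores as
  inputs; LiftOver/BLAT and gkmSVM training are out of scope by design.
* Fragmented RepeatMasker hits of a single element are treated as
  independent instances; rows are not reassembled by repeat ID.
* Sources are pooled when catalogues are merged; no per-sample genotyping
  or caller reconciliation is attempted.
* The expected-match column is computed as P_TE · N_true / N_pseudo (a
  single pooled rate), not per indel.
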