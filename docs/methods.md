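# Methods

This note documents the models and procedures implemented in `ervscape`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Proviral reference model

A provirus is modeled as a consensus sequence with a six-region layout
`5'LTR – gag – pro – pol – env – 3'LTR` in 1-based inclusive coordinates.
The default layout is the 10485-bp HML-8 consensus
(`MER11A-HERVK11-MER11A`): 5'LTR 1–1266, gag 1422–3530, pro 3341–4345,
pol 4303–7032, env 6890–9217, 3'LTR 9220–10485.  Adjacent ORF intervals may
overlap (gag/pro, pro/pol, pol/env junctions do); the two LTRs may not, the
5'LTR starts at base 1 and the 3'LTR ends at the last base.  Synthetic
consensuses are uniform-random A/C/G/T, with the 5'LTR sequence mirrored
into the 3'LTR when the two regions have equal length — a provirus carries
the same LTR at both ends at integration, and LTR–LTR divergence dating
depends on it.

## Synthetic genomes

`plant_loci` builds multi-chromosome genomes: uniform-random background
(25% each base; no composition model is imposed), planted copies described
by insertion plans (kept reference intervals, divergence, strand, nested
foreign insertions), and simple multi-exon gene models.  The mutation model
is substitutions only: each site flips independently with probability d,
replacement uniform over the three alternatives, so the realized divergence
of a copy is directly the p-distance the molecular clock interprets.
Truncation and kb-scale insertions are modeled explicitly via plans rather
than via an indel process, which keeps the truth table exact.  Random
streams are salted per role (reference, mutation, planting) so equal seeds
across functions never alias.

What the generator does **not** emulate: repeat landscapes and segmental
duplications, composition/CpG structure, transition/transversion bias,
micro-indels, solo-LTR formation by recombination (solo LTRs are planted
directly), and realistic gene architecture.  Passing tests on these genomes
demonstrate correctness of the pipeline's logic and calibration of its
statistics under the stated model — not robustness to every artifact of
real assemblies.

Truth coordinates are recorded 1-based inclusive (matching the locus
catalog convention) with 0-based half-open companions; internal code uses
0-based half-open (PSL convention) and converts once, at the report writers.

## Discovery

The built-in search mirrors DNA BLAT at desk scale: the genome is indexed
with overlapping 11-mers sampled every 5 bases (k ≤ 32; words occurring
more than 64 times are dropped, a simple stand-in for repeat masking), and
every consensus 11-mer is looked up on both strands.  Seed hits are grouped
by diagonal `t − q` (tolerance 150 bp) and split at target gaps over 5 kb;
each chain is aligned to its padded window with an infix edit-distance
alignment (edlib).

Two path interpretations compete per window: the edit-distance path, and a
gapless interpretation along the chain's median diagonal.  The winner is
chosen by an affine-style score (match +1, mismatch −2, gap open −5 plus
0.5/bp capped at −40).  The rationale: unit-cost edit paths scatter
spurious 1-bp indel pairs through diverged-but-ungapped sequence, which
both deflates observed divergence (biasing ages downward ~10% at d = 0.10)
and fragments blocks; the gapless candidate wins exactly when it explains
the window better, while true indels keep the edit path.  The chosen path
is trimmed to its maximal-scoring contiguous segment (Kadane over cigar
runs, gap penalties capped so interior kb-scale insertions survive the
trim while random flanks at ~25% identity fall away).

Hits below `min_identity` (match/(match+mismatch)) or `min_len` aligned
bases are discarded.  Defaults are the classic DNA-BLAT operating point,
95% identity over ≥25 bases.  For experiments on copies diverged up to
8–10% this global-identity floor is unreachable (a 8%-diverged copy has
~92% identity), so the synthetic recall and dating experiments run at
`min_identity` 0.90 (0.85 for the d = 0.10 dating level) and `min_len` 100,
chosen from the planted divergence and kept-length ranges; the higher
length floor suppresses the ~25–30-bp chance hits that appear once the
identity floor drops below 95%.

Assembly merges records on one chromosome and strand whose genomic gap is
≤ `merge_gap` (default 2000 bp) and whose consensus intervals are collinear
(tolerance 100 bp).  Per locus: coverage = (match+mismatch)/consensus
length; query-gap fraction = Qgap/(match+mismatch+Qgap) including consensus
spans skipped between merged records; a **Deletion** flag at query-gap
fraction ≥ 0.10 and an **Insertion** flag when genomic length exceeds
aligned bases by ≥ 1000 bp.  Both thresholds are reverse-engineered from
the printed catalog (the largest unflagged query-gap fraction is 9.29%, the
smallest flagged 10.68%; all Insertion rows imply kb-scale foreign
sequence) and are exposed as parameters.  Loci sort by coverage descending,
ties by (chromosome, start), and are named `chr:start-end`.  When a nested
insertion exceeds `merge_gap` the two flanks report as separate loci;
experiments with planted 1.5–2-kb insertions therefore use a merge gap
above the insert size.

## Structure

Region integrity is |union(covered consensus intervals) ∩ region| / region
length; junction bases shared by overlapping ORFs count toward both
regions, each fraction being computed independently.  "Complete deletion"
means exactly zero aligned bases — no epsilon, matching tables that print
0.00%.  A solo LTR requires one LTR at ≥50% coverage (configurable) and
all four internal regions exactly absent.  Percentages print at two
decimals with half-up rounding.

The length summary takes the mean over all loci but the extrema over loci
without an Insertion flag: nested foreign sequence inflates genomic length,
so an insertion-bearing locus does not define the longest or shortest
proviral element (if every locus is flagged the extrema fall back to all).
The coarse >70% / 40–70% / <40% classes bin on coverage fraction, not
genomic length.

## Genomic context

Labels partition loci: no gene overlap → `intergenic`; overlap extending
past every overlapping gene's boundary → `genic&intergenic`; fully genic
with zero exon overlap → `intron`; entirely within exon sequence → `exon`;
otherwise `exonic&intronic`.  Classification is strand-agnostic, and where
isoforms disagree exon overlap takes precedence for the overlapped base
(the conservative call).  Loci on chromosomes absent from the annotation
are labeled intergenic with a logged warning.

## Chromosomal distribution

Expected counts are `e_c = Cl_c · N / Σ Cl` with Cl the chromosome's
nongap length (assembly length minus N bases), so Σe = N.  The headline
test is the global goodness-of-fit χ² with k−1 df (k ≥ 2 required).
Per-chromosome calls use a 1-df χ² of that chromosome against the pooled
rest; `enriched`/`depleted` at p < α (default 0.05) with the o/e fold
reported.  Raw p-values are the default, matching how such scans are
usually reported; BH adjustment across chromosomes is available.  The χ²
approximation needs expected counts of a few per cell — the calibration
experiment uses 12 chromosomes and N = 200, where the measured type-I
error sits within 0.01 of α over 10,000 multinomial null genomes.

## Integration dating

Divergence D is the uncorrected p-distance with pairwise deletion of gaps
and ambiguous sites — the minimal reading of "percent divergent
nucleotides" that the clock formula expects; a Jukes–Cantor correction
(−3/4·ln(1−4p/3)) is exposed as an option.  Ages: internal regions
`T = (D·100)/0.2` Myr against the per-region majority consensus of all
eligible copies; LTR–LTR `T = (D·100)/0.2/2`, halved because both LTRs
accumulate substitutions independently after integration.  The clock rate
(0.2 %/nt/Myr) is a parameter.

A region is eligible for dating when the locus retains ≥90% of its
reference length.  Loci are projected into the consensus coordinate frame
through their alignment blocks (gap where uncovered), so no separate MSA
step is needed; the majority consensus (ties broken A<C<G<T, columns
majority-gap emitted as gap, ≥2 sequences required) stands in for a
maximum-likelihood ancestral sequence.  Per element, the age uses the
unrounded mean of available region divergences; the consensus estimator
needs a reasonable sample — with very few copies each column's majority is
drawn toward individual elements and ages shrink toward the group mean.
Age summaries print at two decimals, half-up; the median uses midpoint
averaging for even n.

## Phylogeny

Distances: p, JC69, or K2P (−½·ln((1−2P−Q)√(1−2Q))), pairwise deletion,
with saturated pairs reported by name.  Trees are Saitou–Nei neighbor
joining implemented in-package so determinism is guaranteed: Q-matrix ties
break on the lowest current index pair, negative branch lengths clamp to
zero with a warning, and the final three nodes join at an unrooted
trifurcation.  NJ is a distance-based stand-in for full ML inference; an
escape hatch exports alignments (FASTA / relaxed PHYLIP) for external ML
tools and re-imports newick.  Bootstrap support resamples columns with
replacement (default 500 replicates, seeded) and scores each full-data
internal split by the percentage of replicate trees containing it;
replicates with undefined distances count against support.  Group
assignment gives a query the label of the panel references in its smallest
ancestor clade containing only one panel label, provided that clade's
support reaches the threshold (default 70); otherwise `unassigned`.

## Regulatory association

Regulatory domains follow the GREAT basal+extension rule: strand-aware
basal window TSS−5000…TSS+1000, extended each side to the nearer of 1 Mb
or the neighboring gene's basal boundary, clipped to the chromosome; when
two basal domains overlap, extension on that side is zero (basal domains
are inviolate — the published rule does not specify this tie, so the
conservative choice is made).  Proprietary curated regulatory domains are
not reproduced.  LTR loci qualify when their better-retained LTR exceeds
70% of the reference LTR; the LTR position is its interval midpoint, and
distances to the TSS bin into <5 kb, 5–50 kb, 50–500 kb, >500 kb with
upstream/downstream orientation in the gene's frame.

ORA tests an associated-gene list against categories restricted to
5–2000 members within the universe: hypergeometric upper-tail p
(scipy), BH FDR across tested categories (statsmodels), sorted by
(FDR, p, category) and truncated to the top 10.

## Packaged catalogs

Three TSVs transcribe the published chimpanzee HML-8 catalog with printed
values preserved (76 loci; 76 six-region integrity rows; 46 dated elements
with per-region divergences).  They are data, not computation: every
summary over them (length statistics, context proportions, deletion
counts, age statistics) is recomputed by the analysis modules at run time,
and loaders verify frozen sha256 checksums.  The locus table prints
context labels with inconsistent spacing and a full-width bracket in the
range bins; loaders normalize whitespace for grouping and the fixture uses
the ASCII bracket.

## Problem sizes and determinism

The test suite and the reproduction script run on desk-scale synthetic
genomes — 13–40-kb chromosomes, 20 planted copies per experiment, 10,000
multinomial draws for χ² calibration, 100–500 bootstrap replicates —
sizes at which every property they check (recall, recovery error,
calibration, exactness against oracles) is already sharp.  All randomness
flows from explicit seeds; repeated runs are byte-identical.

## Known limitations

* The k-mer search is a desk-scale BLAT analogue: no tile masking beyond
  an occurrence cap, no translated search, and no claim of whole-mammal
  genome scalability.
* Alignment-edge trimming can shave a handful of diverged terminal bases
  from a locus, so recovered coordinates are exact only to within a few
  bases at higher divergence.
* Dating ignores rate heterogeneity across sites and lineages and reports
  no uncertainty interval; the consensus ancestor is biased when few
  copies are eligible.
* NJ with bootstrap is not ML: support values and topologies can differ
  from likelihood-based analyses for marginal clades.
* Context classification trusts the supplied annotation; no UTR/promoter
  subclassification is attempted.
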