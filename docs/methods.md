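# Methods

This note documents the models implemented in `lincnet`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want written down.

## Coordinates and transcript structures

All intervals are 0-based half-open internally; GTF input/output converts to
1-based inclusive at the boundary.  A transcript is a sorted, disjoint exon
list on one chromosome and strand; "length" always means spliced length (the
sum of exon lengths), matching standard lncRNA pipelines, and "gene distance"
is measured between locus-level spans (per-gene union of transcript spans),
strand-agnostic.  The TSS of a `+` transcript is its span start; of a `−`
transcript the last coordinate of its half-open span (the first transcribed
base).

## Novelty against a reference annotation

A catalog transcript is `known_match` when its intron chain equals that of a
reference transcript on the same chromosome and strand — terminal-exon
extensions do not change the chain, so assembly-truncated or extended copies
of annotated transcripts are still recognized.  The chain test applies only
to spliced transcripts: a single-exon transcript has an empty chain, which
would vacuously equal any other empty chain, so single-exon entries can only
be `exonic_overlap` (≥ 1 bp same-strand exon overlap) or `novel`.  Antisense
overlap is deliberately not "known": an antisense transcript is novel at this
stage and is instead removed by the strand-agnostic 500 bp distance filter
downstream, which is how "away from any genes" reads at locus level.

## The identification funnel

Stages run in a fixed order: known-removal → exon count ≥ 2 → spliced length
≥ 200 nt → distance ≥ 500 bp → coding probability below threshold.  The
order matters (a single-exon transcript near a gene is reported as failing
the exon filter, not the distance filter) and the report records
input/passed/removed counts per stage plus each transcript's first failing
stage.  The exon threshold is ≥ 2: an unspliced transcript gives no intron
evidence and single-exon assemblies are the least reliable, so they are
excluded even though that costs genuine single-exon lincRNAs.

## Coding potential

Four features: longest ORF length (ATG-initiated, stop-terminated, sense
strand, three frames, length includes the stop codon; codons containing N
break an ORF), ORF coverage (ORF length / transcript length), the Fickett
TESTCODE statistic computed from the published position-bias and composition
lookup tables, and a hexamer log-likelihood ratio.  The hexamer table stores
log(f_coding/f_noncoding) over all 4096 ACGT 6-mers with a pseudocount
(default 1.0); hexamers are counted in-frame (step 3) inside the longest ORF
when one of ≥ 6 nt exists, else by sliding window over the whole sequence.
A logistic regression (unpenalized, features standardized by training
mean/scale) maps the features to a coding probability; the decision
threshold defaults to 0.5 and is recorded in every report.  The model is
trained on user-supplied or generated coding/noncoding sequence sets; the
CLI also accepts precomputed external coding calls for users who want parity
with a specific external tool.

## Tissue specificity

Condition-level expression is the mean FPKM over the condition's replicate
samples (replicate handling must be fixed somehow; averaging is the least
surprising choice and is applied consistently in breadth and specificity).
Detection breadth counts conditions with mean FPKM strictly above 0.1.  The
specificity density p is log10(FPKM+1) per condition normalized to sum 1;
the score against condition t is 1 − JSdist(p, e_t), with JSdist the square
root of the Jensen-Shannon divergence using base-2 entropy, so scores live
in [0, 1] and equal 1 exactly when expression is confined to one condition.
All-zero features are emitted as missing and excluded from summaries rather
than scored 0 (a zero vector has no density).

## Neighbor correlations

Neighbor pairs are cross pairs with gene-body gap strictly below 10 kb,
orientation ignored for pairing but reported via the pair members.
Correlations are Pearson on log2(FPKM+0.05) across samples; zero-variance or
missing members yield NaN with the pair still listed.  The random null draws
unordered feature pairs uniformly without replacement, seeded, excluding the
true neighbor set.  TSS-distance profiles bin pairs with distance strictly
inside a 4 kb window into 400 nt bins, fractions normalized per pair class.

## Co-expression network

Pretreatment follows the stated filters: drop genes with max FPKM < 0.05,
keep the top 75 % by variance (computed on raw FPKM, before the log), then
log2(FPKM+1).  The variance rule keeps `ceil(0.75·n)` genes with a
deterministic tie-break (variance, then gene id).

Adjacency is the signed form a_ij = ((1+cor_ij)/2)^β.  Soft-threshold
selection evaluates β = 1..20: connectivity k is binned into 10 equal-width
bins, log10 p(k) is regressed on log10(mean k) over non-empty bins, and the
fit index is R² signed by the negative slope; the smallest β reaching 0.9 is
chosen, with a warned fallback to the best fit when none does (equal-width
binning is used because equal-occupancy bins make p(k) constant and the
regression degenerate).  On strongly block-structured data — including the
default synthetic panel — the connectivity distribution is bimodal rather
than scale-free and the fallback path is the expected behavior; the paper's
β = 13 can always be set explicitly and is used as the fixed power in the
recovery tests.

TOM is the unsigned topological overlap of the signed adjacency,
t_ij = (ℓ_ij + a_ij)/(min(k_i,k_j)+1−a_ij) with ℓ_ij = Σ_{u≠i,j} a_iu·a_uj,
diagonal 1.  Modules come from average-linkage clustering of 1 − TOM with a
static-height dynamic cut: the tree is cut at the 0.9 quantile of its merge
heights plus 5 % of the height range, and branches below the minimum module
size (default 30) are left unassigned.  Two numerical choices here deserve
explanation.  The quantile sits at 0.9 rather than at the top of the tree
because, measured on planted-module data, within-module merges complete in
the lower height range while uncorrelated genes attach one by one just
under the final inter-module joins — a near-top cut absorbs every such gene
into a module.  The 5 %-range slack exists because a quantile alone
truncates the last few internal merges of a tight, fully coherent branch
and orphans those members.  Both are configurable.

Eigengenes are the first right singular vector of the module's gene-
standardized expression (unit norm over samples), sign-oriented so the
eigengene correlates non-negatively with the module mean profile; explained
variance is reported.  Merging recomputes eigengenes after every merge and
always merges the currently most-correlated pair above the 0.7 threshold
(ties by label order), removing order dependence.  Module–stage statistics
correlate eigengenes with one-hot stage indicators (the encoding is not
canonical; one-hot is the simplest that makes "correlation with a stage"
well defined); p-values are two-sided Student t with df = n−2, uncorrected,
and a module is stage-specific at r > 0.7, p < 10⁻⁴.  kME is the
correlation of each gene with each eigengene; hub tables rank module
members by kME (descending, then gene id) and keep the top 100.

## Enrichment

One-sided (greater) Fisher exact tests on the 2×2 module/term table, which
equal the hypergeometric upper tail; terms unannotated in the background are
skipped, terms hitting no module gene are omitted, and Benjamini–Hochberg
adjustment is applied within each term category (configurable off).  The
default background is the expressed (preprocessed) gene set.

## Synthetic data

The generator plants ground truth for every downstream stage under one
seed; identical configs produce byte-identical files.  Randomness is split
into per-stage `default_rng([seed, stage])` streams so each sub-generator is
independently re-runnable with the same result.

The default study: 3 chromosomes, 60 multi-exon reference genes (3–9 exons)
separated by 8–25 kb gaps, their spliced sequences coding-like and stamped
into a random genome so transcript FASTA and genome FASTA agree exactly.
The 250-transcript catalog contains 90 known copies (reference intron
chains, extended terminal exons), 40 same-strand exon-overlapping novels,
and 120 intergenic transcripts: 30 placed 100–480 bp from a gene (distance
decoys), 20 single-exon decoys, 10 shorter than 200 nt, 25 coding (planted
ORF of 450–900 nt built from a GC-biased codon table between short UTRs)
and 35 noncoding survivors (uniform composition, longest ORF capped at
150 nt by stop-codon interruption).  Each funnel stage therefore removes a
known subset and exactly 35 lincRNAs survive by design.  Training sets for
the coding model are drawn from the same two sequence models.

Expression: the tissue panel covers 6 tissues × 2 replicates; 60 % of
non-cis lincRNAs are tissue-specific (FPKM > 0.1 only in their tissue),
everything else broad; 20 cis pairs place a lincRNA 0.6–4 kb from a partner
gene and couple their log-profiles at ρ = 0.9.  The stage panel covers
6 stages × 2 replicates with 4 modules × 50 genes plus 100 noise genes;
module genes follow a pulse profile (log2 scale 1 baseline, 5 at the
module's peak stage) with Gaussian noise of sd 0.5, hubs (10 % per module)
at one fifth of that, noise genes i.i.d.  The paper-style replicate count
per stage is not published anywhere usable; 2 is this package's default and
is configurable.  Term annotations plant one enriched term per module (60 %
of members plus background contamination) among random terms.

What the generator does **not** emulate: read-level noise and FPKM
estimation error, batch effects, correlated noise structure, overlapping or
nested gene architecture, scale-free connectivity (the planted panel is
block-structured — see the soft-threshold note above), and realistic
hexamer composition learned from real genomes.  Passing recovery tests
therefore demonstrates the correctness of the computations and their
behavior under the planted effect sizes, not performance on real data.

## Problem sizes

Defaults were chosen so that the full synthetic study runs in seconds and
the complete recovery analysis (20 simulation seeds) plus all brute-force
oracle comparisons finish in well under a minute on one core, while still
exercising every code path at the sizes stated above.

## Known limitations

- The dynamic tree cut is the static-height variant; the hybrid PAM-like
  refinement of the reference implementation is out of scope, so genes with
  weak module membership near the cut are left unassigned rather than
  adopted.
- Cuffcompare class codes are not emulated beyond the intron-chain /
  exon-overlap rule; transcripts that share a locus without sharing exonic
  sequence are treated as novel.
- The coding model is only as good as its training sets; with the synthetic
  sequence models the classes are widely separated (held-out AUROC ≈ 1),
  which real transcriptomes will not reproduce.
- Enrichment ignores term hierarchy (no GO DAG propagation).
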