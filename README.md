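# lincnet

Post-assembly analysis of long intergenic noncoding RNAs (lincRNAs) in
transcriptome studies, built for the kind of experiment where a merged
transcript catalog (e.g. from short-read assembly across tissues and
pre-implantation embryo stages) must be mined for novel noncoding genes and
their regulatory context.  The package provides, as one tested library plus a
CLI:

- **lincRNA identification** — a five-stage filter funnel over a merged GTF:
  removal of known/annotation-overlapping transcripts (intron-chain and
  strand-aware exon-overlap tests), exon count ≥ 2, spliced length ≥ 200 nt,
  ≥ 500 bp from any annotated gene, and a coding-potential filter using an
  internal CPAT-style model (longest ORF, ORF coverage, Fickett TESTCODE,
  hexamer usage log-likelihood ratio, combined by logistic regression).
- **Tissue specificity** — detection breadth at FPKM > 0.1 and the
  Jensen-Shannon specificity score
  `JS(t) = 1 − JSdist(p, e_t)`, where `p` is the normalized vector of
  log10(FPKM+1) across conditions and `e_t` the unit vector of condition `t`;
  a transcript's specificity is `max_t JS(t)`.
- **cis neighbor correlation** — gene pairs with body distance < 10 kb,
  Pearson correlation on log2(FPKM+0.05), a seeded random-pair null, and
  TSS-distance profiles (4 kb window, 400 nt bins).
- **Weighted signed co-expression networks** — pretreatment (drop max FPKM
  < 0.05, keep top 75 % by variance, log2(FPKM+1)), signed adjacency
  `a_ij = ((1+cor_ij)/2)^β` with scale-free soft-threshold selection
  (target signed R² = 0.9), topological overlap
  `t_ij = (ℓ_ij + a_ij)/(min(k_i,k_j)+1−a_ij)`, average-linkage clustering
  with a dynamic (static-height + minimum-size) tree cut, module eigengenes
  (first principal component), merging of modules with eigengene correlation
  > 0.7, stage-specific module calling (r > 0.7, p < 10⁻⁴), and hub
  extraction by module membership `kME_q(i) = cor(x_i, E_q)` (top 100 per
  module by default).
- **Enrichment** — one-sided Fisher exact tests of module gene lists against
  term annotations with Benjamini–Hochberg adjustment per category.
- **qPCR quantification** — relative expression as 2^−ΔΔCt.
- **Synthetic data** — a generator that emulates every input (genome +
  annotation GTF/FASTA, merged catalog, transcript sequences, tissue/stage
  FPKM panels, design tables, term annotations) with planted ground truth:
  funnel decoys for every filter stage, tissue-specific transcripts,
  cis-correlated neighbor pairs, stage-specific co-expression modules with
  designated hub genes.

## Worked example

Simulate the default synthetic study and run every stage:

```bash
lincnet run-all --seed 3 --out-dir runs/demo
```

```
simulated 250 transcripts over 60 reference genes -> runs/demo
 known_removal:    250 in,    130 removed,    120 passed
    multi_exon:    120 in,     20 removed,    100 passed
    min_length:    100 in,     10 removed,     90 passed
  min_distance:     90 in,     30 removed,     60 passed
     noncoding:     60 in,     25 removed,     35 passed
35 lincRNAs -> runs/demo/lincrna_ids.txt
9/310 features detected in a single condition (FPKM > 0.1)
mean r (linc_mRNA): +0.378
mean r (mRNA_mRNA): -0.006
mean r (random): -0.058
beta=15; 4 modules (4 stage-specific) over 225 genes
208 hub entries across 4 modules (32 lincRNAs)
4 significant term hits (adjusted p < 0.05)
```

Reading the output: the funnel removes exactly the planted decoy classes
(130 known/overlapping, 20 single-exon, 10 short, 30 near-gene, 25 coding)
and calls the 35 planted lincRNAs.  Planted cis lincRNA:mRNA neighbor pairs
correlate far above the random-pair null.  The co-expression network
recovers the four planted stage-specific modules (each eigengene correlates
with its developmental stage at r > 0.7, p < 10⁻⁴), the hub tables flag the
lincRNA members, and Fisher enrichment finds the term planted in each
module.  Individual stages are also available as subcommands
(`simulate`, `identify`, `specificity`, `cis`, `network`, `hubs`, `enrich`)
with per-threshold flags; every run writes a `manifest.json` with the seed,
counts and output checksums.

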