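# vitiseq

Stage-course RNA-seq analysis of a seeded grapevine cultivar and its
seedless somatic variant.

## The problem

Stenospermocarpic (seedless) grape clones arise as somatic variants of
seeded cultivars and are propagated vegetatively, so the seeded wild type
(WT) and the seedless mutant (MT) are near-isogenic.  Comparing their berry
transcriptomes across development — pre-fertilization flowers (E-L 15),
young berries (E-L 27) and ripe berries (E-L 38) on the modified
Eichhorn–Lorenz scale — localizes the expression changes that travel with
the seedless phenotype.  The catch is the design: one sequencing library
per genotype × stage, six libraries total, **no replicates**.  `vitiseq`
implements the complete analysis for this design as a tested, reusable
Python package, together with a synthetic-data generator with known ground
truth so every stage of the pipeline can be validated without any download.

## What it computes

* **Detection** — RPM (reads per million uniquely mapped reads) per gene
  per library; a gene is *expressed* when RPM ≥ 0.5 or, below that, when
  ≥ 5 high-stringency reads support it.  Expressed-set Venn decompositions
  across stages and genotypes.
* **Count-pair ranking** — for counts n₁, n₂ from two libraries of depths
  N₁, N₂, the exact two-sided binomial p-value of the split (conditional on
  n₁+n₂, success probability N₁/(N₁+N₂)), log-transformed, signed by the
  direction of the rate difference, and multiplied by |log₂ ratio| into a
  ranking value.
* **Differential expression without replicates** — median-of-ratios size
  factors; blind negative-binomial dispersion (variance μ + αμ²) estimated
  from the two libraries of each comparison treated as pseudo-replicates,
  with a robust mean–dispersion trend α(μ) = a₀ + a₁/μ; an exact
  conditional NB test per gene; Benjamini–Hochberg FDR; calls at
  FDR ≤ 5% and |log₂FC| > 1 for the three within-genotype comparisons
  E-L 27 vs 15, E-L 38 vs 27, E-L 38 vs 15.
* **Sign-triplet patterns** — each gene's three calls form a triplet
  (a,b,c) ∈ {−1,0,+1}³; of the 27 triplets, 18 are logically consistent
  expression patterns (e.g. (1,1,−1) is impossible) and are numbered
  groups 1–18, tabulated WT vs MT.
* **Enrichment** — hypergeometric over-representation of annotation terms
  in a study set against the annotated background, significant when
  FDR < 0.05 *and* p < 0.01.
* **Candidates** — genotype-specific non-DE genes in enriched terms;
  genotype-specific DE genes; common DE genes with divergent patterns or
  fold changes; and co-localization of clone-specific genes with seed QTLs
  (proportion inside the 10-Mb window centered on each QTL peak).

## Worked example

Simulate the default study conditions at 2000 genes and run everything:

```sh
vitiseq run --synthetic --n-genes 2000 --seed 7 --out-dir out/
```

prints the DE-overlap summary:

```json
{
  "grand_total": 400,
  "mt_specific": 18,
  "mt_total": 377,
  "pct_mt_specific": 5.0,
  "pct_shared": 90.0,
  "pct_wt_specific": 6.0,
  "shared": 359,
  "wt_specific": 23,
  "wt_total": 382
}
```

The generator planted 400 pattern genes (8 triplet archetypes × 50 genes,
fold 8) active in both genotypes, and the pipeline recovered 382 of them as
DE in WT and 377 in MT, 359 shared — the identities
shared + specific = per-genotype total and WT + MT − shared = grand total
hold exactly.  `out/group_counts.tsv` starts:

```text
group_id  pattern  n_WT  n_MT
1         1,1,1      36    20
2         1,0,1      45    34
3         1,0,0       7     6
```

Group 2 collects genes induced from E-L 15 to E-L 27 that stay high
(triplet 1,0,1); the planted block of 50 lands mostly there, with a few
borderline genes read as the threshold-neighbour patterns (1,1,1) and
(1,0,0).  Every output file carries the configuration hash and seed, and a
re-run with the same configuration is byte-identical.

Other subcommands (`simulate`, `expression`, `rank`, `de`, `patterns`,
`enrich`, `candidates`) expose the individual stages; the same
functionality is available as a library (`vitiseq.differential`,
`vitiseq.pattern_groups`, …).

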