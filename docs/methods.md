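# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the design
decisions made where the design was genuinely open.

## Study design and scope

The analysis targets a fixed six-library design: two near-isogenic
grapevine clones — seeded wild type (WT) and stenospermocarpic seedless
mutant (MT) — each sequenced once at three berry developmental stages
(E-L 15, E-L 27, E-L 38).  All differential testing is *within* a genotype,
between stages; the pipeline deliberately offers no direct WT-vs-MT test at
a stage, because with single libraries and possibly asynchronous sampling
of the two clones such a contrast would confound clone with sampling time.
Clone differences are read off the *comparison of the two stage-course
analyses*: which genes are DE in one background only, and which shared DE
genes follow different patterns.

## Detection rule

RPM = count × 10⁶ / (library's total uniquely mapped reads).  The
denominator is the metadata-supplied library total, not the matrix column
sum: it is stable under gene filtering and matches the convention of
normalizing by sequencing depth rather than by the captured gene set.  A
gene is expressed in a library when RPM ≥ 0.5, or when RPM < 0.5 but at
least five high-stringency reads (identity > 98% over 100 bp) support it.
Stringency is not computable from a count matrix, so the rescue branch
reads an optional `high_confidence` matrix; when absent, raw counts stand
in (a documented dialect switch — with million-read libraries the two
branches coincide anyway, since 5 reads ≈ RPM 5 ≫ 0.5... only for deeper
libraries does the rescue matter).

## Count-pair ranking

For counts n₁, n₂ at depths N₁, N₂ the two-sided exact binomial test of n₁
successes in n₁+n₂ trials against π = N₁/(N₁+N₂) uses the
minimum-likelihood two-sided convention (sum of outcome probabilities not
exceeding the observed one) — the standard exact convention when sidedness
is not otherwise specified.  The score is −log₁₀ p signed by the
rate-difference direction.  The ranking value multiplies the signed log p
by |log₂ ratio|, with the ratio stabilized by a depth-tied pseudocount
ε = 0.5/min(N₁, N₂) so that zero counts stay finite and the stabilization
is scale-free.  The exact functional form combining significance and
effect size is this package's definition; it is monotone in both factors,
which is the property the ordering relies on.  Ranking p-values order
transcripts and are never multiplicity-corrected.

## Differential expression without replicates

The engine follows the classic NB exact-test scheme for unreplicated count
data (the DESeq-v1 lineage), re-implemented here:

1. **Size factors**: median over genes of count/geometric-mean ratios, per
   library, normalized to geometric mean 1; estimated once per genotype
   over its three libraries.
2. **Blind dispersion**: the two libraries of a comparison are treated as
   pseudo-replicates.  The per-gene method-of-moments estimate is
   α̂ = (s² − μ̂)/μ̂² on normalized counts.  The mean–dispersion trend
   α(μ) = a₀ + a₁/μ is fitted by **median (quantile 0.5) regression of the
   unclipped α̂ on 1/μ over genes with μ̂ ≥ 10**, rescaled by the χ²₁
   median (≈ 0.455).  Three deliberate choices here:
   * *unclipped and median*: conditioning on α̂ > 0 biases a one-degree-of
     freedom moment estimator upward by roughly a third, and genes with
     real condition differences contaminate any mean-based fit — the
     median is robust to both;
   * *χ²₁ rescaling*: under the null, s² ≈ var · χ²₁, so the conditional
     median of α̂ understates α by the χ²₁ median; dividing it out makes
     the trend unbiased (Poisson data recover a₀ ≈ 0.004, well under the
     0.01 sanity bound; α = 0.2 data recover ≈ 0.28, mildly conservative
     because NB tails are heavier than the normal approximation assumes);
   * *μ̂ ≥ 10 floor*: below ~10 normalized counts the moment estimate is
     dominated by discreteness and corrupts the 1/μ term.
3. **Sharing mode**: the dispersion used for testing is the fitted trend
   value (`fit-only`, default).  `maximum` (max of raw and fitted) is
   available but, with the signal itself inside the raw estimate of every
   truly DE gene, it removes essentially all power in an unreplicated
   design — it is the right choice only when real replicates exist.
4. **Exact test**: conditional on a gene's count sum, sum the
   probabilities of all splits whose joint probability under independent
   NB laws (matched normalized mean, each scaled by its size factor, the
   gene's trend dispersion) does not exceed the observed split's.  α = 0
   reduces exactly to the conditional binomial (Poisson) test, which the
   suite verifies against an independent enumeration oracle to 10⁻¹⁰.
5. **Calls**: Benjamini–Hochberg across the testable genes (count sum > 0)
   of each comparison; +1/−1 when FDR ≤ 0.05 and log₂FC > 1 / < −1.  The
   fold threshold is two-sided because down-regulation is reported
   symmetrically.  log₂FC is computed from size-factor-normalized means,
   later stage over earlier, with a 0.5 pseudocount only on zero means;
   genes with both means zero are excluded from the test family.

Bit-level parity with any particular DESeq release is not a goal; the
contract is statistical: ≤ 1% false nonzero calls on null data and ≥ 90%
sign recovery for planted fold-8 genes at high base mean, both asserted in
the test suite.

## Sign-triplet patterns

The three calls (a, b, c) for E-L 15→27, 27→38 and 15→38 form a triplet.
The relevance rule — (i) (0,0,0) is not a pattern; (ii) a = b ≠ 0 forces
c = a; (iii) exactly one nonzero step of sign s allows c ∈ {s, 0};
(iv) opposing steps allow any c; (v) a = b = 0 requires c ≠ 0 — admits
exactly 18 of the 27 triplets, verified by exhaustive enumeration against
an independently coded oracle.  Groups are numbered 1 (monotone up) to 18
(monotone down); within narrative pairs the variant that stays significant
end-to-end precedes the one that does not (2 = (1,0,1) before 3 = (1,0,0)).
Negating all calls is an involution pairing 1↔18, 2↔16, 3↔17, 4↔15, 5↔14,
6↔13, 7↔10, 8↔11, 9↔12.  Observed-but-irrelevant triplets (possible on
thresholded data) go to an explicit `inconsistent` bin so that DE genes are
exactly partitioned — silently dropping them would break the overlap
arithmetic.

## Enrichment

One-sided hypergeometric upper tail per term, BH over the family of terms
with k ≥ 1 in the study set, significant under the dual rule FDR < 0.05
and raw p < 0.01.  The background defaults to all annotated genes (the
reference-genome convention); restricting to expressed genes is available
but off by default.  The FDR family is global (not per-ontology); GO-graph
propagation and redundancy reduction are out of scope.

## Candidate selection and QTL windows

Tier 1 keeps genotype-specific genes (detected in ≥ 1 stage of one
genotype, none of the other) with an all-zero triplet, detection in their
genotype, and membership in ≥ 1 significantly enriched term.  Tier 2 is DE
in exactly one genotype.  Tier 3 is DE in both with a different group, or
the same group with fold changes diverging by ≥ 2 on the fold scale
(2^|Δlog₂FC|) in some comparison; the factor 2 is this package's default
for an otherwise qualitative criterion.  The "function relevant to seed
development" criterion is expert curation; it is exposed as an optional
keyword filter over annotation text and never applied by default.

QTL co-localization uses 1-based inclusive intervals: a gene overlaps a
window when its interval intersects [peak − 5 Mb, peak + 5 Mb], both ends
inclusive (a gene starting at peak + 5,000,000 is in; + 5,000,001 is out).
The per-peak proportion divides by the clone-specific candidates on that
peak's chromosome.  BED input is converted to 1-based inclusive on read.

## Synthetic data

The generator draws NB counts (variance μ + αμ²) for the six libraries.
Defaults — the conditions the validation runs use — are 5000 genes,
million-read libraries, α = 0.05, baselines log-uniform over 1–316 RPM,
5% genotype-specific genes (hard-zero mean in the other genotype, baseline
≥ 2 RPM so the detection boundary is exercised by a separate 50-gene class
at 0.3–0.6 RPM instead), eight planted pattern blocks of 50 genes at
fold 8, two planted enriched terms over 30-gene targets, 200 terms at a 5%
base annotation rate, two 30-Mb chromosomes with one QTL peak each, and
100 QTL-proximal genes.

Planted triplets are realized by per-stage mean multipliers in which every
significant step is a full fold change and every zero step an exact
equality; the multipliers are normalized so their minimum is 1, i.e. the
planted baseline (log-uniform over 100–316 RPM, a moderately-to-highly
expressed DE gene) is the gene's *lowest* stage mean.  This keeps every
significant comparison of a planted gene in the count regime where the
replicate-free test has power, so recovery failures indicate engine
defects rather than starvation.  Twelve of the 18 patterns are exactly
realizable this way; the six that exist only through threshold effects
(e.g. (1,0,0): a significant step whose overall change must nonetheless
test non-significant) are rejected by the generator with a configuration
error rather than planted unreliably.

What the generator does **not** emulate: read-level artifacts (mapping
bias, 3′ coverage bias, multi-mapping), correlated gene–gene expression,
GC or length effects on counts, annotation incompleteness, and real GO
structure.  Passing tests therefore demonstrate the correctness of the
statistical machinery under its own model assumptions, not robustness to
those real-data artifacts.

## Numerics and edge cases

* Exact-test point-mass comparisons use a 10⁻⁷ relative slack so ties are
  not lost to floating-point rounding; p-values are floored at the
  smallest subnormal double so log transforms stay finite.
* Size factors require ≥ 1 gene positive in every library and fail with
  guidance otherwise; an all-zero matrix is rejected.
* The dispersion fit falls back to a constant trend (with a warning) when
  fewer than 10 genes are usable.
* Zero-total genes get p = 1 by definition in both exact tests; empty
  study sets in enrichment warn and return an empty frame.
* Report percentages round half-up at the printed precision (so 12.5% at
  zero decimals prints 13); unrounded values are available alongside.
* Problem sizes in the validation suite: recovery and enrichment
  properties are asserted at the 5000-gene study conditions; pipeline
  identity and determinism checks run at 600–800 genes, a scale chosen to
  exercise every code path with the planted structure intact.

## Known limitations

* With one library per condition, dispersion is not identifiable per gene;
  everything rests on the fitted trend.  The trend is mildly conservative
  for strongly overdispersed data (NB tails vs the χ²₁ approximation).
* The exact conditional test saturates in power as counts grow (the
  per-library coefficient of variation tends to √α), so very large fold
  changes at huge counts can still yield only moderate p-values — a
  property of the model, not a bug.
* The ranking-value combination of p and ratio is monotone but otherwise a
  convention; rankings are comparable within a library pair only.
* Group numbering within narrative pairs follows the documented convention
  and cannot be cross-checked further against the source material.
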