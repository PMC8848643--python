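# Methods

This note documents the statistical models behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that matter for
reproducing results.

## Linkage disequilibrium

For two biallelic sites with haplotype frequencies
(p_AB, p_Ab, p_aB, p_ab),

    D  = p_AB − p_A · p_B,      r² = D² / (p_A p_a p_B p_b),

clipped to [0, 1] against float rounding. On phased haplotypes the
frequencies are direct counts. On unphased diploid genotypes only the
double-heterozygote class is phase-ambiguous; the EM estimator starts from
linkage equilibrium and reassigns that class by expected counts each
iteration (convergence: max absolute frequency change < 1e-8, cap 1000
iterations). Because the allele-frequency margins of the MLE equal the
observed allele frequencies, the likelihood has a single free parameter
(p_AB); the test suite exploits this with an exhaustive 1e-4 grid oracle.

`expand_index_snps` returns every variant within `window_kb` (default
1000) of an index SNP whose r² strictly exceeds `r2_min` (default 0.6),
plus the index itself at r² = 1. Phased haplotypes are used when the
input VCF carries them (all GTs `|`-separated), EM otherwise. Missing
genotypes are removed pairwise-complete; the choice is documented rather
than principled — reference LD panels are essentially complete.

## PWMs and exact match p-values

A position frequency matrix (PFM) with counts c_ib over A,C,G,T and
n sites becomes a log-odds PWM against background b:

    L_ib = log2( (c_ib + α·b_b) / (n + α) / b_b ),

with pseudocount α = 0.1 distributed by background frequency: large
enough to keep every entry finite, small enough not to perturb strong
columns. The background defaults to uniform; a 0-order background can be
estimated from the scanned sequences. A window's LLR score is the sum of
its per-column entries; windows containing N score −∞ (cannot match).

The match p-value is the probability, under i.i.d. background bases, that
one window scores at least the observed LLR. Each column contributes one
of four values with its background probability, so the null distribution
of the sum is a convolution of the per-column distributions. Up to width
10 the convolution is carried on the exact support (≤ 4^w distinct sums,
merged at 1e-12 resolution), so p-values agree with exhaustive window
enumeration to float precision; wider motifs use a shift-and-add DP on a
discretized grid of 10,000 × 100 cells, whose rounding error is orders of
magnitude below the p = 1e-3 decision threshold. The published
`ScoreDistribution` histogram uses 10,000 bins spanning exactly the
achievable score range. p is monotone non-increasing in the score, equals
1 at the minimum achievable score and 0 beyond the maximum.

## ZOOPS-EM motif discovery

Each peak-flank sequence is assumed to carry zero or one motif site
(probability γ of a site, uniform over offsets). For each candidate width
w in [min_w, max_w] (defaults 6–20), EM restarts are seeded from the 20
most frequent w-mers in the input (ties broken lexicographically, so
discovery is deterministic); initial column frequencies put 0.7 on the
seed base. All restarts run 8 batched iterations; the best by objective
is refined to convergence (relative log-likelihood change < 1e-6, cap 200
iterations). The objective is the ZOOPS log-likelihood ratio against the
0-order background penalized BIC-style by (3w/2)·ln(1 + expected sites),
which stops wider windows from winning on overfitted flanking columns.
After a motif is reported its sites are probabilistically erased: each
position's erasure probability is updated with the site posteriors, and
subsequent rounds down-weight overlapping offsets. Discovery operates on
the forward strand (sites are planted and scanned strand-aware
downstream).

Database matching scores a query against each database motif as the
maximum over relative offsets (overlap ≥ 4 columns) and both orientations
of the mean per-column Pearson correlation between frequency columns;
ties prefer smaller |offset|, then database order. This metric is a
design choice — simple, symmetric, and adequate for best-match retrieval;
it is not a calibrated motif-similarity p-value.

## Allele-aware scanning and disruption calling

For a variant the two allelic sequences are flank + allele + flank
(flank 20 bp; for indels the two sequences differ in length and the
variant span covers the full replaced segment). The reference allele is
validated against the genome. Per allele, the best (minimum-p) window
among those overlapping the variant span by at least one base, on either
strand, is retained; ties break by higher LLR, then leftmost offset, then
+ strand. Non-overlapping matches elsewhere in the flank are deliberately
ignored for calling.

Two calling modes:

- **one_pass** (default): disrupting iff exactly one allele's best
  overlapping match has p < 1e-3 — direction `loss` if the reference
  allele passes, `gain` if the alternate does.
- **delta**: disrupting iff the better allele passes and
  |LLR_ref − LLR_alt| > delta_min.

The threshold rule alone does not say how the two alleles are compared;
one_pass is the default because a binding-difference claim needs an
allelic contrast, but both behaviors ship. delta_llr is the difference of
the two alleles' best-match LLRs (best-vs-best rather than rescoring one
allele at the other's coordinates, which is ill-defined across indel
length changes); it flips sign under allele relabeling, and relabeling
never changes the disrupting boolean.

## Annotation

Category precedence: exonic > UTR5 > UTR3 > intronic > upstream >
downstream > intergenic, evaluated over all transcripts of all genes
(highest precedence wins; ties go to the lexicographically smaller gene
id so input order is irrelevant). UTR side is strand-aware; the
upstream/downstream window is 1000 bp from the strand-aware TSS/TES
(annotation tools differ here; the value is exposed). Exonic hits in
transcripts without CDS are exonic with a noncoding flag rather than a
separate category.

## Allele-specific expression

A heterozygous transcribed SNP with ref/alt read counts (r, a) is tested
against a null ratio (default 0.5) with the exact two-sided binomial
test, minimum-likelihood convention: p sums the probabilities of all
outcomes no more likely than the observed one. Records with r + a < 8
carry no p-value. The null ratio is accepted per SNP as input; the
reference-bias adjustment that produces it in consortium pipelines is
upstream of this package. On discrete counts the exact test is
conservative — the realized null rejection rate at α = 0.05 and depth 50
is ≈ 0.034, and the calibration tests compare against that exact rate,
not against α.

## eQTL integration and differential expression

Per dataset, expression is regressed on dosage by OLS (optional
covariates), two-sided t-test on the slope; missing values are dropped
pairwise-complete and constant dosages are an error. Support counts, per
SNP, the datasets in which any gene association reaches uncorrected
p < 0.05, with nested tiers ≥ 1 … = all. The four consortium datasets the
design mirrors each used their own pipelines; one additive linear model
is fixed here because the package's role is integration logic, not
re-deriving four pipelines. Case-control differential expression is a
per-gene Welch t-test on log2(x + 1) with Benjamini–Hochberg correction
at q < 0.05 — a declared stand-in for the source study's statistics.

## Synthetic data: what it does and does not emulate

- **Haplotype blocks**: proxy columns are constructed from exact
  haplotype counts (D = r·p(1−p) at equal MAFs) and assigned by seeded
  permutation, so realized r² is within count-rounding (~1/2n) of the
  target; diploids are random pairings. This controls pairwise r²
  directly but has no recombination map, no population history, and no
  multi-locus haplotype structure.
- **Peaks**: i.i.d. background with one PFM-sampled site per sequence at
  probability zoops_prob. No nucleosome bias, no peak-height/site
  correlation.
- **Disruption variants**: the reference allele completes an exact
  consensus site; the alternate allele is the lowest-frequency base at
  the motif's most informative column. The default planted motif is 8
  columns, one near-deterministic (0.97) and seven at 0.75 (~1.3
  bits/column): with that geometry a consensus site sits ~65× below the
  p = 1e-3 threshold and the single-base change lands ~3× above it, so
  calls are unambiguous. Null variants sit in plain i.i.d. background —
  chance motif matches remain possible there, and the measured
  false-positive rate (≈ 0.9% at the default conditions) reflects them.
- **Fixture mode** (`clean=True`, used by the end-to-end bundle): each
  variant's local background is resampled until the scan label equals
  the planted label, making the recorded truth exhaustive. The
  end-to-end check then verifies bookkeeping — that every summary table
  equals what the truth implies — not statistical performance; the
  sensitivity/FPR benchmark never uses fixture mode. The bundle's eQTL
  and DE tables are built the same way (near-orthogonal dosage columns,
  non-tested gene/dataset pairs omitted, null columns redrawn away from
  the significance boundary) so that tier counts and DE gene lists are
  deterministic consequences of the planted design.
- **ASE counts**: binomial draws at the stated depth and imbalance; no
  mapping bias, no overdispersion.

Passing tests on these generators demonstrates correctness of the
algorithms under their stated models, not performance on real ChIP-Seq,
genotype or expression data, which carry artifacts none of the
generators produce.

## Problem sizes and determinism

The shipped test suite and the acceptance script use: 50 random PWMs of
width 6–8 against exhaustive enumeration; 100 random 20-sample genotype
tables against the grid oracle; 500-sequence motif recovery at 5 seeds;
200 + 2000 variants for disruption calling; 10,000 null ASE simulations;
500 + 2000 eQTL simulations at n = 400; and an end-to-end bundle with 18
disrupting + 30 null variants, 4 eQTL datasets of 120 samples and a
24-vs-12 case-control design. Every random quantity flows from a single
seed through `numpy.random.default_rng`; reruns of the same config are
byte-identical, and the pipeline manifest records thresholds and input
and output checksums rather than timestamps.

## Known limitations

- Two-site EM only; no haplotype phasing beyond that, no D′, no
  clumping.
- 0-order backgrounds only; no Markov backgrounds or E-value calibration
  for discovered motifs, no Tomtom-style match p-values.
- Variants are scanned one at a time; nearby variants on the same
  haplotype are not scanned jointly.
- No amino-acid consequence or splice-site annotation.
- BCF/CRAM, tabix, and full VCF INFO parsing are out of scope.
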