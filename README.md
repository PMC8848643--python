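# regsnp

Identification of transcription-factor (TF) binding-disrupting regulatory
SNPs at disease risk loci, as a tested, reusable Python pipeline.

GWAS index SNPs tag risk loci but rarely pinpoint the causal variant:
most risk variants are noncoding and act by perturbing gene regulation.
`regsnp` implements the standard functional-genomics strategy for
prioritizing them:

1. **LD expansion** — expand each index SNP to its proxies with
   r² > 0.6 within 1 Mb, where r² is computed from two-locus haplotype
   frequencies (direct counting on phased genotypes, EM estimation on
   unphased ones).
2. **Motif models from ChIP-Seq** — extract ±20 bp flanks of the top 500
   peaks by height, learn position frequency matrices by
   expectation-maximization under a ZOOPS model (zero or one site per
   sequence), and match each learned motif against a PWM database
   (mean per-column Pearson correlation over offsets and orientations).
3. **Allele-aware scanning** — for each candidate SNP build both allelic
   41 bp sequences, score every motif window overlapping the variant by
   at least one base on both strands with the log-odds PWM
   `log2 P(seq|motif) / P(seq|background)`, and convert scores to exact
   null p-values by dynamic-programming convolution of the per-column
   score distributions. A SNP disrupts a TF's binding when the match is
   significant (p < 1e-3) on exactly one allele.
4. **Annotation** — genomic-context classification (exonic / UTR /
   intronic / upstream / downstream / intergenic) against gene models.
5. **Allele-specific expression** — exact two-sided binomial test of
   ref/alt RNA-Seq read counts against an expected null ratio, after a
   ≥ 8-read depth filter.
6. **eQTL integration** — additive linear regression of expression on
   dosage per dataset, cross-dataset support tiers (significant in ≥ 1,
   ≥ 2, ≥ 3, all datasets), and case-control differential expression
   (Welch t on log2(x+1), Benjamini–Hochberg q < 0.05).

A synthetic-data module generates every input with recorded ground truth
(haplotype blocks with controlled pairwise r², peaks with ZOOPS-planted
motif sites, variants whose alternate allele destroys a planted site,
allelic read counts, genotype-linked expression), so the whole pipeline is
testable without external downloads.

## Worked example

Generate a fully synthetic study and run the pipeline end to end:

```bash
regsnp simulate bundle --seed 3 --out demo
regsnp run --config demo/run.yaml
```

Individual stages are also exposed. LD expansion on the bundled genotypes
(one index SNP, five proxies planted at r² = 0.2, 0.61, 0.9, 0.0, 0.95):

```bash
$ regsnp expand-ld --vcf demo/genotypes.vcf --index demo/index_snps.txt \
    --out pairs.tsv
$ cat pairs.tsv
index_id  proxy_id  r2        distance_bp
index     index     1         0
index     proxy_2   0.608029  2000
index     proxy_3   0.895727  3000
index     proxy_5   0.952948  5000
```

Exactly the proxies planted above the 0.6 cutoff are returned (the
realized r² of each proxy differs from its target only by count
rounding). Allele-aware scanning of the candidate variants against the
motif database:

```bash
$ regsnp scan --vcf demo/candidates.vcf --fasta demo/genome.fa \
    --motifs demo/motif_db.meme --out calls.tsv
$ head -2 calls.tsv
variant  tf   p_ref        p_alt       llr_ref  llr_alt  delta    direction  disrupting
var_0    TF1  1.52588e-05  0.00326538  13.0291  6.43627  6.59279  loss       True
```

`var_0`'s reference allele completes a strong TF1 site (match p ≈ 1.5e-5);
the alternate allele at the motif's most informative column drops the
match below the p < 1e-3 threshold (p ≈ 3.3e-3), so the SNP is called a
binding **loss**. The ASE stage on the bundled counts reports
`10 of 30 depth-passing SNPs show ASE` — exactly the ten planted
imbalanced SNPs.

## Layout

- `src/regsnp/formats.py` — VCF / FASTA / BED / GTF / minimal-MEME I/O
  and the domain containers
- `src/regsnp/ld.py` — EM haplotype frequencies, r², LD expansion
- `src/regsnp/motif.py` — PWMs, ZOOPS-EM discovery, database matching,
  scanning, exact score p-values
- `src/regsnp/allelic.py` — allelic sequences, disruption calling,
  catalogue summaries
- `src/regsnp/annotation.py` — genomic-context classification
- `src/regsnp/ase.py` — allele-specific expression testing
- `src/regsnp/eqtl.py` — eQTL association, support tiers, case-control DE
- `src/regsnp/simulate.py` — ground-truth synthetic data generators
- `src/regsnp/pipeline.py`, `src/regsnp/cli.py` — orchestration and the
  `regsnp` command

See `docs/methods.md` for the models, numerical choices and limitations.
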