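"""Synthetic-data generators with recorded ground truth.

Every pipeline stage can be exercised without external downloads: the
generators here emulate haplotype blocks with controlled pairwise r²,
ChIP-Seq peak flanks with motif sites planted under a ZOOPS model,
variants whose alternate allele destroys a planted binding site, allelic
RNA-Seq read counts with a chosen imbalance, and genotype-linked
expression with stated effect sizes. All generators are deterministic
under their seed and record what they planted in a SimTruth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FeasibilityError, InputError
from .formats import (ALPHABET, MISSING, PFM, GenomicInterval, GenotypeMatrix,
                      Variant)

__all__ = ["SimTruth", "simulate_haplotype_block", "simulate_peak_set",
           "simulate_disruption_variants", "simulate_ase_counts",
           "simulate_eqtl_dataset", "default_disruption_pfm",
           "write_synthetic_bundle"]


@dataclass
class SimTruth:
    """Ground truth recorded by the generators; recovery tests read only this."""

    seed: int
    planted_ld: list = field(default_factory=list)          # ((index, proxy), r2)
    planted_motifs: list = field(default_factory=list)      # (PFM, site offsets)
    planted_disruptions: list = field(default_factory=list)  # (variant_id, tf, dir)
    planted_null_variants: list = field(default_factory=list)
    planted_ase: list = field(default_factory=list)         # (variant_id, imbalance)
    planted_eqtl: list = field(default_factory=list)        # (variant, gene, beta)


# ---------------------------------------------------------------------------
# Haplotype blocks with controlled r^2
# ---------------------------------------------------------------------------

def _proxy_column(index_hap: np.ndarray, target_r2: float, maf: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Proxy haplotype column with realized r² as close as counts allow.

    Haplotype counts are constructed exactly (D = r * pq for equal MAFs),
    then alleles are assigned by a seeded permutation; the realized r² is
    therefore within rounding (~1/2n) of the target.
    """
    n_hap = index_hap.size
    k = int(index_hap.sum())
    p = k / n_hap
    if target_r2 < 0 or target_r2 > 1:
        raise FeasibilityError(f"target r2 {target_r2} outside [0,1]")
    if target_r2 > 0:
        q = p  # equal MAFs make any r2 in [0,1] feasible
        pAB = p * q + np.sqrt(target_r2) * p * (1 - p)
        kB = k
    else:
        q = maf
        pAB = p * q
        kB = int(round(n_hap * q))
    n_AB = int(round(n_hap * pAB))
    n_AB = max(max(0, k + kB - n_hap), min(n_AB, min(k, kB)))
    proxy = np.zeros(n_hap, dtype=np.int8)
    a_idx = np.flatnonzero(index_hap == 1)
    b_idx = np.flatnonzero(index_hap == 0)
    proxy[rng.permutation(a_idx)[:n_AB]] = 1
    proxy[rng.permutation(b_idx)[:kB - n_AB]] = 1
    # realized haplotype r2 from exact counts
    pA, pB = k / n_hap, kB / n_hap
    d = n_AB / n_hap - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    realized = 0.0 if denom == 0 else float(d * d / denom)
    return proxy, realized


def simulate_haplotype_block(n_samples: int, target_r2_profile: list[float],
                             maf_range: tuple[float, float] = (0.2, 0.5),
                             seed: int = 0, chrom: str = "chr1",
                             index_pos: int = 1_000_000, spacing: int = 1000,
                             positions: list[int] | None = None,
                             index_maf: float = 0.3
                             ) -> tuple[GenotypeMatrix, SimTruth]:
    """Diploid genotypes for one index SNP plus proxies at planted r² values.

    The index SNP column is drawn at ``index_maf``; each entry of
    ``target_r2_profile`` yields one proxy SNP. Diploids are formed by
    pairing consecutive haplotypes after a seeded shuffle. ``positions``
    (1-based, parallel to the profile) overrides the default even spacing.
    """
    if any(t < 0 or t > 1 for t in target_r2_profile):
        raise FeasibilityError("target r2 values must lie in [0,1]")
    if not (0 < index_maf < 1):
        raise FeasibilityError("index_maf must be in (0,1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    k = int(round(n_hap * index_maf))
    if k in (0, n_hap):
        raise FeasibilityError("index SNP monomorphic at this n/maf")
    index_col = np.zeros(n_hap, dtype=np.int8)
    index_col[:k] = 1

    cols = [index_col]
    truth = SimTruth(seed=seed)
    for t in target_r2_profile:
        maf = float(rng.uniform(*maf_range))
        col, realized = _proxy_column(index_col, t, maf, rng)
        cols.append(col)
        truth.planted_ld.append((("index", f"proxy_{len(cols) - 1}"), realized))

    haps = np.stack(cols, axis=1)
    haps = haps[rng.permutation(n_hap)]
    dosages = haps[0::2] + haps[1::2]

    if positions is None:
        positions = [index_pos + j * spacing for j in range(1, len(cols))]
    if len(positions) != len(target_r2_profile):
        raise InputError("positions must match the r2 profile length")
    variants = [Variant(chrom, index_pos, "index", "A", "G")]
    variants += [Variant(chrom, positions[j - 1], f"proxy_{j}", "A", "G")
                 for j in range(1, len(cols))]
    gm = GenotypeMatrix([f"s{i}" for i in range(n_samples)], variants,
                        dosages.astype(np.int8), haps)
    return gm, truth


# ---------------------------------------------------------------------------
# Peak sequences with ZOOPS-planted motif sites
# ---------------------------------------------------------------------------

def _sample_site(pfm: PFM, rng: np.random.Generator) -> str:
    f = pfm.frequencies
    return "".join(ALPHABET[rng.choice(4, p=f[i] / f[i].sum())]
                   for i in range(pfm.width))


def _random_seq(length: int, background: np.ndarray,
                rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.choice(4, size=length, p=background))


def simulate_peak_set(pfm: PFM, n_seqs: int = 500, seq_len: int = 41,
                      zoops_prob: float = 0.9,
                      background: np.ndarray | None = None, seed: int = 0
                      ) -> tuple[list[str], SimTruth]:
    """Peak-flank sequences, each with at most one planted motif site.

    With probability ``zoops_prob`` a sequence carries one site sampled from
    the PFM at a uniform offset; otherwise it is pure background. Truth
    records the planted offset per sequence (None for background-only).
    """
    if seq_len < pfm.width:
        raise InputError("seq_len shorter than motif width")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    seqs, offsets = [], []
    for _ in range(n_seqs):
        s = _random_seq(seq_len, bg, rng)
        if rng.random() < zoops_prob:
            off = int(rng.integers(0, seq_len - pfm.width + 1))
            s = s[:off] + _sample_site(pfm, rng) + s[off + pfm.width:]
            offsets.append(off)
        else:
            offsets.append(None)
        seqs.append(s)
    truth = SimTruth(seed=seed, planted_motifs=[(pfm, offsets)])
    return seqs, truth


# ---------------------------------------------------------------------------
# Binding-disruption variants
# ---------------------------------------------------------------------------

def default_disruption_pfm(tf_name: str = "TF1", n_sites: int = 500) -> PFM:
    """A strong 8-column motif with one near-deterministic column.

    Column 4 concentrates 97% of its mass on one base, the rest carry 75%;
    mean information content is about 1.3 bits per column. A single-base
    change at the strong column moves an exact consensus site from far
    below to clearly above the p = 1e-3 match threshold, which is the
    disruption geometry the scanner is meant to detect.
    """
    rng = np.random.default_rng(20220216)
    cons = rng.integers(0, 4, size=8)
    freqs = np.full((8, 4), (1 - 0.75) / 3)
    freqs[np.arange(8), cons] = 0.75
    freqs[4] = (1 - 0.97) / 3
    freqs[4, cons[4]] = 0.97
    return PFM(tf_name, freqs * n_sites, n_sites)


def _consensus(pfm: PFM) -> str:
    return "".join(ALPHABET[int(i)] for i in pfm.frequencies.argmax(axis=1))


def simulate_disruption_variants(pfm: PFM, n_disrupting: int = 200,
                                 n_null: int = 2000, flank_bp: int = 20,
                                 spacing: int = 100, seed: int = 0,
                                 chrom: str = "chrSim",
                                 background: np.ndarray | None = None,
                                 clean: bool = False
                                 ) -> tuple[dict[str, str], list[Variant], SimTruth]:
    """Genome + variants: ref allele completes a planted site, alt destroys it.

    Disrupting variants sit at the motif's most informative column of an
    exact consensus site written into the genome; the alt allele is the
    lowest-scoring base at that column (a 'loss' of binding). Null variants
    sit in plain background with a random alternate base.

    ``clean=True`` additionally resamples each variant's local background
    until neither allele of a null variant, and only the ref allele of a
    disrupting variant, carries a significant overlapping match; this makes
    the recorded truth exhaustive (used by the end-to-end fixture, not by
    the calibration benchmarks).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    w = pfm.width
    ic_col = int((pfm.frequencies *
                  np.log2(np.clip(pfm.frequencies, 1e-12, None) / 0.25)
                  ).sum(axis=1).argmax())
    cons = _consensus(pfm)
    lo_order = np.argsort(pfm.frequencies[ic_col])  # ascending frequency
    ref_base = cons[ic_col]
    alt_base = ALPHABET[int(lo_order[0])]
    if alt_base == ref_base:  # degenerate column; take next-lowest
        alt_base = ALPHABET[int(lo_order[1])]

    n_total = n_disrupting + n_null
    genome_len = spacing * (n_total + 1)
    seq = list(_random_seq(genome_len, bg, rng))
    variants: list[Variant] = []
    truth = SimTruth(seed=seed)

    pwm = None
    if clean:
        from .motif import PWM
        pwm = PWM.from_pfm(pfm)

    order = rng.permutation(n_total)
    kinds = np.array(["disrupt"] * n_disrupting + ["null"] * n_null)[order]
    for i, kind in enumerate(kinds):
        center = spacing // 2 + i * spacing  # 0-based variant position
        for attempt in range(200):
            local = _random_seq(2 * flank_bp + w + 2, bg, rng)
            start = center - flank_bp - w // 2
            seq[start:start + len(local)] = list(local)
            if kind == "disrupt":
                site_start = center - ic_col
                seq[site_start:site_start + w] = list(cons)
                ref, alt = ref_base, alt_base
            else:
                ref = seq[center]
                others = [b for b in ALPHABET if b != ref]
                alt = others[int(rng.integers(0, 3))]
            v = Variant(chrom, center + 1, f"var_{i}", ref, alt)
            if not clean:
                break
            # fixture mode: require the call to match the label exactly
            if _clean_check(v, {chrom: "".join(seq)}, pwm, flank_bp, kind):
                break
        if kind == "disrupt":
            truth.planted_disruptions.append((v.id, pfm.tf_name, "loss"))
        else:
            truth.planted_null_variants.append(v.id)
        variants.append(v)
    return {chrom: "".join(seq)}, variants, truth


def _clean_check(v: Variant, genome: dict[str, str], pwm, flank_bp: int,
                 kind: str) -> bool:
    """True iff scanning this variant reproduces its planted label."""
    from .allelic import allelic_sequences, call_disruption, scan_alleles

    class _Mem:
        def fetch(self, chrom, start, end, strand="+"):
            s = genome[chrom]
            if start < 0 or end > len(s):
                raise InputError("window off contig")
            return s[start:end]

    seqs = allelic_sequences(v, _Mem(), flank_bp)
    ref_m, alt_m = scan_alleles(pwm, seqs)
    call = call_disruption(v, pwm.name, ref_m, alt_m)
    if kind == "disrupt":
        return call.disrupting and call.mode == "loss"
    return not call.disrupting


# ---------------------------------------------------------------------------
# ASE counts and eQTL datasets
# ---------------------------------------------------------------------------

def simulate_ase_counts(n_snps: int, depth: int | tuple = 50,
                        imbalance: float = 0.5, seed: int = 0,
                        id_prefix: str = "ase"
                        ) -> tuple[list[tuple[str, int, int]], SimTruth]:
    """Allelic read counts: ref ~ Binomial(depth, imbalance).

    ``depth`` is a constant, ("poisson", lam) or ("uniform", lo, hi).
    """
    if not (0.0 < imbalance < 1.0):
        raise InputError("imbalance must be in (0,1)")
    rng = np.random.default_rng(seed)
    if isinstance(depth, int):
        depths = np.full(n_snps, depth)
    elif depth[0] == "poisson":
        depths = rng.poisson(depth[1], size=n_snps)
    elif depth[0] == "uniform":
        depths = rng.integers(depth[1], depth[2] + 1, size=n_snps)
    else:
        raise InputError(f"unknown depth spec {depth!r}")
    counts = []
    truth = SimTruth(seed=seed)
    for i, d in enumerate(depths):
        ref = int(rng.binomial(int(d), imbalance))
        counts.append((f"{id_prefix}_{i}", ref, int(d) - ref))
        truth.planted_ase.append((f"{id_prefix}_{i}", imbalance))
    return counts, truth


def simulate_eqtl_dataset(n_samples: int, maf: float = 0.3, beta: float = 0.5,
                          noise_sd: float = 1.0, seed: int = 0,
                          variant_id: str = "snp", gene_id: str = "gene",
                          dataset: str = "ds"
                          ) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Dosages ~ Binomial(2, maf); expression = beta * dosage + N(0, sd)."""
    if not (0 < maf < 1):
        raise InputError("maf must be in (0,1)")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        dos = rng.binomial(2, maf, size=n_samples)
        if np.ptp(dos) > 0:
            break
    else:
        raise FeasibilityError("could not draw a polymorphic dosage vector")
    expr = beta * dos + rng.normal(0.0, noise_sd, size=n_samples)
    truth = SimTruth(seed=seed,
                     planted_eqtl=[(variant_id, gene_id, beta)])
    return dos.astype(np.int8), expr, truth


# ---------------------------------------------------------------------------
# End-to-end synthetic bundle
# ---------------------------------------------------------------------------

def _random_pfm(width: int, rng: np.random.Generator, name: str,
                sharp: float = 0.8) -> PFM:
    cons = rng.integers(0, 4, size=width)
    freqs = np.full((width, 4), (1 - sharp) / 3)
    freqs[np.arange(width), cons] = sharp
    return PFM(name, freqs * 200, 200)


def _bundle_gene_models():
    """Two designed genes on chrCand (coordinates chosen so every candidate
    variant's genomic category is known arithmetically)."""
    from .formats import GeneModel, Transcript

    gene_a = GeneModel("GENEA", "chrCand", "+", (Transcript(
        200, 2000, 400, 1850,
        ((200, 600), (1000, 1300), (1700, 2000))),))
    gene_b = GeneModel("GENEB", "chrCand", "-", (Transcript(
        2500, 3500, None, None, ((2500, 2800), (3200, 3500))),))
    return [gene_a, gene_b]


def _bundle_category(pos0: int, flank: int = 1000) -> str:
    """Independent arithmetic classification for the designed gene layout."""
    # gene A (+): tx [200,2000), CDS [400,1850), exons below
    a_exons = [(200, 600), (1000, 1300), (1700, 2000)]
    if any(s <= pos0 < e for s, e in a_exons):
        if 400 <= pos0 < 1850:
            return "exonic"
        return "UTR5" if pos0 < 400 else "UTR3"
    if 200 <= pos0 < 2000:
        return "intronic"
    # gene B (-): noncoding, tx [2500,3500)
    b_exons = [(2500, 2800), (3200, 3500)]
    if any(s <= pos0 < e for s, e in b_exons):
        return "exonic"
    if 2500 <= pos0 < 3500:
        return "intronic"
    # flanks (strand-aware)
    if 200 - flank <= pos0 < 200:
        return "upstream"
    if 2000 <= pos0 < 2000 + flank:
        cat_a = "downstream"
    else:
        cat_a = None
    if 3500 <= pos0 < 3500 + flank:
        cat_b = "upstream"
    elif 2500 - flank <= pos0 < 2500:
        cat_b = "downstream"
    else:
        cat_b = None
    if cat_a == "downstream" and cat_b == "upstream":
        return "upstream"  # upstream outranks downstream
    if cat_b == "upstream":
        return "upstream"
    if cat_a == "downstream" or cat_b == "downstream":
        return "downstream"
    return "intergenic"


def _write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for t_i, tx in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{t_i + 1}"
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                for es, ee in tx.exons:
                    fh.write(f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t"
                             f"{g.strand}\t.\t{attrs}\n")
                if tx.coding:
                    fh.write(f"{g.chrom}\tsim\tCDS\t{tx.cds_start + 1}\t"
                             f"{tx.cds_end}\t.\t{g.strand}\t.\t{attrs}\n")


def write_synthetic_bundle(out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic input bundle plus its ground truth.

    Produces genome FASTA, genotype and candidate VCFs, peaks BED, a motif
    database (planted TF plus decoys), gene models, ASE counts, per-dataset
    eQTL expression tables, case-control expression, a pipeline YAML and
    ``truth.json``. All signal is planted with wide margins (and local
    backgrounds resampled where a chance hit would contradict the label) so
    that the recorded truth is exhaustive: a correct pipeline recovers the
    catalogue exactly, which is what the end-to-end consistency check
    verifies. Returns the truth dictionary.
    """
    import json
    from pathlib import Path

    from scipy import stats as _stats

    from .formats import write_fasta, write_meme_motifs, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"seed": seed}

    # --- LD block ---------------------------------------------------------
    profile = [0.2, 0.61, 0.9, 0.0, 0.95]
    gm, ld_truth = simulate_haplotype_block(400, profile, seed=seed + 1)
    write_vcf(gm, out / "genotypes.vcf")
    (out / "index_snps.txt").write_text("index\n")
    truth["ld_realized"] = [[a, b, r] for (a, b), r in ld_truth.planted_ld]
    truth["ld_expected_proxies"] = sorted(
        ["index"] + [p for (_, p), r in ld_truth.planted_ld if r > 0.6])

    # --- motif database and peaks ----------------------------------------
    pfm = default_disruption_pfm("TF1")
    decoys = [_random_pfm(int(w), rng, f"DECOY{i + 1}")
              for i, w in enumerate(rng.integers(6, 13, size=7))]
    write_meme_motifs([pfm] + decoys, out / "motif_db.meme")

    seqs, _ = simulate_peak_set(pfm, n_seqs=120, seq_len=41,
                                zoops_prob=0.9, seed=seed + 2)
    spacer = 20
    parts, peaks = [], []
    pos = 0
    scores = rng.permutation(len(seqs)) + 10.0
    for i, s in enumerate(seqs):
        parts.append(_random_seq(spacer, np.full(4, 0.25), rng))
        pos += spacer
        peaks.append(("chrPeaks", pos, pos + len(s), f"peak{i}",
                      float(scores[i])))
        parts.append(s)
        pos += len(s)
    parts.append(_random_seq(spacer, np.full(4, 0.25), rng))
    chr_peaks = "".join(parts)
    with open(out / "peaks.bed", "w") as fh:
        for c, s, e, n, sc in peaks:
            fh.write(f"{c}\t{s}\t{e}\t{n}\t{sc:g}\n")

    # --- disruption candidates -------------------------------------------
    genome, variants, dtruth = simulate_disruption_variants(
        pfm, n_disrupting=18, n_null=30, seed=seed + 3, chrom="chrCand",
        clean=True)
    write_fasta({"chrPeaks": chr_peaks, "chrCand": genome["chrCand"]},
                out / "genome.fa")
    cand_gm = GenotypeMatrix(
        ["s0"], variants,
        np.ones((1, len(variants)), dtype=np.int8))
    write_vcf(cand_gm, out / "candidates.vcf")
    truth["disruptions"] = [[i, tf, d]
                            for i, tf, d in dtruth.planted_disruptions]
    truth["null_variants"] = list(dtruth.planted_null_variants)

    # --- gene models + truth locations for the disrupting SNPs -----------
    genes = _bundle_gene_models()
    _write_gtf(genes, out / "genes.gtf")
    disrupt_ids = {i for i, _, _ in dtruth.planted_disruptions}
    truth["locations"] = {v.id: _bundle_category(v.start)
                          for v in variants if v.id in disrupt_ids}

    # --- ASE counts -------------------------------------------------------
    rows = []
    flagged, filtered = [], []
    for i in range(10):  # strongly imbalanced
        d = 80
        ref = int(rng.binomial(d, 0.88))
        rows.append((f"ase_hi_{i}", ref, d - ref))
        flagged.append(f"ase_hi_{i}")
    for i in range(20):  # balanced, resampled clear of the 0.05 boundary
        d = 60
        for _ in range(200):
            ref = int(rng.binomial(d, 0.5))
            p = _stats.binomtest(ref, d, 0.5).pvalue
            if p >= 0.1:
                break
        rows.append((f"ase_null_{i}", ref, d - ref))
    for i in range(5):  # below read-depth filter
        rows.append((f"ase_low_{i}", int(rng.integers(0, 4)),
                     int(rng.integers(0, 4))))
        filtered.append(f"ase_low_{i}")
    with open(out / "ase_counts.tsv", "w") as fh:
        fh.write("variant\tref_count\talt_count\n")
        for vid, r, a in rows:
            fh.write(f"{vid}\t{r}\t{a}\n")
    truth["ase_flagged"] = flagged
    truth["ase_filtered"] = filtered

    # --- eQTL datasets ----------------------------------------------------
    n_eq = 120
    datasets = ["ds1", "ds2", "ds3", "ds4"]
    support_levels = [4, 4, 3, 3, 2, 2, 1, 1, 0, 0]
    esnps = []
    dosage_mat = np.zeros((n_eq, len(support_levels)), dtype=np.int8)
    for i in range(len(support_levels)):
        # keep dosage columns near-orthogonal so a planted effect at one
        # SNP cannot leak a nominal association onto another
        for _ in range(2000):
            dos = rng.binomial(2, 0.3, size=n_eq)
            if np.ptp(dos) == 0:
                continue
            if i == 0 or max(abs(float(np.corrcoef(dos, dosage_mat[:, j])[0, 1]))
                             for j in range(i)) < 0.1:
                break
        else:
            raise FeasibilityError("could not draw decorrelated dosages")
        dosage_mat[:, i] = dos
        esnps.append(Variant("chrEq", 1000 * (i + 1), f"esnp_{i}", "A", "G"))
    eq_gm = GenotypeMatrix([f"e{i}" for i in range(n_eq)], esnps, dosage_mat)
    write_vcf(eq_gm, out / "eqtl_genotypes.vcf")

    def _clean_gene(signal_dos, all_dos, rng, beta):
        """Expression column significant for its own SNP (if any) and
        clear of the nominal threshold for every other SNP."""
        for _ in range(500):
            e = rng.normal(0.0, 0.4, size=n_eq)
            expr = (beta * signal_dos if signal_dos is not None else 0.0) + e
            ok = True
            for j in range(all_dos.shape[1]):
                p = _stats.linregress(all_dos[:, j], expr).pvalue
                own = signal_dos is not None and np.array_equal(
                    all_dos[:, j], signal_dos)
                if own and p >= 0.005:
                    ok = False
                    break
                if not own and p < 0.1:
                    ok = False
                    break
            if ok:
                return expr
        raise FeasibilityError("could not draw a clean expression column")

    support_map = {}
    for ds_i, ds in enumerate(datasets):
        cols = {}
        for i, lvl in enumerate(support_levels):
            if ds_i < lvl:
                cols[f"gene_esnp_{i}"] = _clean_gene(
                    dosage_mat[:, i], dosage_mat, rng, beta=1.5)
        cols[f"nullgene_{ds}"] = _clean_gene(None, dosage_mat, rng, beta=0.0)
        import pandas as pd
        df = pd.DataFrame(cols, index=[f"e{i}" for i in range(n_eq)])
        df.index.name = "sample"
        df.reset_index().to_csv(out / f"eqtl_expr_{ds}.tsv", sep="\t",
                                index=False, float_format="%.6f")
    for i, lvl in enumerate(support_levels):
        support_map[f"esnp_{i}"] = lvl
    truth["eqtl_support"] = support_map

    # --- case-control DE --------------------------------------------------
    n_case, n_ctrl = 24, 12
    sample_ids = [f"pd{i}" for i in range(n_case)] + \
                 [f"ct{i}" for i in range(n_ctrl)]
    labels = np.array([1] * n_case + [0] * n_ctrl)
    genes_de = [f"deg_{i}" for i in range(40)]
    planted_de = genes_de[:4]
    X = np.zeros((40, n_case + n_ctrl))
    lab = labels.astype(bool)
    for gi, g in enumerate(genes_de):
        mu = float(rng.uniform(5, 9))
        if g in planted_de:
            row = np.empty(n_case + n_ctrl)
            row[lab] = rng.normal(mu + 1.0, 0.25, size=n_case)
            row[~lab] = rng.normal(mu, 0.25, size=n_ctrl)
        else:
            for _ in range(200):
                row = rng.normal(mu, 0.25, size=n_case + n_ctrl)
                p = _stats.ttest_ind(row[lab], row[~lab],
                                     equal_var=False).pvalue
                if p >= 0.1:
                    break
        X[gi] = 2.0 ** row
    import pandas as pd
    dfx = pd.DataFrame(X, index=genes_de, columns=sample_ids)
    dfx.index.name = "gene"
    dfx.to_csv(out / "de_expression.tsv", sep="\t", float_format="%.4f")
    pd.DataFrame({"sample": sample_ids, "label": labels}).to_csv(
        out / "de_labels.tsv", sep="\t", index=False)
    truth["de_genes"] = planted_de

    # --- pipeline config --------------------------------------------------
    cfg = {
        "out_dir": str(out / "results"),
        "genome_fasta": str(out / "genome.fa"),
        "genotypes_vcf": str(out / "genotypes.vcf"),
        "index_snps": str(out / "index_snps.txt"),
        "peaks_bed": str(out / "peaks.bed"),
        "motif_db": str(out / "motif_db.meme"),
        "candidates_vcf": str(out / "candidates.vcf"),
        "genes_gtf": str(out / "genes.gtf"),
        "ase_counts": str(out / "ase_counts.tsv"),
        "eqtl_genotypes_vcf": str(out / "eqtl_genotypes.vcf"),
        "eqtl_expression": {ds: str(out / f"eqtl_expr_{ds}.tsv")
                            for ds in datasets},
        "de_expression": str(out / "de_expression.tsv"),
        "de_labels": str(out / "de_labels.tsv"),
        "n_top_peaks": 100,
        "n_motifs": 1,
        "max_w": 12,
        "seed": seed,
    }
    import yaml
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
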