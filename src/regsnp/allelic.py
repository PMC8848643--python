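"""Allele-aware motif scanning and TF binding-disruption calling.

For each candidate variant both allelic flank sequences are built
(reference flank + allele + flank), every PWM window overlapping the
variant by at least one base is scored on both strands, and a variant is
called binding-disrupting for a TF when the motif-match p-value crosses
the significance threshold on exactly one allele (one_pass mode) or when
the allelic score difference exceeds a margin (delta mode).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ReferenceMismatchError
from .formats import SequenceStore, Variant
from .motif import PWM, encode, _window_scores

__all__ = ["AllelicSequences", "MotifMatch", "DisruptionCall",
           "allelic_sequences", "scan_alleles", "call_disruption",
           "scan_variant", "summarize_disruptions", "DisruptionSummary"]


@dataclass(frozen=True)
class AllelicSequences:
    variant: Variant
    ref_seq: str
    alt_seq: str
    ref_snp_span: tuple[int, int]  # [start, end) of the ref allele in ref_seq
    alt_snp_span: tuple[int, int]


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    allele: str            # 'ref' or 'alt'
    offset: int
    strand: str
    llr: float
    pvalue: float
    overlaps_variant: bool = True


@dataclass(frozen=True)
class DisruptionCall:
    variant: Variant
    tf_name: str
    best_ref_match: MotifMatch | None
    best_alt_match: MotifMatch | None
    delta_llr: float
    disrupting: bool
    mode: str  # 'loss', 'gain', 'delta' or 'none'


def allelic_sequences(variant: Variant, genome: SequenceStore,
                      flank_bp: int = 20) -> AllelicSequences:
    """Build the two allelic sequences flank + allele + flank.

    The variant's REF allele is validated against the genome; a mismatch is
    an error rather than a silent wrong scan.
    """
    obs = genome.fetch(variant.chrom, variant.start, variant.end)
    if obs.upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.id}: genome has {obs!r} at {variant.chrom}:{variant.pos}, "
            f"variant ref is {variant.ref!r}")
    left = genome.fetch(variant.chrom, variant.start - flank_bp, variant.start)
    right = genome.fetch(variant.chrom, variant.end, variant.end + flank_bp)
    ref_seq = left + variant.ref.upper() + right
    alt_seq = left + variant.alt.upper() + right
    return AllelicSequences(
        variant, ref_seq, alt_seq,
        (flank_bp, flank_bp + len(variant.ref)),
        (flank_bp, flank_bp + len(variant.alt)))


def _best_overlapping(pwm: PWM, seq: str, span: tuple[int, int],
                      allele: str) -> MotifMatch | None:
    """Minimum-p window among windows overlapping the variant span.

    Ties break toward higher llr, then leftmost offset, then + strand.
    """
    w = pwm.width
    if len(seq) < w:
        raise InputError(f"allelic sequence shorter than PWM width {w}")
    codes = encode(seq)
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement_matrix())
    dist = pwm.score_distribution()
    best = None
    for j in range(len(fwd)):
        if j >= span[1] or j + w <= span[0]:
            continue  # window does not overlap the variant
        for strand, score in (("+", fwd[j]), ("-", rev[j])):
            p = dist.pvalue(score)
            key = (p, -score, j, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, MotifMatch(pwm.name, allele, j, strand,
                                        float(score), float(p)))
    return None if best is None else best[1]


def scan_alleles(pwm: PWM, seqs: AllelicSequences,
                 p_threshold: float = 1e-3
                 ) -> tuple[MotifMatch | None, MotifMatch | None]:
    """Best variant-overlapping match on each allele, regardless of threshold."""
    ref = _best_overlapping(pwm, seqs.ref_seq, seqs.ref_snp_span, "ref")
    alt = _best_overlapping(pwm, seqs.alt_seq, seqs.alt_snp_span, "alt")
    return ref, alt


def call_disruption(variant: Variant, tf_name: str,
                    ref_match: MotifMatch | None,
                    alt_match: MotifMatch | None,
                    p_threshold: float = 1e-3,
                    mode: str = "one_pass",
                    delta_min: float = 0.0) -> DisruptionCall:
    """Classify a variant for one TF from its paired allelic matches.

    one_pass: disrupting iff exactly one allele's best overlapping match is
    significant (loss if ref, gain if alt). delta: disrupting iff the better
    allele is significant and |llr_ref - llr_alt| > delta_min.
    """
    if mode not in ("one_pass", "delta"):
        raise InputError(f"unknown mode {mode!r}")
    p_ref = ref_match.pvalue if ref_match else 1.0
    p_alt = alt_match.pvalue if alt_match else 1.0
    llr_ref = ref_match.llr if ref_match else -np.inf
    llr_alt = alt_match.llr if alt_match else -np.inf
    delta = llr_ref - llr_alt
    if not np.isfinite(delta):
        delta = 0.0 if llr_ref == llr_alt else delta

    ref_sig = p_ref < p_threshold
    alt_sig = p_alt < p_threshold
    if mode == "one_pass":
        if ref_sig and not alt_sig:
            return DisruptionCall(variant, tf_name, ref_match, alt_match,
                                  delta, True, "loss")
        if alt_sig and not ref_sig:
            return DisruptionCall(variant, tf_name, ref_match, alt_match,
                                  delta, True, "gain")
        return DisruptionCall(variant, tf_name, ref_match, alt_match,
                              delta, False, "none")
    disrupting = (ref_sig or alt_sig) and abs(delta) > delta_min
    return DisruptionCall(variant, tf_name, ref_match, alt_match,
                          delta, disrupting, "delta" if disrupting else "none")


def scan_variant(variant: Variant, genome: SequenceStore, pwms: list[PWM],
                 flank_bp: int = 20, p_threshold: float = 1e-3,
                 mode: str = "one_pass", delta_min: float = 0.0
                 ) -> list[DisruptionCall]:
    """Convenience: build allelic sequences and call disruption for each PWM."""
    seqs = allelic_sequences(variant, genome, flank_bp)
    calls = []
    for pwm in pwms:
        ref_m, alt_m = scan_alleles(pwm, seqs, p_threshold)
        calls.append(call_disruption(variant, pwm.name, ref_m, alt_m,
                                     p_threshold, mode, delta_min))
    return calls


@dataclass
class DisruptionSummary:
    per_tf_counts: dict[str, int]           # TF -> number of disrupting SNPs
    per_snp_multiplicity: dict[str, int]    # SNP id -> number of TFs disrupted
    co_disruption: "np.ndarray"             # TF x TF symmetric SNP counts
    tf_order: list[str]


def summarize_disruptions(calls: list[DisruptionCall]) -> DisruptionSummary:
    """Per-TF SNP counts, per-SNP TF multiplicity, TF-pair co-disruption."""
    snp_tfs: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        if c.disrupting:
            snp_tfs[c.variant.id].add(c.tf_name)
    tfs = sorted({tf for s in snp_tfs.values() for tf in s})
    tf_idx = {tf: i for i, tf in enumerate(tfs)}
    per_tf = {tf: 0 for tf in tfs}
    co = np.zeros((len(tfs), len(tfs)), dtype=int)
    multiplicity = {}
    for snp, ts in snp_tfs.items():
        multiplicity[snp] = len(ts)
        for tf in ts:
            per_tf[tf] += 1
        ts_sorted = sorted(ts)
        for i, a in enumerate(ts_sorted):
            for b in ts_sorted[i + 1:]:
                co[tf_idx[a], tf_idx[b]] += 1
                co[tf_idx[b], tf_idx[a]] += 1
    return DisruptionSummary(per_tf, multiplicity, co, tfs)
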