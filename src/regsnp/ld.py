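"""Linkage-disequilibrium r² and LD expansion of GWAS index SNPs.

r² between two sites is computed from two-locus haplotype frequencies. On
unphased diploid genotypes the four haplotype frequencies are estimated by
an EM algorithm that resolves the double-heterozygote phase ambiguity by
expected counts — the same estimator classic LD software applies before
thresholding proxies at r² > 0.6 within 1 Mb of each index SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedLdError
from .formats import MISSING, GenotypeMatrix

__all__ = ["LdPair", "em_haplotype_freqs", "haplotype_freqs_phased", "r2",
           "r2_from_dosages", "genotype_correlation_r2", "expand_index_snps"]


@dataclass(frozen=True)
class LdPair:
    index_id: str
    proxy_id: str
    r2: float
    distance_bp: int


def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise InsufficientDataError("dosage vectors differ in length")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size < 2:
        raise InsufficientDataError(
            f"only {a.size} pairwise-complete samples (need >= 2)")
    return a, b


def em_haplotype_freqs(dosages_a: np.ndarray, dosages_b: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 1000
                       ) -> tuple[float, float, float, float]:
    """EM haplotype frequencies (pAB, pAb, paB, pab) from unphased dosages.

    'A'/'B' denote the ALT alleles at the two sites (dosage counts ALT).
    Starts from linkage equilibrium; only the double-heterozygote class is
    phase-ambiguous, and its haplotype assignment is updated by expected
    counts each iteration. Converges when the largest absolute frequency
    change drops below ``tol``.
    """
    a, b = _pairwise_complete(dosages_a, dosages_b)
    n = a.size
    if len(set(a.tolist())) == 1 or len(set(b.tolist())) == 1:
        raise UndefinedLdError("monomorphic site: LD undefined")

    # 3x3 genotype table: rows dosage at A, cols dosage at B
    tab = np.zeros((3, 3))
    np.add.at(tab, (a, b), 1.0)

    pA = a.mean() / 2.0
    pB = b.mean() / 2.0
    # haplotypes: AB, Ab, aB, ab  (uppercase = ALT allele present)
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_hap = 2.0 * n
    ndh = tab[1, 1]  # double heterozygotes

    # Haplotype counts fixed by the unambiguous genotype classes: any
    # genotype pair with at most one heterozygous site has a forced phase.
    fixed = np.zeros(4)
    for dA in range(3):
        for dB in range(3):
            if dA == 1 and dB == 1:
                continue
            cnt = tab[dA, dB]
            if cnt == 0:
                continue
            hapA = [1, 0] if dA == 1 else ([1, 1] if dA == 2 else [0, 0])
            hapB = [1, 0] if dB == 1 else ([1, 1] if dB == 2 else [0, 0])
            for hA, hB in zip(hapA, hapB):
                idx = (1 - hA) * 2 + (1 - hB)  # AB=0, Ab=1, aB=2, ab=3
                fixed[idx] += cnt

    for _ in range(max_iter):
        # E-step: split double heterozygotes between AB/ab and Ab/aB phases
        denom = p[0] * p[3] + p[1] * p[2]
        frac_cis = 0.5 if denom == 0 else (p[0] * p[3]) / denom
        counts = fixed.copy()
        counts[0] += ndh * frac_cis
        counts[3] += ndh * frac_cis
        counts[1] += ndh * (1 - frac_cis)
        counts[2] += ndh * (1 - frac_cis)
        new_p = counts / n_hap
        if np.max(np.abs(new_p - p)) < tol:
            p = new_p
            break
        p = new_p
    return tuple(float(x) for x in p)


def haplotype_freqs_phased(haps_a: np.ndarray, haps_b: np.ndarray
                           ) -> tuple[float, float, float, float]:
    """Direct haplotype counting on phased 0/1 haplotype vectors."""
    a = np.asarray(haps_a)
    b = np.asarray(haps_b)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise InsufficientDataError("no complete haplotypes")
    n = a.size
    pAB = float(np.sum((a == 1) & (b == 1))) / n
    pAb = float(np.sum((a == 1) & (b == 0))) / n
    paB = float(np.sum((a == 0) & (b == 1))) / n
    pab = float(np.sum((a == 0) & (b == 0))) / n
    return pAB, pAb, paB, pab


def r2(freqs: tuple[float, float, float, float]) -> float:
    """r² = D² / (pA pa pB pb) with D = pAB − pA·pB, clipped to [0, 1]."""
    pAB, pAb, paB, pab = freqs
    pA = pAB + pAb
    pB = pAB + paB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise UndefinedLdError("zero allele-frequency margin: r2 undefined")
    d = pAB - pA * pB
    return float(np.clip(d * d / denom, 0.0, 1.0))


def r2_from_dosages(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """EM-based r² between two unphased dosage vectors."""
    return r2(em_haplotype_freqs(dosages_a, dosages_b))


def genotype_correlation_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages — a cross-check estimator."""
    a, b = _pairwise_complete(dosages_a, dosages_b)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedLdError("monomorphic site: LD undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def expand_index_snps(index_ids: list[str], genotypes: GenotypeMatrix,
                      window_kb: int = 1000, r2_min: float = 0.6,
                      use_phase: bool = True) -> list[LdPair]:
    """Return all proxies with r² strictly above ``r2_min`` within the window.

    Each index SNP pairs with itself (r² = 1). Distance is measured index
    position to proxy position. Output is ordered by (index id order,
    proxy position). Variants whose pairwise LD is undefined (monomorphic
    in the pairwise-complete overlap) are silently not proxies.
    """
    pos = np.array([v.pos for v in genotypes.variants])
    chroms = np.array([v.chrom for v in genotypes.variants])
    window_bp = window_kb * 1000

    missing = [i for i in index_ids
               if all(v.id != i for v in genotypes.variants)]
    if missing:
        raise KeyError(f"index SNP(s) not in genotype matrix: {missing}")

    pairs: list[LdPair] = []
    for idx_id in index_ids:
        j = genotypes.variant_index(idx_id)
        v_idx = genotypes.variants[j]
        near = np.where((chroms == v_idx.chrom)
                        & (np.abs(pos - v_idx.pos) <= window_bp))[0]
        hits: list[LdPair] = []
        for k in near:
            if k == j:
                hits.append(LdPair(idx_id, idx_id, 1.0, 0))
                continue
            try:
                if use_phase and genotypes.phased_haplotypes is not None:
                    freqs = haplotype_freqs_phased(
                        genotypes.phased_haplotypes[:, j],
                        genotypes.phased_haplotypes[:, k])
                else:
                    freqs = em_haplotype_freqs(genotypes.dosages[:, j],
                                               genotypes.dosages[:, k])
                val = r2(freqs)
            except (UndefinedLdError, InsufficientDataError):
                continue
            if val > r2_min:
                hits.append(LdPair(idx_id, genotypes.variants[k].id, val,
                                   int(abs(pos[k] - v_idx.pos))))
        hits.sort(key=lambda p: pos[genotypes.variant_index(p.proxy_id)])
        pairs.extend(hits)
    return pairs
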