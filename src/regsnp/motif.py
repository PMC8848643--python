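"""PWM construction, motif discovery, scanning and exact match p-values.

This module replaces the MEME/FIMO steps of a TF-binding functional-genomics
pipeline:

* ``top_peak_flanks`` extracts fixed-width sequences around the summits of
  the strongest ChIP-Seq peaks,
* ``discover_motifs_zoops`` learns position frequency matrices from those
  sequences by expectation-maximization under a ZOOPS model (zero or one
  motif occurrence per sequence),
* ``match_to_database`` finds the closest motif in a PWM database,
* ``score_windows`` scans a sequence with a log-odds PWM on both strands, and
* ``score_pvalue`` converts a log-likelihood-ratio score into an exact
  p-value under an i.i.d. background via dynamic-programming convolution of
  the per-column score distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .errors import InputError
from .formats import ALPHABET, PFM, GenomicInterval, SequenceStore

log = logging.getLogger(__name__)

_ENC = np.full(256, 4, dtype=np.int8)  # everything unknown -> 4 ('N')
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

UNIFORM_BG = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Map a sequence to int codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def estimate_background(seqs: list[str]) -> np.ndarray:
    """0-order background from base composition (ACGT only)."""
    counts = np.zeros(4)
    for s in seqs:
        e = encode(s)
        counts += np.bincount(e[e < 4], minlength=4)
    tot = counts.sum()
    if tot == 0:
        return UNIFORM_BG.copy()
    return counts / tot


# ---------------------------------------------------------------------------
# PWM and exact score distribution
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Log-odds matrix over ACGT against an i.i.d. background.

    log_odds[i, b] = log2( (counts[i, b] + pseudocount*bg[b])
                           / (n_sites + pseudocount) / bg[b] )
    """

    name: str
    log_odds: np.ndarray  # width x 4
    background: np.ndarray
    pseudocount: float = 0.1
    _dist: "ScoreDistribution | None" = field(default=None, repr=False,
                                              compare=False)

    @classmethod
    def from_pfm(cls, pfm: PFM, background: np.ndarray | None = None,
                 pseudocount: float = 0.1) -> "PWM":
        bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
        if not np.isclose(bg.sum(), 1.0):
            raise InputError("background must sum to 1")
        counts = pfm.counts
        # scale counts so rows sum to n_sites (counts may come from
        # probability matrices scaled arbitrarily)
        rows = counts.sum(axis=1, keepdims=True)
        counts = counts / np.where(rows == 0, 1, rows) * pfm.n_sites
        num = counts + pseudocount * bg
        lo = np.log2(num / (pfm.n_sites + pseudocount) / bg)
        return cls(pfm.tf_name, lo, bg, pseudocount)

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def reverse_complement_matrix(self) -> np.ndarray:
        return self.log_odds[::-1, ::-1]

    def score_distribution(self, n_bins: int = 10_000) -> "ScoreDistribution":
        if self._dist is None or len(self._dist.probabilities) != n_bins:
            self._dist = build_score_distribution(self, n_bins=n_bins)
        return self._dist


@dataclass
class ScoreDistribution:
    """Discretized null distribution of single-window PWM scores.

    ``bin_edges``/``probabilities`` expose the distribution at the requested
    resolution; p-value queries use a finer internal grid so that the
    per-column rounding error stays far below the p = 1e-3 decision
    threshold.
    """

    bin_edges: np.ndarray       # n_bins + 1, spanning [min, max] achievable
    probabilities: np.ndarray   # n_bins, sums to 1
    _support: np.ndarray        # sorted achievable scores (exact mode) or grid
    _sf: np.ndarray             # survival function P(score >= support point)
    _min_total: float
    _max_total: float

    def pvalue(self, score: float) -> float:
        """P(window score >= ``score``) for one window of i.i.d. background."""
        if not np.isfinite(score):
            return 1.0 if score < 0 else 0.0
        if score <= self._min_total + 1e-11:
            return 1.0
        if score > self._max_total + 1e-11:
            return 0.0
        idx = int(np.searchsorted(self._support, score - 1e-11, side="left"))
        idx = min(idx, len(self._sf) - 1)
        return float(self._sf[idx])


_EXACT_MAX_WIDTH = 10  # 4^10 = ~1e6 distinct sums still fits comfortably


def build_score_distribution(pwm: PWM, n_bins: int = 10_000,
                             oversample: int = 100) -> ScoreDistribution:
    """DP convolution of the per-column score distributions.

    Each column contributes one of four log-odds values with its background
    probability. Up to width 10 the convolution is carried out on the exact
    support (at most 4^w distinct sums, merged at 1e-9 resolution), so
    p-values agree with exhaustive window enumeration to float precision;
    wider motifs fall back to a fine discretized grid of
    ``n_bins * oversample`` cells, whose rounding error is negligible
    relative to the p = 1e-3 decision threshold.
    """
    lo = pwm.log_odds
    bg = pwm.background
    min_total = float(lo.min(axis=1).sum())
    max_total = float(lo.max(axis=1).sum())
    span = max_total - min_total

    if span <= 0:  # uniform PWM: every window scores min_total
        edges = np.linspace(min_total - 0.5, min_total + 0.5, n_bins + 1)
        probs = np.zeros(n_bins)
        probs[n_bins // 2] = 1.0
        return ScoreDistribution(edges, probs, np.array([min_total]),
                                 np.array([1.0]), min_total, max_total)

    if pwm.width <= _EXACT_MAX_WIDTH:
        vals = np.zeros(1)
        pmf = np.ones(1)
        for i in range(pwm.width):
            vals = (vals[:, None] + lo[i][None, :]).ravel()
            pmf = (pmf[:, None] * bg[None, :]).ravel()
            keys = np.round(vals / 1e-12).astype(np.int64)
            uniq, inv = np.unique(keys, return_inverse=True)
            merged = np.zeros(len(uniq))
            np.add.at(merged, inv, pmf)
            vals = uniq * 1e-12
            pmf = merged
        order = np.argsort(vals)
        support = vals[order]
        pmf = pmf[order]
    else:
        eps = span / (n_bins * oversample)
        col_min = lo.min(axis=1)
        z = np.rint((lo - col_min[:, None]) / eps).astype(np.int64)  # w x 4
        pmf = np.zeros(1)
        pmf[0] = 1.0
        cur = 1
        for i in range(pwm.width):
            zi = z[i]
            new = np.zeros(cur + int(zi.max()))
            for b in range(4):
                new[zi[b]:zi[b] + cur] += bg[b] * pmf[:cur]
            pmf = new
            cur = len(new)
        support = min_total + eps * np.arange(cur)

    sf = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    edges = np.linspace(min_total, max_total, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, support, side="right") - 1,
                  0, n_bins - 1)
    probs = np.bincount(idx, weights=pmf, minlength=n_bins)
    return ScoreDistribution(edges, probs, support, sf, min_total, max_total)


def score_pvalue(pwm: PWM, score: float, n_bins: int = 10_000) -> float:
    """Exact null p-value of a single-window LLR score (see ScoreDistribution)."""
    return pwm.score_distribution(n_bins).pvalue(score)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of every window of len(matrix) in codes; N windows -> -inf."""
    w = matrix.shape[0]
    if codes.size < w:
        return np.empty(0)
    win = sliding_window_view(codes, w)           # m x w
    valid = (win < 4).all(axis=1)
    safe = np.where(win < 4, win, 0)
    scores = matrix[np.arange(w), safe].sum(axis=1)
    return np.where(valid, scores, -np.inf)


def score_windows(pwm: PWM, seq: str) -> list[tuple[int, str, float]]:
    """Score all windows of ``seq`` on both strands.

    A match on the minus strand at offset ``j`` means the reverse complement
    of ``seq[j:j+w]`` matches the motif; it is scored with the
    reverse-complemented matrix at the same forward coordinates.
    """
    if len(seq) < pwm.width:
        raise InputError(
            f"sequence of length {len(seq)} shorter than PWM width {pwm.width}")
    codes = encode(seq)
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement_matrix())
    out = []
    for j in range(len(fwd)):
        out.append((j, "+", float(fwd[j])))
        out.append((j, "-", float(rev[j])))
    return out


# ---------------------------------------------------------------------------
# Peak flanks
# ---------------------------------------------------------------------------

def top_peak_flanks(peaks: list[GenomicInterval], genome: SequenceStore,
                    n_top: int = 500, flank_bp: int = 20) -> list[str]:
    """Sequences at summit +/- flank_bp of the n_top highest-scoring peaks.

    The summit is the interval midpoint. Peaks whose window would run off
    the contig are dropped (counted in the log). Score ties break toward
    lower (chrom, start).
    """
    if not peaks or all(p.score == 0 for p in peaks):
        raise InputError("no scored peaks")
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))[:n_top]
    seqs = []
    dropped = 0
    for p in ranked:
        mid = p.midpoint
        start, end = mid - flank_bp, mid + flank_bp + 1
        try:
            seqs.append(genome.fetch(p.chrom, start, end))
        except Exception:
            dropped += 1
    if dropped:
        log.info("top_peak_flanks: dropped %d peaks truncated by contig ends",
                 dropped)
    return seqs


# ---------------------------------------------------------------------------
# ZOOPS-EM motif discovery
# ---------------------------------------------------------------------------

def _seed_wmers(groups: list[np.ndarray], w: int, n_seeds: int) -> np.ndarray:
    """Most frequent w-mers across all sequences (deterministic order)."""
    keys = []
    for codes in groups:
        if codes.shape[1] < w:
            continue
        win = sliding_window_view(codes, w, axis=1).reshape(-1, w)
        valid = (win < 4).all(axis=1)
        win = win[valid]
        if len(win) == 0:
            continue
        # pack each w-mer into one integer (w <= 31 fits in int64 base 4)
        packed = (win * (4 ** np.arange(w, dtype=np.int64))).sum(axis=1)
        keys.append(packed)
    if not keys:
        raise InputError(f"no valid {w}-mers in input")
    packed = np.concatenate(keys)
    uniq, counts = np.unique(packed, return_counts=True)
    order = np.lexsort((uniq, -counts))  # by count desc, then lexicographic
    top = uniq[order[:n_seeds]]
    out = np.empty((len(top), w), dtype=np.int64)
    for i, p in enumerate(top):
        for k in range(w):
            out[i, k] = p % 4
            p //= 4
    return out


def _zoops_em(groups: list[np.ndarray], onehots: list[np.ndarray],
              erasure_logw: list[np.ndarray] | None,
              freqs: np.ndarray, gammas: np.ndarray, log_bg: np.ndarray,
              n_iter: int, tol: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list]:
    """Batched ZOOPS EM.

    groups: sequences encoded, grouped by length (each n_g x L_g);
    onehots: matching n_g x m_g x w x 4 window one-hot tensors;
    freqs: R x w x 4 motif frequencies; gammas: R site probabilities.
    Returns updated (freqs, gammas, objective LLR per restart, expected
    n_sites per restart, per-group posteriors of the restarts).
    """
    R, w, _ = freqs.shape
    prev_llr = None
    for it in range(n_iter):
        logratio = np.log(np.clip(freqs, 1e-300, None)) - log_bg  # R x w x 4
        new_counts = np.zeros((R, w, 4))
        q_sum = np.zeros(R)
        llr = np.zeros(R)
        n_seq = 0
        posts = []
        for g, (codes, oh) in enumerate(zip(groups, onehots)):
            n_g, m_g = oh.shape[0], oh.shape[1]
            n_seq += n_g
            scores = np.einsum("nmwb,rwb->rnm", oh, logratio)  # R x n x m
            if erasure_logw is not None:
                scores = scores + erasure_logw[g][None, :, :]
            log_prior = np.log(gammas / m_g)[:, None, None]
            log_site = log_prior + scores                       # R x n x m
            log_nosite = np.log1p(-gammas)[:, None]             # R x 1
            tot = np.logaddexp(
                logsumexp(log_site, axis=2), log_nosite)        # R x n
            post = np.exp(log_site - tot[:, :, None])           # R x n x m
            posts.append(post)
            new_counts += np.einsum("rnm,nmwb->rwb", post, oh)
            q_sum += post.sum(axis=(1, 2))
            llr += tot.sum(axis=1)
        # M-step
        pseudo = 0.1 * np.exp(log_bg)                           # 1 x? w? -> 4
        counts = new_counts + pseudo
        freqs = counts / counts.sum(axis=2, keepdims=True)
        gammas = np.clip(q_sum / n_seq, 1e-4, 1 - 1e-4)
        if tol > 0 and prev_llr is not None:
            if np.all(np.abs(llr - prev_llr) < tol * (np.abs(llr) + 1)):
                prev_llr = llr
                break
        prev_llr = llr
    return freqs, gammas, prev_llr, q_sum, posts


def discover_motifs_zoops(seqs: list[str], n_motifs: int = 5,
                          min_w: int = 6, max_w: int = 20, seed: int = 0,
                          n_restarts: int = 20, max_iter: int = 200,
                          tol: float = 1e-6,
                          background: np.ndarray | None = None) -> list[PFM]:
    """EM motif discovery under a ZOOPS model.

    For each candidate width, ``n_restarts`` EM runs are started from the
    most enriched w-mers, iterated briefly, and the best restart (by a
    BIC-penalized log-likelihood-ratio objective against the 0-order
    background) is refined to convergence. The best width wins; its sites
    are probabilistically erased and discovery repeats ``n_motifs`` times.
    Fully deterministic for fixed inputs and seed.
    """
    if len(seqs) < 2:
        raise InputError("need at least 2 sequences")
    if any(len(s) < min_w for s in seqs):
        raise InputError(f"all sequences must be at least min_w={min_w} long")
    max_w = min(max_w, min(len(s) for s in seqs))
    if max_w < min_w:
        raise InputError("max_w < min_w after clipping to sequence lengths")

    bg = estimate_background(seqs) if background is None else np.asarray(background)
    bg = np.clip(bg, 1e-6, None)
    bg = bg / bg.sum()
    log_bg = np.log(bg)

    # group sequences by length for vectorization
    by_len: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(encode(s))
    groups = [np.stack(v) for _, v in sorted(by_len.items())]

    # erasure state: probability each position is covered by a found motif
    erasure = [np.zeros(g.shape, dtype=float) for g in groups]

    rng = np.random.default_rng(seed)  # reserved; discovery itself is closed-form
    del rng

    found: list[PFM] = []
    for _ in range(n_motifs):
        best = None  # (objective, freqs, gamma, q, w, posts)
        for w in range(min_w, max_w + 1):
            onehots = []
            eras_logw = []
            for g, codes in enumerate(groups):
                win = sliding_window_view(codes, w, axis=1)  # n x m x w
                oh = (win[..., None] == np.arange(4)).astype(np.float32)
                oh[(win >= 4)] = 0.0  # N contributes nothing / kills ratio
                onehots.append(oh)
                log1m = np.log1p(-np.clip(erasure[g], 0, 1 - 1e-12))
                sw = sliding_window_view(log1m, w, axis=1).sum(axis=2)
                eras_logw.append(sw)

            seeds = _seed_wmers(groups, w, n_restarts)
            R = len(seeds)
            freqs = np.full((R, w, 4), 0.1)
            freqs[np.arange(R)[:, None], np.arange(w)[None, :], seeds] = 0.7
            gammas = np.full(R, 0.5)

            freqs, gammas, llr, q, _ = _zoops_em(
                groups, onehots, eras_logw, freqs, gammas, log_bg, n_iter=8)
            obj = llr - 1.5 * w * np.log1p(q)
            r = int(np.argmax(obj))
            f1, g1, llr1, q1, posts1 = _zoops_em(
                groups, onehots, eras_logw, freqs[r:r + 1], gammas[r:r + 1],
                log_bg, n_iter=max_iter, tol=tol)
            obj1 = float(llr1[0] - 1.5 * w * np.log1p(q1[0]))
            if best is None or obj1 > best[0]:
                best = (obj1, f1[0], float(g1[0]), float(q1[0]), w,
                        [p[0] for p in posts1])
        obj1, f, gamma, q, w, posts = best
        n_sites = max(1, int(round(q)))
        found.append(PFM(f"motif_{len(found) + 1}", f * n_sites, n_sites))

        # probabilistic erasure of the found sites
        for g, post in enumerate(posts):
            n_g, L = groups[g].shape
            m = post.shape[1]
            log_keep = np.zeros((n_g, L))
            logp = np.log1p(-np.clip(post, 0, 1 - 1e-12))
            for j in range(m):
                log_keep[:, j:j + w] += logp[:, j:j + 1]
            cov = 1.0 - np.exp(log_keep)
            erasure[g] = 1.0 - (1.0 - erasure[g]) * (1.0 - cov)
    return found


# ---------------------------------------------------------------------------
# Database matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDbMatch:
    motif: PFM
    similarity: float
    orientation: str  # '+' (forward) or '-' (reverse complement)
    offset: int       # db motif start relative to query start


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two frequency 4-vectors; degenerate -> {0,1}."""
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if np.allclose(a, b, atol=1e-9) else 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))


def _alignment_similarity(qf: np.ndarray, df: np.ndarray, min_overlap: int
                          ) -> tuple[float, int]:
    qw, dw = len(qf), len(df)
    best, best_off = -np.inf, 0
    for off in range(-(dw - min_overlap), qw - min_overlap + 1):
        lo, hi = max(0, off), min(qw, off + dw)
        if hi - lo < min_overlap:
            continue
        cols = [_column_corr(qf[j], df[j - off]) for j in range(lo, hi)]
        sim = float(np.mean(cols))
        if sim > best + 1e-12 or (abs(sim - best) <= 1e-12
                                  and abs(off) < abs(best_off)):
            best, best_off = sim, off
    return best, best_off


def match_to_database(query: PFM, db: list[PFM]) -> MotifDbMatch:
    """Best database motif by mean per-column Pearson correlation.

    The similarity is maximized over relative offsets with at least four
    overlapping columns (fewer if a motif is shorter) and both orientations.
    Ties break toward smaller |offset|, then database order, then forward
    orientation.
    """
    if not db:
        raise InputError("empty motif database")
    qf = query.frequencies
    best: MotifDbMatch | None = None
    for pfm in db:
        for orient in "+-":
            df = (pfm.frequencies if orient == "+"
                  else pfm.reverse_complement().frequencies)
            min_ov = min(4, len(qf), len(df))
            sim, off = _alignment_similarity(qf, df, min_ov)
            cand = MotifDbMatch(pfm, sim, orient, off)
            if best is None:
                best = cand
                continue
            if (sim > best.similarity + 1e-12
                or (abs(sim - best.similarity) <= 1e-12
                    and abs(off) < abs(best.offset))):
                best = cand
    return best
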