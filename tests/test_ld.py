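import numpy as np
import pytest

from regsnp.errors import InsufficientDataError, UndefinedLdError
from regsnp.ld import (em_haplotype_freqs, expand_index_snps,
                       genotype_correlation_r2, haplotype_freqs_phased, r2,
                       r2_from_dosages)
from regsnp.simulate import simulate_haplotype_block


def grid_mle_pAB(dos_a, dos_b, step=1e-4):
    """Brute-force 1-D grid maximizer of the two-locus multinomial likelihood.

    The allele-frequency margins of the MLE equal the observed frequencies,
    so only pAB is free; this oracle scans it exhaustively.
    """
    a, b = np.asarray(dos_a), np.asarray(dos_b)
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    tab = np.zeros((3, 3))
    np.add.at(tab, (a, b), 1.0)
    pA, pB = a.mean() / 2, b.mean() / 2
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.arange(lo, hi + step / 2, step)
    best_ll, best = -np.inf, lo
    for pAB in grid:
        p = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
        if (p < -1e-12).any():
            continue
        p = np.clip(p, 1e-300, None)
        # genotype class probabilities from random union of two haplotypes
        gp = np.zeros((3, 3))
        hA = np.array([1, 1, 0, 0])
        hB = np.array([1, 0, 1, 0])
        for i in range(4):
            for j in range(4):
                gp[hA[i] + hA[j], hB[i] + hB[j]] += p[i] * p[j]
        ll = float((tab * np.log(np.clip(gp, 1e-300, None))).sum())
        if ll > best_ll:
            best_ll, best = ll, pAB
    return best


class TestEmHaplotypeFreqs:
    def test_no_double_heterozygotes_equals_direct_counting(self):
        # genotypes chosen so every sample has at most one het site
        a = np.array([0, 0, 1, 2, 2, 1, 0, 2])
        b = np.array([0, 0, 0, 2, 2, 0, 1, 1])
        freqs = em_haplotype_freqs(a, b)
        # direct counting: phase forced for every sample
        hapA = np.concatenate([[x > 0, x > 1] for x in a]).astype(int)
        # per-sample forced pairing (enumerate by hand): counts below
        expected = np.zeros(4)
        for dA, dB in zip(a, b):
            pairs = {(0, 0): [(0, 0), (0, 0)], (0, 1): [(0, 1), (0, 0)],
                     (0, 2): [(0, 1), (0, 1)], (1, 0): [(1, 0), (0, 0)],
                     (1, 2): [(1, 1), (0, 1)], (2, 0): [(1, 0), (1, 0)],
                     (2, 1): [(1, 1), (1, 0)], (2, 2): [(1, 1), (1, 1)]}
            for hA, hB in pairs[(dA, dB)]:
                expected[(1 - hA) * 2 + (1 - hB)] += 1
        np.testing.assert_allclose(freqs, expected / 16, atol=1e-9)

    def test_identical_vectors_give_perfect_ld(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=200)
        pAB, pAb, paB, pab = em_haplotype_freqs(d, d)
        assert pAb == pytest.approx(0.0, abs=1e-8)
        assert paB == pytest.approx(0.0, abs=1e-8)
        assert pAB == pytest.approx(d.mean() / 2, abs=1e-8)
        assert r2((pAB, pAb, paB, pab)) == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, 50)
        b = rng.binomial(2, 0.3, 50)
        assert sum(em_haplotype_freqs(a, b)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_likelihood_maximizer(self):
        """EM equals a 1e-4 grid-search MLE on random 20-sample tables."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            a = rng.binomial(2, rng.uniform(0.2, 0.8), 20)
            b = rng.binomial(2, rng.uniform(0.2, 0.8), 20)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            pAB_em = em_haplotype_freqs(a, b)[0]
            pAB_grid = grid_mle_pAB(a, b)
            assert pAB_em == pytest.approx(pAB_grid, abs=1.5e-4)
            checked += 1

    def test_monomorphic_site_is_undefined(self):
        with pytest.raises(UndefinedLdError):
            em_haplotype_freqs(np.zeros(10, dtype=int),
                               np.array([0, 1] * 5))

    def test_all_missing_overlap_is_insufficient(self):
        a = np.array([0, 1, -1, -1])
        b = np.array([-1, -1, 0, 1])
        with pytest.raises(InsufficientDataError):
            em_haplotype_freqs(a, b)


class TestR2:
    def test_complete_ld(self):
        assert r2((0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # pAB = pA * pB exactly
        assert r2((0.12, 0.18, 0.28, 0.42)) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_hand_value(self):
        # D = 0.4 - 0.25 = 0.15; r2 = 0.15^2 / 0.5^4 = 0.36
        assert r2((0.4, 0.1, 0.1, 0.4)) == pytest.approx(0.36)

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedLdError):
            r2((0.5, 0.5, 0.0, 0.0))

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.4, 300)
        b = rng.binomial(2, 0.3, 300)
        v1 = r2_from_dosages(a, b)
        assert r2_from_dosages(b, a) == pytest.approx(v1, abs=1e-9)
        assert r2_from_dosages(2 - a, b) == pytest.approx(v1, abs=1e-9)
        assert r2_from_dosages(a, 2 - b) == pytest.approx(v1, abs=1e-9)


class TestPhasedCounting:
    def test_em_equals_direct_counting_without_ambiguity(self):
        """When the genotype data contain no double heterozygotes the EM
        fixed point is exactly the direct haplotype count."""
        haps_a = np.array([1, 1, 0, 0, 1, 0, 0, 0])
        haps_b = np.array([1, 1, 0, 0, 0, 1, 0, 0])
        direct = haplotype_freqs_phased(haps_a, haps_b)
        dos_a = haps_a[0::2] + haps_a[1::2]
        dos_b = haps_b[0::2] + haps_b[1::2]
        if not np.any((dos_a == 1) & (dos_b == 1)):
            em = em_haplotype_freqs(dos_a, dos_b)
            np.testing.assert_allclose(em, direct, atol=1e-9)

    def test_em_r2_tracks_generating_haplotype_r2(self):
        """RMSE of EM r2 against planted haplotype r2 < 0.02 at n=500."""
        errs = []
        for seed in range(10):
            gm, truth = simulate_haplotype_block(
                500, [0.1, 0.3, 0.5, 0.7, 0.9], seed=seed)
            for j, ((_, _), planted) in enumerate(truth.planted_ld, start=1):
                est = r2_from_dosages(gm.dosages[:, 0], gm.dosages[:, j])
                errs.append(est - planted)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.02


class TestExpandIndexSnps:
    def test_planted_profile_recovers_exactly_the_high_ld_proxies(self):
        gm, truth = simulate_haplotype_block(500, [0.2, 0.61, 0.9], seed=3)
        pairs = expand_index_snps(["index"], gm)
        assert [p.proxy_id for p in pairs] == ["index", "proxy_2", "proxy_3"]
        assert pairs[0].r2 == pytest.approx(1.0)

    def test_window_bound_excludes_distant_proxy(self):
        gm, _ = simulate_haplotype_block(
            300, [0.99, 0.99], seed=5, index_pos=2_000_000,
            positions=[2_000_500, 3_000_001])  # second is 1,000,001 bp away
        pairs = expand_index_snps(["index"], gm, window_kb=1000)
        assert [p.proxy_id for p in pairs] == ["index", "proxy_1"]

    def test_no_polymorphic_neighbors_yields_self_pair_only(self):
        gm, _ = simulate_haplotype_block(100, [], seed=1)
        pairs = expand_index_snps(["index"], gm)
        assert [(p.index_id, p.proxy_id, p.r2) for p in pairs] == \
            [("index", "index", 1.0)]

    def test_missing_index_id_raises_lookup_error(self):
        gm, _ = simulate_haplotype_block(50, [0.5], seed=1)
        with pytest.raises(KeyError, match="rs_missing"):
            expand_index_snps(["rs_missing"], gm)

    def test_unphased_fallback_matches_phase_for_strong_ld(self):
        gm, _ = simulate_haplotype_block(500, [0.9], seed=9)
        with_phase = expand_index_snps(["index"], gm, use_phase=True)
        gm.phased_haplotypes = None
        without = expand_index_snps(["index"], gm, use_phase=False)
        assert [p.proxy_id for p in with_phase] == [p.proxy_id for p in without]


def test_genotype_correlation_r2_close_to_em_on_phased_blocks():
    gm, _ = simulate_haplotype_block(800, [0.7], seed=11)
    em = r2_from_dosages(gm.dosages[:, 0], gm.dosages[:, 1])
    gc = genotype_correlation_r2(gm.dosages[:, 0], gm.dosages[:, 1])
    assert abs(em - gc) < 0.05
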