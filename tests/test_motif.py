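import itertools

import numpy as np
import pytest

from regsnp.errors import InputError
from regsnp.formats import PFM, GenomicInterval, read_fasta, write_fasta
from regsnp.motif import (PWM, build_score_distribution,
                          discover_motifs_zoops, match_to_database,
                          score_pvalue, score_windows, top_peak_flanks)
from regsnp.simulate import simulate_peak_set


def enumeration_pvalue(pwm, score):
    """Oracle: exhaustive sum over all 4^w windows under the background."""
    w = pwm.width
    lo = pwm.log_odds
    bg = pwm.background
    total = 0.0
    for window in itertools.product(range(4), repeat=w):
        s = sum(lo[i, b] for i, b in enumerate(window))
        if s >= score - 1e-12:
            total += float(np.prod([bg[b] for b in window]))
    return total


def uniform_pwm(width=5):
    return PWM.from_pfm(PFM("U", np.full((width, 4), 25.0), 100),
                        pseudocount=0.0)


class TestPwm:
    def test_log_odds_definition(self):
        counts = np.array([[60, 20, 10, 10.0]])
        pwm = PWM.from_pfm(PFM("T", counts, 100), pseudocount=0.1)
        expected = np.log2((counts[0] + 0.1 * 0.25) / 100.1 / 0.25)
        np.testing.assert_allclose(pwm.log_odds[0], expected)

    def test_uniform_pwm_scores_zero(self):
        pwm = uniform_pwm()
        assert pwm.max_score == pytest.approx(0.0)
        for _, _, s in score_windows(pwm, "ACGTACGTA"):
            assert s == pytest.approx(0.0)


class TestScoreWindows:
    def test_window_count_and_hand_summed_scores(self):
        rng = np.random.default_rng(0)
        counts = rng.dirichlet([1] * 4, size=4) * 50
        pwm = PWM.from_pfm(PFM("T", counts, 50))
        seq = "ACGTACGT"
        hits = score_windows(pwm, seq)
        assert len(hits) == 2 * 5  # 5 offsets x 2 strands
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for off, strand, s in hits:
            if strand == "+":
                expected = sum(pwm.log_odds[i, code[seq[off + i]]]
                               for i in range(4))
                assert s == pytest.approx(expected)

    def test_strand_symmetry_under_reverse_complement(self):
        from regsnp.formats import reverse_complement
        rng = np.random.default_rng(1)
        counts = rng.dirichlet([0.7] * 4, size=6) * 80
        pwm = PWM.from_pfm(PFM("T", counts, 80))
        seq = "ACGTTTGACCAGT"
        fwd = score_windows(pwm, seq)
        rev = score_windows(pwm, reverse_complement(seq))
        multiset = sorted(round(s, 9) for _, _, s in fwd)
        multiset_rc = sorted(round(s, 9) for _, _, s in rev)
        assert multiset == multiset_rc
        by_strand = lambda hits, st: sorted(
            round(s, 9) for _, x, s in hits if x == st)
        assert by_strand(fwd, "+") == by_strand(rev, "-")

    def test_window_with_n_scores_minus_infinity(self):
        pwm = uniform_pwm(4)
        scores = dict(((o, st), s) for o, st, s in score_windows(pwm, "ACNTACGT"))
        assert scores[(0, "+")] == -np.inf
        assert scores[(4, "+")] == 0.0

    def test_sequence_shorter_than_width_rejected(self):
        with pytest.raises(InputError):
            score_windows(uniform_pwm(6), "ACG")


class TestScorePvalue:
    @pytest.mark.parametrize("bg", [np.full(4, 0.25),
                                    np.array([0.2, 0.3, 0.3, 0.2])])
    def test_dp_matches_enumeration(self, bg):
        rng = np.random.default_rng(5)
        for _ in range(3):
            w = int(rng.integers(5, 8))
            counts = rng.dirichlet([0.5] * 4, size=w) * 100
            pwm = PWM.from_pfm(PFM("T", counts, 100), background=bg)
            lo = pwm.log_odds
            scores = [float(lo[np.arange(w),
                              rng.integers(0, 4, w)].sum())
                      for _ in range(8)]
            for s in scores:
                p_dp = score_pvalue(pwm, s)
                p_enum = enumeration_pvalue(pwm, s)
                assert p_dp == pytest.approx(p_enum, rel=1e-3)

    def test_tail_boundaries(self, sharp_pfm):
        pwm = PWM.from_pfm(sharp_pfm)
        assert score_pvalue(pwm, pwm.max_score + 1.0) == 0.0
        assert score_pvalue(pwm, pwm.min_score) == 1.0
        assert score_pvalue(pwm, -np.inf) == 1.0

    def test_monotone_non_increasing(self, sharp_pfm):
        pwm = PWM.from_pfm(sharp_pfm)
        grid = np.linspace(pwm.min_score, pwm.max_score, 200)
        ps = [score_pvalue(pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_distribution_sums_to_one_and_spans_support(self, sharp_pfm):
        pwm = PWM.from_pfm(sharp_pfm)
        dist = build_score_distribution(pwm)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert dist.bin_edges[0] == pytest.approx(pwm.min_score)
        assert dist.bin_edges[-1] == pytest.approx(pwm.max_score)

    def test_column_permutation_does_not_change_pvalues(self):
        rng = np.random.default_rng(9)
        counts = rng.dirichlet([0.6] * 4, size=6) * 60
        pwm1 = PWM.from_pfm(PFM("A", counts, 60))
        pwm2 = PWM.from_pfm(PFM("B", counts[::-1], 60))
        for q in np.linspace(pwm1.min_score, pwm1.max_score, 25):
            assert score_pvalue(pwm1, q) == pytest.approx(
                score_pvalue(pwm2, q), rel=1e-9, abs=1e-12)


class TestTopPeakFlanks:
    def test_top_k_by_score(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        peaks = [GenomicInterval("chr1", 100, 141, "p1", 10.0),
                 GenomicInterval("chr1", 200, 241, "p2", 99.0),
                 GenomicInterval("chr1", 300, 341, "p3", 50.0)]
        out = top_peak_flanks(peaks, genome, n_top=2, flank_bp=20)
        assert len(out) == 2
        assert out[0] == seqs["chr1"][200:241]  # highest score first
        assert out[1] == seqs["chr1"][300:341]

    def test_truncated_peak_dropped(self, tiny_genome):
        path, _ = tiny_genome
        genome = read_fasta(path)
        peaks = [GenomicInterval("chrS", 5, 15, "edge", 5.0),
                 GenomicInterval("chr1", 100, 141, "ok", 4.0)]
        out = top_peak_flanks(peaks, genome, n_top=2, flank_bp=20)
        assert len(out) == 1

    def test_score_tie_breaks_by_position(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        peaks = [GenomicInterval("chr1", 300, 341, "b", 7.0),
                 GenomicInterval("chr1", 100, 141, "a", 7.0)]
        out = top_peak_flanks(peaks, genome, n_top=1, flank_bp=20)
        assert out[0] == seqs["chr1"][100:141]

    def test_unscored_peaks_rejected(self, tiny_genome):
        path, _ = tiny_genome
        genome = read_fasta(path)
        with pytest.raises(InputError):
            top_peak_flanks([GenomicInterval("chr1", 100, 141)], genome)


class TestZoopsDiscovery:
    def test_recovers_planted_motif(self, sharp_pfm):
        seqs, _ = simulate_peak_set(sharp_pfm, n_seqs=300, seq_len=41,
                                    zoops_prob=0.9, seed=21)
        found = discover_motifs_zoops(seqs, n_motifs=1, max_w=12, seed=1)
        m = match_to_database(found[0], [sharp_pfm])
        assert m.similarity >= 0.9

    def test_deterministic_given_seed(self, sharp_pfm):
        seqs, _ = simulate_peak_set(sharp_pfm, n_seqs=60, seq_len=41,
                                    zoops_prob=0.9, seed=2)
        a = discover_motifs_zoops(seqs, n_motifs=1, max_w=10, seed=3)
        b = discover_motifs_zoops(seqs, n_motifs=1, max_w=10, seed=3)
        np.testing.assert_array_equal(a[0].counts, b[0].counts)

    def test_background_sequences_give_low_information_motif(self, sharp_pfm):
        rng = np.random.default_rng(4)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 41))
                for _ in range(120)]
        found = discover_motifs_zoops(seqs, n_motifs=1, max_w=10, seed=1)
        planted_seqs, _ = simulate_peak_set(sharp_pfm, n_seqs=120,
                                            seq_len=41, zoops_prob=0.9,
                                            seed=4)
        planted_found = discover_motifs_zoops(planted_seqs, n_motifs=1,
                                              max_w=10, seed=1)
        assert found[0].information_content() < \
            planted_found[0].information_content()

    def test_too_short_sequences_rejected(self):
        with pytest.raises(InputError):
            discover_motifs_zoops(["ACG", "ACGTACGT"], min_w=6)


class TestMatchToDatabase:
    def test_self_match(self, sharp_pfm):
        m = match_to_database(sharp_pfm, [sharp_pfm])
        assert m.similarity == pytest.approx(1.0)
        assert (m.orientation, m.offset) == ("+", 0)

    def test_reverse_complement_match(self, sharp_pfm):
        m = match_to_database(sharp_pfm.reverse_complement(), [sharp_pfm])
        assert m.similarity == pytest.approx(1.0)
        assert m.orientation == "-"

    def test_noisy_planted_copy_is_argmax(self, sharp_pfm):
        rng = np.random.default_rng(12)
        noisy = np.clip(sharp_pfm.frequencies
                        + rng.normal(0, 0.05, sharp_pfm.counts.shape),
                        1e-3, None)
        noisy /= noisy.sum(axis=1, keepdims=True)
        query = PFM("noisy", noisy * 100, 100)
        decoys = []
        for i in range(9):
            cons = rng.integers(0, 4, int(rng.integers(6, 12)))
            f = np.full((len(cons), 4), 0.1)
            f[np.arange(len(cons)), cons] = 0.7
            decoys.append(PFM(f"D{i}", f * 100, 100))
        db = decoys[:4] + [sharp_pfm] + decoys[4:]
        m = match_to_database(query, db)
        assert m.motif.tf_name == "SHARP"

    def test_empty_database_rejected(self, sharp_pfm):
        with pytest.raises(InputError):
            match_to_database(sharp_pfm, [])
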