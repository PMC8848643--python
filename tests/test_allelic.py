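import numpy as np
import pytest

from regsnp.allelic import (allelic_sequences, call_disruption, scan_alleles,
                            scan_variant, summarize_disruptions)
from regsnp.errors import BoundaryError, ReferenceMismatchError
from regsnp.formats import PFM, Variant, read_fasta, reverse_complement, \
    write_fasta
from regsnp.motif import PWM
from regsnp.simulate import (default_disruption_pfm,
                             simulate_disruption_variants)


class MemGenome:
    def __init__(self, seqs):
        self.seqs = seqs

    def fetch(self, chrom, start, end, strand="+"):
        s = self.seqs[chrom]
        if start < 0 or end > len(s):
            raise BoundaryError(f"{chrom}:{start}-{end}")
        out = s[start:end]
        return reverse_complement(out) if strand == "-" else out


@pytest.fixture
def disruption_setup():
    pfm = default_disruption_pfm()
    genome, variants, truth = simulate_disruption_variants(
        pfm, n_disrupting=30, n_null=30, seed=17)
    return PWM.from_pfm(pfm), MemGenome(genome), variants, truth


class TestAllelicSequences:
    def test_snv_gives_two_41bp_strings_differing_at_center(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        pos = 101  # 1-based
        ref = seqs["chr1"][100]
        alt = "ACGT".replace(ref, "")[0]
        v = Variant("chr1", pos, "snv", ref, alt)
        a = allelic_sequences(v, genome, flank_bp=20)
        assert len(a.ref_seq) == 41 and len(a.alt_seq) == 41
        diffs = [i for i, (x, y) in enumerate(zip(a.ref_seq, a.alt_seq))
                 if x != y]
        assert diffs == [20]
        assert a.ref_snp_span == (20, 21)

    def test_insertion_lengthens_alt_sequence(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        ref = seqs["chr1"][200]
        v = Variant("chr1", 201, "ins", ref, ref + "GA")
        a = allelic_sequences(v, genome, flank_bp=20)
        assert len(a.ref_seq) == 41
        assert len(a.alt_seq) == 43
        assert a.alt_snp_span == (20, 23)

    def test_reference_mismatch_raises(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        ref = seqs["chr1"][100]
        wrong = "ACGT".replace(ref, "")[0]
        v = Variant("chr1", 101, "bad", wrong, ref)
        with pytest.raises(ReferenceMismatchError, match="bad"):
            allelic_sequences(v, genome)

    def test_flank_off_contig_raises_boundary_error(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        v = Variant("chr1", 3, "edge", seqs["chr1"][2],
                    "ACGT".replace(seqs["chr1"][2], "")[0])
        with pytest.raises(BoundaryError):
            allelic_sequences(v, genome, flank_bp=20)


class TestScanAndCall:
    def test_planted_disruption_called_loss(self, disruption_setup):
        pwm, genome, variants, truth = disruption_setup
        disrupt_ids = {d[0] for d in truth.planted_disruptions}
        v = next(v for v in variants if v.id in disrupt_ids)
        seqs = allelic_sequences(v, genome)
        ref_m, alt_m = scan_alleles(pwm, seqs)
        assert ref_m.pvalue < 1e-3
        assert alt_m.pvalue >= 1e-3
        call = call_disruption(v, pwm.name, ref_m, alt_m)
        assert call.disrupting and call.mode == "loss"
        assert call.delta_llr > 0

    def test_uniform_pwm_matches_nothing(self, tiny_genome):
        path, seqs = tiny_genome
        genome = read_fasta(path)
        pwm = PWM.from_pfm(PFM("U", np.full((6, 4), 25.0), 100),
                           pseudocount=0.0)
        ref = seqs["chr1"][300]
        v = Variant("chr1", 301, "v", ref, "ACGT".replace(ref, "")[0])
        ref_m, alt_m = scan_alleles(pwm, allelic_sequences(v, genome))
        assert ref_m.llr == pytest.approx(0.0)
        assert ref_m.pvalue == 1.0
        assert alt_m.pvalue == 1.0

    def test_only_overlapping_windows_considered(self, disruption_setup):
        pwm, genome, variants, truth = disruption_setup
        v = variants[0]
        seqs = allelic_sequences(v, genome)
        ref_m, _ = scan_alleles(pwm, seqs)
        w = pwm.width
        span = seqs.ref_snp_span
        assert ref_m.offset < span[1] and ref_m.offset + w > span[0]

    @pytest.mark.parametrize("p_ref,p_alt,expect,mode_out", [
        (1e-5, 0.2, True, "loss"),
        (0.2, 1e-5, True, "gain"),
        (1e-5, 1e-5, False, "none"),
        (0.5, 0.5, False, "none"),
    ])
    def test_one_pass_rule(self, p_ref, p_alt, expect, mode_out):
        from regsnp.allelic import MotifMatch
        v = Variant("chr1", 100, "v", "A", "G")
        rm = MotifMatch("TF", "ref", 15, "+", 8.0, p_ref)
        am = MotifMatch("TF", "alt", 15, "+", 8.0, p_alt)
        call = call_disruption(v, "TF", rm, am)
        assert call.disrupting is expect
        assert call.mode == mode_out

    def test_delta_mode_requires_score_difference(self):
        from regsnp.allelic import MotifMatch
        v = Variant("chr1", 100, "v", "A", "G")
        rm = MotifMatch("TF", "ref", 15, "+", 9.0, 1e-5)
        am = MotifMatch("TF", "alt", 15, "+", 4.0, 2e-3)
        assert call_disruption(v, "TF", rm, am, mode="delta").disrupting
        am_same = MotifMatch("TF", "alt", 15, "+", 9.0, 1e-5)
        assert not call_disruption(v, "TF", rm, am_same,
                                   mode="delta").disrupting


class TestAlleleAndStrandSymmetry:
    def test_swapping_alleles_flips_direction_not_disrupting(
            self, disruption_setup):
        pwm, genome, variants, truth = disruption_setup
        disrupt_ids = {d[0] for d in truth.planted_disruptions}
        checked = 0
        for v in variants[:20]:
            seqs = allelic_sequences(v, genome)
            rm, am = scan_alleles(pwm, seqs)
            fwd = call_disruption(v, pwm.name, rm, am)
            # swapped: scan with ref/alt roles exchanged
            swapped = call_disruption(v, pwm.name, am, rm)
            assert swapped.disrupting == fwd.disrupting
            assert swapped.delta_llr == pytest.approx(-fwd.delta_llr)
            if fwd.mode == "loss":
                assert swapped.mode == "gain"
                checked += 1
        assert checked > 0

    def test_reverse_complement_scan_gives_same_calls(self, disruption_setup):
        pwm, genome, variants, truth = disruption_setup
        from regsnp.allelic import AllelicSequences
        for v in variants[:10]:
            seqs = allelic_sequences(v, genome)
            rc = AllelicSequences(
                v, reverse_complement(seqs.ref_seq),
                reverse_complement(seqs.alt_seq),
                (len(seqs.ref_seq) - seqs.ref_snp_span[1],
                 len(seqs.ref_seq) - seqs.ref_snp_span[0]),
                (len(seqs.alt_seq) - seqs.alt_snp_span[1],
                 len(seqs.alt_seq) - seqs.alt_snp_span[0]))
            rm, am = scan_alleles(pwm, seqs)
            rm_rc, am_rc = scan_alleles(pwm, rc)
            assert rm_rc.pvalue == pytest.approx(rm.pvalue)
            assert am_rc.pvalue == pytest.approx(am.pvalue)
            assert rm_rc.strand != rm.strand or rm.llr == pytest.approx(
                rm_rc.llr)


class TestSummarize:
    def _call(self, vid, tf, disrupting=True):
        v = Variant("chr1", 100, vid, "A", "G")
        return call_disruption(
            v, tf,
            __import__("regsnp.allelic", fromlist=["MotifMatch"]).MotifMatch(
                tf, "ref", 15, "+", 9.0, 1e-5 if disrupting else 0.5),
            None)

    def test_counts_and_co_disruption(self):
        calls = [self._call("s1", "TFA"), self._call("s1", "TFB"),
                 self._call("s2", "TFA")]
        summary = summarize_disruptions(calls)
        assert summary.per_tf_counts == {"TFA": 2, "TFB": 1}
        assert summary.per_snp_multiplicity == {"s1": 2, "s2": 1}
        i, j = (summary.tf_order.index("TFA"), summary.tf_order.index("TFB"))
        assert summary.co_disruption[i, j] == 1
        assert np.array_equal(summary.co_disruption,
                              summary.co_disruption.T)

    def test_empty_input_gives_empty_summary(self):
        summary = summarize_disruptions([])
        assert summary.per_tf_counts == {}
        assert summary.co_disruption.size == 0

    def test_per_tf_count_equals_indicator_sum(self, disruption_setup):
        pwm, genome, variants, truth = disruption_setup
        calls = []
        for v in variants:
            calls.extend(scan_variant(v, genome, [pwm]))
        summary = summarize_disruptions(calls)
        manual = sum(1 for c in calls if c.disrupting
                     and c.tf_name == pwm.name)
        assert summary.per_tf_counts.get(pwm.name, 0) == manual
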