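import numpy as np
import pytest

from regsnp.formats import PFM, write_fasta


@pytest.fixture
def tiny_genome(tmp_path):
    """Deterministic 600 bp contig plus a short contig for boundary tests."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
    path = tmp_path / "genome.fa"
    write_fasta({"chr1": seq, "chrS": "ACGTACGTACGTACGTACGTACGTA"}, path)
    return path, {"chr1": seq, "chrS": "ACGTACGTACGTACGTACGTACGTA"}


@pytest.fixture
def sharp_pfm():
    """Strong 8-column motif, one dominant base per column (0.85)."""
    rng = np.random.default_rng(7)
    cons = rng.integers(0, 4, 8)
    freqs = np.full((8, 4), 0.05)
    freqs[np.arange(8), cons] = 0.85
    return PFM("SHARP", freqs * 100, 100)


def write_vcf_text(path, body, samples=("S1", "S2")):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n")
    path.write_text(header + body)
    return path
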