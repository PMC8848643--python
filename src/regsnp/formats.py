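"""Readers and writers for the standard formats the pipeline consumes.

All internal coordinates are 0-based half-open; VCF and GTF positions are
converted at this boundary. Domain containers (Variant, GenotypeMatrix,
GenomicInterval, GeneModel, PFM) live here because every other module
consumes them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

from .errors import BoundaryError, FormatError, InputError

log = logging.getLogger(__name__)

MISSING = -1  # missing dosage code

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic SNV or indel, VCF-style (1-based pos of first ref base)."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise InputError(f"{self.id}: empty allele")
        if self.ref == self.alt:
            raise InputError(f"{self.id}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise InputError(f"{self.id}: pos must be >= 1, got {self.pos}")

    @property
    def start(self) -> int:
        """0-based start of the ref allele."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the ref allele."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosages, optionally with phased haplotypes.

    dosages[i, j] counts ALT alleles for sample i at variant j; MISSING (-1)
    marks no-calls. phased_haplotypes, when present, is a 2*n_samples x
    n_variants 0/1 matrix with rows 2i, 2i+1 being sample i's haplotypes.
    """

    sample_ids: list[str]
    variants: list[Variant]
    dosages: np.ndarray
    phased_haplotypes: np.ndarray | None = None

    def __post_init__(self):
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosages.shape != (n, m):
            raise InputError(
                f"dosage shape {self.dosages.shape} != ({n}, {m})")
        if self.phased_haplotypes is not None:
            if self.phased_haplotypes.shape != (2 * n, m):
                raise InputError(
                    f"haplotype shape {self.phased_haplotypes.shape} != ({2*n}, {m})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(variant_id)

    def missingness_report(self) -> dict[str, int]:
        return {
            "n_missing_cells": int((self.dosages == MISSING).sum()),
            "n_cells": int(self.dosages.size),
        }


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an optional score (e.g. peak height)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Transcript:
    tx_start: int  # 0-based
    tx_end: int
    cds_start: int | None  # None for non-coding transcripts
    cds_end: int | None
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping

    def __post_init__(self):
        ex = list(self.exons)
        if ex != sorted(ex):
            raise InputError("exons must be sorted")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise InputError("exons overlap")
        if (self.cds_start is None) != (self.cds_end is None):
            raise InputError("cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise InputError("CDS outside transcript bounds")

    @property
    def coding(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be + or -")

    @property
    def start(self) -> int:
        return min(t.tx_start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.tx_end for t in self.transcripts)


@dataclass
class PFM:
    """Position frequency matrix: per-column base counts over ACGT."""

    tf_name: str
    counts: np.ndarray  # width x 4
    n_sites: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise InputError("PFM counts must be width x 4")
        if (self.counts < 0).any():
            raise InputError("PFM counts must be non-negative")
        rows = self.counts.sum(axis=1)
        if rows.size and not np.allclose(rows, rows[0], atol=1e-6 * max(1.0, rows[0])):
            raise InputError("PFM column sums must be equal across positions")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        return self.counts / np.where(tot == 0, 1.0, tot)

    def reverse_complement(self) -> "PFM":
        return PFM(self.tf_name, self.counts[::-1, ::-1].copy(), self.n_sites)

    def information_content(self, background: np.ndarray | None = None) -> float:
        """Mean per-column information content in bits."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        f = np.clip(self.frequencies, 1e-12, None)
        return float(np.mean((f * np.log2(f / bg)).sum(axis=1)))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class SequenceStore:
    """Random-access genome sequence backed by a pyfaidx index.

    Coordinates are 0-based half-open. Soft-masked bases are uppercased;
    N bases are preserved (motif scanning treats them as unmatchable).
    """

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True,
                            rebuild=True, build_index=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(chrom)
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._fasta:
            raise KeyError(chrom)
        if start < 0 or end > len(self._fasta[chrom]) or start > end:
            raise BoundaryError(
                f"{chrom}:{start}-{end} outside contig of length "
                f"{len(self._fasta[chrom])}")
        seq = str(self._fasta[chrom][start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        elif strand != "+":
            raise InputError(f"strand must be + or -, got {strand!r}")
        return seq

    def close(self):
        self._fasta.close()


def read_fasta(path: str | Path) -> SequenceStore:
    return SequenceStore(path)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _prescan_vcf(path: str | Path) -> None:
    """Cheap structural check so format errors can name a line number."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise FormatError(f"{path}: line {lineno}: data before #CHROM header")
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 10 tab-separated "
                    f"fields, got {len(fields)}")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise FormatError(f"{path}: line {lineno}: no GT in FORMAT")
            gt_idx = fmt.index("GT")
            for s in fields[9:]:
                gt = s.split(":")[gt_idx]
                if not re.fullmatch(r"[0-9.]+([/|][0-9.]+)?", gt):
                    raise FormatError(
                        f"{path}: line {lineno}: malformed GT field {gt!r}")
        if not saw_header:
            raise FormatError(f"{path}: missing #CHROM header line")


def read_vcf(path: str | Path, multiallelic: str = "split") -> GenotypeMatrix:
    """Load a VCF 4.x with GT fields into a GenotypeMatrix.

    Multiallelic records are decomposed into biallelic variants sharing the
    position (``multiallelic="split"``, the default) or skipped
    (``multiallelic="skip"``); either way the count is logged. Phase is kept
    only if every genotype at every retained site is phased.
    """
    import cyvcf2

    if multiallelic not in ("split", "skip"):
        raise InputError("multiallelic must be 'split' or 'skip'")
    _prescan_vcf(path)
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"{path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    dosage_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    n_multi = 0
    n_missing = 0

    for rec in vcf:
        alts = [a for a in rec.ALT if a not in (None, "", "*", "<NON_REF>")]
        if len(alts) > 1:
            n_multi += 1
            if multiallelic == "skip":
                continue
        gts = rec.genotypes  # list of [a1, a2, phased]
        for k, alt in enumerate(alts, start=1):
            vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(alts) > 1:
                vid = f"{vid}_{k}" if rec.ID else vid
            variants.append(Variant(rec.CHROM, rec.POS, vid, rec.REF, alt))
            dos = np.empty(len(sample_ids), dtype=np.int8)
            hap = np.empty(2 * len(sample_ids), dtype=np.int8)
            for i, g in enumerate(gts):
                a1, a2, phased = g[0], g[1], bool(g[-1])
                if a1 < 0 or a2 < 0:
                    dos[i] = MISSING
                    hap[2 * i] = hap[2 * i + 1] = MISSING
                    n_missing += 1
                    all_phased = False if not phased else all_phased
                    continue
                dos[i] = int(a1 == k) + int(a2 == k)
                hap[2 * i] = int(a1 == k)
                hap[2 * i + 1] = int(a2 == k)
                if not phased:
                    all_phased = False
            dosage_cols.append(dos)
            hap_cols.append(hap)

    if n_multi:
        log.info("%s: %d multiallelic records %s", path, n_multi,
                 "split" if multiallelic == "split" else "skipped")
    if n_missing:
        log.info("%s: %d missing genotype calls", path, n_missing)

    n, m = len(sample_ids), len(variants)
    dosages = (np.stack(dosage_cols, axis=1) if m else
               np.zeros((n, 0), dtype=np.int8))
    haps = (np.stack(hap_cols, axis=1) if (m and all_phased) else None)
    return GenotypeMatrix(sample_ids, variants, dosages, haps)


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths is None:
            contig_lengths = {}
            for v in gm.variants:
                contig_lengths[v.chrom] = max(
                    contig_lengths.get(v.chrom, 0), v.end + 1000)
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        phased = gm.phased_haplotypes is not None
        for j, v in enumerate(gm.variants):
            gts = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if d == MISSING:
                    gts.append("./.")
                elif phased:
                    a1 = gm.phased_haplotypes[2 * i, j]
                    a2 = gm.phased_haplotypes[2 * i + 1, j]
                    gts.append(f"{a1}|{a2}")
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED5 (name and score optional) into GenomicIntervals."""
    import pandas as pd

    intervals: list[GenomicInterval] = []
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    for idx, row in df.iterrows():
        try:
            chrom = row[0]
            start, end = int(row[1]), int(row[2])
            name = row[3] if df.shape[1] > 3 and isinstance(row[3], str) else "."
            score = float(row[4]) if df.shape[1] > 4 else 0.0
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {idx + 1}: {exc}") from exc
        intervals.append(GenomicInterval(chrom, start, end, name, score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a 9-column GTF (exon and CDS features).

    Transcript extent is the union of its exons; CDS extent the union of its
    CDS features. GTF coordinates (1-based inclusive) are converted to
    0-based half-open.
    """
    tx_exons: dict[tuple, list[tuple[int, int]]] = {}
    tx_cds: dict[tuple, list[tuple[int, int]]] = {}
    tx_meta: dict[tuple, tuple[str, str, str]] = {}  # key -> (gene, chrom, strand)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            d = dict(_GTF_ATTR.findall(attrs))
            gene = d.get("gene_id")
            tx = d.get("transcript_id")
            if gene is None or tx is None:
                raise FormatError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id")
            key = (gene, tx)
            tx_meta.setdefault(key, (gene, chrom, strand))
            iv = (int(start) - 1, int(end))
            (tx_exons if feature == "exon" else tx_cds).setdefault(key, []).append(iv)

    genes: dict[str, list[Transcript]] = {}
    gene_meta: dict[str, tuple[str, str]] = {}
    for key, (gene, chrom, strand) in tx_meta.items():
        exons = sorted(tx_exons.get(key, []))
        if not exons:
            continue
        cds = sorted(tx_cds.get(key, []))
        cds_start = cds[0][0] if cds else None
        cds_end = cds[-1][1] if cds else None
        genes.setdefault(gene, []).append(Transcript(
            tx_start=exons[0][0], tx_end=exons[-1][1],
            cds_start=cds_start, cds_end=cds_end, exons=tuple(exons)))
        gene_meta[gene] = (chrom, strand)

    return [GeneModel(g, gene_meta[g][0], gene_meta[g][1], tuple(txs))
            for g, txs in genes.items()]


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path) -> list[PFM]:
    """Read PFMs from a minimal MEME text file (letter-probability matrices)."""
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "minimal")
        except Exception as exc:
            raise FormatError(f"{path}: not minimal MEME format: {exc}") from exc
    out = []
    for m in parsed:
        n = m.num_occurrences or 20
        counts = np.array([[m.counts[b][i] for b in ALPHABET]
                           for i in range(m.length)], dtype=float)
        # printed probabilities round to fixed decimals; renormalize rows so
        # the equal-row-sum invariant holds exactly
        rows = counts.sum(axis=1, keepdims=True)
        counts = counts / np.where(rows == 0, 1, rows) * int(n)
        out.append(PFM(m.name or m.consensus, counts, int(n)))
    return out


def write_meme_motifs(motifs: Sequence[PFM], path: str | Path,
                      background: np.ndarray | None = None) -> None:
    """Write PFMs in minimal MEME text format (probabilities to 6 decimals)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(ALPHABET)) + "\n\n")
        for pfm in motifs:
            freqs = pfm.frequencies
            fh.write(f"MOTIF {pfm.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pfm.width} "
                     f"nsites= {pfm.n_sites} E= 0\n")
            for row in freqs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
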