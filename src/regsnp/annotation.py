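"""Genomic-context classification of variants against gene models.

Categories follow the usual annotation precedence: exonic > UTR5 > UTR3 >
intronic > upstream > downstream > intergenic, with upstream/downstream
windows measured strand-aware from the transcription start/end sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import GeneModel, Transcript, Variant

__all__ = ["LocationCall", "classify_location", "location_summary",
           "CATEGORIES"]

CATEGORIES = ("exonic", "UTR5", "UTR3", "intronic", "upstream",
              "downstream", "intergenic")
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class LocationCall:
    variant: Variant
    category: str
    gene_id: str | None  # None iff intergenic
    noncoding: bool = False  # exonic hit in a transcript without CDS


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _classify_transcript(v: Variant, tx: Transcript, strand: str,
                         flank_bp: int) -> tuple[str, bool] | None:
    s, e = v.start, v.end
    in_exon = any(_overlaps(s, e, es, ee) for es, ee in tx.exons)
    if in_exon:
        if not tx.coding:
            return "exonic", True
        if _overlaps(s, e, tx.cds_start, tx.cds_end):
            return "exonic", False
        # exonic but outside the CDS: UTR, side depends on strand
        before_cds = e <= tx.cds_start
        if strand == "+":
            return ("UTR5" if before_cds else "UTR3"), False
        return ("UTR3" if before_cds else "UTR5"), False
    if _overlaps(s, e, tx.tx_start, tx.tx_end):
        return "intronic", False
    if strand == "+":
        upstream = (tx.tx_start - flank_bp, tx.tx_start)
        downstream = (tx.tx_end, tx.tx_end + flank_bp)
    else:
        upstream = (tx.tx_end, tx.tx_end + flank_bp)
        downstream = (tx.tx_start - flank_bp, tx.tx_start)
    if _overlaps(s, e, *upstream):
        return "upstream", False
    if _overlaps(s, e, *downstream):
        return "downstream", False
    return None


def classify_location(variant: Variant, genes: list[GeneModel],
                      flank_bp: int = 1000) -> LocationCall:
    """Highest-precedence category over all transcripts of all genes.

    Classification is invariant to gene/transcript input order: on a
    precedence tie the lexicographically smaller gene id wins.
    """
    best: tuple[int, str, str, bool] | None = None  # (prec, gene, cat, nc)
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        for tx in gene.transcripts:
            res = _classify_transcript(variant, tx, gene.strand, flank_bp)
            if res is None:
                continue
            cat, nc = res
            key = (_PRECEDENCE[cat], gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (_PRECEDENCE[cat], gene.gene_id, cat, nc)
    if best is None:
        return LocationCall(variant, "intergenic", None)
    return LocationCall(variant, best[2], best[1], best[3])


def location_summary(calls: list[LocationCall]
                     ) -> tuple[dict[str, int], dict[str, float]]:
    """Category counts and proportions (empty input -> empty summary)."""
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n = len(calls)
    if n == 0:
        return {}, {}
    props = {c: counts[c] / n for c in CATEGORIES}
    return counts, props
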