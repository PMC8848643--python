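"""Allele-specific expression testing from allelic RNA-Seq read counts.

A heterozygous transcribed SNP with ref/alt read counts is tested against
an expected null ratio with a two-sided exact binomial test; records with
fewer than ``min_reads`` total reads carry no p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .errors import InputError
from .formats import Variant

__all__ = ["AseRecord", "ase_binomial", "ase_catalogue"]


@dataclass(frozen=True)
class AseRecord:
    variant: Variant | str
    ref_count: int
    alt_count: int
    null_ratio: float
    pvalue: float | None
    passed_depth: bool

    @property
    def variant_id(self) -> str:
        return self.variant if isinstance(self.variant, str) else self.variant.id


def ase_binomial(variant: Variant | str, ref_count: int, alt_count: int,
                 null_ratio: float = 0.5, min_reads: int = 8) -> AseRecord:
    """Two-sided exact binomial test of ref_count / (ref+alt) vs null_ratio.

    The two-sided p sums the probabilities of all outcomes whose density is
    at most the observed one (minimum-likelihood convention). Below
    ``min_reads`` total reads the record is depth-filtered: no p-value.
    """
    if ref_count < 0 or alt_count < 0:
        raise InputError("counts must be non-negative")
    if not (0.0 < null_ratio < 1.0):
        raise InputError("null_ratio must be in (0, 1)")
    n = ref_count + alt_count
    if n < min_reads:
        return AseRecord(variant, ref_count, alt_count, null_ratio, None, False)
    p = binomtest(ref_count, n, null_ratio, alternative="two-sided").pvalue
    return AseRecord(variant, ref_count, alt_count, null_ratio, float(p), True)


def ase_catalogue(records: list[AseRecord], alpha: float = 0.05
                  ) -> tuple[list[AseRecord], dict[str, int]]:
    """SNPs showing ASE (p < alpha among depth-passing records) plus totals."""
    passing = [r for r in records if r.passed_depth]
    flagged = [r for r in passing if r.pvalue is not None and r.pvalue < alpha]
    summary = {
        "n_records": len(records),
        "n_passed_depth": len(passing),
        "n_ase": len(flagged),
    }
    return flagged, summary
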