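"""End-to-end orchestration: config, stage ordering, manifest, TSV outputs.

Stages run in dependency order over whichever inputs the config provides:
LD expansion -> motif discovery + database match -> allele-aware scan ->
annotation of disrupting SNPs -> ASE -> eQTL association and support
tiers -> case-control differential expression. Identical config and
inputs produce byte-identical outputs (the manifest records checksums,
not timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .allelic import scan_variant, summarize_disruptions
from .annotation import classify_location, location_summary
from .ase import ase_binomial, ase_catalogue
from .eqtl import case_control_de, cross_dataset_support, eqtl_association
from .errors import InputError, UndefinedAssociationError
from .formats import (read_bed, read_fasta, read_gtf, read_meme_motifs,
                      read_vcf, write_meme_motifs)
from .ld import expand_index_snps
from .motif import PWM, discover_motifs_zoops, match_to_database, top_peak_flanks

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative run configuration; defaults are the pipeline's canonical
    thresholds (r² > 0.6 within 1 Mb, ±20 bp flanks, match p < 1e-3,
    ≥8 reads for ASE, nominal 0.05 significance, q < 0.05 for DE)."""

    out_dir: str = "results"
    # inputs (all optional; stages with missing inputs are skipped)
    genome_fasta: str | None = None
    genotypes_vcf: str | None = None
    index_snps: str | None = None
    peaks_bed: str | None = None
    motif_db: str | None = None
    candidates_vcf: str | None = None
    genes_gtf: str | None = None
    ase_counts: str | None = None
    eqtl_genotypes_vcf: str | None = None
    eqtl_expression: dict[str, str] = field(default_factory=dict)
    de_expression: str | None = None
    de_labels: str | None = None
    # thresholds
    window_kb: int = 1000
    r2_min: float = 0.6
    flank_bp: int = 20
    p_threshold: float = 1e-3
    min_reads: int = 8
    null_ratio: float = 0.5
    alpha: float = 0.05
    alpha_q: float = 0.05
    n_top_peaks: int = 500
    n_motifs: int = 5
    min_w: int = 6
    max_w: int = 20
    gene_flank_bp: int = 1000
    mode: str = "one_pass"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0.0 <= self.r2_min <= 1.0):
            raise InputError(f"r2_min must be in [0,1], got {self.r2_min}")
        for name in ("p_threshold", "alpha", "alpha_q", "null_ratio"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InputError(f"{name} must be in (0,1), got {v}")
        for name in ("window_kb", "flank_bp", "n_top_peaks", "n_motifs",
                     "min_w", "max_w", "gene_flank_bp"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.min_reads < 0:
            raise InputError("min_reads must be >= 0")
        if self.mode not in ("one_pass", "delta"):
            raise InputError(f"mode must be one_pass or delta, got {self.mode}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages with available inputs; returns the result bundle.

    Outputs are TSV files plus a JSON manifest (thresholds, seed, input and
    output checksums) under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: dict[str, Path] = {}
    inputs: dict[str, str] = {}

    def note_input(name, path):
        if path:
            inputs[name] = _sha256(Path(path))

    genome = None
    if config.genome_fasta:
        note_input("genome_fasta", config.genome_fasta)
        genome = read_fasta(config.genome_fasta)

    # ---- stage 1: LD expansion -------------------------------------------
    if config.genotypes_vcf and config.index_snps:
        note_input("genotypes_vcf", config.genotypes_vcf)
        note_input("index_snps", config.index_snps)
        gm = read_vcf(config.genotypes_vcf)
        index_ids = [ln.strip() for ln in open(config.index_snps)
                     if ln.strip()]
        try:
            pairs = expand_index_snps(index_ids, gm, config.window_kb,
                                      config.r2_min)
        except Exception as exc:
            raise type(exc)(f"[ld_expansion] {exc}") from exc
        df = pd.DataFrame([(p.index_id, p.proxy_id, p.r2, p.distance_bp)
                           for p in pairs],
                          columns=["index_id", "proxy_id", "r2", "distance_bp"])
        _write_tsv(df, out / "ld_pairs.tsv")
        outputs["ld_pairs"] = out / "ld_pairs.tsv"
        results["ld_pairs"] = pairs

    # ---- stage 2: motif discovery + database match -----------------------
    scan_pfms = []
    if config.peaks_bed and genome is not None:
        note_input("peaks_bed", config.peaks_bed)
        peaks = read_bed(config.peaks_bed)
        flanks = top_peak_flanks(peaks, genome, config.n_top_peaks,
                                 config.flank_bp)
        discovered = discover_motifs_zoops(
            flanks, n_motifs=config.n_motifs, min_w=config.min_w,
            max_w=config.max_w, seed=config.seed)
        write_meme_motifs(discovered, out / "discovered_motifs.meme")
        outputs["discovered_motifs"] = out / "discovered_motifs.meme"
        results["discovered_motifs"] = discovered
        if config.motif_db:
            note_input("motif_db", config.motif_db)
            db = read_meme_motifs(config.motif_db)
            rows = []
            for q in discovered:
                m = match_to_database(q, db)
                rows.append((q.tf_name, m.motif.tf_name, m.similarity,
                             m.orientation, m.offset))
                if all(p.tf_name != m.motif.tf_name for p in scan_pfms):
                    scan_pfms.append(m.motif)
            dfm = pd.DataFrame(rows, columns=["query", "best_match",
                                              "similarity", "orientation",
                                              "offset"])
            _write_tsv(dfm, out / "motif_matches.tsv")
            outputs["motif_matches"] = out / "motif_matches.tsv"
            results["motif_matches"] = rows
        else:
            scan_pfms = discovered
    elif config.motif_db:
        note_input("motif_db", config.motif_db)
        scan_pfms = read_meme_motifs(config.motif_db)

    # ---- stage 3: allele-aware scan --------------------------------------
    calls = []
    if config.candidates_vcf and genome is not None and scan_pfms:
        note_input("candidates_vcf", config.candidates_vcf)
        cand = read_vcf(config.candidates_vcf)
        pwms = [PWM.from_pfm(p) for p in scan_pfms]
        for v in cand.variants:
            try:
                calls.extend(scan_variant(v, genome, pwms, config.flank_bp,
                                          config.p_threshold, config.mode))
            except Exception as exc:
                raise type(exc)(f"[allelic_scan] {v.id}: {exc}") from exc
        rows = []
        for c in calls:
            r, a = c.best_ref_match, c.best_alt_match
            rows.append((c.variant.id, c.tf_name,
                         r.pvalue if r else np.nan, a.pvalue if a else np.nan,
                         r.llr if r else np.nan, a.llr if a else np.nan,
                         c.delta_llr, c.mode, c.disrupting))
        dfc = pd.DataFrame(rows, columns=["variant", "tf", "p_ref", "p_alt",
                                          "llr_ref", "llr_alt", "delta_llr",
                                          "direction", "disrupting"])
        _write_tsv(dfc, out / "disruption_calls.tsv")
        outputs["disruption_calls"] = out / "disruption_calls.tsv"
        summary = summarize_disruptions(calls)
        _write_tsv(pd.DataFrame(sorted(summary.per_tf_counts.items()),
                                columns=["tf", "n_snps"]),
                   out / "per_tf_counts.tsv")
        co = pd.DataFrame(summary.co_disruption, index=summary.tf_order,
                          columns=summary.tf_order)
        co.insert(0, "tf", summary.tf_order)
        _write_tsv(co, out / "co_disruption.tsv")
        outputs["per_tf_counts"] = out / "per_tf_counts.tsv"
        outputs["co_disruption"] = out / "co_disruption.tsv"
        results["calls"] = calls
        results["summary"] = summary

    # ---- stage 4: annotation of disrupting SNPs --------------------------
    if config.genes_gtf and calls:
        note_input("genes_gtf", config.genes_gtf)
        genes = read_gtf(config.genes_gtf)
        seen = set()
        loc_calls = []
        for c in calls:
            if c.disrupting and c.variant.id not in seen:
                seen.add(c.variant.id)
                loc_calls.append(classify_location(c.variant, genes,
                                                   config.gene_flank_bp))
        counts, props = location_summary(loc_calls)
        dfl = pd.DataFrame([(lc.variant.id, lc.category, lc.gene_id or ".")
                            for lc in loc_calls],
                           columns=["variant", "category", "gene_id"])
        _write_tsv(dfl, out / "locations.tsv")
        dfs = pd.DataFrame([(k, counts[k], props.get(k, 0.0))
                            for k in counts],
                           columns=["category", "count", "proportion"])
        _write_tsv(dfs, out / "location_summary.tsv")
        outputs["locations"] = out / "locations.tsv"
        outputs["location_summary"] = out / "location_summary.tsv"
        results["locations"] = loc_calls
        results["location_summary"] = (counts, props)

    # ---- stage 5: allele-specific expression -----------------------------
    if config.ase_counts:
        note_input("ase_counts", config.ase_counts)
        dfa = pd.read_csv(config.ase_counts, sep="\t")
        records = []
        for _, row in dfa.iterrows():
            nr = float(row["null_ratio"]) if "null_ratio" in dfa.columns \
                else config.null_ratio
            records.append(ase_binomial(str(row["variant"]),
                                        int(row["ref_count"]),
                                        int(row["alt_count"]),
                                        nr, config.min_reads))
        flagged, asum = ase_catalogue(records, config.alpha)
        dfo = pd.DataFrame([(r.variant_id, r.ref_count, r.alt_count,
                             r.null_ratio,
                             r.pvalue if r.pvalue is not None else np.nan,
                             r.passed_depth,
                             bool(r.pvalue is not None
                                  and r.pvalue < config.alpha))
                            for r in records],
                           columns=["variant", "ref_count", "alt_count",
                                    "null_ratio", "pvalue", "passed_depth",
                                    "ase"])
        _write_tsv(dfo, out / "ase.tsv")
        outputs["ase"] = out / "ase.tsv"
        results["ase"] = (records, flagged, asum)

    # ---- stage 6: eQTL + cross-dataset support ---------------------------
    if config.eqtl_genotypes_vcf and config.eqtl_expression:
        note_input("eqtl_genotypes_vcf", config.eqtl_genotypes_vcf)
        egm = read_vcf(config.eqtl_genotypes_vcf)
        eq_results = []
        for ds, path in sorted(config.eqtl_expression.items()):
            note_input(f"eqtl_expression:{ds}", path)
            dfe = pd.read_csv(path, sep="\t")
            dfe = dfe.set_index("sample").loc[egm.sample_ids]
            for j, v in enumerate(egm.variants):
                for gene in dfe.columns:
                    try:
                        eq_results.append(eqtl_association(
                            egm.dosages[:, j], dfe[gene].to_numpy(),
                            variant=v.id, gene_id=gene, dataset=ds))
                    except UndefinedAssociationError:
                        continue
        summaries, tiers = cross_dataset_support(eq_results, config.alpha)
        dfe = pd.DataFrame([(r.variant, r.gene_id, r.dataset, r.beta, r.se,
                             r.pvalue, r.n) for r in eq_results],
                          columns=["variant", "gene", "dataset", "beta",
                                   "se", "pvalue", "n"])
        _write_tsv(dfe, out / "eqtl.tsv")
        dft = pd.DataFrame([(s.variant, s.n_datasets_significant,
                             ",".join(s.genes) or ".") for s in summaries],
                          columns=["variant", "n_datasets", "genes"])
        _write_tsv(dft, out / "eqtl_support.tsv")
        outputs["eqtl"] = out / "eqtl.tsv"
        outputs["eqtl_support"] = out / "eqtl_support.tsv"
        results["eqtl"] = eq_results
        results["support"] = (summaries, tiers)

    # ---- stage 7: case-control differential expression -------------------
    if config.de_expression and config.de_labels:
        note_input("de_expression", config.de_expression)
        note_input("de_labels", config.de_labels)
        dfx = pd.read_csv(config.de_expression, sep="\t", index_col=0)
        lab = pd.read_csv(config.de_labels, sep="\t", index_col=0)["label"]
        lab = lab.loc[dfx.columns].to_numpy()
        de = case_control_de(dfx.to_numpy(), lab, list(dfx.index),
                             config.alpha_q)
        dfd = pd.DataFrame([(r.gene_id, r.log_fold_change, r.pvalue,
                             r.qvalue, r.significant) for r in de],
                           columns=["gene", "log2_fc", "pvalue", "qvalue",
                                    "significant"])
        _write_tsv(dfd, out / "de.tsv")
        outputs["de"] = out / "de.tsv"
        results["de"] = de

    manifest = {
        "version": _version,
        "seed": config.seed,
        "thresholds": {k: getattr(config, k) for k in
                       ("window_kb", "r2_min", "flank_bp", "p_threshold",
                        "min_reads", "null_ratio", "alpha", "alpha_q",
                        "mode")},
        "inputs": dict(sorted(inputs.items())),
        "outputs": {k: _sha256(v) for k, v in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
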