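"""End-to-end orchestration of the transcriptome-complexity analysis.

Stages run in dependency order over plain-text inputs and write inspectable
TSV intermediates plus a summary table into a single run directory:

    io -> loci/classification -> splicing -> ends/poly(A) -> lncRNA ->
    expression -> domains -> coupling

Every effective parameter is written to ``provenance.yaml``; re-running with
the same inputs and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import annotation_io, domains as domains_mod, ends_polya, expression as expr_mod
from . import lncrna as lncrna_mod, locus as locus_mod, splicing

log = logging.getLogger("isoplex")

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending file."""


@dataclasses.dataclass
class RunConfig:
    """Input paths and every stage parameter (all have defaults)."""

    genome_fa: str = "genome.fa"
    reference_gtf: str = "reference.gtf"
    observed_gtf: str = "observed.gtf"
    flnc_fastq: str | None = "flnc.fastq"
    alignments_bed12: str | None = "flnc_alignments.bed12"
    fpkm_tsv: str | None = "fpkm.tsv"
    counts_tsv: str | None = "counts.tsv"
    domains_tsv: str | None = "domains.tsv"
    go_map_tsv: str | None = "go_map.tsv"
    out_dir: str = "run"
    # parameters
    seed: int = 1
    mono_exon_tol: int = 50
    expressed_fpkm: float = 1.0
    end_cluster_tol: int = 50
    polya_collapse_tol: int = 24
    polya_window: int = 30
    polya_min_a: int = 8
    polya_max_non_a: int = 1
    polya_mode: str = "sliding"
    kmer_ks: tuple[int, int] = (5, 6)
    kmer_upstream: int = 50
    lnc_min_length: int = 200
    lnc_max_orf_aa: int = 100
    lnc_score_cutoff: float = 0.5
    lnc_max_dist_kb: float = 100.0
    lnc_pcc_threshold: float = 0.6
    expr_clusters_k: int = 5
    das_q_max: float = 0.05
    das_min_delta_psi: float = 0.1
    deg_min_fold: float = 1.0
    deg_min_fpkm: float = 1.0


def _require(path: str | None, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(f"stage '{stage}': required input missing: {path}")
    return Path(path)


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages; returns in-memory results keyed by stage name."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- io -----------------------------------------------------------------
    genome = annotation_io.read_genome(_require(cfg.genome_fa, "io"))
    reference = annotation_io.read_annotation(_require(cfg.reference_gtf, "io"))
    observed = annotation_io.read_annotation(_require(cfg.observed_gtf, "io"))
    log.info("io: %d reference / %d observed transcripts", len(reference),
             len(observed))

    # --- loci + classification ----------------------------------------------
    # original gene_id attributes, before locus ids overwrite them
    orig_gene_id = {t.transcript_id: t.gene_id for t in observed}
    loci = locus_mod.build_loci(observed)
    categories = locus_mod.classify_all(observed, reference, cfg.mono_exon_tol)
    _tsv(categories, out / "isoform_categories.tsv")
    gene_stats = locus_mod.per_gene_stats(loci, genome)
    _tsv(gene_stats, out / "gene_stats.tsv")
    results.update(loci=loci, categories=categories, gene_stats=gene_stats)

    fpkm = None
    if cfg.fpkm_tsv and Path(cfg.fpkm_tsv).exists():
        fpkm = pd.read_csv(cfg.fpkm_tsv, sep="\t", index_col=0)
        spec_table, overlap = locus_mod.tissue_specificity(fpkm, cfg.expressed_fpkm)
        _tsv(spec_table.reset_index(names="isoform_id"), out / "specificity.tsv")
        results["specificity"] = spec_table
        results["expression_overlap"] = overlap

    # --- splicing -----------------------------------------------------------
    events = splicing.detect_events_all(loci)
    ev_table = splicing.events_table(events)
    _tsv(ev_table, out / "events.tsv")
    offsets = pd.concat(
        [splicing.splice_site_offsets(l) for l in loci if l.n_isoforms >= 2],
        ignore_index=True,
    ) if any(l.n_isoforms >= 2 for l in loci) else pd.DataFrame()
    _tsv(offsets, out / "splice_site_offsets.tsv")
    dinucs = pd.concat(
        [splicing.boundary_dinucleotides(l, genome) for l in loci],
        ignore_index=True,
    )
    _tsv(dinucs, out / "boundary_dinucleotides.tsv")
    corr = splicing.as_structure_correlation(gene_stats)
    _tsv(corr, out / "as_structure_correlation.tsv")
    results.update(events=events, events_table=ev_table, offsets=offsets,
                   dinucleotides=dinucs, structure_correlation=corr)

    # --- differential splicing (PSI from isoform counts) ---------------------
    counts_df = None
    if cfg.counts_tsv and Path(cfg.counts_tsv).exists():
        counts_df = pd.read_csv(cfg.counts_tsv, sep="\t", index_col=0)
        das_counts = {}
        for e in events:
            per_sample = {}
            for s in counts_df.columns:
                inc = int(counts_df.loc[
                    counts_df.index.isin(e.inclusion), s].sum())
                exc = int(counts_df.loc[
                    counts_df.index.isin(e.exclusion), s].sum())
                per_sample[s] = (inc, exc)
            das_counts[e.event_id] = per_sample
        sample_pairs = list(itertools.combinations(counts_df.columns, 2))
        das = splicing.differential_splicing(
            das_counts, sample_pairs, cfg.das_q_max, cfg.das_min_delta_psi
        )
        _tsv(das, out / "das.tsv")
        results["das"] = das

    # --- ends + poly(A) ------------------------------------------------------
    flags = ends_polya.end_flags(loci, cfg.end_cluster_tol)
    _tsv(flags, out / "end_flags.tsv")
    results["end_flags"] = flags

    calls = []
    if cfg.flnc_fastq and cfg.alignments_bed12:
        fq = _require(cfg.flnc_fastq, "ends_polya")
        bed = _require(cfg.alignments_bed12, "ends_polya")
        alignments = {
            a.read_id: a for a in ends_polya.read_bed12_alignments(bed)
        }
        for rec in SeqIO.parse(str(fq), "fastq"):
            calls.append(
                ends_polya.call_polya(
                    str(rec.seq), alignments.get(rec.id),
                    cfg.polya_window, cfg.polya_min_a, cfg.polya_max_non_a,
                    cfg.polya_mode, read_id=rec.id,
                )
            )
        sites, hist = ends_polya.polya_sites_per_gene(
            calls, loci, cfg.polya_collapse_tol
        )
        _tsv(sites, out / "polya_sites.tsv")
        _tsv(hist.reset_index(), out / "polya_site_histogram.tsv")
        calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
        _tsv(calls_df, out / "polya_calls.tsv")
        site_tuples = [
            (r.chrom, int(r.site_pos), r.strand)
            for r in sites.itertuples(index=False)
        ]
        profile = ends_polya.composition_profile(site_tuples, genome)
        _tsv(profile, out / "composition_profile.tsv")
        if len(site_tuples) >= 10:
            kmers = ends_polya.upstream_kmer_enrichment(
                site_tuples, genome, cfg.kmer_ks, cfg.kmer_upstream,
                seed=cfg.seed,
            )
            _tsv(kmers.head(200), out / "kmer_enrichment.tsv")
            results["kmer_enrichment"] = kmers
        results.update(polya_calls=calls, polya_sites=sites,
                       polya_hist=hist, composition=profile)

    # --- lncRNA --------------------------------------------------------------
    cat_map = dict(zip(categories["transcript_id"], categories["category"]))
    candidates = [t for t in observed
                  if cat_map[t.transcript_id] == locus_mod.NOVEL_LOCUS]
    coding_tx = [t for t in observed
                 if cat_map[t.transcript_id] != locus_mod.NOVEL_LOCUS]
    lnc_records = lncrna_mod.identify_lncrnas(
        candidates, genome, coding_tx, cfg.lnc_min_length,
        cfg.lnc_max_orf_aa, cfg.lnc_score_cutoff,
    )
    _tsv(lncrna_mod.records_table(lnc_records), out / "lncrna_records.tsv")
    results["lncrnas"] = lnc_records
    lnc_model_map = {t.transcript_id: t for t in candidates}
    with open(out / "lncrna.fa", "w") as fh:
        for rec in lnc_records:
            seq = annotation_io.transcript_sequence(
                lnc_model_map[rec.transcript_id], genome
            )
            fh.write(f">{rec.transcript_id} {rec.positional_class}\n{seq}\n")

    if fpkm is not None:
        coding_ids = {t.transcript_id for t in coding_tx}
        coding_loci = [l for l in loci
                       if any(t.transcript_id in coding_ids
                              for t in l.transcripts)]
        gene_fpkm = fpkm.groupby(
            pd.Series({t.transcript_id: t.gene_id for l in loci
                       for t in l.transcripts})
        ).sum()
        combined = pd.concat([fpkm, gene_fpkm])
        lnc_models = {t.transcript_id: t for t in observed}
        pairs = lncrna_mod.lnc_target_pairs(
            lnc_records, lnc_models, coding_loci, combined,
            cfg.lnc_max_dist_kb, cfg.lnc_pcc_threshold,
        )
        _tsv(pairs, out / "lnc_targets.tsv")
        results["lnc_pairs"] = pairs
        results["gene_fpkm"] = gene_fpkm

    # --- expression ----------------------------------------------------------
    deg_union: set[str] = set()
    if fpkm is not None:
        scores, evr, _ = expr_mod.pca(fpkm)
        pca_out = scores.copy()
        pca_out["explained_variance_ratio"] = list(evr) + [np.nan] * (
            len(scores) - len(evr)
        )
        _tsv(pca_out.reset_index(names="sample"), out / "pca.tsv")
        results["pca_scores"], results["pca_evr"] = scores, evr

        lnc_ids = [r.transcript_id for r in lnc_records
                   if r.transcript_id in fpkm.index]
        if len(lnc_ids) >= cfg.expr_clusters_k:
            labels, means = expr_mod.cluster_profiles(
                fpkm.loc[lnc_ids], cfg.expr_clusters_k, cfg.seed
            )
            _tsv(labels.rename_axis("isoform_id").reset_index(),
                 out / "clusters.tsv")
            results["lnc_cluster_labels"] = labels

        gene_fpkm = results.get("gene_fpkm")
        if gene_fpkm is not None:
            pairs_all = list(itertools.combinations(gene_fpkm.columns, 2))
            deg_table, deg_union = expr_mod.deg_pairwise(
                gene_fpkm, pairs_all, cfg.deg_min_fold, cfg.deg_min_fpkm
            )
            _tsv(deg_table[deg_table["deg"]], out / "deg.tsv")
            results["deg_table"], results["deg_union"] = deg_table, deg_union

            if cfg.go_map_tsv and Path(cfg.go_map_tsv).exists() and deg_union:
                go = pd.read_csv(cfg.go_map_tsv, sep="\t")
                gene2locus = {}
                for l in loci:
                    for t in l.transcripts:
                        gene2locus.setdefault(
                            orig_gene_id[t.transcript_id], l.locus_id
                        )
                term_map: dict[str, set] = {}
                for r in go.itertuples(index=False):
                    locus_id = gene2locus.get(r.gene_id)
                    if locus_id:
                        term_map.setdefault(r.term, set()).add(locus_id)
                universe = set(gene_fpkm.index)
                selected = deg_union & universe
                if selected:
                    enrich = expr_mod.term_enrichment(selected, universe, term_map)
                    _tsv(enrich, out / "enrichment.tsv")
                    results["enrichment"] = enrich

    # --- domains -------------------------------------------------------------
    if cfg.domains_tsv and Path(cfg.domains_tsv).exists():
        annotations = domains_mod.read_domain_table(cfg.domains_tsv)
        changes = []
        for l in loci:
            iso_ids = [t.transcript_id for t in l.transcripts]
            if not any(i in annotations for i in iso_ids):
                continue
            changes.extend(domains_mod.classify_gene(iso_ids, annotations))
        ch_df = pd.DataFrame(
            [
                {
                    "isoform_id": c.isoform_id,
                    "reference_isoform_id": c.reference_isoform_id,
                    "lost": ",".join(c.lost),
                    "gained": ",".join(c.gained),
                    "change_class": c.change_class,
                }
                for c in changes
            ]
        )
        _tsv(ch_df, out / "domain_changes.tsv")
        results["domain_changes"] = changes
        results["domain_annotations"] = annotations

    # --- coupling ------------------------------------------------------------
    as_genes = {e.locus_id for e in events}
    per_gene, cells = ends_polya.coupling_venn(loci, as_genes, flags, deg_union)
    _tsv(per_gene, out / "coupling_flags.tsv")
    _tsv(cells, out / "coupling_venn.tsv")
    results.update(coupling_flags=per_gene, coupling_cells=cells)

    # --- summary + provenance ------------------------------------------------
    summary_rows = [
        ("n_observed_isoforms", len(observed)),
        ("n_loci", len(loci)),
        ("n_multi_isoform_loci", sum(l.n_isoforms >= 2 for l in loci)),
    ]
    for cat in locus_mod.CATEGORIES:
        summary_rows.append(
            (f"isoforms_{cat}", int((categories["category"] == cat).sum()))
        )
    n_events = len(events)
    for etype in splicing.EVENT_TYPES:
        n = sum(e.event_type == etype for e in events)
        summary_rows.append((f"as_events_{etype}", n))
        summary_rows.append(
            (f"as_events_{etype}_pct",
             round(100 * n / n_events, 2) if n_events else 0.0)
        )
    summary_rows.append(("as_events_total", n_events))
    if "polya_hist" in results:
        for k, v in results["polya_hist"].items():
            summary_rows.append((f"genes_with_{k}_polya_sites", int(v)))
    summary_rows.append(("n_lncrnas", len(lnc_records)))
    if len(per_gene):
        summary_rows.append(
            ("genes_atss_and_atts",
             int((per_gene["has_aTSS"] & per_gene["has_aTTS"]).sum()))
        )
        summary_rows.append(
            ("genes_as_with_atss_atts",
             int((per_gene["has_AS"] & per_gene["has_aTSS"]
                  & per_gene["has_aTTS"]).sum()))
        )
    summary = pd.DataFrame(summary_rows, columns=["quantity", "value"])
    _tsv(summary, out / "summary.tsv")
    results["summary"] = summary

    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return results
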