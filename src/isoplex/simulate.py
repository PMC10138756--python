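"""Synthetic multi-exon transcriptome corpora with machine-readable ground truth.

The generator emulates the data structure of a long-read (Iso-Seq)
transcriptome survey of a multi-tissue plant experiment: a small genome of
multi-exon gene loci with canonical GT..AG introns, a reference annotation,
observed isoforms derived from the reference by planting typed alternative
splicing events (IR / ES / A3SS / A5SS / MXE) and alternative start /
termination sites, full-length reads carrying poly(A) tails whose cleavage
sites sit at annotated 3' ends, noncoding loci (lincRNA and antisense
lncNAT), an isoform-by-sample FPKM matrix with planted expression clusters
and planted lncRNA-target correlations, and per-isoform domain tables with
planted losses/gains.  Every quantity is driven by a single seed; the same
seed yields byte-identical output files.

Each gene carries at most one planted structural feature, so the set of
events a correct detector should report equals the truth table exactly —
error-free reads make structural recovery an all-or-nothing check.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    transcript_sequence,
    write_genome,
    write_gtf,
)
from .lncrna import longest_orf

__all__ = ["SimConfig", "SimResult", "generate", "coding_noncoding_set"]

_BASES = np.array(list("ACGT"))

# biased sense-codon pool for coding-like exon content (plant-leaning usage);
# gives the Fickett statistic a codon-periodic signal to detect
_CODONS = [
    "GCT", "GCC", "GAG", "GAA", "AAG", "CTT", "CTC", "GAT", "GAC", "GTT",
    "GTG", "TCT", "TCC", "GGA", "GGT", "ATC", "ATT", "ACT", "ACC", "AAC",
    "CCA", "CCT", "TTC", "AGG", "AGA", "TAC", "CAA", "CAG", "ATG", "TGG",
    "CAT", "CAC", "TTG", "AAA", "AGC",
]
_CODON_W = np.array(
    [5, 3, 6, 5, 6, 5, 3, 6, 3, 4,
     3, 4, 3, 5, 4, 4, 3, 4, 3, 4,
     4, 3, 4, 3, 2, 3, 3, 2, 2, 1,
     2, 2, 4, 4, 2], dtype=float
)
_CODON_W /= _CODON_W.sum()

EVENT_KINDS = ("IR", "ES", "A3SS", "A5SS", "MXE", "aTSS", "aTTS")


@dataclasses.dataclass
class SimConfig:
    """All tunables of the synthetic corpus; defaults are the study conditions."""

    seed: int = 1
    n_chromosomes: int = 2
    gc_fraction: float = 0.42
    n_genes: int = 200
    # fraction of genes carrying each planted feature (disjoint assignment)
    event_rates: dict = dataclasses.field(
        default_factory=lambda: {k: 0.12 for k in EVENT_KINDS}
    )
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (100, 300)
    terminal_exon_length_range: tuple[int, int] = (350, 450)
    intron_length_range: tuple[int, int] = (120, 500)
    splice_shift_range: tuple[int, int] = (4, 20)
    end_shift_nt: int = 200
    intergenic_gap_range: tuple[int, int] = (1200, 2500)
    utr5_nt: int = 50
    utr3_nt: int = 250
    # reads
    n_reads_per_isoform: int = 3
    tail_length_range: tuple[int, int] = (30, 30)
    tail_impurity_rate: float = 0.0
    # poly(A) signal
    polya_motif: str = "TCTGT"
    motif_rate: float = 0.7
    a_rich_downstream: bool = True
    # noncoding loci
    n_lincrnas: int = 12
    n_lncnats: int = 8
    linc_length_range: tuple[int, int] = (400, 1000)
    # expression
    n_samples: int = 7
    n_expr_clusters: int = 5
    cluster_separation: float = 2.5
    lnc_target_r: float = 0.8
    positive_pair_fraction: float = 0.65
    deg_rate: float = 0.3
    deg_min_fold: float = 1.0
    deg_min_fpkm: float = 1.0
    # domains
    domain_alphabet: tuple[str, ...] = ("DomA", "DomB", "DomC", "DomD", "DomE")
    domain_change_rates: dict = dataclasses.field(
        default_factory=lambda: {"loss": 0.35, "gain": 0.15, "both": 0.15}
    )

    def __post_init__(self):
        for k, v in self.event_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"event rate {k}={v} outside [0,1]")
        if sum(self.event_rates.values()) > 1:
            raise ValueError("event rates sum to more than 1")


@dataclasses.dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    event: str
    isoforms: list[TranscriptModel]
    full_exons: list[tuple[int, int]]


@dataclasses.dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    reference: list[TranscriptModel]
    observed: list[TranscriptModel]
    truth: dict
    fpkm: pd.DataFrame
    counts: pd.DataFrame
    reads: list[tuple[str, str]]  # (read_id, sequence)
    alignments: list  # bed12-style tuples


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _make_coding_seq(rng, total_nt: int, utr5: int, utr3: int, gc: float) -> str:
    """UTR + ATG + biased codons + stop + UTR, exactly ``total_nt`` long."""
    cds_nt = total_nt - utr5 - utr3
    n_codons = max(cds_nt // 3 - 2, 10)  # minus start and stop
    cds = "ATG" + "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_W)) + "TAA"
    pad = total_nt - utr5 - len(cds)
    if pad < 0:
        cds = cds[: len(cds) + pad - 3] + "TAA"
        pad = total_nt - utr5 - len(cds)
    tail = "".join(_random_seq(rng, pad, gc))
    head = "".join(_random_seq(rng, utr5, gc))
    return head + cds + tail


def _write_transcript_oriented(arr: np.ndarray, boundary: int, strand: str,
                               offset: int, seq: str) -> None:
    """Write ``seq`` at transcript-oriented offsets [offset, offset+len) around
    a cleavage boundary (offset -1 = last transcribed base)."""
    for j, base in enumerate(seq):
        o = offset + j
        gpos = boundary + o if strand == "+" else boundary - 1 - o
        if 0 <= gpos < len(arr):
            arr[gpos] = base if strand == "+" else base.translate(
                str.maketrans("ACGT", "TGCA")
            )


def _write_spliced(arr: np.ndarray, exons: Sequence[tuple[int, int]],
                   strand: str, seq: str) -> None:
    """Lay a transcript-oriented sequence into genomic exon intervals."""
    genomic = seq if strand == "+" else reverse_complement(seq)
    pos = 0
    for s, e in exons:
        arr[s:e] = list(genomic[pos : pos + (e - s)])
        pos += e - s


def _spliced_seq(arr: np.ndarray, exons, strand) -> str:
    seq = "".join("".join(arr[s:e]) for s, e in exons)
    return reverse_complement(seq) if strand == "-" else seq


def _break_orfs(arr: np.ndarray, exons, strand, max_aa: int = 90,
                max_iter: int = 200) -> None:
    """Mutate a (noncoding) region until its longest ORF is <= ``max_aa``.

    A stop codon is written into the middle of the offending ORF; only
    positions inside the given exons are touched.
    """
    tx_positions = []
    for s, e in exons:
        tx_positions.extend(range(s, e))
    if strand == "-":
        tx_positions = tx_positions[::-1]
    for _ in range(max_iter):
        seq = _spliced_seq(arr, exons, strand)
        orf = longest_orf(seq)
        if orf.aa_length <= max_aa:
            return
        mid = orf.start + 3 * ((orf.aa_length // 2) or 1)
        for j, base in enumerate("TAA"):
            gpos = tx_positions[mid + j]
            arr[gpos] = base if strand == "+" else base.translate(
                str.maketrans("ACGT", "TGCA")
            )
    raise RuntimeError("could not suppress ORFs in noncoding region")


def coding_noncoding_set(n: int, seed: int = 0,
                         length_range: tuple[int, int] = (300, 1500)
                         ) -> tuple[list[str], list[int]]:
    """Labelled coding (codon-structured) vs noncoding (shuffled) sequences.

    Coding sequences carry a long biased-codon ORF covering most of the
    transcript; noncoding sequences are mononucleotide-preserving shuffles of
    coding ones (same length and composition, no codon structure).
    Returns (sequences, labels) with label 1 = coding.
    """
    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    for i in range(n):
        length = int(rng.integers(*length_range)) // 3 * 3
        coding = _make_coding_seq(rng, length, utr5=min(30, length // 10),
                                  utr3=min(60, length // 5), gc=0.45)
        if i % 2 == 0:
            seqs.append(coding)
            labels.append(1)
        else:
            arr = np.array(list(coding))
            seqs.append("".join(rng.permutation(arr)))
            labels.append(0)
    return seqs, labels


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _gene_structure(rng, cfg: SimConfig, event: str, start: int,
                    chrom: str, strand: str, gene_id: str) -> _Gene:
    """Lay out one gene's full exon set and derive its isoforms."""
    lo, hi = cfg.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    if event == "MXE":
        n_exons = max(n_exons, 4)
    elif event == "ES":
        n_exons = max(n_exons, 3)

    exon_lens = [int(rng.integers(*cfg.exon_length_range)) for _ in range(n_exons)]
    term_idx = n_exons - 1 if strand == "+" else 0
    exon_lens[term_idx] = int(rng.integers(*cfg.terminal_exon_length_range))
    intron_lens = [int(rng.integers(*cfg.intron_length_range))
                   for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += intron_lens[i]

    def model(iso_id, exon_list):
        return TranscriptModel(
            iso_id, gene_id, chrom, strand,
            [GenomicInterval(chrom, s, e, strand) for s, e in exon_list],
        )

    internal = list(range(1, n_exons - 1))
    shift = int(rng.integers(*cfg.splice_shift_range))
    iso_exons: list[list[tuple[int, int]]]

    if event == "IR":
        j = int(rng.integers(0, n_exons - 1))  # intron index to retain
        retained = exons[: j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2 :]
        iso_exons = [exons, retained]
    elif event == "ES":
        k = int(rng.choice(internal))
        skipped = exons[: k] + exons[k + 1 :]
        iso_exons = [exons, skipped]
    elif event in ("A5SS", "A3SS"):
        j = int(rng.integers(0, n_exons - 1))
        s_i, e_i = exons[j][1], exons[j + 1][0]  # intron j
        variant = [list(x) for x in exons]
        # decide which genomic boundary moves: the donor-side exon extends for
        # A5SS, the acceptor-side exon for A3SS, each in transcript orientation
        extend_left_exon = (event == "A5SS") == (strand == "+")
        if extend_left_exon:
            variant[j][1] = s_i + shift        # exon j grows into the intron
        else:
            variant[j + 1][0] = e_i - shift    # exon j+1 grows leftwards
        iso_exons = [exons, [tuple(x) for x in variant]]
    elif event == "MXE":
        a = int(rng.choice(internal[:-1])) if len(internal) > 1 else 1
        iso_a = exons[: a + 1] + exons[a + 2 :]   # keeps exon a, drops a+1
        iso_b = exons[: a] + exons[a + 1 :]       # drops exon a, keeps a+1
        iso_exons = [iso_a, iso_b]
    elif event == "aTSS":
        shifted = [list(x) for x in exons]
        if strand == "+":
            shifted[0][0] -= cfg.end_shift_nt
        else:
            shifted[-1][1] += cfg.end_shift_nt
        iso_exons = [exons, [tuple(x) for x in shifted]]
    elif event == "aTTS":
        shifted = [list(x) for x in exons]
        if strand == "+":
            shifted[-1][1] += cfg.end_shift_nt
        else:
            shifted[0][0] -= cfg.end_shift_nt
        iso_exons = [exons, [tuple(x) for x in shifted]]
    else:  # no planted feature: single isoform
        iso_exons = [exons]

    isoforms = [
        model(f"{gene_id}.{i + 1}", ex) for i, ex in enumerate(iso_exons)
    ]
    return _Gene(gene_id, chrom, strand, event, isoforms, exons)


def _planted_event_record(gene: _Gene) -> dict | None:
    """Anchor coordinates of the planted AS event, as the detector keys them."""
    if gene.event not in ("IR", "ES", "A5SS", "A3SS", "MXE"):
        return None
    iso0, iso1 = gene.isoforms[0], gene.isoforms[1]
    e0 = [(e.start, e.end) for e in iso0.exons]
    e1 = [(e.start, e.end) for e in iso1.exons]
    if gene.event == "IR":
        introns0 = set(iso0.introns())
        retained = sorted(introns0 - set(iso1.introns()))[0]
        coords = list(retained)
    elif gene.event == "ES":
        spanned = sorted(set(iso1.introns()) - set(iso0.introns()))[0]
        skipped = [ex for ex in e0 if spanned[0] <= ex[0] and ex[1] <= spanned[1]]
        coords = list(spanned) + [c for ex in skipped for c in ex]
    elif gene.event in ("A5SS", "A3SS"):
        only0 = sorted(set(iso0.introns()) - set(iso1.introns()))[0]
        only1 = sorted(set(iso1.introns()) - set(iso0.introns()))[0]
        coords = sorted(set(only0) | set(only1))
    else:  # MXE
        alt0 = [ex for ex in e0 if ex not in e1][0]
        alt1 = [ex for ex in e1 if ex not in e0][0]
        full = gene.full_exons
        a = full.index(alt0)
        coords = [full[a - 1][1], full[a + 2][0], *alt0, *alt1]
    return {
        "gene_id": gene.gene_id,
        "event_type": gene.event,
        "coords": sorted(coords),
        "inclusion": gene.isoforms[0].transcript_id,
        "exclusion": gene.isoforms[1].transcript_id,
    }


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

def _correlated_profile(rng, base_profile: np.ndarray, r: float,
                        mean: float = 3.5, amp: float = 6.0) -> np.ndarray:
    """A log-space profile whose Pearson correlation with ``base_profile``
    is exactly ``r`` (Gram-Schmidt construction)."""
    u = base_profile - base_profile.mean()
    u = u / np.linalg.norm(u)
    e = rng.normal(size=len(u))
    e = e - e.mean()
    e = e - (e @ u) * u
    if np.linalg.norm(e) < 1e-12:
        e = np.roll(u, 1) - np.roll(u, 1).mean()
        e = e - (e @ u) * u
    v = e / np.linalg.norm(e)
    t = r * u + np.sqrt(max(0.0, 1 - r * r)) * v
    return mean + amp * t


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Build the full synthetic corpus; optionally write all files to a directory."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # -- assign a planted feature to each gene ------------------------------
    assignments = []
    for kind in EVENT_KINDS:
        assignments.extend([kind] * round(cfg.event_rates.get(kind, 0) * cfg.n_genes))
    assignments.extend(["none"] * (cfg.n_genes - len(assignments)))
    rng.shuffle(assignments)

    # -- lay out genes and noncoding loci per chromosome --------------------
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    genes: list[_Gene] = []
    linc_slots: list[tuple[str, int, int, str]] = []  # chrom, start, length, strand
    chrom_lens: dict[str, int] = {}
    n_linc_left = cfg.n_lincrnas
    linc_every = max(1, cfg.n_genes // max(cfg.n_lincrnas, 1))

    gene_counter = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 600
        for _ in per_chrom[ci]:
            if n_linc_left > 0 and gene_counter % linc_every == linc_every - 1:
                llen = int(rng.integers(*cfg.linc_length_range))
                lstrand = str(rng.choice(["+", "-"]))
                linc_slots.append((chrom, cursor, llen, lstrand))
                n_linc_left -= 1
                cursor += llen + 600
            gid = f"G{gene_counter:04d}"
            strand = str(rng.choice(["+", "-"]))
            event = assignments[gene_counter]
            # leave room for upstream end-shift extensions
            gene = _gene_structure(rng, cfg, event, cursor + cfg.end_shift_nt + 50,
                                   chrom, strand, gid)
            genes.append(gene)
            span_end = max(t.end for t in gene.isoforms)
            cursor = span_end + int(rng.integers(*cfg.intergenic_gap_range))
            gene_counter += 1
        chrom_lens[chrom] = cursor + 600

    # -- raw genome ----------------------------------------------------------
    arrs = {c: _random_seq(rng, n, cfg.gc_fraction) for c, n in chrom_lens.items()}

    # -- splice-site dinucleotides for every intron of every isoform ---------
    for gene in genes:
        arr = arrs[gene.chrom]
        introns = set()
        for t in gene.isoforms:
            introns.update(t.introns())
        for s, e in introns:
            if gene.strand == "+":
                arr[s], arr[s + 1] = "G", "T"
                arr[e - 2], arr[e - 1] = "A", "G"
            else:
                arr[e - 2], arr[e - 1] = "A", "C"
                arr[s], arr[s + 1] = "C", "T"

    # -- coding exon content for the primary isoform -------------------------
    for gene in genes:
        arr = arrs[gene.chrom]
        iso0 = gene.isoforms[0]
        seq = _make_coding_seq(rng, iso0.length, cfg.utr5_nt, cfg.utr3_nt,
                               cfg.gc_fraction)
        _write_spliced(arr, [(e.start, e.end) for e in iso0.exons],
                       gene.strand, seq)

    # -- noncoding loci -------------------------------------------------------
    lnc_models: list[TranscriptModel] = []
    lnc_truth: list[dict] = []
    for i, (chrom, start, llen, lstrand) in enumerate(linc_slots):
        lid = f"LINC{i:03d}"
        # one or two exons
        if llen > 700 and rng.random() < 0.5:
            il = int(rng.integers(*cfg.intron_length_range))
            half = llen // 2
            exons = [(start, start + half), (start + half + il, start + llen + il)]
        else:
            exons = [(start, start + llen)]
        t = TranscriptModel(
            f"{lid}.1", lid, chrom, lstrand,
            [GenomicInterval(chrom, s, e, lstrand) for s, e in exons],
        )
        arr = arrs[chrom]
        for s, e in t.introns():
            if lstrand == "+":
                arr[s], arr[s + 1], arr[e - 2], arr[e - 1] = "G", "T", "A", "G"
            else:
                arr[e - 2], arr[e - 1], arr[s], arr[s + 1] = "A", "C", "C", "T"
        _break_orfs(arr, exons, lstrand)
        lnc_models.append(t)
        lnc_truth.append({"transcript_id": t.transcript_id, "class": "lincRNA"})

    # lncNATs: antisense mono-exon transcripts over a host gene's 3' UTR
    host_pool = [g for g in genes if g.event == "none"]
    rng.shuffle(host_pool)
    nat_hosts = host_pool[: cfg.n_lncnats]
    for i, host in enumerate(nat_hosts):
        lid = f"NAT{i:03d}"
        nat_strand = "-" if host.strand == "+" else "+"
        iso0 = host.isoforms[0]
        if host.strand == "+":
            utr_end = iso0.end  # 3' UTR is the tail of the last genomic exon
            span = (utr_end - 180, utr_end + 280)
        else:
            utr_start = iso0.start
            span = (utr_start - 280, utr_start + 180)
        t = TranscriptModel(
            f"{lid}.1", lid, host.chrom, nat_strand,
            [GenomicInterval(host.chrom, span[0], span[1], nat_strand)],
        )
        _break_orfs(arrs[host.chrom], [span], nat_strand)
        lnc_models.append(t)
        lnc_truth.append(
            {"transcript_id": t.transcript_id, "class": "lncNAT",
             "host_gene": host.gene_id}
        )

    # -- poly(A) site context: planted motif and downstream A-richness -------
    # every observed locus (coding and noncoding) contributes its 3' ends
    polya_truth: list[dict] = []
    motif = cfg.polya_motif.upper()
    site_owners = [
        (g.gene_id, g.chrom, g.strand, sorted({t.tts for t in g.isoforms}))
        for g in genes
    ] + [
        (t.gene_id, t.chrom, t.strand, [t.tts]) for t in lnc_models
    ]
    for owner_id, chrom, strand, sites in site_owners:
        arr = arrs[chrom]
        for pos in sites:
            has_motif = bool(rng.random() < cfg.motif_rate)
            if has_motif:
                off = int(rng.integers(-30, -10 - len(motif) + 1))
                _write_transcript_oriented(arr, pos, strand, off, motif)
            if cfg.a_rich_downstream:
                downstream = "".join(
                    "A" if rng.random() < 0.7 else str(rng.choice(_BASES))
                    for _ in range(11)
                )
                _write_transcript_oriented(arr, pos, strand, 0, downstream)
            polya_truth.append(
                {"gene_id": owner_id, "chrom": chrom,
                 "strand": strand, "site_pos": int(pos),
                 "has_motif": has_motif}
            )

    genome = {c: "".join(arr) for c, arr in arrs.items()}

    # -- observed / reference transcript sets --------------------------------
    reference = []
    for gene in genes:
        iso0 = gene.isoforms[0]
        reference.append(
            TranscriptModel(
                f"{gene.gene_id}.ref", gene.gene_id, gene.chrom, gene.strand,
                list(iso0.exons),
            )
        )
    observed = [t for g in genes for t in g.isoforms] + lnc_models

    # -- reads + alignments ---------------------------------------------------
    reads: list[tuple[str, str]] = []
    alignments = []
    for t in observed:
        tseq = transcript_sequence(t, genome)
        for r in range(cfg.n_reads_per_isoform):
            tail_len = int(rng.integers(cfg.tail_length_range[0],
                                        cfg.tail_length_range[1] + 1))
            tail = "".join(
                str(rng.choice(np.array(list("CGT"))))
                if rng.random() < cfg.tail_impurity_rate else "A"
                for _ in range(tail_len)
            )
            read_id = f"{t.transcript_id}_read{r}"
            reads.append((read_id, tseq + tail))
            alignments.append(
                (t.chrom, t.start, t.end, read_id, 0, t.strand,
                 [(e.start, e.end) for e in t.exons])
            )

    # -- expression -----------------------------------------------------------
    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]
    n_s = cfg.n_samples
    group_b = set(range(n_s - n_s // 2, n_s))  # later samples form group B

    gene_logs: dict[str, np.ndarray] = {}
    deg_planted = set(
        rng.choice([g.gene_id for g in genes],
                   size=round(cfg.deg_rate * cfg.n_genes), replace=False)
    )
    for gene in genes:
        base = rng.uniform(2, 5)
        delta = rng.normal(0, 1.2)
        g = np.array(
            [base + (delta if j in group_b else 0.0) + rng.normal(0, 0.4)
             for j in range(n_s)]
        )
        if gene.gene_id in deg_planted:
            g[int(rng.integers(0, n_s))] += 2.5
        gene_logs[gene.gene_id] = np.clip(g, 0, None)

    # lncRNA cluster profiles
    protos = []
    for m in range(cfg.n_expr_clusters):
        p = np.zeros(n_s)
        idx = np.arange(m * n_s // cfg.n_expr_clusters,
                        (m + 1) * n_s // cfg.n_expr_clusters)
        if len(idx) == 0:
            idx = np.array([m % n_s])
        p[idx] = 1.0
        protos.append(p)
    lnc_logs: dict[str, np.ndarray] = {}
    lnc_clusters: dict[str, int] = {}
    for i, t in enumerate(lnc_models):
        m = i % cfg.n_expr_clusters
        g = 1.5 + cfg.cluster_separation * protos[m] + rng.normal(0, 0.3, n_s)
        lnc_logs[t.transcript_id] = np.clip(g, 0, None)
        lnc_clusters[t.transcript_id] = m + 1

    # planted lncRNA-target correlations (exact-r construction in log space)
    pair_truth: list[dict] = []
    used_targets = set()
    # antisense pairs claim their hosts first so a lincRNA cannot steal one
    pair_order = sorted(
        zip(lnc_truth, lnc_models), key=lambda p: p[0]["class"] != "lncNAT"
    )
    for rec, t in pair_order:
        if rec["class"] == "lncNAT":
            target = rec["host_gene"]
        else:
            # nearest coding gene on the same chromosome
            cands = [
                (max(g.isoforms[0].start - t.end, t.start - g.isoforms[0].end, 0), g.gene_id)
                for g in genes if g.chrom == t.chrom
            ]
            target = min(cands)[1] if cands else None
        if target is None or target in used_targets:
            continue
        used_targets.add(target)
        sign = 1.0 if rng.random() < cfg.positive_pair_fraction else -1.0
        r = sign * cfg.lnc_target_r
        gene_logs[target] = np.clip(
            _correlated_profile(rng, lnc_logs[t.transcript_id], r), 0, None
        )
        # clipping is a no-op for these amplitudes; correlation stays exact
        pair_truth.append(
            {"lncrna_id": t.transcript_id, "target_gene": target,
             "planted_r": r,
             "pair_class": "positive" if r > 0 else "negative"}
        )
        rec["target_gene"] = target

    # isoform-level FPKM: gene profile split by fixed isoform weights
    fpkm_rows = {}
    for gene in genes:
        F = np.exp2(gene_logs[gene.gene_id]) - 1
        n_iso = len(gene.isoforms)
        weights = [0.65, 0.35] if n_iso == 2 else [1.0]
        for t, w in zip(gene.isoforms, weights):
            fpkm_rows[t.transcript_id] = F * w
    for t in lnc_models:
        fpkm_rows[t.transcript_id] = np.exp2(lnc_logs[t.transcript_id]) - 1
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=samples)
    fpkm.index.name = "isoform_id"

    # integer counts consistent with FPKM at a nominal library size of 1e6
    lengths = pd.Series({t.transcript_id: t.length for t in observed})
    counts = (fpkm.mul(lengths, axis=0) * 1e6 / 1e9).round().astype(int)

    # truth DEG set: the fold-change rule applied to planted gene profiles
    deg_truth = set()
    for gid, g in gene_logs.items():
        F = np.exp2(g) - 1
        diffs = np.abs(g[:, None] - g[None, :])
        pairmax = np.maximum(F[:, None], F[None, :])
        if ((diffs >= cfg.deg_min_fold) & (pairmax >= cfg.deg_min_fpkm)).any():
            deg_truth.add(gid)

    # -- domains --------------------------------------------------------------
    domain_rows = []
    domain_truth = []
    event_genes = [g for g in genes if len(g.isoforms) == 2]
    classes = []
    for kind, rate in cfg.domain_change_rates.items():
        classes.extend([kind] * round(rate * len(event_genes)))
    classes.extend(["unchanged"] * (len(event_genes) - len(classes)))
    rng.shuffle(classes)
    for gene in genes:
        ref_iso = gene.isoforms[0].transcript_id
        n_dom = int(rng.integers(1, 4))
        ref_domains = list(rng.choice(cfg.domain_alphabet, size=n_dom, replace=False))
        pos = 10
        for d in ref_domains:
            domain_rows.append((ref_iso, d, pos, pos + 50))
            pos += 60
        if len(gene.isoforms) < 2:
            continue
        var_iso = gene.isoforms[1].transcript_id
        cls = classes.pop()
        var_domains = list(ref_domains)
        lost, gained = [], []
        if cls in ("loss", "both"):
            lost = [var_domains.pop(int(rng.integers(0, len(var_domains))))]
        if cls in ("gain", "both"):
            extra = [d for d in cfg.domain_alphabet if d not in ref_domains]
            if extra:
                gained = [str(rng.choice(extra))]
                var_domains.extend(gained)
            elif cls == "gain":
                cls = "unchanged"
        if not lost and not gained:
            cls = "unchanged"
        pos = 10
        for d in var_domains:
            domain_rows.append((var_iso, d, pos, pos + 50))
            pos += 60
        domain_truth.append(
            {"gene_id": gene.gene_id, "isoform_id": var_iso,
             "reference_isoform_id": ref_iso, "change_class": cls,
             "lost": sorted(lost), "gained": sorted(gained)}
        )

    # -- GO map and paralog pairs --------------------------------------------
    terms = [f"GO:{i:07d}" for i in range(1, 21)]
    go_rows = []
    for gene in genes:
        assigned = set(rng.choice(terms[1:], size=int(rng.integers(1, 4)),
                                  replace=False))
        p_hit = 0.6 if gene.gene_id in deg_truth else 0.1
        if rng.random() < p_hit:
            assigned.add(terms[0])
        for term in sorted(assigned):
            go_rows.append((gene.gene_id, term))
    half = cfg.n_genes // 2
    paralog_rows = [
        (genes[i].gene_id, genes[i + half].gene_id)
        for i in range(min(30, half))
    ]

    # -- truth tables ---------------------------------------------------------
    events_truth = [r for r in (_planted_event_record(g) for g in genes) if r]
    truth = {
        "isoforms": {
            t.transcript_id: t.gene_id for t in observed
        },
        "categories": {
            t.transcript_id: ("novel_locus" if t.gene_id.startswith(("LINC", "NAT"))
                              else "known" if t.intron_chain_key()
                              == next(r for r in reference
                                      if r.gene_id == t.gene_id).intron_chain_key()
                              else "novel_of_annotated")
            for t in observed
        },
        "events": events_truth,
        "end_flags": {
            g.gene_id: {"atss": g.event == "aTSS", "atts": g.event == "aTTS"}
            for g in genes if len(g.isoforms) >= 2
        },
        "polya_sites": polya_truth,
        "polya_motif": motif,
        "lncrnas": lnc_truth,
        "lnc_clusters": lnc_clusters,
        "lnc_pairs": pair_truth,
        "deg_genes": sorted(deg_truth),
        "domain_changes": domain_truth,
        "samples": samples,
        "sample_groups": {s: ("B" if j in group_b else "A")
                          for j, s in enumerate(samples)},
    }

    result = SimResult(
        cfg, genome, reference, observed, truth, fpkm, counts, reads, alignments
    )
    if out_dir is not None:
        _write_corpus(result, Path(out_dir), domain_rows, go_rows, paralog_rows)
    return result


def _write_corpus(res: SimResult, out: Path, domain_rows, go_rows,
                  paralog_rows) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_genome(res.genome, out / "genome.fa")
    write_gtf(res.reference, out / "reference.gtf")
    write_gtf(res.observed, out / "observed.gtf")
    with open(out / "flnc.fastq", "w") as fh:
        for rid, seq in res.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(out / "flnc_alignments.bed12", "w") as fh:
        for chrom, start, end, rid, score, strand, blocks in res.alignments:
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            offs = ",".join(str(s - start) for s, e in blocks) + ","
            fh.write(
                f"{chrom}\t{start}\t{end}\t{rid}\t{score}\t{strand}\t"
                f"{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{offs}\n"
            )
    res.fpkm.to_csv(out / "fpkm.tsv", sep="\t", float_format="%.6f")
    res.counts.to_csv(out / "counts.tsv", sep="\t")
    pd.DataFrame(
        domain_rows, columns=["isoform_id", "domain_name", "start_aa", "end_aa"]
    ).to_csv(out / "domains.tsv", sep="\t", index=False)
    pd.DataFrame(go_rows, columns=["gene_id", "term"]).to_csv(
        out / "go_map.tsv", sep="\t", index=False
    )
    pd.DataFrame(paralog_rows, columns=["gene_1", "gene_2"]).to_csv(
        out / "paralog_pairs.tsv", sep="\t", index=False
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(res.truth, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
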