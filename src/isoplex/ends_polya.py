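"""Alternative transcript ends and poly(A) cleavage-site analysis.

Transcript 5'/3' ends are clustered per locus by 1-D single linkage; a gene
with two or more end clusters uses alternative start (aTSS) or termination
(aTTS) sites.  Poly(A) tails are called from full-length (FLNC) reads with a
numeric window rule — a 30-nt window of the 3' soft-clipped segment must
contain at least eight adenines and at most one non-A base — and the cleavage
site is the genomic boundary immediately after the last aligned transcript
base.  Downstream, cleavage sites are collapsed per gene, the nucleotide
composition around sites is profiled, and upstream k-mers are tested for
enrichment against a shuffled background (a transparent stand-in for motif
discovery tools).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import reverse_complement
from .expression import bh_adjust
from .locus import GeneLocus

__all__ = [
    "EndCluster",
    "AlignmentRecord",
    "PolyACall",
    "cluster_ends",
    "end_flags",
    "read_bed12_alignments",
    "read_sam_alignments",
    "call_polya",
    "polya_sites_per_gene",
    "composition_profile",
    "upstream_kmer_enrichment",
    "coupling_venn",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class EndCluster:
    locus_id: str
    end_kind: str  # "TSS" or "TTS"
    representative: int  # modal end position
    members: list[str]
    tolerance: int


@dataclasses.dataclass
class AlignmentRecord:
    """Minimal read-to-genome alignment: blocks of aligned genomic intervals.

    The read is assumed 5'->3' in transcript orientation (FLNC convention);
    ``aligned_read_length`` is the number of read bases consumed by the
    blocks, so the 3' soft-clip is ``read[aligned_read_length:]``.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]

    @property
    def aligned_read_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def cleavage_pos(self) -> int:
        """Genomic boundary following the last aligned base, strand-adjusted."""
        return self.blocks[-1][1] if self.strand == "+" else self.blocks[0][0]


@dataclasses.dataclass
class PolyACall:
    read_id: str
    tail_detected: bool
    a_count: int
    non_a_count: int
    window_len: int
    chrom: str | None
    cleavage_pos: int | None
    strand: str | None
    gene_id: str | None = None


# ---------------------------------------------------------------------------
# end clustering
# ---------------------------------------------------------------------------

def cluster_ends(locus: GeneLocus, end_kind: str,
                 tolerance_nt: int = 50) -> list[EndCluster]:
    """Single-linkage clustering of a locus's 5' or 3' transcript ends.

    ``end_kind`` is ``"TSS"`` (5' end in transcript orientation) or ``"TTS"``.
    Ends whose sorted neighbours are within ``tolerance_nt`` join one cluster.
    The representative is the modal member position (ties toward the 5'-most
    position in transcript orientation).
    """
    if end_kind not in ("TSS", "TTS"):
        raise ValueError(f"end_kind must be TSS or TTS, got {end_kind!r}")
    ends = [
        (t.tss if end_kind == "TSS" else t.tts, t.transcript_id)
        for t in locus.transcripts
    ]
    ends.sort()
    clusters: list[list[tuple[int, str]]] = []
    for pos, tx in ends:
        if clusters and pos - clusters[-1][-1][0] <= tolerance_nt:
            clusters[-1].append((pos, tx))
        else:
            clusters.append([(pos, tx)])
    out = []
    for members in clusters:
        counts = Counter(pos for pos, _ in members)
        top = max(counts.values())
        modal = [p for p, c in counts.items() if c == top]
        rep = min(modal) if locus.strand == "+" else max(modal)
        out.append(
            EndCluster(
                locus.locus_id, end_kind, rep,
                [tx for _, tx in members], tolerance_nt,
            )
        )
    return out


def end_flags(loci: Iterable[GeneLocus], tolerance_nt: int = 50) -> pd.DataFrame:
    """Per multi-isoform locus: number of end clusters and aTSS/aTTS flags."""
    rows = []
    for locus in loci:
        if locus.n_isoforms < 2:
            continue
        tss = cluster_ends(locus, "TSS", tolerance_nt)
        tts = cluster_ends(locus, "TTS", tolerance_nt)
        rows.append(
            {
                "gene_id": locus.locus_id,
                "n_tss_clusters": len(tss),
                "n_tts_clusters": len(tts),
                "atss": len(tss) >= 2,
                "atts": len(tts) >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_tss_clusters", "n_tts_clusters", "atss", "atts"],
    )


# ---------------------------------------------------------------------------
# poly(A) calling
# ---------------------------------------------------------------------------

def read_bed12_alignments(path) -> list[AlignmentRecord]:
    """Parse BED12 alignment records (blocks = aligned exonic segments)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED fields")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append(AlignmentRecord(name, chrom, strand, blocks))
    return out


def read_sam_alignments(path) -> dict[str, tuple[str, AlignmentRecord]]:
    """Parse SAM records into (5'->3' read sequence, alignment) per read id.

    Only the fields the tail caller needs are kept: read id, strand, and the
    aligned blocks (from the CIGAR M/=/X runs).  Reads mapped to the minus
    strand are stored reverse-complemented in SAM, so their sequence is
    flipped back to transcript orientation here.  Insertions are assumed
    absent (exact FLNC alignments), so the aligned read length equals the
    block total.
    """
    import pysam

    out: dict[str, tuple[str, AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            blocks = [(int(s), int(e)) for s, e in rec.get_blocks()]
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = reverse_complement(seq)
            out[rec.query_name] = (
                seq,
                AlignmentRecord(rec.query_name, rec.reference_name, strand,
                                blocks),
            )
    return out


def _window_ok(window: str, min_a: int, max_non_a: int) -> bool:
    a = window.count("A")
    return a >= min_a and len(window) - a <= max_non_a


def call_polya(read_seq: str, alignment: AlignmentRecord | None,
               window: int = 30, min_a: int = 8, max_non_a: int = 1,
               mode: str = "sliding", read_id: str = "unaligned") -> PolyACall:
    """Apply the poly(A) window rule to the 3' terminal segment of a read.

    The segment is the soft-clipped read tail beyond the last aligned base
    (the whole read for unaligned reads).  A tail is detected when some
    ``window``-nt window of the segment (the terminal-anchored window only in
    ``mode="anchored"``) holds >= ``min_a`` adenines and <= ``max_non_a``
    non-A bases; segments shorter than ``window`` are evaluated as-is.
    """
    read_seq = read_seq.upper()
    if alignment is None:
        segment = read_seq
    else:
        segment = read_seq[alignment.aligned_read_length :]

    detected = False
    best = (0, 0, 0)  # (a_count, -non_a, window_len) of best-scoring window
    if segment:
        if len(segment) <= window:
            windows = [segment]
        elif mode == "anchored":
            # single window anchored at the clip start (just past the cleavage)
            windows = [segment[:window]]
        else:
            windows = [
                segment[i : i + window] for i in range(len(segment) - window + 1)
            ]
        for w in windows:
            a = w.count("A")
            non_a = len(w) - a
            if a >= min_a and non_a <= max_non_a:
                detected = True
            if (a, -non_a) > (best[0], -best[1]):
                best = (a, non_a, len(w))

    if alignment is None:
        return PolyACall(
            read_id, detected, best[0], best[1], best[2], None, None, None
        )
    return PolyACall(
        alignment.read_id, detected, best[0], best[1], best[2],
        alignment.chrom, alignment.cleavage_pos, alignment.strand,
    )


def assign_calls_to_genes(calls: Sequence[PolyACall],
                          loci: Sequence[GeneLocus]) -> None:
    """Assign each aligned call to the locus whose span contains its site."""
    by_key: dict[tuple[str, str], list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        by_key[(locus.chrom, locus.strand)].append(locus)
    for key in by_key:
        by_key[key].sort(key=lambda l: l.start)
    for call in calls:
        if call.cleavage_pos is None:
            continue
        candidates = [
            l for l in by_key.get((call.chrom, call.strand), [])
            if l.start <= call.cleavage_pos <= l.end
        ]
        if candidates:
            # nearest span midpoint on rare overlap
            call.gene_id = min(
                candidates,
                key=lambda l: abs((l.start + l.end) / 2 - call.cleavage_pos),
            ).locus_id


def polya_sites_per_gene(calls: Sequence[PolyACall],
                         loci: Sequence[GeneLocus],
                         collapse_tol_nt: int = 24) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse tailed-read cleavage positions into per-gene poly(A) sites.

    Calls with a detected tail and a gene assignment contribute their cleavage
    position; positions within ``collapse_tol_nt`` (single linkage) merge into
    one site whose coordinate is the modal member position.  Returns the site
    table and the sites-per-gene histogram.
    """
    assign_calls_to_genes(calls, loci)
    per_gene: dict[str, list[PolyACall]] = defaultdict(list)
    for c in calls:
        if c.tail_detected and c.gene_id is not None:
            per_gene[c.gene_id].append(c)

    rows = []
    for gene_id in sorted(per_gene):
        gcalls = sorted(per_gene[gene_id], key=lambda c: c.cleavage_pos)
        clusters: list[list[PolyACall]] = []
        for c in gcalls:
            if clusters and c.cleavage_pos - clusters[-1][-1].cleavage_pos <= collapse_tol_nt:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        for cl in clusters:
            counts = Counter(c.cleavage_pos for c in cl)
            top = max(counts.values())
            site = min(p for p, n in counts.items() if n == top)
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": cl[0].chrom,
                    "strand": cl[0].strand,
                    "site_pos": site,
                    "n_reads": len(cl),
                }
            )
    sites = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "site_pos", "n_reads"]
    )
    hist = (
        sites.groupby("gene_id").size().value_counts().sort_index()
        if len(sites)
        else pd.Series(dtype=int)
    )
    hist.name = "n_genes"
    hist.index.name = "sites_per_gene"
    return sites, hist


# ---------------------------------------------------------------------------
# sequence context of cleavage sites
# ---------------------------------------------------------------------------

def composition_profile(sites: Sequence[tuple[str, int, str]],
                        genome: Mapping[str, str],
                        window: tuple[int, int] = (-50, 10)) -> pd.DataFrame:
    """Per-position A/C/G/T fractions around cleavage sites.

    Offsets are in transcript orientation: -1 is the last transcribed base,
    0 the first base after the cleavage boundary.  Ns and out-of-range
    positions are excluded; each row is normalised to sum to 1.
    """
    lo, hi = window
    offsets = range(lo, hi + 1)
    counts = {off: Counter() for off in offsets}
    for chrom, pos, strand in sites:
        seq = genome[chrom]
        for off in offsets:
            gpos = pos + off if strand == "+" else pos - 1 - off
            if 0 <= gpos < len(seq):
                base = seq[gpos]
                if strand == "-":
                    base = base.translate(_COMP)
                if base in "ACGT":
                    counts[off][base] += 1
    rows = []
    for off in offsets:
        total = sum(counts[off].values())
        rows.append(
            {
                "offset": off,
                **{
                    b: (counts[off][b] / total if total else float("nan"))
                    for b in "ACGT"
                },
            }
        )
    return pd.DataFrame(rows, columns=["offset", "A", "C", "G", "T"])


def _upstream_window(genome: Mapping[str, str], chrom: str, pos: int,
                     strand: str, length: int) -> str:
    if strand == "+":
        return genome[chrom][max(0, pos - length) : pos]
    return reverse_complement(genome[chrom][pos : pos + length])


def upstream_kmer_enrichment(
    sites: Sequence[tuple[str, int, str]],
    genome: Mapping[str, str],
    ks: Sequence[int] = (5, 6),
    upstream: int = 50,
    n_shuffles: int = 10,
    seed: int = 0,
    background_windows: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank k-mers over-represented in the 50 nt upstream of poly(A) sites.

    Observed statistic: number of upstream windows containing the k-mer.
    Background: mononucleotide-preserving shuffles of the same windows
    (seeded), or explicit ``background_windows``.  One-sided binomial test
    per k-mer, BH-corrected; ranked by (p, -fold).
    """
    windows = [
        _upstream_window(genome, chrom, pos, strand, upstream)
        for chrom, pos, strand in sites
    ]
    windows = [w for w in windows if len(w) >= max(ks)]
    if not windows:
        raise ValueError("no usable upstream windows")
    if background_windows is None:
        rng = np.random.default_rng(seed)
        background = []
        for w in windows:
            arr = np.frombuffer(w.encode(), dtype="S1")
            for _ in range(n_shuffles):
                background.append(rng.permutation(arr).tobytes().decode())
    else:
        background = list(background_windows)

    rows = []
    n_obs, n_bg = len(windows), len(background)
    for k in ks:
        kmers = set()
        for w in windows:
            kmers.update(w[i : i + k] for i in range(len(w) - k + 1))
        kmers = {m for m in kmers if set(m) <= set("ACGT")}
        for kmer in sorted(kmers):
            obs = sum(kmer in w for w in windows)
            bg = sum(kmer in w for w in background)
            bg_p = bg / n_bg if bg > 0 else 0.5 / (n_bg + 1)
            bg_p = min(bg_p, 1.0)
            p = stats.binomtest(obs, n_obs, bg_p, alternative="greater").pvalue
            fold = (obs / n_obs) / bg_p
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "n_windows": n_obs,
                    "n_hits": obs,
                    "bg_freq": bg_p,
                    "fold_enrichment": fold,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"])
    df = df.sort_values(
        ["p_value", "fold_enrichment"], ascending=[True, False]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# AS / aTSS / aTTS / DEG coupling
# ---------------------------------------------------------------------------

def coupling_venn(loci: Sequence[GeneLocus],
                  as_genes: set[str],
                  end_flag_table: pd.DataFrame,
                  deg_genes: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean AS/aTSS/aTTS/DEG flags per multi-isoform gene + Venn cells.

    Returns the per-gene flag table and the 2^4 cell-count table; cell counts
    partition the multi-isoform gene set.
    """
    flags = end_flag_table.set_index("gene_id")
    rows = []
    for locus in loci:
        if locus.n_isoforms < 2:
            continue
        g = locus.locus_id
        rows.append(
            {
                "gene_id": g,
                "has_AS": g in as_genes,
                "has_aTSS": bool(flags.loc[g, "atss"]) if g in flags.index else False,
                "has_aTTS": bool(flags.loc[g, "atts"]) if g in flags.index else False,
                "is_DEG": g in deg_genes,
            }
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "has_AS", "has_aTSS", "has_aTTS", "is_DEG"]
    )
    cells = (
        per_gene.groupby(["has_AS", "has_aTSS", "has_aTTS", "is_DEG"])
        .size()
        .rename("n_genes")
        .reset_index()
        if len(per_gene)
        else pd.DataFrame(columns=["has_AS", "has_aTSS", "has_aTTS", "is_DEG", "n_genes"])
    )
    return per_gene, cells
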