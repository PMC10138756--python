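"""Gene-locus construction, isoform classification and per-gene summaries.

A gene locus is the strand-aware single-linkage closure of exonic overlap
(>= 1 bp) among observed transcripts: transcripts that share exonic sequence on
the same strand, directly or through intermediates, are one locus.  Observed
isoforms are then classified against a reference annotation into three
categories — ``known`` (exact intron-chain match, the "full splice match"
notion), ``novel_of_annotated`` (exonic overlap with a reference transcript on
the same strand but a new splice structure) and ``novel_locus`` (no same-strand
reference overlap at all).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel, gc_content, transcript_sequence

__all__ = [
    "GeneLocus",
    "build_loci",
    "classify_isoform",
    "classify_all",
    "per_gene_stats",
    "tissue_specificity",
]

KNOWN = "known"
NOVEL_OF_ANNOTATED = "novel_of_annotated"
NOVEL_LOCUS = "novel_locus"
CATEGORIES = (KNOWN, NOVEL_OF_ANNOTATED, NOVEL_LOCUS)


@dataclasses.dataclass
class GeneLocus:
    """A strand-aware overlap group of transcripts (the gene unit)."""

    locus_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_loci(transcripts: Sequence[TranscriptModel],
               prefix: str = "LOC") -> list[GeneLocus]:
    """Group transcripts into gene loci by single-linkage exonic overlap.

    Two transcripts belong to the same locus iff they are connected by a chain
    of >= 1 bp exon-to-exon overlaps on the same chromosome and strand.  Locus
    ids are deterministic, numbered by (chrom, span start).  Each member's
    ``gene_id`` is set to its locus id.
    """
    uf = _UnionFind(len(transcripts))
    # sweep exons per (chrom, strand): connected components of the interval
    # overlap graph are exactly the maximal runs of the sweep
    exons = []
    for i, t in enumerate(transcripts):
        for e in t.exons:
            exons.append((t.chrom, t.strand, e.start, e.end, i))
    exons.sort()
    run_key = None
    run_rep = -1
    run_end = -1
    for chrom, strand, start, end, idx in exons:
        key = (chrom, strand)
        if key != run_key or start >= run_end:
            run_key, run_rep, run_end = key, idx, end
        else:
            uf.union(run_rep, idx)
            run_end = max(run_end, end)

    groups: dict[int, list[TranscriptModel]] = defaultdict(list)
    for i, t in enumerate(transcripts):
        groups[uf.find(i)].append(t)

    loci = sorted(
        groups.values(),
        key=lambda ts: (ts[0].chrom, min(t.start for t in ts), ts[0].strand),
    )
    out = []
    width = max(4, len(str(len(loci))))
    for n, members in enumerate(loci, start=1):
        locus_id = f"{prefix}{n:0{width}d}"
        members = sorted(members, key=lambda t: (t.start, t.end, t.transcript_id))
        for t in members:
            t.gene_id = locus_id
        out.append(GeneLocus(locus_id, members[0].chrom, members[0].strand, members))
    return out


class ReferenceIndex:
    """Pre-indexed reference annotation for fast isoform classification."""

    def __init__(self, reference: Sequence[TranscriptModel]):
        self.chains: set[tuple] = set()
        self.mono: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
        self.exons: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for t in reference:
            if len(t.exons) > 1:
                self.chains.add(t.intron_chain_key())
            else:
                self.mono[(t.chrom, t.strand)].append(t)
            for e in t.exons:
                self.exons[(t.chrom, t.strand)].append((e.start, e.end))
        for key in self.exons:
            self.exons[key].sort()

    def has_exonic_overlap(self, t: TranscriptModel) -> bool:
        ref_exons = self.exons.get((t.chrom, t.strand), [])
        if not ref_exons:
            return False
        starts = [s for s, _ in ref_exons]
        import bisect

        for e in t.exons:
            # candidate reference exons with start < e.end
            hi = bisect.bisect_left(starts, e.end)
            for s, en in ref_exons[:hi]:
                if en > e.start:
                    return True
        return False


def classify_isoform(t: TranscriptModel,
                     reference: Sequence[TranscriptModel] | ReferenceIndex,
                     mono_exon_tol: int = 50) -> str:
    """Assign one of the three isoform categories against the reference.

    ``known``: a multi-exon isoform whose intron chain equals a reference
    transcript's chain on the same chrom/strand (end positions are free — end
    variation is the business of aTSS/aTTS calling), or a mono-exon isoform
    whose both ends fall within ``mono_exon_tol`` nt of a mono-exon reference
    transcript's ends.  ``novel_of_annotated``: not known, but >= 1 bp exonic
    overlap with a same-strand reference transcript.  ``novel_locus``:
    everything else (antisense-only overlap counts as novel_locus).
    """
    idx = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    if len(t.exons) > 1:
        if t.intron_chain_key() in idx.chains:
            return KNOWN
    else:
        exon = t.exons[0]
        for ref in idx.mono.get((t.chrom, t.strand), []):
            if (
                abs(exon.start - ref.start) <= mono_exon_tol
                and abs(exon.end - ref.end) <= mono_exon_tol
            ):
                return KNOWN
    if idx.has_exonic_overlap(t):
        return NOVEL_OF_ANNOTATED
    return NOVEL_LOCUS


def classify_all(transcripts: Sequence[TranscriptModel],
                 reference: Sequence[TranscriptModel],
                 mono_exon_tol: int = 50) -> pd.DataFrame:
    """Classify every observed isoform; returns transcript_id/category table."""
    idx = ReferenceIndex(reference)
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "category": classify_isoform(t, idx, mono_exon_tol),
        }
        for t in transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "category"])


def per_gene_stats(loci: Sequence[GeneLocus],
                   genome: Mapping[str, str] | None = None) -> pd.DataFrame:
    """One row per locus: isoform/exon counts, mean lengths, GC.

    GC and length columns require a genome; without one they are NaN.
    """
    rows = []
    for locus in loci:
        exon_counts = [len(t.exons) for t in locus.transcripts]
        lengths = [t.length for t in locus.transcripts]
        row = {
            "gene_id": locus.locus_id,
            "chrom": locus.chrom,
            "strand": locus.strand,
            "start": locus.start,
            "end": locus.end,
            "n_isoforms": locus.n_isoforms,
            "exon_counts": ",".join(map(str, exon_counts)),
            "max_exons": max(exon_counts),
            "mean_exons": float(np.mean(exon_counts)),
            "mean_mrna_length": float(np.mean(lengths)),
            "mean_exon_length": float(np.mean(
                [len(e) for t in locus.transcripts for e in t.exons]
            )),
        }
        if genome is not None:
            gcs = [gc_content(transcript_sequence(t, genome))
                   for t in locus.transcripts]
            row["mean_gc"] = float(np.mean(gcs))
        else:
            row["mean_gc"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def tissue_specificity(expression: pd.DataFrame,
                       threshold_fpkm: float = 1.0) -> tuple[pd.DataFrame, pd.Series]:
    """Expressed-sample sets per isoform and the n-way overlap counts.

    An isoform is *expressed* in a sample when FPKM >= ``threshold_fpkm``
    and *specific* when it is expressed in exactly one sample.  The second
    return value counts isoforms by the number of samples they are expressed
    in (the overlap/upset summary).
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("negative FPKM values in expression matrix")
    expressed = expression >= threshold_fpkm
    n_expressed = expressed.sum(axis=1)
    sets = expressed.apply(
        lambda row: ",".join(expression.columns[row.to_numpy()]), axis=1
    )
    table = pd.DataFrame(
        {
            "expressed_in": sets,
            "n_samples": n_expressed,
            "specific": n_expressed == 1,
        },
        index=expression.index,
    )
    overlap_counts = n_expressed.value_counts().sort_index()
    return table, overlap_counts
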