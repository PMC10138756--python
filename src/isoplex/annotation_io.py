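"""Reading and writing of genome annotation and sequence data.

All coordinates inside the package are 0-based, half-open intervals on an
explicit strand; GTF/GFF3 files use 1-based inclusive coordinates and are
converted at the I/O boundary.  Unstranded records are rejected because every
downstream comparison (isoform classification, splice-site typing, end
clustering) is strand-aware.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_gtf",
    "write_bed12",
    "transcript_sequence",
    "reverse_complement",
    "gc_content",
    "AnnotationError",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation records or invalid transcript models."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclasses.dataclass
class TranscriptModel:
    """An exon chain on a strand — the atomic unit all stages compare.

    Exons are stored in genomic-ascending order, non-overlapping, separated by
    at least 1 nt (the introns).  ``gene_id`` may be empty before loci are
    built.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev = None
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon {exon} does not match "
                    f"{self.chrom}/{self.strand}"
                )
            if prev is not None and exon.start <= prev.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or touch "
                    f"({prev.end} .. {exon.start})"
                )
            prev = exon

    # -- convenience accessors -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """5' end in transcript orientation (genomic coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """3' end in transcript orientation (genomic coordinate)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic-ascending (start, end)."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain_key(self) -> tuple:
        """Hashable identity of the splice structure (chrom, strand, introns)."""
        return (self.chrom, self.strand, tuple(self.introns()))

    def exonic_overlap(self, other: "TranscriptModel") -> int:
        """Total exon-to-exon overlap in nt with another model (same strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += max(0, min(a.end, b.end) - max(a.start, b.start))
        return total


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence map."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise AnnotationError(f"no sequences found in {path}")
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, fmt: str | None = None) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into validated transcript models.

    ``fmt`` is ``"gtf"`` or ``"gff3"``; inferred from the file suffix when
    omitted.  Exon features must carry ``transcript_id``/``gene_id``
    attributes (GTF) or ``Parent`` links (GFF3).  File coordinates (1-based
    inclusive) are converted to internal 0-based half-open.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "gtf"
    if fmt not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation format {fmt!r}")

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    # map transcript-level feature id -> gene id for GFF3 Parent chains
    tx_gene: dict[str, str] = {}
    if fmt == "gff3":
        for feat in db.all_features():
            if feat.featuretype == "exon":
                continue
            parents = feat.attributes.get("Parent", [])
            fid = feat.id
            tx_gene[fid] = parents[0] if parents else fid

    exons_by_tx: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("exon"):
        if fmt == "gtf":
            tx_ids = feat.attributes.get("transcript_id", [])
            gene_ids = feat.attributes.get("gene_id", [""])
            if not tx_ids:
                raise AnnotationError(
                    f"{path}: exon at {feat.seqid}:{feat.start} lacks transcript_id"
                )
            tx_list = [(t, gene_ids[0]) for t in tx_ids]
        else:
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise AnnotationError(
                    f"{path}: exon at {feat.seqid}:{feat.start} lacks Parent"
                )
            tx_list = [(t, tx_gene.get(t, t)) for t in parents]
        if feat.strand not in STRANDS:
            raise AnnotationError(
                f"{path}: unstranded exon at {feat.seqid}:{feat.start}"
            )
        for tx, gene in tx_list:
            exons_by_tx[tx].append((feat.start - 1, feat.end))
            meta[tx] = (feat.seqid, feat.strand, gene)

    models = []
    for tx, exon_coords in exons_by_tx.items():
        chrom, strand, gene = meta[tx]
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
        models.append(TranscriptModel(tx, gene, chrom, strand, exons))
    models.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "isoplex") -> None:
    """Write transcript models as ensembl-dialect GTF (transcript + exon rows)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for exon in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Export transcript models as BED12 (one block per exon)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            sizes = ",".join(str(len(e)) for e in t.exons) + ","
            starts = ",".join(str(e.start - t.start) for e in t.exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def transcript_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation.

    Exon sequences are concatenated in genomic order and reverse-complemented
    for minus-strand models.  Ns pass through unchanged.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom} not in genome")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise IndexError(
            f"transcript {t.transcript_id} extends past end of {t.chrom} "
            f"({t.end} > {len(chrom_seq)})"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def gc_content(seq: str) -> float:
    """G+C fraction with N excluded from numerator and denominator."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return gc / denom


def translate(seq: str) -> str:
    """Translate a nucleotide sequence (complete codons only, no stop symbol)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    pep = str(Seq(trimmed).translate())
    return pep.rstrip("*")
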