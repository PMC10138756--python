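"""Alternative-splicing event detection, typing and differential analysis.

Events are detected pairwise within a gene locus and deduplicated by anchor
coordinates, in the spirit of pairwise structure comparison between isoform
pairs.  Five classical types are emitted:

IR    intron retention — an intron of one isoform lies fully inside an exon
      of the other.
ES    exon skipping — one or more internal exons of one isoform are spanned
      by a single intron of the other, with matching outer splice sites.
A5SS  alternative 5' (donor) splice site — two introns share the acceptor but
      differ at the donor, and the donor-side variable region is contiguous
      exon in the shorter-intron isoform.
A3SS  alternative 3' (acceptor) splice site — the mirror case at the acceptor.
MXE   mutually exclusive exons — each isoform of a pair includes exactly one
      of two non-overlapping internal exons sharing the flanking splice sites.

The exon-coverage requirement on A5SS/A3SS keeps the five types disjoint:
without it every exon-skipping pair would additionally fire the donor- and
acceptor-shift rules via the spanning intron.  Donor/acceptor are defined in
transcript orientation (the donor is the 5' splice site of the transcript),
so the same genomic configuration types differently on the two strands.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import TranscriptModel, reverse_complement
from .expression import bh_adjust
from .locus import GeneLocus

__all__ = [
    "ASEvent",
    "intron_chain",
    "detect_events",
    "detect_events_all",
    "splice_site_offsets",
    "boundary_dinucleotides",
    "as_structure_correlation",
    "differential_splicing",
]

EVENT_TYPES = ("IR", "ES", "A3SS", "A5SS", "MXE")


@dataclasses.dataclass
class ASEvent:
    """A typed, coordinate-anchored splicing difference within a locus."""

    event_type: str
    locus_id: str
    chrom: str
    strand: str
    anchor: tuple
    inclusion: set[str]
    exclusion: set[str]

    @property
    def event_id(self) -> str:
        coords = "_".join(str(x) for x in _flatten(self.anchor))
        return f"{self.locus_id}:{self.event_type}:{coords}"


def _flatten(x):
    for item in x:
        if isinstance(item, tuple):
            yield from _flatten(item)
        else:
            yield item


def anchor_coords(anchor) -> tuple[int, ...]:
    """Numeric coordinates of an anchor (side markers dropped), sorted."""
    return tuple(sorted(c for c in _flatten(anchor) if isinstance(c, int)))


def intron_chain(t: TranscriptModel) -> list[tuple[int, int]]:
    """Introns as (start, end) genomic half-open intervals, sorted."""
    return t.introns()


def _exon_covering(t: TranscriptModel, start: int, end: int):
    """Exon of ``t`` that fully covers [start, end), or None."""
    for e in t.exons:
        if e.start <= start and e.end >= end:
            return e
    return None


def _pair_events(t1: TranscriptModel, t2: TranscriptModel):
    """Yield (type, anchor, inclusion_tx, exclusion_tx) for one pair."""
    strand = t1.strand
    for a, b in ((t1, t2), (t2, t1)):
        ia = a.introns()
        ib = b.introns()
        ib_set = set(ib)

        # IR: intron of `a` retained inside an exon of `b`
        for s, e in ia:
            cov = _exon_covering(b, s, e)
            if cov is not None and cov.start < s and cov.end > e:
                yield "IR", (s, e), b.transcript_id, a.transcript_id

        # ES: run of >=2 consecutive introns of `a` whose outer boundaries
        # equal a single intron of `b`; exons between are skipped in `b`
        for j in range(len(ia)):
            for k in range(j + 1, len(ia)):
                outer = (ia[j][0], ia[k][1])
                if outer in ib_set:
                    skipped = tuple(
                        (ex.start, ex.end) for ex in a.exons[j + 1 : k + 1]
                    )
                    yield (
                        "ES",
                        (outer, skipped),
                        a.transcript_id,
                        b.transcript_id,
                    )

    # alternative donor/acceptor: introns sharing exactly one boundary
    i1s, i2s = t1.introns(), t2.introns()
    for (s1, e1), (s2, e2) in itertools.product(i1s, i2s):
        if s1 == s2 and e1 != e2:
            # shared left boundary
            short_t, short_i, long_i = (
                (t1, (s1, e1), (s2, e2)) if e1 < e2 else (t2, (s2, e2), (s1, e1))
            )
            # variable region must be contiguous exon in the short-intron form
            exon = _exon_covering(short_t, short_i[1], long_i[1])
            if exon is None or exon.start != short_i[1]:
                continue
            kind = "A3SS" if strand == "+" else "A5SS"
            anchor = (("L", s1), tuple(sorted((e1, e2))))
            yield kind, anchor, short_t.transcript_id, (
                t2.transcript_id if short_t is t1 else t1.transcript_id
            )
        elif e1 == e2 and s1 != s2:
            short_t, short_i, long_i = (
                (t1, (s1, e1), (s2, e2)) if s1 > s2 else (t2, (s2, e2), (s1, e1))
            )
            exon = _exon_covering(short_t, long_i[0], short_i[0])
            if exon is None or exon.end != short_i[0]:
                continue
            kind = "A5SS" if strand == "+" else "A3SS"
            anchor = (("R", e1), tuple(sorted((s1, s2))))
            yield kind, anchor, short_t.transcript_id, (
                t2.transcript_id if short_t is t1 else t1.transcript_id
            )

    # MXE: each isoform holds exactly one of two alternative internal exons
    def internal(t):
        out = []
        introns = t.introns()
        for idx in range(1, len(t.exons) - 1):
            out.append((t.exons[idx], introns[idx - 1], introns[idx]))
        return out

    for (ex1, l1, r1), (ex2, l2, r2) in itertools.product(internal(t1), internal(t2)):
        if l1[0] != l2[0] or r1[1] != r2[1]:
            continue
        if ex1.overlaps(ex2):
            continue
        # exclusivity within the pair
        if _overlaps_any(t2, ex1) or _overlaps_any(t1, ex2):
            continue
        left, right = sorted(
            [(ex1.start, ex1.end), (ex2.start, ex2.end)]
        )
        anchor = ((l1[0], r1[1]), left, right)
        # convention: isoforms using the genomic-left exon form the inclusion set
        left_user = t1 if (ex1.start, ex1.end) == left else t2
        other = t2 if left_user is t1 else t1
        yield "MXE", anchor, left_user.transcript_id, other.transcript_id


def _overlaps_any(t: TranscriptModel, exon) -> bool:
    return any(e.start < exon.end and exon.start < e.end for e in t.exons)


def detect_events(locus: GeneLocus) -> list[ASEvent]:
    """Detect and deduplicate AS events across all transcript pairs of a locus.

    Events are keyed by (type, anchor coordinates); inclusion/exclusion
    transcript sets accumulate over pairs.  Output order is deterministic:
    (anchor start, type).
    """
    acc: dict[tuple, ASEvent] = {}
    for t1, t2 in itertools.combinations(locus.transcripts, 2):
        for etype, anchor, inc, exc in _pair_events(t1, t2):
            key = (etype, anchor)
            if key not in acc:
                acc[key] = ASEvent(
                    etype, locus.locus_id, locus.chrom, locus.strand,
                    anchor, set(), set(),
                )
            acc[key].inclusion.add(inc)
            acc[key].exclusion.add(exc)
    events = [e for e in acc.values() if e.inclusion and e.exclusion]
    events.sort(key=lambda e: (anchor_coords(e.anchor), e.event_type))
    return events


def detect_events_all(loci: Iterable[GeneLocus]) -> list[ASEvent]:
    out: list[ASEvent] = []
    for locus in loci:
        if locus.n_isoforms >= 2:
            out.extend(detect_events(locus))
    return out


def events_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        coords = list(anchor_coords(e.anchor))
        rows.append(
            {
                "event_id": e.event_id,
                "locus_id": e.locus_id,
                "event_type": e.event_type,
                "chrom": e.chrom,
                "strand": e.strand,
                "anchor_start": min(coords),
                "anchor_end": max(coords),
                "anchor": ";".join(map(str, coords)),
                "inclusion_tx": ",".join(sorted(e.inclusion)),
                "exclusion_tx": ",".join(sorted(e.exclusion)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id", "locus_id", "event_type", "chrom", "strand",
            "anchor_start", "anchor_end", "anchor", "inclusion_tx",
            "exclusion_tx",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["chrom", "anchor_start", "event_type"]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# splice-site usage
# ---------------------------------------------------------------------------

def splice_site_offsets(locus: GeneLocus) -> pd.DataFrame:
    """Alternative donor/acceptor usage relative to the dominant site.

    Introns are grouped by their partner boundary; within each group the
    dominant site is the one used by most isoforms (ties broken toward the
    5'-most site in transcript orientation) and every alternative site is
    reported as a signed offset in transcript orientation (negative =
    upstream of the dominant site).
    """
    strand = locus.strand
    # usage[site_kind][partner_pos][site_pos] = #isoforms
    usage: dict[str, dict[int, dict[int, int]]] = {
        "donor": defaultdict(lambda: defaultdict(int)),
        "acceptor": defaultdict(lambda: defaultdict(int)),
    }
    for t in locus.transcripts:
        for s, e in t.introns():
            if strand == "+":
                donor, acceptor = s, e
            else:
                donor, acceptor = e, s
            usage["donor"][acceptor][donor] += 1
            usage["acceptor"][donor][acceptor] += 1

    rows = []
    for kind, groups in usage.items():
        for partner, sites in sorted(groups.items()):
            if len(sites) < 2:
                continue
            # dominant: max usage, tie -> 5'-most in transcript orientation
            def tie_key(item):
                pos, n = item
                five_most = pos if strand == "+" else -pos
                return (-n, five_most)

            dominant = min(sites.items(), key=tie_key)[0]
            for pos, n in sorted(sites.items()):
                if pos == dominant:
                    continue
                offset = pos - dominant if strand == "+" else dominant - pos
                rows.append(
                    {
                        "locus_id": locus.locus_id,
                        "site_kind": kind,
                        "partner_pos": partner,
                        "dominant_pos": dominant,
                        "alt_pos": pos,
                        "offset": offset,
                        "n_dominant": sites[dominant],
                        "n_alt": n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "site_kind", "partner_pos", "dominant_pos",
            "alt_pos", "offset", "n_dominant", "n_alt",
        ],
    )


def boundary_dinucleotides(locus: GeneLocus,
                           genome: Mapping[str, str]) -> pd.DataFrame:
    """Donor/acceptor dinucleotides of every distinct intron, strand-oriented.

    Canonical means GT at the donor and AG at the acceptor on the transcript
    strand (the GU..AG rule at DNA level).
    """
    chrom_seq = genome[locus.chrom]
    seen = set()
    rows = []
    for t in locus.transcripts:
        for s, e in t.introns():
            if (s, e) in seen:
                continue
            seen.add((s, e))
            if locus.strand == "+":
                donor = chrom_seq[s : s + 2]
                acceptor = chrom_seq[e - 2 : e]
            else:
                donor = reverse_complement(chrom_seq[e - 2 : e])
                acceptor = reverse_complement(chrom_seq[s : s + 2])
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "intron_start": s,
                    "intron_end": e,
                    "donor_dinuc": donor,
                    "acceptor_dinuc": acceptor,
                    "canonical": donor == "GT" and acceptor == "AG",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "intron_start", "intron_end", "donor_dinuc",
            "acceptor_dinuc", "canonical",
        ],
    )


# ---------------------------------------------------------------------------
# AS frequency vs gene structure
# ---------------------------------------------------------------------------

def as_structure_correlation(gene_stats: pd.DataFrame,
                             n_bins: int = 5) -> pd.DataFrame:
    """Spearman correlation of per-gene isoform count with structural factors.

    Factors: exon number, mRNA length, mean exon length, GC content.  Genes
    with a constant factor or constant isoform count yield an undefined
    correlation, reported as NaN.  A binned mean table is attached per factor
    for plotting.
    """
    if len(gene_stats) < 3:
        raise ValueError("need >= 3 genes for correlation analysis")
    factors = {
        "exon_number": "max_exons",
        "mrna_length": "mean_mrna_length",
        "mean_exon_length": "mean_exon_length",
        "gc_content": "mean_gc",
    }
    y = gene_stats["n_isoforms"].to_numpy(dtype=float)
    rows = []
    for name, col in factors.items():
        x = gene_stats[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"factor": name, "spearman_rho": rho, "p_value": p})
    return pd.DataFrame(rows, columns=["factor", "spearman_rho", "p_value"])


def structure_bins(gene_stats: pd.DataFrame, factor_col: str,
                   n_bins: int = 5) -> pd.DataFrame:
    """Mean isoform count within quantile bins of a structural factor."""
    df = gene_stats[[factor_col, "n_isoforms"]].dropna()
    df = df.assign(bin=pd.qcut(df[factor_col], q=n_bins, duplicates="drop"))
    out = (
        df.groupby("bin", observed=True)
        .agg(mean_isoforms=("n_isoforms", "mean"), n_genes=("n_isoforms", "size"))
        .reset_index()
    )
    out["bin"] = out["bin"].astype(str)
    return out


# ---------------------------------------------------------------------------
# differential splicing (PSI + Fisher exact + BH)
# ---------------------------------------------------------------------------

def differential_splicing(
    counts: Mapping[str, Mapping[str, tuple[int, int]]],
    sample_pairs: Sequence[tuple[str, str]],
    q_max: float = 0.05,
    min_delta_psi: float = 0.1,
) -> pd.DataFrame:
    """Per-event differential splicing between sample pairs.

    ``counts`` maps event_id -> sample -> (inclusion_reads, exclusion_reads).
    For each pair a two-sided Fisher exact test is run on the 2x2 table of
    inclusion/exclusion counts; p-values are BH-adjusted across events within
    the pair.  An event is called differentially spliced when q < ``q_max``
    and \\|delta PSI\\| >= ``min_delta_psi``.  Events with zero coverage in
    either sample of a pair are skipped for that pair.
    """
    rows = []
    for s1, s2 in sample_pairs:
        pair_rows = []
        for event_id, per_sample in counts.items():
            if s1 not in per_sample or s2 not in per_sample:
                continue
            inc1, exc1 = per_sample[s1]
            inc2, exc2 = per_sample[s2]
            if min(inc1, exc1, inc2, exc2) < 0:
                raise ValueError(f"negative read count for event {event_id}")
            if inc1 + exc1 == 0 or inc2 + exc2 == 0:
                continue
            psi1 = inc1 / (inc1 + exc1)
            psi2 = inc2 / (inc2 + exc2)
            _, p = stats.fisher_exact([[inc1, exc1], [inc2, exc2]],
                                      alternative="two-sided")
            pair_rows.append(
                {
                    "event_id": event_id,
                    "sample_1": s1,
                    "sample_2": s2,
                    "psi_1": psi1,
                    "psi_2": psi2,
                    "delta_psi": psi1 - psi2,
                    "p_value": p,
                }
            )
        if not pair_rows:
            continue
        pdf = pd.DataFrame(pair_rows)
        pdf["q_value"] = bh_adjust(pdf["p_value"])
        pdf["das"] = (pdf["q_value"] < q_max) & (
            pdf["delta_psi"].abs() >= min_delta_psi
        )
        pdf["direction"] = np.where(
            pdf["delta_psi"] > 0, "higher_in_1",
            np.where(pdf["delta_psi"] < 0, "higher_in_2", "equal"),
        )
        rows.append(pdf)
    if not rows:
        return pd.DataFrame(
            columns=[
                "event_id", "sample_1", "sample_2", "psi_1", "psi_2",
                "delta_psi", "p_value", "q_value", "das", "direction",
            ]
        )
    return pd.concat(rows, ignore_index=True)
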