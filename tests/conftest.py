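import json
from pathlib import Path

import pytest

from isoplex.annotation_io import GenomicInterval, TranscriptModel
from isoplex.simulate import SimConfig, generate


def make_tx(tx_id, exons, strand="+", chrom="chr1", gene=""):
    """Shorthand transcript constructor used across the suite."""
    return TranscriptModel(
        tx_id, gene, chrom, strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 40-gene synthetic corpus (files on disk + in-memory result + truth)."""
    out = tmp_path_factory.mktemp("corpus40")
    res = generate(
        SimConfig(seed=11, n_genes=40, n_lincrnas=5, n_lncnats=3), out
    )
    truth = json.loads((out / "truth.json").read_text())
    return {"dir": out, "result": res, "truth": truth}


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """The default 200-gene study-condition corpus with planted truth."""
    out = tmp_path_factory.mktemp("corpus200")
    res = generate(SimConfig(seed=1), out)
    truth = json.loads((out / "truth.json").read_text())
    return {"dir": out, "result": res, "truth": truth}


def random_locus(rng, locus_id="L", max_tx=5, max_exons=8):
    """A random multi-transcript locus with shared and perturbed structures.

    Transcripts derive from one base exon chain by dropping internal exons,
    merging across introns, and nudging splice boundaries, so alternative
    structures share boundaries often enough to exercise every event type.
    """
    from isoplex.locus import GeneLocus

    strand = str(rng.choice(["+", "-"]))
    n_exons = int(rng.integers(2, max_exons + 1))
    pos = int(rng.integers(0, 1000))
    base = []
    for _ in range(n_exons):
        end = pos + int(rng.integers(30, 200))
        base.append([pos, end])
        pos = end + int(rng.integers(30, 200))
    n_tx = int(rng.integers(2, max_tx + 1))
    txs = []
    for i in range(n_tx):
        exons = [list(e) for e in base]
        for _ in range(int(rng.integers(0, 3))):
            op = rng.integers(0, 3)
            if op == 0 and len(exons) > 2:  # drop an internal exon
                del exons[int(rng.integers(1, len(exons) - 1))]
            elif op == 1 and len(exons) > 1:  # retain an intron
                j = int(rng.integers(0, len(exons) - 1))
                exons[j][1] = exons[j + 1][1]
                del exons[j + 1]
            elif op == 2 and len(exons) > 1:  # shift a boundary
                j = int(rng.integers(0, len(exons) - 1))
                gap = exons[j + 1][0] - exons[j][1]
                if gap > 8:
                    d = int(rng.integers(1, min(gap - 2, 25)))
                    if rng.random() < 0.5:
                        exons[j][1] += d
                    else:
                        exons[j + 1][0] -= d
        txs.append(make_tx(f"{locus_id}.t{i}", [tuple(e) for e in exons], strand))
    return GeneLocus(locus_id, "chr1", strand, txs)


def run_config_for(corpus_dir: Path, out_dir: Path, **overrides):
    from isoplex.pipeline import RunConfig

    base = dict(
        genome_fa=str(corpus_dir / "genome.fa"),
        reference_gtf=str(corpus_dir / "reference.gtf"),
        observed_gtf=str(corpus_dir / "observed.gtf"),
        flnc_fastq=str(corpus_dir / "flnc.fastq"),
        alignments_bed12=str(corpus_dir / "flnc_alignments.bed12"),
        fpkm_tsv=str(corpus_dir / "fpkm.tsv"),
        counts_tsv=str(corpus_dir / "counts.tsv"),
        domains_tsv=str(corpus_dir / "domains.tsv"),
        go_map_tsv=str(corpus_dir / "go_map.tsv"),
        out_dir=str(out_dir),
    )
    base.update(overrides)
    return RunConfig(**base)
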