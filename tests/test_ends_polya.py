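import itertools

import numpy as np
import pandas as pd
import pytest

from isoplex.ends_polya import (
    AlignmentRecord,
    call_polya,
    cluster_ends,
    composition_profile,
    coupling_venn,
    end_flags,
    polya_sites_per_gene,
    read_bed12_alignments,
    upstream_kmer_enrichment,
)
from isoplex.locus import GeneLocus

from conftest import make_tx


def locus_of(*txs, locus_id="L"):
    for t in txs:
        t.gene_id = locus_id
    return GeneLocus(locus_id, txs[0].chrom, txs[0].strand, list(txs))


class TestClusterEnds:
    def test_two_clusters_set_atss_flag(self):
        l = locus_of(
            make_tx("a", [(100, 500)]),
            make_tx("b", [(103, 500)]),
            make_tx("c", [(250, 500)]),
        )
        clusters = cluster_ends(l, "TSS", tolerance_nt=50)
        assert len(clusters) == 2
        assert end_flags([l]).iloc[0].atss

    def test_close_ends_form_one_cluster(self):
        l = locus_of(make_tx("a", [(100, 500)]), make_tx("b", [(110, 500)]))
        assert len(cluster_ends(l, "TSS", 50)) == 1
        assert not end_flags([l]).iloc[0].atss

    def test_minus_strand_tss_is_genomic_right_end(self):
        l = locus_of(
            make_tx("a", [(100, 500)], "-"),
            make_tx("b", [(100, 800)], "-"),
        )
        tss = cluster_ends(l, "TSS", 50)
        tts = cluster_ends(l, "TTS", 50)
        assert len(tss) == 2 and {c.representative for c in tss} == {500, 800}
        assert len(tts) == 1 and tts[0].representative == 100

    def test_cluster_count_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(5)
        ends = sorted(int(x) for x in rng.integers(0, 2000, size=12))
        txs = [make_tx(f"t{i}", [(p, p + 3000)]) for i, p in enumerate(ends)]
        l = locus_of(*txs)
        counts = [len(cluster_ends(l, "TSS", tol)) for tol in (0, 10, 50, 200, 5000)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1


class TestCallPolya:
    def aln(self, blocks, strand="+"):
        return AlignmentRecord("r", "chr1", strand, blocks)

    def test_pure_a_tail_detected(self):
        aln = self.aln([(0, 50)])
        call = call_polya("G" * 50 + "A" * 30, aln)
        assert call.tail_detected and call.cleavage_pos == 50

    def test_two_non_a_in_thirty_rejected(self):
        # 28 A + 2 non-A violates "less than two non-A bases"
        tail = "A" * 14 + "G" + "A" * 14 + "C"
        assert len(tail) == 30
        call = call_polya("G" * 10 + tail, self.aln([(0, 10)]))
        assert not call.tail_detected

    def test_one_non_a_in_thirty_accepted(self):
        tail = "A" * 15 + "G" + "A" * 14
        call = call_polya("G" * 10 + tail, self.aln([(0, 10)]))
        assert call.tail_detected

    def test_seven_a_tail_rejected_eight_accepted(self):
        assert not call_polya("G" * 10 + "A" * 7, self.aln([(0, 10)])).tail_detected
        assert call_polya("G" * 10 + "A" * 8, self.aln([(0, 10)])).tail_detected

    def test_minus_strand_cleavage_at_block_start(self):
        call = call_polya("G" * 40 + "A" * 30,
                          self.aln([(500, 520), (600, 620)], "-"))
        assert call.cleavage_pos == 500

    def test_unaligned_read_has_no_cleavage_site(self):
        call = call_polya("A" * 40, None, read_id="r9")
        assert call.tail_detected and call.cleavage_pos is None
        assert call.read_id == "r9"

    def test_sliding_window_finds_interior_tail(self):
        # clip = 10 junk + 30 A: anchored window fails, sliding succeeds
        seq = "G" * 20 + "CGTCGTCGTC" + "A" * 30
        aln = self.aln([(0, 20)])
        assert call_polya(seq, aln, mode="sliding").tail_detected
        assert not call_polya(seq, aln, mode="anchored").tail_detected

    def test_matches_exhaustive_rule_on_short_tails(self):
        # all 4^6 6-nt clips evaluated as-is against a literal re-statement
        for tail in map("".join, itertools.product("ACGT", repeat=6)):
            call = call_polya("G" * 5 + tail, self.aln([(0, 5)]))
            a = tail.count("A")
            expected = a >= 8 and (len(tail) - a) <= 1  # never: too short
            assert call.tail_detected == expected
        assert not call_polya("G" * 5 + "AAAAAA", self.aln([(0, 5)])).tail_detected


class TestBed12:
    def test_round_trip_blocks(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t400\tr1\t0\t-\t100\t400\t0\t2\t50,100,\t0,200,\n")
        (rec,) = read_bed12_alignments(p)
        assert rec.blocks == [(100, 150), (300, 400)]
        assert rec.aligned_read_length == 150
        assert rec.cleavage_pos == 100  # minus strand


class TestSam:
    def test_tail_call_from_sam_both_strands(self, tmp_path):
        from isoplex.annotation_io import reverse_complement
        from isoplex.ends_polya import read_sam_alignments

        # plus-strand read: 20 aligned + 30 A soft-clipped at the right;
        # minus-strand read: SAM stores the reverse complement, so the tail
        # shows up as 30 T soft-clipped at the left
        fwd = "G" * 20 + "A" * 30
        rev = reverse_complement("C" * 20 + "A" * 30)
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            f"r_plus\t0\tchr1\t101\t60\t20M30S\t*\t0\t0\t{fwd}\t*\n"
            f"r_minus\t16\tchr1\t201\t60\t30S20M\t*\t0\t0\t{rev}\t*\n"
        )
        recs = read_sam_alignments(sam)
        seq_p, aln_p = recs["r_plus"]
        call_p = call_polya(seq_p, aln_p)
        assert call_p.tail_detected and call_p.cleavage_pos == 120
        seq_m, aln_m = recs["r_minus"]
        call_m = call_polya(seq_m, aln_m)
        assert call_m.tail_detected and call_m.cleavage_pos == 200


class TestPolyaSites:
    def make_calls(self, positions, gene_locus):
        calls = []
        for i, p in enumerate(positions):
            aln = AlignmentRecord(f"r{i}", "chr1", "+", [(p - 50, p)])
            calls.append(call_polya("G" * 50 + "A" * 30, aln))
        return calls

    def test_nearby_cleavages_collapse_to_one_site(self):
        l = locus_of(make_tx("t", [(900, 1100)]))
        sites, hist = polya_sites_per_gene(
            self.make_calls([1000, 1010], l), [l], collapse_tol_nt=24
        )
        assert len(sites) == 1 and hist[1] == 1

    def test_distant_cleavages_stay_separate(self):
        l = locus_of(make_tx("t", [(900, 1200)]))
        sites, hist = polya_sites_per_gene(
            self.make_calls([1000, 1100], l), [l], collapse_tol_nt=24
        )
        assert len(sites) == 2 and hist[2] == 1

    def test_untailed_reads_do_not_contribute(self):
        l = locus_of(make_tx("t", [(900, 1100)]))
        aln = AlignmentRecord("r", "chr1", "+", [(950, 1000)])
        call = call_polya("G" * 50 + "CGTCG", aln)
        sites, _ = polya_sites_per_gene([call], [l])
        assert len(sites) == 0


class TestCompositionProfile:
    def test_uniform_t_genome(self):
        prof = composition_profile([("chr1", 100, "+")], {"chr1": "T" * 200})
        assert (prof["T"] == 1.0).all()
        assert prof["offset"].tolist() == list(range(-50, 11))

    def test_minus_strand_uses_reverse_complement(self):
        genome = {"chr1": "G" * 200}
        prof = composition_profile([("chr1", 100, "-")], genome)
        assert (prof["C"] == 1.0).all()

    def test_rows_are_simplex_normalised(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGTN"), size=400))}
        sites = [("chr1", int(p), str(s)) for p, s in
                 zip(rng.integers(60, 340, 20), rng.choice(["+", "-"], 20))]
        prof = composition_profile(sites, genome)
        sums = prof[list("ACGT")].sum(axis=1)
        assert np.allclose(sums.dropna(), 1.0)

    def test_planted_a_rich_region_recovered(self):
        rng = np.random.default_rng(1)
        arr = rng.choice(list("CGT"), size=2000)
        sites = []
        for p in range(200, 1900, 100):
            arr[p - 20 : p - 10] = "A"  # offsets -20..-11
            sites.append(("chr1", p, "+"))
        prof = composition_profile(sites, {"chr1": "".join(arr)}).set_index("offset")
        assert (prof.loc[-20:-11, "A"] == 1.0).all()
        assert prof.loc[-40:-30, "A"].max() == 0.0


class TestKmerEnrichment:
    def test_planted_motif_top_ranked(self):
        rng = np.random.default_rng(2)
        arr = rng.choice(list("ACGT"), size=6000)
        sites = []
        for p in range(100, 5900, 100):
            arr[p - 30 : p - 24] = list("AATAAA")
            sites.append(("chr1", p, "+"))
        table = upstream_kmer_enrichment(sites, {"chr1": "".join(arr)},
                                         ks=(6,), seed=0)
        assert table.iloc[0].kmer == "AATAAA"
        assert table.iloc[0].fold_enrichment > 5

    def test_self_background_folds_are_one(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}
        sites = [("chr1", int(p), "+") for p in range(100, 2900, 100)]
        windows = None
        from isoplex.ends_polya import _upstream_window

        windows = [_upstream_window(genome, c, p, s, 50) for c, p, s in sites]
        table = upstream_kmer_enrichment(sites, genome, ks=(5,),
                                         background_windows=windows)
        assert np.allclose(table.fold_enrichment, 1.0)


class TestCouplingVenn:
    def test_flags_and_partition(self):
        l1 = locus_of(
            make_tx("a", [(0, 100), (200, 300)]),
            make_tx("b", [(0, 300)]),
            locus_id="L1",
        )  # AS, shared ends
        l2 = locus_of(
            make_tx("c", [(1000, 1500)]),
            make_tx("d", [(1300, 1800)]),
            locus_id="L2",
        )  # aTSS+aTTS, no AS
        flags = end_flags([l1, l2])
        per_gene, cells = coupling_venn([l1, l2], {"L1"}, flags, {"L2"})
        g = per_gene.set_index("gene_id")
        assert g.loc["L1"].tolist() == [True, False, False, False]
        assert g.loc["L2"].tolist() == [False, True, True, True]
        assert cells["n_genes"].sum() == 2
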