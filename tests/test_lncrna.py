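import numpy as np
import pandas as pd
import pytest

from isoplex.lncrna import (
    coding_potential,
    fickett_score,
    identify_lncrnas,
    lnc_target_pairs,
    longest_orf,
)
from isoplex.locus import GeneLocus, build_loci
from isoplex.simulate import coding_noncoding_set

from conftest import make_tx


class TestLongestOrf:
    def test_simple_orf_with_stop(self):
        orf = longest_orf("ATGAAATAA")
        assert (orf.start, orf.end) == (0, 9)
        assert orf.peptide == "MK" and orf.aa_length == 2

    def test_no_atg_gives_empty_call(self):
        orf = longest_orf("CCCCCCCTTTGGG")
        assert orf.aa_length == 0 and orf.peptide == ""

    def test_orf_runs_to_end_without_stop(self):
        orf = longest_orf("ATGAAAAAA")
        assert orf.peptide == "MKK"

    def test_tie_resolved_to_five_prime_most(self):
        # equal-length ORFs in different frames at offsets 1 and 12
        seq = "C" + "ATGAAATAA" + "CC" + "ATGCCCTAA"
        orf = longest_orf(seq)
        assert orf.start == 1

    def test_longest_across_frames(self):
        seq = "ATGTAA" + "C" + "ATGAAAAAAAAATAG"
        orf = longest_orf(seq)
        assert orf.peptide == "MKKK"


class TestCodingPotential:
    def test_longer_orf_scores_higher(self):
        # same transcript body; an early stop truncates the ORF to 10 aa
        core = "GCTGAAAAGCTT" * 25  # 100 codons, no internal ATG
        full = "ATG" + core + "TAA"
        truncated = "ATG" + core[:30] + "TAA" + core[33:] + "TAA"
        assert longest_orf(truncated).aa_length < longest_orf(full).aa_length
        assert coding_potential(full) > coding_potential(truncated)

    def test_case_insensitive(self):
        seq = "ATG" + "GCTGAAAAGCTT" * 20 + "TAA"
        assert coding_potential(seq) == pytest.approx(coding_potential(seq.lower()))

    def test_score_bounded(self):
        for seq in ("ATGAAATAA" * 30, "ACGT" * 100):
            assert 0.0 <= coding_potential(seq) <= 1.0

    def test_separates_codon_structured_from_shuffled(self):
        seqs, labels = coding_noncoding_set(300, seed=5)
        scores = np.array([coding_potential(s) for s in seqs])
        labels = np.array(labels)
        # AUC by rank statistic
        order = np.argsort(scores)
        ranks = np.empty(len(scores))
        ranks[order] = np.arange(1, len(scores) + 1)
        n1, n0 = labels.sum(), (1 - labels).sum()
        auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc > 0.9

    def test_fickett_higher_for_coding(self):
        seqs, labels = coding_noncoding_set(60, seed=6)
        coding = np.mean([fickett_score(s) for s, l in zip(seqs, labels) if l])
        noncod = np.mean([fickett_score(s) for s, l in zip(seqs, labels) if not l])
        assert coding > noncod


def _noncoding_seq(length, seed=0):
    """Random sequence with all ORFs broken below the filter threshold."""
    rng = np.random.default_rng(seed)
    arr = rng.choice(list("ACGT"), size=length)
    while True:
        seq = "".join(arr)
        orf = longest_orf(seq)
        if orf.aa_length <= 60:
            return seq
        mid = orf.start + 3 * (orf.aa_length // 2)
        arr[mid : mid + 3] = list("TAA")


class TestIdentifyLncrnas:
    coding_ref = [
        make_tx("cg.1", [(10_000, 10_400), (10_900, 11_500)], "+", gene="CG"),
    ]

    def _genome(self, inserts):
        rng = np.random.default_rng(9)
        arr = rng.choice(list("ACGT"), size=20_000)
        for pos, seq in inserts:
            arr[pos : pos + len(seq)] = list(seq)
        return {"chr1": "".join(arr)}

    def test_short_transcript_rejected(self):
        seq = _noncoding_seq(150)
        genome = self._genome([(1000, seq)])
        t = make_tx("x", [(1000, 1150)])
        assert identify_lncrnas([t], genome, self.coding_ref) == []

    def test_long_orf_rejected_at_101_aa_boundary(self):
        # 101-aa ORF (ATG + 100 codons + stop) fails; 100 aa passes
        body = "GCA" * 100
        orf101 = "ATG" + body + "TAA"
        filler = _noncoding_seq(194, seed=3)
        genome = self._genome([(1000, orf101 + filler)])
        t = make_tx("x", [(1000, 1500)])
        recs = identify_lncrnas([t], genome, self.coding_ref, score_cutoff=1.1)
        assert recs == []

    def test_clean_intergenic_candidate_is_lincRNA(self):
        seq = _noncoding_seq(500, seed=4)
        genome = self._genome([(1000, seq)])
        t = make_tx("x", [(1000, 1500)])
        recs = identify_lncrnas([t], genome, self.coding_ref)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.positional_class == "lincRNA" and rec.target_gene is None
        # every emitted record satisfies all three filter predicates
        assert rec.length_nt >= 200 and rec.orf_aa <= 100 and rec.coding_score < 0.5

    def test_antisense_overlap_is_lncNAT(self):
        seq = _noncoding_seq(500, seed=5)
        genome = self._genome([(10_200, seq)])
        t = make_tx("x", [(10_200, 10_700)], "-")
        (rec,) = identify_lncrnas([t], genome, self.coding_ref)
        assert rec.positional_class == "lncNAT" and rec.target_gene == "CG"

    def test_intronic_class(self):
        seq = _noncoding_seq(300, seed=6)
        genome = self._genome([(10_450, seq)])
        t = make_tx("x", [(10_450, 10_750)], "+")
        (rec,) = identify_lncrnas([t], genome, self.coding_ref)
        assert rec.positional_class == "intronic" and rec.target_gene == "CG"

    def test_sense_exonic_overlap_class(self):
        seq = _noncoding_seq(400, seed=7)
        genome = self._genome([(10_300, seq)])
        t = make_tx("x", [(10_300, 10_700)], "+")
        (rec,) = identify_lncrnas([t], genome, self.coding_ref)
        assert rec.positional_class == "sense_overlapping"

    def test_lnc_exons_fewer_than_coding_on_synthetic_set(self, small_corpus):
        res = small_corpus["result"]
        truth = small_corpus["truth"]
        lnc_ids = {r["transcript_id"] for r in truth["lncrnas"]}
        lnc_ex = np.mean([len(t.exons) for t in res.observed
                          if t.transcript_id in lnc_ids])
        cod_ex = np.mean([len(t.exons) for t in res.observed
                          if t.transcript_id not in lnc_ids])
        assert lnc_ex < cod_ex


class TestTargetPairs:
    def _setup(self, r):
        lnc = make_tx("lnc.1", [(1000, 1600)], "+", gene="lnc")
        coding = make_tx("cg.1", [(5000, 5400), (5800, 6400)], "+", gene="CG")
        loci = build_loci([coding])
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 50, 6)
        if r == 1:
            y = x.copy()
        elif r == 0.5:
            # deliberately decorrelated partner
            y = rng.uniform(1, 50, 6)
        expr = pd.DataFrame([x, y], index=["lnc.1", loci[0].locus_id],
                            columns=[f"s{i}" for i in range(6)])
        rec_cls = type("R", (), {})
        from isoplex.lncrna import LncRnaRecord

        rec = LncRnaRecord("lnc.1", 600, 1, 10, 0.1, "lincRNA", None)
        return [rec], {"lnc.1": lnc}, loci, expr

    def test_identical_profiles_pair_positive(self):
        recs, models, loci, expr = self._setup(1)
        out = lnc_target_pairs(recs, models, loci, expr)
        assert out.iloc[0].pair_class == "positive"
        assert out.iloc[0].pcc == pytest.approx(1.0)

    def test_sub_threshold_correlation_is_none(self):
        recs, models, loci, expr = self._setup(0.5)
        out = lnc_target_pairs(recs, models, loci, expr)
        assert abs(out.iloc[0].pcc) <= 0.6
        assert out.iloc[0].pair_class == "none"

    def test_distance_cap_excludes_far_genes(self):
        recs, models, loci, expr = self._setup(1)
        out = lnc_target_pairs(recs, models, loci, expr, max_dist_kb=0.001)
        assert len(out) == 0

    def test_zero_variance_profile_skipped(self):
        recs, models, loci, expr = self._setup(1)
        expr.loc["lnc.1"] = 5.0
        assert len(lnc_target_pairs(recs, models, loci, expr)) == 0

    def test_planted_pairs_recovered_with_sign(self, small_corpus):
        truth = small_corpus["truth"]
        res = small_corpus["result"]
        expr = res.fpkm
        gene_sum = {}
        for iso, gene in truth["isoforms"].items():
            if iso in expr.index:
                gene_sum.setdefault(gene, []).append(expr.loc[iso])
        gene_expr = pd.DataFrame({g: sum(v) for g, v in gene_sum.items()}).T
        for pair in truth["lnc_pairs"]:
            x = np.log2(expr.loc[pair["lncrna_id"]].to_numpy() + 1)
            y = np.log2(gene_expr.loc[pair["target_gene"]].to_numpy() + 1)
            r = np.corrcoef(x, y)[0, 1]
            if pair["pair_class"] == "positive":
                assert r > 0.6
            else:
                assert r < -0.6
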