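import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isoplex.locus import GeneLocus
from isoplex.splicing import (
    anchor_coords,
    as_structure_correlation,
    boundary_dinucleotides,
    detect_events,
    differential_splicing,
    intron_chain,
    splice_site_offsets,
)

from conftest import make_tx, random_locus
from oracle_events import oracle_events


def locus_of(*txs):
    return GeneLocus("L", txs[0].chrom, txs[0].strand, list(txs))


def event_keys(events):
    return {(e.event_type, anchor_coords(e.anchor)) for e in events}


class TestIntronChain:
    def test_gaps_between_exons(self):
        assert intron_chain(make_tx("t", [(100, 200), (300, 400)])) == [(200, 300)]

    def test_mono_exon_empty(self):
        assert intron_chain(make_tx("t", [(0, 500)])) == []

    def test_three_exons_two_introns_sorted(self):
        t = make_tx("t", [(0, 10), (20, 30), (50, 60)])
        assert intron_chain(t) == [(10, 20), (30, 50)]


class TestDetectEvents:
    def test_intron_retention(self):
        ev = detect_events(locus_of(
            make_tx("t1", [(0, 100), (200, 300)]),
            make_tx("t2", [(0, 300)]),
        ))
        assert event_keys(ev) == {("IR", (100, 200))}
        (e,) = ev
        assert e.inclusion == {"t2"} and e.exclusion == {"t1"}

    def test_exon_skipping(self):
        ev = detect_events(locus_of(
            make_tx("t1", [(0, 100), (200, 250), (300, 400)]),
            make_tx("t2", [(0, 100), (300, 400)]),
        ))
        assert event_keys(ev) == {("ES", (100, 200, 250, 300))}

    def test_alt_site_type_flips_with_strand(self):
        # introns (100,200) vs (120,200): shared acceptor on +, donor on -
        for strand, expected in (("+", "A5SS"), ("-", "A3SS")):
            ev = detect_events(locus_of(
                make_tx("t1", [(0, 100), (200, 300)], strand),
                make_tx("t2", [(0, 120), (200, 300)], strand),
            ))
            assert event_keys(ev) == {(expected, (100, 120, 200))}

    def test_mutually_exclusive_exons(self):
        ev = detect_events(locus_of(
            make_tx("t1", [(0, 100), (150, 200), (400, 500)]),
            make_tx("t2", [(0, 100), (250, 300), (400, 500)]),
        ))
        assert event_keys(ev) == {("MXE", (100, 150, 200, 250, 300, 400))}

    def test_skipping_pair_does_not_fire_alt_site_rules(self):
        # the spanning intron shares each boundary with a flanking intron;
        # these must not be typed as A5SS/A3SS
        ev = detect_events(locus_of(
            make_tx("t1", [(0, 100), (200, 250), (300, 400)]),
            make_tx("t2", [(0, 100), (300, 400)]),
        ))
        assert {e.event_type for e in ev} == {"ES"}

    def test_symmetric_in_pair_order(self):
        t1 = make_tx("t1", [(0, 100), (200, 250), (300, 400)])
        t2 = make_tx("t2", [(0, 100), (300, 400)])
        assert event_keys(detect_events(locus_of(t1, t2))) == event_keys(
            detect_events(locus_of(t2, t1))
        )

    def test_translation_invariance(self):
        def shifted(delta):
            return locus_of(
                make_tx("t1", [(0 + delta, 100 + delta), (200 + delta, 300 + delta)]),
                make_tx("t2", [(0 + delta, 300 + delta)]),
            )

        base = event_keys(detect_events(shifted(0)))
        moved = event_keys(detect_events(shifted(1000)))
        assert {(t, tuple(c - 1000 for c in coords)) for t, coords in moved} == base

    def test_agrees_with_brute_force_oracle_on_random_loci(self):
        rng = np.random.default_rng(7)
        for i in range(120):
            locus = random_locus(rng, f"L{i}")
            got = event_keys(detect_events(locus))
            expected = oracle_events(locus.transcripts)
            assert got == expected, f"locus {i}: {got ^ expected}"


class TestSpliceSiteOffsets:
    def test_dominant_and_offset_plus_strand(self):
        txs = [make_tx(f"t{i}", [(0, 100), (200, 300)]) for i in range(3)]
        txs.append(make_tx("t3", [(0, 104), (200, 300)]))
        table = splice_site_offsets(locus_of(*txs))
        row = table[table.site_kind == "donor"].iloc[0]
        assert row.dominant_pos == 100 and row.alt_pos == 104 and row.offset == 4

    def test_tie_broken_toward_five_prime(self):
        txs = [
            make_tx("t0", [(0, 100), (200, 300)]),
            make_tx("t1", [(0, 100), (200, 300)]),
            make_tx("t2", [(0, 104), (200, 300)]),
            make_tx("t3", [(0, 104), (200, 300)]),
        ]
        table = splice_site_offsets(locus_of(*txs))
        row = table[table.site_kind == "donor"].iloc[0]
        assert row.dominant_pos == 100  # 5'-most on + strand

    def test_minus_strand_flips_offset_sign(self):
        txs = [make_tx(f"t{i}", [(0, 100), (200, 300)], "-") for i in range(3)]
        txs.append(make_tx("t3", [(0, 104), (200, 300)], "-"))
        table = splice_site_offsets(locus_of(*txs))
        row = table[table.site_kind == "acceptor"].iloc[0]
        # genomic +4 is upstream in transcript orientation on the minus strand
        assert row.dominant_pos == 100 and row.offset == -4


class TestBoundaryDinucleotides:
    def test_canonical_plus_strand(self):
        genome = {"chr1": "A" * 100 + "GT" + "A" * 96 + "AG" + "A" * 100}
        table = boundary_dinucleotides(
            locus_of(make_tx("t", [(0, 100), (200, 300)])), genome
        )
        assert table.iloc[0].donor_dinuc == "GT"
        assert table.iloc[0].acceptor_dinuc == "AG"
        assert bool(table.iloc[0].canonical)

    def test_canonical_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "A" * 100 + "CT" + "A" * 96 + "AC" + "A" * 100}
        table = boundary_dinucleotides(
            locus_of(make_tx("t", [(0, 100), (200, 300)], "-")), genome
        )
        assert table.iloc[0].donor_dinuc == "GT"
        assert table.iloc[0].acceptor_dinuc == "AG"
        assert bool(table.iloc[0].canonical)

    def test_gc_donor_counted_noncanonical(self):
        genome = {"chr1": "A" * 100 + "GC" + "A" * 96 + "AG" + "A" * 100}
        table = boundary_dinucleotides(
            locus_of(make_tx("t", [(0, 100), (200, 300)])), genome
        )
        assert not bool(table.iloc[0].canonical)


class TestStructureCorrelation:
    def test_perfect_monotone_relation(self):
        stats = pd.DataFrame(
            {
                "n_isoforms": [1, 2, 3, 4],
                "max_exons": [2, 4, 6, 8],
                "mean_mrna_length": [1.0, 2.0, 3.0, 4.0],
                "mean_exon_length": [4.0, 3.0, 2.0, 1.0],
                "mean_gc": [0.5, 0.5, 0.5, 0.5],
            }
        )
        out = as_structure_correlation(stats).set_index("factor")
        assert out.loc["exon_number", "spearman_rho"] == pytest.approx(1.0)
        assert out.loc["mean_exon_length", "spearman_rho"] == pytest.approx(-1.0)

    def test_degenerate_factor_reported_as_nan(self):
        stats = pd.DataFrame(
            {
                "n_isoforms": [1, 2, 3],
                "max_exons": [5, 5, 5],
                "mean_mrna_length": [1.0, 2.0, 3.0],
                "mean_exon_length": [1.0, 2.0, 3.0],
                "mean_gc": [0.4, 0.5, 0.6],
            }
        )
        out = as_structure_correlation(stats).set_index("factor")
        assert math.isnan(out.loc["exon_number", "spearman_rho"])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            as_structure_correlation(pd.DataFrame({"n_isoforms": [1]}))


class TestDifferentialSplicing:
    def test_fisher_two_by_two_matches_hypergeometric_sum(self):
        # table [[2,0],[0,2]]: enumerate all tables with the same margins
        counts = {"e": {"s1": (2, 0), "s2": (0, 2)}}
        out = differential_splicing(counts, [("s1", "s2")])
        from math import comb

        probs = [comb(2, x) * comb(2, 2 - x) / comb(4, 2) for x in range(3)]
        obs = probs[2]
        expected = sum(p for p in probs if p <= obs + 1e-12)
        assert out.iloc[0].p_value == pytest.approx(expected)
        assert expected == pytest.approx(1 / 3)

    def test_identical_counts_not_das(self):
        counts = {"e": {"s1": (5, 5), "s2": (5, 5)}}
        out = differential_splicing(counts, [("s1", "s2")])
        assert out.iloc[0].delta_psi == 0 and not out.iloc[0].das

    def test_zero_coverage_sample_skipped(self):
        counts = {"e": {"s1": (0, 0), "s2": (5, 5)}}
        assert len(differential_splicing(counts, [("s1", "s2")])) == 0

    def test_psi_and_direction(self):
        counts = {"e": {"s1": (30, 10), "s2": (5, 35)}}
        out = differential_splicing(counts, [("s1", "s2")]).iloc[0]
        assert out.psi_1 == pytest.approx(0.75)
        assert out.psi_2 == pytest.approx(0.125)
        assert out.direction == "higher_in_1" and out.das

    def test_bh_q_values_dominate_p_and_are_monotone(self):
        rng = np.random.default_rng(3)
        counts = {
            f"e{i}": {
                "s1": (int(rng.integers(0, 40)), int(rng.integers(1, 40))),
                "s2": (int(rng.integers(0, 40)), int(rng.integers(1, 40))),
            }
            for i in range(50)
        }
        out = differential_splicing(counts, [("s1", "s2")])
        assert (out.q_value >= out.p_value - 1e-12).all()
        s = out.sort_values("p_value")
        assert s.q_value.is_monotonic_increasing
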