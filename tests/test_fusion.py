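"""Fusion prediction: donor/acceptor orientation logic, retained exons,
run-through partner search, reading-frame arithmetic against a
translated-CDS oracle, and multi-junction transcript tracing."""

import pytest
from Bio.Seq import Seq

from svfuse import fixtures, fusion
from svfuse.model import Breakend, JunctionCandidate, LEFT, RIGHT
from svfuse.synthdata import Segment, make_gene


def candidate(chrom_a, mid_a, side_a, chrom_b, mid_b, side_b, cid="J1"):
    return JunctionCandidate(
        id=cid,
        breakend_a=Breakend(chrom_a, mid_a - 50, mid_a + 50, side_a),
        breakend_b=Breakend(chrom_b, mid_b - 50, mid_b + 50, side_b),
        strand_a="+" if side_a == LEFT else "-",
        strand_b="+" if side_b == LEFT else "-", support=2)


@pytest.fixture()
def gene_pair():
    donor = make_gene("DON", "chrA", "+", 10_000, [150] * 4, [3_000] * 3,
                      utr5=30, utr3=30)
    acceptor = make_gene("ACC", "chrB", "+", 40_000, [150] * 5, [3_000] * 4,
                         utr5=30, utr3=30)
    return donor, acceptor


class TestDirectFusion:
    def test_intron_break_joins_expected_exons(self, gene_pair):
        donor, acceptor = gene_pair
        # break donor in intron 2 (13,300-16,300), acceptor in intron 1
        cand = candidate("chrA", 14_700, LEFT, "chrB", 41_700, RIGHT)
        fusions, breaks = fusion.predict_fusion(cand, list(gene_pair))
        assert len(fusions) == 1 and not breaks
        f = fusions[0]
        assert (f.five_prime_gene, f.five_prime_exon) == ("DON", 2)
        assert (f.three_prime_gene, f.three_prime_exon) == ("ACC", 2)
        assert f.kind == "direct" and f.frame == "in_frame"
        assert f.transcript_model == [("DON", 1), ("DON", 2),
                                      ("ACC", 2), ("ACC", 3), ("ACC", 4),
                                      ("ACC", 5)]

    def test_opposed_orientations_yield_breaks_not_fusion(self, gene_pair):
        donor, acceptor = gene_pair
        # both sides retain their 5' ends: no transcript can traverse
        cand = candidate("chrA", 11_800, LEFT, "chrB", 41_700, LEFT)
        fusions, breaks = fusion.predict_fusion(cand, list(gene_pair))
        assert fusions == []
        assert sorted(b.gene_id for b in breaks) == ["ACC", "DON"]
        assert all(b.retained_end == "five_prime" for b in breaks)

    def test_minus_strand_donor(self):
        donor = make_gene("DONM", "chrA", "-", 10_000, [150] * 4, [3_000] * 3,
                          utr5=30, utr3=30)
        acceptor = make_gene("ACC", "chrB", "+", 40_000, [150] * 3, [3_000] * 2,
                             utr5=30, utr3=30)
        # '-' donor transcribes leftwards: retained flank right of the break;
        # 14,700 sits between transcript exons 2 and 3
        cand = candidate("chrA", 14_700, RIGHT, "chrB", 41_700, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, [donor, acceptor])
        assert len(fusions) == 1
        f = fusions[0]
        assert f.five_prime_gene == "DONM" and f.five_prime_exon == 2
        assert f.three_prime_gene == "ACC" and f.three_prime_exon == 2

    def test_self_fusion_across_intra_gene_junction_in_frame(self):
        g = make_gene("SELF", "chrA", "+", 10_000, [150] * 4, [3_000] * 3,
                      utr5=30, utr3=30)
        # junction within intron 1: exon 1 splices back onto exon 2
        cand = candidate("chrA", 11_800, LEFT, "chrA", 11_900, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, [g])
        assert len(fusions) == 1
        f = fusions[0]
        assert f.five_prime_gene == f.three_prime_gene == "SELF"
        assert (f.five_prime_exon, f.three_prime_exon) == (1, 2)
        assert f.frame == "in_frame"


class TestRunthrough:
    def test_downstream_intact_gene_within_window(self, gene_pair):
        donor, acceptor = gene_pair
        # landing point 200 kb upstream of the intact acceptor
        cand = candidate("chrA", 11_800, LEFT, "chrB", 40_000 - 200_000, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, list(gene_pair),
                                           runthrough_window=1_000_000)
        assert len(fusions) == 1
        f = fusions[0]
        assert f.kind == "runthrough"
        assert f.three_prime_exon == 2  # first splice acceptor

    def test_gene_desert_no_fusion(self, gene_pair):
        donor, acceptor = gene_pair
        cand = candidate("chrA", 11_800, LEFT, "chrB", 40_000 - 200_000, RIGHT)
        fusions, breaks = fusion.predict_fusion(cand, list(gene_pair),
                                                runthrough_window=100_000)
        assert fusions == []
        assert [b.gene_id for b in breaks] == ["DON"]

    def test_nearest_partner_chosen_alternatives_listed(self, gene_pair):
        donor, acceptor = gene_pair
        far = make_gene("FAR", "chrB", "+", 300_000, [150] * 3, [3_000] * 2,
                        utr5=30, utr3=30)
        cand = candidate("chrA", 11_800, LEFT, "chrB", 1_000, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, [donor, acceptor, far])
        assert fusions[0].three_prime_gene == "ACC"
        assert fusions[0].alternatives == ["FAR"]


class TestGenesAtBreakpoints:
    def test_overlap_and_adjacent_sets(self, gene_pair):
        donor, acceptor = gene_pair
        cand = candidate("chrA", 11_800, LEFT, "chrB", 1_000, RIGHT)
        ga, gb, adj = fusion.genes_at_breakpoints(cand, list(gene_pair))
        assert [g.gene_id for g in ga] == ["DON"]
        assert gb == []
        assert [g.gene_id for g in adj["b"]] == ["ACC"]

    def test_empty_window_empty_sets(self, gene_pair):
        cand = candidate("chrA", 5_000, RIGHT, "chrB", 1_000, LEFT)
        ga, gb, adj = fusion.genes_at_breakpoints(cand, list(gene_pair),
                                                  runthrough_window=100)
        assert ga == [] and gb == []
        assert adj["a"] == [] and adj["b"] == []


class TestFrame:
    @pytest.mark.parametrize("utr5_d,utr5_a,expected", [
        (30, 30, "in_frame"),    # phases 0 == 0
        (29, 30, "out_of_frame"),  # 1 vs 0
        (28, 29, "out_of_frame"),  # 2 vs 1
        (28, 28, "in_frame"),
    ])
    def test_phase_arithmetic(self, utr5_d, utr5_a, expected):
        donor = make_gene("D", "chrA", "+", 10_000, [150] * 3, [3_000] * 2,
                          utr5=utr5_d, utr3=30)
        acceptor = make_gene("A", "chrB", "+", 40_000, [150] * 3, [3_000] * 2,
                             utr5=utr5_a, utr3=30)
        cand = candidate("chrA", 11_800, LEFT, "chrB", 41_700, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, [donor, acceptor])
        assert fusions[0].frame == expected

    def test_noncoding_partner_indeterminate(self):
        donor = make_gene("D", "chrA", "+", 10_000, [150] * 3, [3_000] * 2,
                          coding=False)
        acceptor = make_gene("A", "chrB", "+", 40_000, [150] * 3, [3_000] * 2,
                             utr5=30, utr3=30)
        cand = candidate("chrA", 11_800, LEFT, "chrB", 41_700, RIGHT)
        fusions, _ = fusion.predict_fusion(cand, [donor, acceptor])
        assert fusions[0].frame == "indeterminate"

    def test_translated_cds_oracle_on_in_frame_fixtures(self):
        """In-frame calls agree with translating the fused CDS: no stop
        codon until the acceptor's own terminator."""
        for fx in fixtures.build_fixture_bank():
            preds = fixtures.run_fixture(fx)
            assert preds, fx.name
            p = preds[0]
            if p.frame != "in_frame":
                continue
            donor = next(g for g in fx.genes if g.gene_id == p.five_prime_gene)
            acc = next(g for g in fx.genes if g.gene_id == p.three_prime_gene)
            d_prefix = sum(donor.coding_lengths()[:p.five_prime_exon])
            a_before = sum(acc.coding_lengths()[:p.three_prime_exon - 1])
            fused = donor.cds_sequence(fx.ref)[:d_prefix] + \
                acc.cds_sequence(fx.ref)[a_before:]
            assert len(fused) % 3 == 0, fx.name
            aa = str(Seq(fused).translate())
            assert "*" not in aa[:-1], fx.name  # no premature stop
            assert aa[-1] == "*", fx.name


class TestMultiJunction:
    def test_insert_traversal_two_junctions(self):
        fx = next(f for f in fixtures.build_fixture_bank()
                  if f.name == "APPBP2_PHF20L1")
        preds = fixtures.run_fixture(fx)
        assert len(preds) == 1
        p = preds[0]
        assert (p.five_prime_exon, p.three_prime_exon) == (9, 3)
        assert len(p.junction_ids) == 2

    def test_single_junction_path_reduces_to_predict_fusion(self, gene_pair):
        donor, acceptor = gene_pair
        ref_len_b = 200_000
        path = [Segment("chrA", 0, 11_800),
                Segment("chrB", 41_700, ref_len_b)]
        traced = fusion.trace_multi_junction_transcript(path, list(gene_pair))
        cand = candidate("chrA", 11_800, LEFT, "chrB", 41_700, RIGHT)
        direct, _ = fusion.predict_fusion(cand, list(gene_pair))
        assert len(traced) == len(direct) == 1
        t, d = traced[0], direct[0]
        assert (t.five_prime_gene, t.five_prime_exon, t.three_prime_gene,
                t.three_prime_exon, t.kind, t.frame) == \
            (d.five_prime_gene, d.five_prime_exon, d.three_prime_gene,
             d.three_prime_exon, d.kind, d.frame)

    def test_orientation_flip_in_insert_aborts(self, gene_pair):
        donor, acceptor = gene_pair
        flipped = make_gene("FLIP", "chrC", "-", 5_000, [150] * 2, [3_000],
                            utr5=30, utr3=30)
        path = [Segment("chrA", 0, 11_800),
                Segment("chrC", 2_000, 15_000),   # insert carries a '-' gene
                Segment("chrB", 41_700, 200_000)]
        preds = fusion.trace_multi_junction_transcript(
            path, [donor, acceptor, flipped])
        assert preds == []

    def test_cyclic_path_rejected(self, gene_pair):
        seg = Segment("chrA", 0, 11_800)
        with pytest.raises(ValueError, match="cyclic"):
            fusion.trace_multi_junction_transcript([seg, seg], list(gene_pair))


class TestFixtureBank:
    def test_all_twelve_topologies_concordant(self):
        ok, failures = fixtures.fixture_concordance()
        assert ok == 12, failures
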