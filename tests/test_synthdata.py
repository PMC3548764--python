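"""Generator contracts: determinism, truth bookkeeping, and the statistical
structure (depth proportional to copy number, concordant geometry on an
unrearranged genome) that the downstream analysis assumes."""

import numpy as np
import pytest

from svfuse import synthdata
from svfuse.model import LEFT, RIGHT, LibrarySpec, revcomp
from svfuse.synthdata import (
    RearrangementEvent, Segment, amplicon_event, deletion_event,
    inversion_event, tandem_dup_event, translocation_event,
)


class TestReference:
    def test_lengths_and_determinism(self):
        a = synthdata.generate_reference(2, [10_000, 8_000], 0.41, seed=7)
        b = synthdata.generate_reference(2, [10_000, 8_000], 0.41, seed=7)
        assert [a.length(n) for n in a.names] == [10_000, 8_000]
        assert a.contigs == b.contigs
        c = synthdata.generate_reference(2, [10_000, 8_000], 0.41, seed=8)
        assert c.contigs != a.contigs

    @pytest.mark.parametrize("args", [
        (1, [0], 0.4), (1, [1_000], 0.0), (1, [1_000], 1.0), (2, [1_000], 0.4),
    ])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            synthdata.generate_reference(*args, seed=1)

    def test_gc_content_tracks_request(self):
        ref = synthdata.generate_reference(1, [200_000], 0.6, seed=3)
        seq = ref.sequence("chr1")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.01


class TestGenes:
    def test_count_nonoverlap_both_strands(self, small_ref):
        genes = synthdata.generate_genes(small_ref, 15, (2, 8), seed=1)
        assert len(genes) == 15
        assert {g.strand for g in genes} == {"+", "-"}
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            assert g.n_exons >= 2
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals[:-1], ivals[1:]):
                assert e1 <= s2

    def test_placement_error_names_contig(self):
        tiny = synthdata.generate_reference(1, [5_000], 0.4, seed=1)
        with pytest.raises(synthdata.PlacementError, match="chr1"):
            synthdata.generate_genes(tiny, 10, (8, 10), seed=1)

    def test_phase_recurrence_matches_bruteforce(self, small_ref):
        """phase_{k+1} = (phase_k + cds_len_k) mod 3, via explicit cumsum."""
        genes = synthdata.generate_genes(small_ref, 10, (2, 10), seed=5)
        for g in genes:
            phases = g.exon_phases()
            clens = g.coding_lengths()
            brute, cum = [], 0
            for clen in clens:
                brute.append(cum % 3)
                cum += clen
            assert phases == brute
            for k in range(len(phases) - 1):
                assert phases[k + 1] == (phases[k] + clens[k]) % 3


class TestPlanting:
    def test_deletion_single_truth(self, small_ref):
        ev = deletion_event("d", small_ref, "chr1", 30_000, 70_000)
        der, truths = synthdata.plant_rearrangements(small_ref, [ev])
        assert len(truths) == 1
        t = truths[0]
        assert (t.breakend_a.chrom, t.breakend_a.pos, t.breakend_a.side) == \
            ("chr1", 30_000, LEFT)
        assert (t.breakend_b.chrom, t.breakend_b.pos, t.breakend_b.side) == \
            ("chr1", 70_000, RIGHT)

    def test_amplicon_adjacency_count(self, small_ref):
        frags = [Segment("chr1", 10_000 + 20_000 * i, 20_000 + 20_000 * i)
                 for i in range(5)] + [Segment("chr2", 10_000, 20_000)]
        ev = amplicon_event("amp", frags, copy_number=20)
        der, truths = synthdata.plant_rearrangements(small_ref, [ev])
        assert len(truths) == 5
        assert all(t.copy_number == 20 for t in truths)

    def test_shard_insert_folded_into_junction(self, small_ref):
        segs = [Segment("chr1", 0, 40_000), Segment("chr2", 5_000, 5_015),
                Segment("chr1", 60_000, 120_000)]
        ev = RearrangementEvent("sh", "shard_insertion", segs)
        der, truths = synthdata.plant_rearrangements(small_ref, [ev])
        assert len(truths) == 1
        assert len(truths[0].inserted_seq) == 15
        assert truths[0].inserted_seq == small_ref.sequence("chr2", 5_000, 5_015)

    @pytest.mark.parametrize("build,expected", [
        (lambda r: deletion_event("e", r, "chr1", 20_000, 50_000), 1),
        (lambda r: tandem_dup_event("e", r, "chr1", 20_000, 50_000), 1),
        (lambda r: inversion_event("e", r, "chr1", 20_000, 50_000), 2),
        (lambda r: translocation_event("e", r, "chr1", 40_000, "chr2", 30_000), 1),
    ])
    def test_truth_conservation(self, small_ref, build, expected):
        """#TruthRecords equals #non-reference segment adjacencies."""
        ev = build(small_ref)
        der, truths = synthdata.plant_rearrangements(small_ref, [ev])
        path = der.paths[0]
        nonref = sum(
            1 for a, b in zip(path.segments[:-1], path.segments[1:])
            if not synthdata._reference_contiguous(a, b))
        assert len(truths) == nonref == expected

    def test_out_of_bounds_segment_rejected(self, small_ref):
        ev = RearrangementEvent("bad", "deletion",
                                [Segment("chr1", 0, 500_000)])
        with pytest.raises(ValueError, match="bounds"):
            synthdata.plant_rearrangements(small_ref, [ev])

    def test_conflicting_edits_rejected(self, small_ref):
        e1 = deletion_event("a", small_ref, "chr1", 30_000, 70_000, mh=4)
        e2 = translocation_event("b", small_ref, "chr2", 10_000, "chr1", 70_000,
                                 mh=4)
        with pytest.raises(synthdata.ConflictError):
            synthdata.plant_rearrangements(small_ref, [e1, e2])

    def test_inversion_derivative_sequence(self, small_ref):
        ev = inversion_event("i", small_ref, "chr1", 20_000, 50_000)
        der, _ = synthdata.plant_rearrangements(small_ref, [ev],
                                                include_reference=False)
        seq = der.paths[0].sequence
        ref = small_ref
        assert seq[:20_000] == ref.sequence("chr1", 0, 20_000)
        assert seq[20_000:50_000] == revcomp(ref.sequence("chr1", 20_000, 50_000))
        assert seq[50_000:] == ref.sequence("chr1", 50_000, 120_000)


class TestReadSimulation:
    def test_unrearranged_genome_all_concordant(self, small_ref, pe_lib):
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        pairs = synthdata.simulate_read_pairs(der, pe_lib, seed=2)
        assert len(pairs) == pe_lib.n_pairs
        assert (pairs["chrom1"] == pairs["chrom2"]).all()
        assert (pairs["strand1"] == "+").all() and (pairs["strand2"] == "-").all()
        span = pairs["pos2"] - pairs["pos1"] + 1
        assert span.between(pe_lib.frag_min, pe_lib.frag_max).all()

    def test_determinism(self, small_ref, pe_lib):
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        a = synthdata.simulate_read_pairs(der, pe_lib, seed=9)
        b = synthdata.simulate_read_pairs(der, pe_lib, seed=9)
        assert a.equals(b)

    def test_no_identical_pairs_without_duplicate_injection(self, small_ref):
        lib = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=300)
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        pairs = synthdata.simulate_read_pairs(der, lib, dup_rate=0.0,
                                              chimera_rate=0.0, seed=4)
        key = pairs[["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]]
        assert not key.duplicated().any()

    def test_sequences_match_reference(self, small_ref, pe_lib):
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        pairs = synthdata.simulate_read_pairs(der, pe_lib, seed=3,
                                              with_sequences=True).head(50)
        for _, row in pairs.iterrows():
            fwd = small_ref.sequence(row["chrom1"], row["pos1"],
                                     row["pos1"] + pe_lib.read_length)
            assert row["seq1"] == fwd  # canonical end1 is the + read here

    def test_depth_proportional_to_copy_number(self):
        """Mean depth ratio over a copy-5 path vs copy-1 within 3 SE of 5."""
        ref = synthdata.generate_reference(2, [50_000, 50_000], 0.41, seed=21)
        ev = RearrangementEvent("amp", "amplicon_fragment",
                                [Segment("chr2", 0, 50_000)], copy_number=4)
        # chr2 carries 1 (reference) + 4 (event) = 5 copies; chr1 carries 1
        der, _ = synthdata.plant_rearrangements(ref, [ev])
        lib = LibrarySpec("pe", 36, 504, 404, 619, n_pairs=2_000)
        ratios = []
        for rep in range(200):
            pairs = synthdata.simulate_read_pairs(der, lib, seed=rep)
            n2 = (pairs["chrom1"] == "chr2").sum()
            n1 = (pairs["chrom1"] == "chr1").sum()
            ratios.append(n2 / n1)
        mean, se = np.mean(ratios), np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 5.0) <= 3 * se + 0.02  # tiny allowance for ratio bias

    def test_chimera_rate_adds_artefact_pairs(self, small_ref, pe_lib):
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        pairs = synthdata.simulate_read_pairs(der, pe_lib, chimera_rate=0.05,
                                              seed=6)
        from svfuse import readpairs
        labels = readpairs.classify_pairs(pairs, {pe_lib.name: pe_lib})
        frac = (labels == readpairs.ABERRANT).mean()
        assert 0.02 < frac < 0.08  # most chimeras land discordantly


class TestCGH:
    def test_noiseless_values(self):
        cm = {"chr1": [(0, 50_000, 2), (50_000, 80_000, 20), (80_000, 120_000, 2)]}
        prof = synthdata.simulate_cgh(cm, 1_000, 0.0, seed=0)
        vals = prof.probes
        flat = vals[(vals["pos"] < 50_000) | (vals["pos"] >= 80_000)]
        amp = vals[(vals["pos"] >= 50_000) & (vals["pos"] < 80_000)]
        assert (flat["log2_ratio"] == 0.0).all()
        assert np.allclose(amp["log2_ratio"], np.log2(10))

    def test_noiseless_steps_at_truth_breakpoints(self):
        from svfuse import cnsteps
        cm = {"chr1": [(0, 50_000, 2), (50_000, 80_000, 8), (80_000, 120_000, 2)]}
        prof = synthdata.simulate_cgh(cm, 500, 0.0, seed=0)
        segs = cnsteps.segment_profile(prof)
        steps = cnsteps.detect_steps(segs)
        assert len(steps) == 2
        for step, bp in zip(steps, (50_000, 80_000)):
            assert abs(step.midpoint - bp) <= 500

    def test_copy_map_from_derivative(self, small_ref):
        ev = deletion_event("d", small_ref, "chr1", 30_000, 70_000)
        der, _ = synthdata.plant_rearrangements(small_ref, [ev])
        cm = der.copy_map()
        assert cm["chr1"] == [(0, 30_000, 2), (30_000, 70_000, 1),
                              (70_000, 120_000, 2)]

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            synthdata.simulate_cgh({"chr1": [(0, 1_000, 2)]}, 0, 0.1)


class TestPanel:
    def test_rate_zero_empty(self, small_ref):
        panel = synthdata.build_panel_of_normals(small_ref, 18, 0.0, seed=1)
        assert len(panel) == 0

    def test_planted_polymorphism_present(self, small_ref):
        ev = deletion_event("p", small_ref, "chr1", 20_000, 60_000)
        _, truths = synthdata.plant_rearrangements(small_ref, [ev])
        panel = synthdata.build_panel_of_normals(small_ref, 18, 0.0, seed=1,
                                                 planted=truths)
        assert len(panel) == 1
        assert panel.iloc[0]["pos_a"] == 20_000
        assert panel.iloc[0]["n_samples"] == 18

    def test_disjoint_seeds_never_hit_tumour_truths(self, small_ref):
        ev = deletion_event("t", small_ref, "chr1", 30_000, 70_000)
        _, truths = synthdata.plant_rearrangements(small_ref, [ev])
        tumour = {(t.breakend_a.chrom, t.breakend_a.pos,
                   t.breakend_b.chrom, t.breakend_b.pos) for t in truths}
        for seed in range(20):
            panel = synthdata.build_panel_of_normals(small_ref, 18, 3.0,
                                                     seed=1_000 + seed)
            sigs = {(r["chrom_a"], r["pos_a"], r["chrom_b"], r["pos_b"])
                    for _, r in panel.iterrows()}
            assert not (sigs & tumour)
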