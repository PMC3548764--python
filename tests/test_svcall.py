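"""Clustering consistency, the filter cascade, confirmation logic, and the
full calling pipeline against planted truth."""

import numpy as np
import pandas as pd
import pytest

from svfuse import cnsteps, readpairs, svcall, synthdata
from svfuse.model import Breakend, CNStep, JunctionCandidate, LEFT, RIGHT, LibrarySpec
from svfuse.synthdata import deletion_event, translocation_event

from tests.conftest import make_pair


def aberrant_df(rows):
    return pd.DataFrame([make_pair(**r) for r in rows])


class TestClustering:
    def test_two_consistent_pairs_one_candidate(self, pe_lib):
        df = aberrant_df([
            dict(pair_id="p1", chrom1="chrA", pos1=49_900, strand1="+",
                 chrom2="chrB", pos2=120_100, strand2="-"),
            dict(pair_id="p2", chrom1="chrA", pos1=49_700, strand1="+",
                 chrom2="chrB", pos2=120_300, strand2="-"),
        ])
        cands = svcall.cluster_pairs(df, {"pe500": pe_lib})
        assert len(cands) == 1
        c = cands[0]
        assert c.support == 2
        assert c.breakend_a.chrom == "chrA" and c.breakend_b.chrom == "chrB"
        assert c.breakend_a.side == LEFT and c.breakend_b.side == RIGHT

    def test_isolated_pair_emits_nothing(self, pe_lib):
        df = aberrant_df([dict(pair_id="p1", chrom1="chrA", chrom2="chrB",
                               pos2=120_000)])
        assert svcall.cluster_pairs(df, {"pe500": pe_lib}) == []

    def test_orientation_classes_split(self, pe_lib):
        df = aberrant_df([
            dict(pair_id="p1", chrom1="chrA", pos1=50_000, strand1="+",
                 chrom2="chrB", pos2=120_000, strand2="+"),
            dict(pair_id="p2", chrom1="chrA", pos1=50_050, strand1="+",
                 chrom2="chrB", pos2=120_050, strand2="+"),
            dict(pair_id="p3", chrom1="chrA", pos1=50_025, strand1="-",
                 chrom2="chrB", pos2=120_025, strand2="-"),
        ])
        cands = svcall.cluster_pairs(df, {"pe500": pe_lib})
        # brute-force pairwise enumeration gives groups {2, 1}
        assert len(cands) == 1 and cands[0].support == 2
        assert {p for p in cands[0].pair_ids} == {"p1", "p2"}

    def test_matches_bruteforce_component_enumeration(self, lib_specs):
        """Cluster memberships equal connected components of the pairwise
        consistency relation, enumerated exhaustively."""
        rng = np.random.default_rng(23)
        rows = []
        for i in range(60):
            lib = "pe500" if rng.random() < 0.7 else "mp3k"
            rows.append(dict(
                pair_id=f"p{i}", library=lib,
                chrom1="chrA", pos1=int(rng.integers(0, 40_000)),
                strand1=str(rng.choice(["+", "-"])),
                chrom2="chrB", pos2=int(rng.integers(0, 40_000)),
                strand2=str(rng.choice(["+", "-"]))))
        df = aberrant_df(rows)
        cands = svcall.cluster_pairs(df, lib_specs)
        emitted = sorted(tuple(sorted(c.pair_ids)) for c in cands)

        # oracle: explicit graph over all O(n^2) pairs
        recs = df.to_dict("records")
        n = len(recs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if svcall.pairs_consistent(recs[i], recs[j], lib_specs):
                    parent[find(j)] = find(i)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(recs[i]["pair_id"])
        expected = sorted(tuple(sorted(c)) for c in comps.values() if len(c) >= 2)
        assert emitted == expected

    def test_members_pairwise_consistent_on_clean_data(self, small_ref):
        lib = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=6_000)
        ev = translocation_event("t", small_ref, "chr1", 60_000, "chr2", 30_000)
        der, _ = synthdata.plant_rearrangements(small_ref, [ev])
        pairs = synthdata.simulate_read_pairs(der, lib, seed=3)
        labels = readpairs.classify_pairs(pairs, {"pe500": lib})
        ab = pairs[labels == readpairs.ABERRANT]
        cands = svcall.cluster_pairs(ab, {"pe500": lib})
        assert len(cands) == 1
        recs = ab.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                assert svcall.pairs_consistent(recs[i], recs[j],
                                               {"pe500": lib})


def cand(chrom_a="chrA", mid_a=100_000, side_a=LEFT, chrom_b="chrA",
         mid_b=200_000, side_b=RIGHT, libraries=("pe500",), cid="J1",
         support=3, frag_max=619):
    sa = "+" if side_a == LEFT else "-"
    sb = "+" if side_b == LEFT else "-"
    return JunctionCandidate(
        id=cid, breakend_a=Breakend(chrom_a, mid_a - 50, mid_a + 50, side_a),
        breakend_b=Breakend(chrom_b, mid_b - 50, mid_b + 50, side_b),
        strand_a=sa, strand_b=sb, support=support,
        libraries=set(libraries), frag_max=frag_max)


class TestFilters:
    def test_min_span_strictly_below(self):
        near = cand(mid_b=100_000 + 9_500, cid="near")
        exact = cand(mid_b=100_000 + 10_000, cid="exact")
        kept, removed = svcall.apply_filters([near, exact])
        assert [c.id for c in kept] == ["exact"]
        assert removed[0][1] == svcall.REASON_MIN_SPAN

    def test_interchromosomal_exempt_from_span_rule(self):
        c = cand(chrom_b="chrB", mid_b=100_500, cid="inter")
        kept, removed = svcall.apply_filters([c])
        assert kept == [c] and removed == []

    def test_panel_match_removed(self):
        panel = pd.DataFrame([{"chrom_a": "chrA", "pos_a": 100_020, "side_a": LEFT,
                               "chrom_b": "chrA", "pos_b": 200_010, "side_b": RIGHT}])
        c = cand()
        kept, removed = svcall.apply_filters([c], panel=panel)
        assert kept == [] and removed[0][1] == svcall.REASON_PANEL

    def test_panel_orientation_mismatch_kept(self):
        panel = pd.DataFrame([{"chrom_a": "chrA", "pos_a": 100_000, "side_a": RIGHT,
                               "chrom_b": "chrA", "pos_b": 200_000, "side_b": LEFT}])
        kept, _ = svcall.apply_filters([cand()], panel=panel)
        assert len(kept) == 1

    def test_blacklist_reciprocal_overlap(self):
        bl = pd.DataFrame([{"chrom": "chrA", "start": 95_000, "end": 205_000}])
        c = cand()  # deletion-type spanning 100k-200k: ~91% reciprocal
        kept, removed = svcall.apply_filters([c], cnv_blacklist=bl)
        assert removed and removed[0][1] == svcall.REASON_BLACKLIST
        small = pd.DataFrame([{"chrom": "chrA", "start": 95_000, "end": 130_000}])
        kept, removed = svcall.apply_filters([cand()], cnv_blacklist=small)
        assert kept and not removed  # <50% of the candidate span

    def test_malformed_blacklist_rejected(self):
        bl = pd.DataFrame([{"chrom": "chrA", "start": 10, "end": 10}])
        with pytest.raises(ValueError, match="malformed"):
            svcall.apply_filters([cand()], cnv_blacklist=bl)

    def test_filters_only_remove_and_reasons_partition(self):
        cands = [cand(cid=f"J{i}", mid_b=100_000 + 5_000 + i * 7_000)
                 for i in range(5)]
        kept, removed = svcall.apply_filters(cands)
        assert len(kept) + len(removed) == len(cands)
        assert set(c.id for c in kept).isdisjoint(c.id for c, _ in removed)

    def test_filter_order_irrelevant(self):
        """Panel and blacklist tests are independent set-membership rules."""
        panel = pd.DataFrame([{"chrom_a": "chrA", "pos_a": 100_000, "side_a": LEFT,
                               "chrom_b": "chrA", "pos_b": 200_000, "side_b": RIGHT}])
        bl = pd.DataFrame([{"chrom": "chrA", "start": 295_000, "end": 405_000}])
        cands = [cand(cid="panelhit"),
                 cand(cid="blhit", mid_a=300_000, mid_b=400_000),
                 cand(cid="clean", mid_a=500_000, mid_b=600_000)]
        kept_ab, _ = svcall.apply_filters(cands, cnv_blacklist=bl, panel=panel)
        kept_a, _ = svcall.apply_filters(
            [c for c in cands], cnv_blacklist=bl, panel=None)
        kept_ba, _ = svcall.apply_filters(kept_a, cnv_blacklist=None, panel=panel)
        assert {c.id for c in kept_ab} == {c.id for c in kept_ba} == {"clean"}


class TestConfirmation:
    def test_multi_library(self):
        c = cand(libraries=("pe500", "mp3k_a"))
        svcall.confirm_candidates([c])
        assert c.confirmation == svcall.CONFIRM_MULTI_LIBRARY

    def test_cn_step_within_tolerance(self):
        c = cand()
        step = CNStep("chrA", 98_900, 99_100, delta_log2=-1.0)
        svcall.confirm_candidates([c], [step], step_tolerance=10_000)
        assert c.confirmation == svcall.CONFIRM_CN_STEP
        assert c.matched_steps == [step]

    def test_unconfirmed_when_step_far(self):
        c = cand()
        step = CNStep("chrA", 19_900, 20_100, delta_log2=-1.0)
        svcall.confirm_candidates([c], [step], step_tolerance=10_000)
        assert c.confirmation == svcall.UNCONFIRMED

    def test_external_breakpoints_act_as_pseudo_steps(self):
        c = cand()
        extra = pd.DataFrame([{"chrom": "chrA", "pos": 100_500}])
        svcall.confirm_candidates([c], [], extra_breakpoints=extra)
        assert c.confirmation == svcall.CONFIRM_CN_STEP


class TestCallPipeline:
    def test_zero_aberrant_pairs(self, small_ref, pe_lib):
        der, _ = synthdata.plant_rearrangements(small_ref, [])
        pairs = synthdata.simulate_read_pairs(der, pe_lib, seed=1)
        res = svcall.call_pipeline(pairs, {"pe500": pe_lib})
        assert res.candidates == []
        for key in ("input_pairs", "post_mapq", "post_dedup", "aberrant",
                    "clusters", "post_filter", "confirmed"):
            assert key in res.report

    def test_recovers_planted_junctions_exactly(self, small_ref):
        lib = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=8_000)
        mp = LibrarySpec("mp3k", 36, 3_000, 2_500, 3_600, n_pairs=3_000)
        events = [deletion_event("d", small_ref, "chr1", 40_000, 90_000),
                  translocation_event("t", small_ref, "chr1", 20_000,
                                      "chr2", 50_000)]
        der, truths = synthdata.plant_rearrangements(small_ref, events)
        parts = [synthdata.simulate_read_pairs(der, lib, seed=5),
                 synthdata.simulate_read_pairs(der, mp, seed=6)]
        pairs = pd.concat(parts, ignore_index=True)
        profile = synthdata.simulate_cgh(der.copy_map(), 500, 0.05, seed=7)
        res = svcall.call_pipeline(pairs, {"pe500": lib, "mp3k": mp},
                                   cn_profile=profile)
        confirmed = [c for c in res.candidates
                     if c.confirmation != svcall.UNCONFIRMED]
        assert len(res.candidates) == len(truths) == 2
        for t in truths:
            assert any(svcall.candidate_matches_truth(c, t, 3_600)
                       for c in confirmed)

    def test_deterministic(self, small_ref):
        lib = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=4_000)
        ev = deletion_event("d", small_ref, "chr1", 40_000, 90_000)
        der, _ = synthdata.plant_rearrangements(small_ref, [ev])
        pairs = synthdata.simulate_read_pairs(der, lib, seed=5)
        r1 = svcall.call_pipeline(pairs, {"pe500": lib})
        r2 = svcall.call_pipeline(pairs.copy(), {"pe500": lib})
        assert r1.report == r2.report
        assert [(c.breakend_a.lo, c.breakend_b.lo) for c in r1.candidates] == \
            [(c.breakend_a.lo, c.breakend_b.lo) for c in r2.candidates]


class TestStepMatching:
    def test_tolerance_monotonicity(self):
        c = cand()
        steps = [CNStep("chrA", 90_000 + i * 4_000, 90_200 + i * 4_000, 1.0)
                 for i in range(10)]
        prev = -1
        for tol in (0, 2_000, 5_000, 10_000, 50_000):
            n = len(cnsteps.match_junction_to_steps(c, steps, tol))
            assert n >= prev
            prev = n

    def test_deletion_matches_both_steps(self):
        c = cand()  # deletion-type 100k -> 200k
        down = CNStep("chrA", 99_500, 100_400, -1.0)
        up = CNStep("chrA", 199_600, 200_500, 1.0)
        got = cnsteps.match_junction_to_steps(c, [down, up], 10_000)
        assert got == [down, up]
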