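"""Packaged demonstration scenarios.

``build_demo`` constructs a desk-scale analogue of a heavily rearranged
breast-cancer cell-line genome (the ZR-75-30 pattern): a complex
coamplification of six interleaved fragments from two chromosomes at copy
number 20, a 160 kb interstitial deletion fusing two genes, a balanced
inversion, and a translocation that creates a run-through fusion into an
intact downstream gene. Junctions carry planted microhomologies (1-4 bp on
four of the seven "sequenced" junctions) and one genomic shard, mirroring
the sequence classes seen at real junction breakpoints.

``build_coverage_scenario`` is a calibration genome of isolated single-copy
and amplified junctions used to study detection probability as a function
of physical coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import svcall, synthdata
from .config import PipelineConfig
from .model import LibrarySpec, ReferenceGenome
from .synthdata import (
    RearrangementEvent, Segment, amplicon_event, deletion_event,
    inversion_event, make_gene, translocation_event,
)

#: Triangular-distribution means used to convert a target per-copy physical
#: coverage into a pair count.
def _mean_frag(lib: LibrarySpec) -> float:
    return (lib.frag_min + lib.frag_median + lib.frag_max) / 3.0


@dataclass
class DemoScenario:
    ref: ReferenceGenome
    genes: list
    events: list
    derivative: synthdata.DerivativeGenome
    truths: list
    lib_specs: dict
    repeat_intervals: dict
    panel: pd.DataFrame
    blacklist: pd.DataFrame
    sequenced_junctions: list     # the junctions "Sanger-resolved" downstream
    expected_fusions: list        # (5' gene, 3' gene, kind, donor ex, acc ex, frame)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def frag_max(self) -> int:
        return max(l.frag_max for l in self.lib_specs.values())


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31))]


def build_demo(seed: int = 0, coverage_per_copy_pe: float = 15.0,
               coverage_per_copy_mp: float = 8.0) -> DemoScenario:
    """Construct the rearranged-genome demonstration scenario.

    Per-copy physical coverage defaults are deep enough that every planted
    single-copy junction is supported in all three libraries with high
    probability, so recovery is limited by the pipeline, not sampling.
    """
    s_ref, s_genes, *_ = _derived_seeds(seed, 4)
    base = synthdata.generate_reference(
        5, [800_000, 800_000, 600_000, 300_000, 300_000], gc=0.41, seed=s_ref)
    names = ["chr8a", "chr17a", "chr21a", "chr10a", "chr11a"]
    ref = ReferenceGenome(list(zip(names, base.contigs.values())))

    # --- planted genes ---------------------------------------------------
    # the deletion fuses TIAM1L exon 1 in frame to NRIP1L exon 2
    tiam1 = make_gene("TIAM1L", "chr21a", "+", 200_000,
                      [200, 150, 150, 150], [9_800, 3_000, 3_000], utr5=50, utr3=31)
    nrip1 = make_gene("NRIP1L", "chr21a", "+", 360_000,
                      [150, 150, 150], [7_850, 3_000], utr5=102, utr3=30)
    # the translocation runs TIMM23L exon 6 out of frame into ARHGAP32L exon 2
    timm23 = make_gene("TIMM23L", "chr10a", "+", 100_000,
                       [160, 150, 150, 150, 150, 151, 150], [2_000] * 6,
                       utr5=30, utr3=31)
    arhgap32 = make_gene("ARHGAP32L", "chr11a", "+", 180_000,
                         [150, 150, 150], [2_000, 2_000], utr5=30, utr3=30)
    # amplicon junction 1 fuses COL14A1L exon 2 in frame to SKAP1L exon 5
    col14a1 = make_gene("COL14A1L", "chr8a", "+", 110_000,
                        [200, 150, 150, 150], [1_800, 9_850, 2_000], utr5=50, utr3=31)
    skap1 = make_gene("SKAP1L", "chr17a", "+", 193_000,
                      [150] * 6, [1_500, 1_500, 1_500, 6_350, 1_500],
                      utr5=30, utr3=30)
    # amplicon junction 3 fuses USP32L exon 5 out of frame to CCDC49L exon 3
    usp32 = make_gene("USP32L", "chr8a", "+", 310_000,
                      [150] * 6, [1_500, 1_500, 1_500, 1_500, 5_850],
                      utr5=29, utr3=32)
    ccdc49 = make_gene("CCDC49L", "chr17a", "+", 396_000,
                       [150] * 4, [1_500, 4_500, 1_500], utr5=30, utr3=30)
    planted = [tiam1, nrip1, timm23, arhgap32, col14a1, skap1, usp32, ccdc49]

    avoid = {
        "chr8a": [(95_000, 135_000), (295_000, 335_000), (495_000, 525_000),
                  (635_000, 765_000)],
        "chr17a": [(190_000, 225_000), (393_000, 425_000), (595_000, 625_000),
                   (695_000, 725_000)],
        "chr21a": [(195_000, 215_000), (355_000, 375_000), (40_000, 60_000)],
        "chr10a": [(95_000, 125_000)],
        "chr11a": [(140_000, 230_000)],
    }
    background = synthdata.generate_genes(ref, 20, (2, 6), seed=s_genes,
                                          avoid=avoid)
    genes = planted + background

    # --- rearrangement events -------------------------------------------
    frags = [Segment("chr8a", 100_000, 120_000), Segment("chr17a", 200_000, 220_000),
             Segment("chr8a", 300_000, 320_000), Segment("chr17a", 400_000, 420_000),
             Segment("chr8a", 500_000, 520_000), Segment("chr17a", 600_000, 620_000)]
    shard_donor = _unique_shard_locus(ref, "chr21a", 50_000, 15)
    amp_segments = frags[:4] + [shard_donor] + frags[4:]
    events = [
        RearrangementEvent("amp8_17", "amplicon_fragment", amp_segments,
                           copy_number=20, microhomologies={1: 3}),
        deletion_event("del21", ref, "chr21a", 205_000, 365_000, mh=2),
        translocation_event("t10_11", ref, "chr10a", 111_900, "chr11a", 150_000,
                            mh=1),
        inversion_event("inv8", ref, "chr8a", 650_000, 750_000, mh={0: 4}),
    ]
    derivative, truths = synthdata.plant_rearrangements(ref, events, seed=seed)

    by_event: dict[str, list] = {}
    for t in truths:
        by_event.setdefault(t.event_id, []).append(t)
    sequenced = [by_event["del21"][0], by_event["t10_11"][0],
                 by_event["inv8"][0], by_event["inv8"][1],
                 by_event["amp8_17"][0], by_event["amp8_17"][1],
                 by_event["amp8_17"][3]]

    # --- libraries scaled to the requested per-copy physical coverage ----
    weighted = sum(p.copy_number * p.length for p in derivative.paths)
    pe = LibrarySpec("pe500", 36, 504, 404, 619,
                     n_pairs=int(round(coverage_per_copy_pe * weighted
                                       / _mean_frag(LibrarySpec("x")))))
    mp_pairs = int(round(coverage_per_copy_mp * weighted
                         / _mean_frag(LibrarySpec("x", 36, 3_000, 2_500, 3_600))))
    mpa = LibrarySpec("mp3k_a", 36, 3_000, 2_500, 3_600, n_pairs=mp_pairs)
    mpb = LibrarySpec("mp3k_b", 36, 3_000, 2_500, 3_600, n_pairs=mp_pairs)
    libs = {l.name: l for l in (pe, mpa, mpb)}

    expected_fusions = [
        ("COL14A1L", "SKAP1L", "direct", 2, 5, "in_frame"),
        ("USP32L", "CCDC49L", "direct", 5, 3, "out_of_frame"),
        ("TIAM1L", "NRIP1L", "direct", 1, 2, "in_frame"),
        ("TIMM23L", "ARHGAP32L", "runthrough", 6, 2, "out_of_frame"),
    ]
    return DemoScenario(
        ref=ref, genes=genes, events=events, derivative=derivative,
        truths=truths, lib_specs=libs,
        repeat_intervals={"chr17a": [(700_000, 720_000)]},
        panel=pd.DataFrame(columns=["chrom_a", "pos_a", "side_a",
                                    "chrom_b", "pos_b", "side_b"]),
        blacklist=pd.DataFrame(columns=["chrom", "start", "end"]),
        sequenced_junctions=sequenced, expected_fusions=expected_fusions,
        config=PipelineConfig(seed=seed,
                              libraries=[pe, mpa, mpb]))


def _unique_shard_locus(ref: ReferenceGenome, chrom: str, start: int,
                        length: int) -> Segment:
    """Find a start >= ``start`` whose ``length``-mer occurs uniquely."""
    from .junctionseq import detect_shard
    pos = start
    while pos + length <= ref.length(chrom):
        probe = ref.sequence(chrom, pos, pos + length)
        locus, reason = detect_shard(probe, ref, shard_min_len=length)
        if reason == "unique":
            return Segment(chrom, pos, pos + length)
        pos += 97
    raise synthdata.PlacementError(f"no unique {length}-mer found on {chrom}")


def simulate_demo_pairs(scn: DemoScenario, seed: int, dup_rate: float = 0.0,
                        offset_dup_rate: float = 0.0, chimera_rate: float = 0.0,
                        with_sequences: bool = False) -> pd.DataFrame:
    seeds = _derived_seeds(seed, len(scn.lib_specs))
    mapq_model = {"repeat_intervals": scn.repeat_intervals}
    frames = []
    for s, lib in zip(seeds, scn.lib_specs.values()):
        frames.append(synthdata.simulate_read_pairs(
            scn.derivative, lib, dup_rate=dup_rate,
            offset_dup_rate=offset_dup_rate, chimera_rate=chimera_rate,
            mapq_model=mapq_model, seed=s, with_sequences=with_sequences))
    return pd.concat(frames, ignore_index=True)


def run_demo(seed: int = 0, dup_rate: float = 0.0, offset_dup_rate: float = 0.0,
             chimera_rate: float = 0.0, cgh_noise_sd: float = 0.1,
             probe_spacing: int = 400,
             scn: Optional[DemoScenario] = None) -> dict:
    """End-to-end run of the demo scenario: simulate, call, predict fusions.

    Returns a dict with the scenario, the call result, fusion predictions,
    and recall/precision against the planted truth.
    """
    from . import fusion as fusion_mod
    if scn is None:
        scn = build_demo(seed)
    pairs = simulate_demo_pairs(scn, seed, dup_rate, offset_dup_rate, chimera_rate)
    cgh_seed = _derived_seeds(seed, 5)[4]
    profile = synthdata.simulate_cgh(scn.derivative.copy_map(), probe_spacing,
                                     cgh_noise_sd, seed=cgh_seed,
                                     baseline_ploidy=scn.config.baseline_ploidy)
    result = svcall.call_pipeline(pairs, scn.lib_specs, ref=scn.ref,
                                  blacklist=scn.blacklist, panel=scn.panel,
                                  cn_profile=profile, config=scn.config)
    confirmed = [c for c in result.candidates
                 if c.confirmation != svcall.UNCONFIRMED]
    fusions, breaks = [], []
    for cand in confirmed:
        fs, bs = fusion_mod.predict_fusion(cand, scn.genes,
                                           scn.config.runthrough_window_bp)
        fusions.extend(fs)
        breaks.extend(bs)
    recovery = evaluate_recovery(scn, confirmed)
    return {"scenario": scn, "pairs": len(pairs), "result": result,
            "confirmed": confirmed, "fusions": fusions, "gene_breaks": breaks,
            "recovery": recovery, "profile": profile}


def evaluate_recovery(scn: DemoScenario, candidates: list) -> dict:
    """Recall and precision of candidates against the planted truth."""
    tol = scn.frag_max
    found = sum(1 for t in scn.truths
                if any(svcall.candidate_matches_truth(c, t, tol)
                       for c in candidates))
    true_pos = sum(1 for c in candidates
                   if any(svcall.candidate_matches_truth(c, t, tol)
                          for t in scn.truths))
    return {
        "truth_total": len(scn.truths),
        "truth_found": found,
        "recall": found / len(scn.truths) if scn.truths else float("nan"),
        "candidates": len(candidates),
        "precision": true_pos / len(candidates) if candidates else float("nan"),
    }


# ---------------------------------------------------------------------------
# coverage-calibration scenario
# ---------------------------------------------------------------------------

@dataclass
class CoverageScenario:
    ref: ReferenceGenome
    derivative: synthdata.DerivativeGenome
    truths: list
    lib: LibrarySpec
    copy1_ids: list
    amplified_ids: list


def build_coverage_scenario(seed: int = 0, n_copy1: int = 30,
                            n_amplified: int = 10, amplified_copy: int = 20,
                            coverage_per_copy: float = 1.7,
                            segment_len: int = 30_000) -> CoverageScenario:
    """Isolated inter-chromosomal junctions at copy 1 and at high copy.

    The pair count is chosen analytically so the expected number of
    *usable* junction-spanning fragments per single-copy junction equals
    ``coverage_per_copy`` (a fragment is usable when neither 36 bp read
    crosses the junction).
    """
    n_j = n_copy1 + n_amplified
    pitch = segment_len + 5_000
    clen = n_j * pitch + 10_000
    ref = synthdata.generate_reference(2, [clen, clen], gc=0.41, seed=seed)
    events = []
    for i in range(n_j):
        xa = 2_000 + i * pitch
        xb = 2_000 + i * pitch
        cn = 1 if i < n_copy1 else amplified_copy
        events.append(RearrangementEvent(
            f"jx{i}", "translocation",
            [Segment("chr1", xa, xa + segment_len),
             Segment("chr2", xb, xb + segment_len)], copy_number=cn))
    derivative, truths = synthdata.plant_rearrangements(
        ref, events, seed=seed, include_reference=False)
    lib0 = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=1)
    weighted = sum(p.copy_number * p.length for p in derivative.paths)
    usable_span = _mean_frag(lib0) - 2 * lib0.read_length + 1
    n_pairs = int(round(coverage_per_copy * weighted / usable_span))
    lib = LibrarySpec("pe500", 36, 504, 404, 619, n_pairs=n_pairs)
    copy1 = [t.junction_id for t in truths if t.copy_number == 1]
    amp = [t.junction_id for t in truths if t.copy_number > 1]
    return CoverageScenario(ref, derivative, truths, lib, copy1, amp)


def run_coverage_replicate(scn: CoverageScenario, seed: int) -> dict:
    """Simulate one library draw and count support per truth junction."""
    from . import readpairs
    pairs = synthdata.simulate_read_pairs(scn.derivative, scn.lib, seed=seed)
    libs = {scn.lib.name: scn.lib}
    labels = readpairs.classify_pairs(pairs, libs)
    aberrant = pairs[labels == readpairs.ABERRANT]
    return svcall.support_counts(aberrant, scn.truths, libs)
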