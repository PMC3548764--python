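"""Clustering of discordant read pairs into junction candidates, the filter
cascade (minimum span, panel of normals, germline-CNV blacklist), and
confirmation by multi-library support or copy-number-step correspondence.

Clustering uses the standard geometric construction: each read of an
aberrant pair implies a breakpoint interval extending from its 5' position
in the read's facing direction by ``frag_max - read_length``; two pairs are
consistent when they share the contig pair and orientation class and both
implied intervals overlap. Candidates are maximal consistent groups
(transitive closure) with at least two supporting pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import cnsteps, readpairs
from .model import (
    LEFT, RIGHT, Breakend, JunctionCandidate, LibrarySpec, TruthRecord,
    strand_to_side,
)

log = logging.getLogger(__name__)

MIN_SUPPORT = 2


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _implied_interval(pos: int, strand: str, window: int) -> tuple[int, int]:
    """Breakpoint interval implied by one read (half-open)."""
    if strand == "+":
        return pos, pos + window + 1
    return pos - window, pos + 1


def cluster_pairs(aberrant: pd.DataFrame, lib_specs: dict
                  ) -> list[JunctionCandidate]:
    """Group consistent aberrant pairs into junction candidates.

    Pairs must be canonically ordered (end1 <= end2). Mixed-library groups
    use each pair's own uncertainty window. Groups are maximal under
    transitive closure of pairwise consistency; only groups with >=
    :data:`MIN_SUPPORT` members are emitted. Each candidate's breakend
    interval is the intersection of its members' implied intervals.
    """
    if len(aberrant) == 0:
        return []
    win = aberrant["library"].map(lambda l: lib_specs[l].cluster_window).to_numpy()
    fmax = aberrant["library"].map(lambda l: lib_specs[l].frag_max).to_numpy()
    pos1 = aberrant["pos1"].to_numpy()
    pos2 = aberrant["pos2"].to_numpy()
    s1 = aberrant["strand1"].to_numpy()
    s2 = aberrant["strand2"].to_numpy()
    lo1 = np.where(s1 == "+", pos1, pos1 - win)
    hi1 = np.where(s1 == "+", pos1 + win + 1, pos1 + 1)
    lo2 = np.where(s2 == "+", pos2, pos2 - win)
    hi2 = np.where(s2 == "+", pos2 + win + 1, pos2 + 1)
    groupkey = (aberrant["chrom1"].astype(str) + "\x00" + aberrant["chrom2"].astype(str)
                + "\x00" + aberrant["strand1"].astype(str)
                + "\x00" + aberrant["strand2"].astype(str)).to_numpy()

    order = np.lexsort((lo1, groupkey))
    parent = np.arange(len(aberrant))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for a in range(len(order)):
        i = order[a]
        b = a + 1
        while b < len(order):
            j = order[b]
            if groupkey[j] != groupkey[i] or lo1[j] >= hi1[i]:
                break
            # end1 intervals overlap (lo1[j] < hi1[i] and lo1[j] >= lo1[i])
            if lo2[j] < hi2[i] and lo2[i] < hi2[j]:
                union(i, j)
            b += 1

    roots: dict[int, list[int]] = {}
    for i in range(len(aberrant)):
        roots.setdefault(find(i), []).append(i)

    idx = aberrant.reset_index(drop=True)
    cands = []
    for members in roots.values():
        if len(members) < MIN_SUPPORT:
            continue
        m = np.array(members)
        a_lo, a_hi = int(lo1[m].max()), int(hi1[m].min())
        b_lo, b_hi = int(lo2[m].max()), int(hi2[m].min())
        if a_hi <= a_lo:  # transitive chains can void the strict intersection
            a_lo, a_hi = int(lo1[m].min()), int(hi1[m].max())
        if b_hi <= b_lo:
            b_lo, b_hi = int(lo2[m].min()), int(hi2[m].max())
        rows = idx.iloc[m]
        side_a = strand_to_side(str(s1[m[0]]))
        side_b = strand_to_side(str(s2[m[0]]))
        cands.append(JunctionCandidate(
            id="",
            breakend_a=Breakend(str(rows["chrom1"].iloc[0]), a_lo, a_hi, side_a),
            breakend_b=Breakend(str(rows["chrom2"].iloc[0]), b_lo, b_hi, side_b),
            strand_a=str(s1[m[0]]), strand_b=str(s2[m[0]]),
            support=len(members),
            libraries=set(rows["library"]),
            pair_ids=list(rows["pair_id"]),
            frag_max=int(fmax[m].max()),
        ))
    cands.sort(key=lambda c: (c.breakend_a.chrom, c.breakend_a.lo,
                              c.breakend_b.chrom, c.breakend_b.lo))
    for i, c in enumerate(cands):
        c.id = f"J{i + 1:04d}"
    return cands


def pairs_consistent(p: dict, q: dict, lib_specs: dict) -> bool:
    """Reference pairwise-consistency predicate (used by tests as an oracle
    and exported for completeness)."""
    if (p["chrom1"], p["chrom2"], p["strand1"], p["strand2"]) != \
       (q["chrom1"], q["chrom2"], q["strand1"], q["strand2"]):
        return False
    for end in ("1", "2"):
        wp = lib_specs[p["library"]].cluster_window
        wq = lib_specs[q["library"]].cluster_window
        lp = _implied_interval(p[f"pos{end}"], p[f"strand{end}"], wp)
        lq = _implied_interval(q[f"pos{end}"], q[f"strand{end}"], wq)
        if not (lp[0] < lq[1] and lq[0] < lp[1]):
            return False
    return True


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

REASON_MIN_SPAN = "min_span"
REASON_PANEL = "panel_of_normals"
REASON_BLACKLIST = "cnv_blacklist"


def _panel_match(cand: JunctionCandidate, panel: pd.DataFrame) -> bool:
    tol = cand.frag_max
    for _, row in panel.iterrows():
        if (row["chrom_a"], row["chrom_b"]) != (cand.breakend_a.chrom,
                                                cand.breakend_b.chrom):
            continue
        if (row["side_a"], row["side_b"]) != (cand.breakend_a.side,
                                              cand.breakend_b.side):
            continue
        if (abs(int(row["pos_a"]) - cand.breakend_a.midpoint) <= tol
                and abs(int(row["pos_b"]) - cand.breakend_b.midpoint) <= tol):
            return True
    return False


def _blacklist_hit(cand: JunctionCandidate, trees: dict) -> bool:
    # applies to deletion/duplication-type intra-chromosomal candidates only
    if not cand.intra:
        return False
    sides = (cand.breakend_a.side, cand.breakend_b.side)
    if sides not in ((LEFT, RIGHT), (RIGHT, LEFT)):
        return False
    lo = min(cand.breakend_a.midpoint, cand.breakend_b.midpoint)
    hi = max(cand.breakend_a.midpoint, cand.breakend_b.midpoint)
    if hi <= lo:
        return False
    tree = trees.get(cand.breakend_a.chrom)
    if tree is None:
        return False
    for iv in tree.overlap(lo, hi):
        inter = min(hi, iv.end) - max(lo, iv.begin)
        if inter >= 0.5 * (hi - lo) and inter >= 0.5 * (iv.end - iv.begin):
            return True
    return False


def blacklist_trees(blacklist: Optional[pd.DataFrame]) -> dict:
    """Build per-chromosome interval trees from a BED-like table
    (columns chrom, start, end)."""
    trees: dict[str, IntervalTree] = {}
    if blacklist is None or len(blacklist) == 0:
        return trees
    for _, row in blacklist.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if s >= e:
            raise ValueError(f"malformed blacklist interval {row['chrom']}:{s}-{e}")
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(s, e)
    return trees


def apply_filters(candidates: Sequence[JunctionCandidate],
                  cnv_blacklist: Optional[pd.DataFrame] = None,
                  panel: Optional[pd.DataFrame] = None,
                  min_span: int = 10_000,
                  ) -> tuple[list, list]:
    """Apply the candidate filter cascade; returns (kept, removed).

    Removal rules (each removed candidate records its reason):

    * intra-chromosomal candidates spanning less than ``min_span`` between
      breakend midpoints (strictly less: a span of exactly ``min_span`` is
      kept);
    * candidates matching a panel-of-normals junction (same orientation
      class, both breakends within the widest contributing ``frag_max``);
    * deletion/duplication-type intra-chromosomal candidates whose spanned
      interval reciprocally overlaps a known-CNV blacklist interval >= 50%.
    """
    trees = blacklist_trees(cnv_blacklist)
    kept, removed = [], []
    for cand in candidates:
        reason = None
        if cand.intra and cand.span is not None and cand.span < min_span:
            reason = REASON_MIN_SPAN
        elif panel is not None and len(panel) and _panel_match(cand, panel):
            reason = REASON_PANEL
        elif trees and _blacklist_hit(cand, trees):
            reason = REASON_BLACKLIST
        if reason is None:
            kept.append(cand)
        else:
            cand.filter_state.append(reason)
            removed.append((cand, reason))
    return kept, removed


# ---------------------------------------------------------------------------
# confirmation
# ---------------------------------------------------------------------------

CONFIRM_MULTI_LIBRARY = "multi_library"
CONFIRM_CN_STEP = "cn_step"
UNCONFIRMED = "unconfirmed"


def confirm_candidates(candidates: Sequence[JunctionCandidate],
                       cn_steps: Sequence = (),
                       step_tolerance: int = 10_000,
                       extra_breakpoints: Optional[pd.DataFrame] = None,
                       ) -> list:
    """Set each candidate's confirmation state.

    A candidate is confirmed when it is supported by more than one library,
    or when at least one breakend lies within ``step_tolerance`` of a
    copy-number step (one-breakend matching: the partner of a balanced
    junction leaves no step). ``extra_breakpoints`` (columns chrom, pos) is
    an optional externally determined breakpoint list treated as additional
    pseudo-steps — e.g. breakpoints from chromosome-sorting/array data.
    Unconfirmed candidates are retained but flagged.
    """
    pseudo = []
    if extra_breakpoints is not None:
        from .model import CNStep
        for _, row in extra_breakpoints.iterrows():
            pseudo.append(CNStep(str(row["chrom"]), int(row["pos"]),
                                 int(row["pos"]) + 1, delta_log2=0.0))
    allsteps = list(cn_steps) + pseudo
    for cand in candidates:
        if len(cand.libraries) >= 2:
            cand.confirmation = CONFIRM_MULTI_LIBRARY
            continue
        matches = cnsteps.match_junction_to_steps(cand, allsteps, step_tolerance)
        if matches:
            cand.confirmation = CONFIRM_CN_STEP
            cand.matched_steps = matches
        else:
            cand.confirmation = UNCONFIRMED
    return list(candidates)


# ---------------------------------------------------------------------------
# truth matching (simulation mode)
# ---------------------------------------------------------------------------

def candidate_matches_truth(cand: JunctionCandidate, truth: TruthRecord,
                            tolerance: int) -> bool:
    """True when both candidate breakends are within ``tolerance`` of the
    truth junction's breakends, with matching sides (either breakend order)."""

    def m(be, tp):
        return (be.chrom == tp.chrom and be.side == tp.side
                and abs(be.midpoint - tp.pos) <= tolerance)

    return ((m(cand.breakend_a, truth.breakend_a) and m(cand.breakend_b, truth.breakend_b))
            or (m(cand.breakend_a, truth.breakend_b) and m(cand.breakend_b, truth.breakend_a)))


def support_counts(aberrant: pd.DataFrame, truths: Sequence[TruthRecord],
                   lib_specs: dict) -> dict:
    """Number of aberrant pairs whose implied breakpoints match each truth
    junction (orientation-aware, within frag_max). Support-only detection
    for calibration experiments."""
    counts = {t.junction_id: 0 for t in truths}
    if len(aberrant) == 0:
        return counts
    fmax = aberrant["library"].map(lambda l: lib_specs[l].frag_max).to_numpy()
    c1 = aberrant["chrom1"].to_numpy()
    c2 = aberrant["chrom2"].to_numpy()
    p1 = aberrant["pos1"].to_numpy()
    p2 = aberrant["pos2"].to_numpy()
    sd1 = np.array([strand_to_side(s) for s in aberrant["strand1"]])
    sd2 = np.array([strand_to_side(s) for s in aberrant["strand2"]])
    for t in truths:
        for (ta, tb) in ((t.breakend_a, t.breakend_b), (t.breakend_b, t.breakend_a)):
            hit = ((c1 == ta.chrom) & (sd1 == ta.side)
                   & (np.abs(p1 - ta.pos) <= fmax)
                   & (c2 == tb.chrom) & (sd2 == tb.side)
                   & (np.abs(p2 - tb.pos) <= fmax))
            n = int(hit.sum())
            if n:
                counts[t.junction_id] += n
                break
    return counts


# ---------------------------------------------------------------------------
# orchestration of the calling stages
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    candidates: list            # kept, confirmation set
    removed: list               # (candidate, reason)
    report: dict = field(default_factory=dict)
    cn_segments: list = field(default_factory=list)
    cn_steps: list = field(default_factory=list)


def call_pipeline(pairs: pd.DataFrame, lib_specs: dict,
                  ref=None, blacklist: Optional[pd.DataFrame] = None,
                  panel: Optional[pd.DataFrame] = None,
                  cn_profile=None, config=None) -> CallResult:
    """Run triage -> clustering -> filters -> CN integration -> confirmation.

    ``config`` is a :class:`svfuse.config.PipelineConfig` (defaults used
    when omitted). The run report records counts at every stage so the
    candidate funnel is visible on any dataset.
    """
    from .config import PipelineConfig
    cfg = config or PipelineConfig()
    try:
        tables, counts = readpairs.triage_pairs(
            pairs, lib_specs, mapq_threshold=cfg.mapq_threshold,
            max_offset=cfg.dedup_max_offset_bp, ref=ref,
            recheck_k=cfg.recheck_kmer)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"triage stage failed: {exc}") from exc

    cands = cluster_pairs(tables[readpairs.ABERRANT], lib_specs)
    kept, removed = apply_filters(cands, cnv_blacklist=blacklist, panel=panel,
                                  min_span=cfg.min_span_intra_bp)
    segments, steps = [], []
    if cn_profile is not None:
        segments = cnsteps.segment_profile(
            cn_profile, step_threshold=cfg.step_threshold_log2,
            min_probes=cfg.min_probes)
        steps = cnsteps.detect_steps(segments, step_threshold=cfg.step_threshold_log2)
    confirm_candidates(kept, steps, step_tolerance=cfg.step_match_tolerance_bp)

    counts.update({
        "clusters": len(cands),
        "post_filter": len(kept),
        "confirmed": sum(1 for c in kept if c.confirmation != UNCONFIRMED),
        "cn_steps": len(steps),
    })
    log.info("call funnel: %s", counts)
    return CallResult(candidates=kept, removed=removed, report=counts,
                      cn_segments=segments, cn_steps=steps)
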