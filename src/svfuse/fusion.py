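"""Fusion-gene prediction from confirmed junctions and gene models.

For each junction we ask whether the 5' or the 3' end of an overlapping
gene is retained in the derivative chromosome. A *direct* fusion joins a
gene retaining its transcription start (the donor) to a gene retaining its
stop (the acceptor) in concordant transcriptional orientation across the
junction. When the donor lands in gene-free sequence, transcription can
instead *run through* into the nearest intact downstream gene, splicing
into its first splice acceptor — the second exon, since exon 1 has no
acceptor site. Breakends inside genes that do not form a fusion are
reported as gene breaks.

Reading-frame status compares the coding phase at the donor's last
retained exon with the phase at the acceptor exon's start (phases are
cumulative CDS length mod 3); junctions touching untranslated sequence or
non-coding partners are called indeterminate.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .model import (
    LEFT, RIGHT, FusionPrediction, GeneBreak, GeneModel, JunctionCandidate,
)
from .synthdata import Segment

log = logging.getLogger(__name__)

DEFAULT_RUNTHROUGH_WINDOW = 1_000_000

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# orientation predicates
# ---------------------------------------------------------------------------

def _toward_junction(gene: GeneModel, side: str) -> bool:
    """Gene transcribes *into* the junction (donor-compatible direction)."""
    return (gene.strand == "+") == (side == LEFT)


def _away_from_junction(gene: GeneModel, side: str) -> bool:
    """Gene transcribes away from the junction (acceptor-compatible)."""
    return not _toward_junction(gene, side)


def _pos_retained(pos: int, junction_pos: int, side: str) -> bool:
    return pos < junction_pos if side == LEFT else pos >= junction_pos


def _gene_broken(gene: GeneModel, pos: int) -> bool:
    return gene.start < pos < gene.end


# ---------------------------------------------------------------------------
# exon bookkeeping (1-based exon numbers, transcript order)
# ---------------------------------------------------------------------------

def donor_last_exon(gene: GeneModel, pos: int, side: str) -> Optional[int]:
    """Last exon fully retained on the donor side, or None."""
    exons = gene.exons_transcript_order()
    k = 0
    for s, e in exons:
        retained = e <= pos if side == LEFT else s >= pos
        if retained:
            k += 1
        else:
            break
    return k or None


def acceptor_first_exon(gene: GeneModel, pos: int, side: str) -> Optional[int]:
    """First exon whose splice acceptor lies 3' of the junction point."""
    exons = gene.exons_transcript_order()
    for i, (s, e) in enumerate(exons, start=1):
        retained = s >= pos if side == RIGHT else e <= pos
        if retained:
            # exon 1 has no splice acceptor: landing upstream of the gene
            # splices into exon 2
            return max(i, 2)
    return None


def donor_end_phase(gene: GeneModel, last_exon: int) -> Optional[int]:
    """Coding phase at the 3' end of the donor's last retained exon."""
    if not gene.is_coding:
        return None
    clens = gene.coding_lengths()
    cum = sum(clens[:last_exon])
    if cum == 0 or cum >= gene.total_cds_length():
        return None  # junction in 5' UTR or past the stop codon
    return cum % 3


def acceptor_start_phase(gene: GeneModel, first_exon: int) -> Optional[int]:
    """Coding phase at the 5' start of the acceptor exon."""
    if not gene.is_coding:
        return None
    clens = gene.coding_lengths()
    cum_before = sum(clens[:first_exon - 1])
    if cum_before >= gene.total_cds_length():
        return None  # acceptor exon in the 3' UTR
    if cum_before == 0 and clens[first_exon - 1] == 0:
        return None  # acceptor exon entirely upstream of the CDS start
    return cum_before % 3


def check_frame(prediction: FusionPrediction, genes_by_id: dict) -> str:
    """Set and return the reading-frame status of a prediction."""
    donor = genes_by_id[prediction.five_prime_gene]
    acceptor = genes_by_id[prediction.three_prime_gene]
    dp = donor_end_phase(donor, prediction.five_prime_exon)
    ap = acceptor_start_phase(acceptor, prediction.three_prime_exon)
    if dp is None or ap is None:
        prediction.frame = INDETERMINATE
    else:
        prediction.frame = IN_FRAME if dp == ap else OUT_OF_FRAME
    return prediction.frame


# ---------------------------------------------------------------------------
# gene lookup around a junction
# ---------------------------------------------------------------------------

def genes_at_breakpoints(candidate: JunctionCandidate, genes: Sequence[GeneModel],
                         runthrough_window: int = DEFAULT_RUNTHROUGH_WINDOW
                         ) -> tuple[list, list, dict]:
    """Genes overlapping each breakend, and nearest downstream intact genes.

    "Downstream" means: in the retained flank, transcribing away from the
    junction, entirely clear of the breakend, within ``runthrough_window``
    of the breakend midpoint; sorted nearest first.
    """
    out_overlap = []
    adjacent = {}
    for key, be in (("a", candidate.breakend_a), ("b", candidate.breakend_b)):
        ov = [g for g in genes
              if g.chrom == be.chrom and g.start < be.hi and g.end > be.lo]
        out_overlap.append(ov)
        pos = be.midpoint
        cands = []
        for g in genes:
            if g.chrom != be.chrom or not _away_from_junction(g, be.side):
                continue
            if be.side == RIGHT and g.start >= pos:
                dist = g.start - pos
            elif be.side == LEFT and g.end <= pos:
                dist = pos - g.end
            else:
                continue
            if dist <= runthrough_window:
                cands.append((dist, g))
        cands.sort(key=lambda t: (t[0], t[1].gene_id))
        adjacent[key] = [g for _, g in cands]
    return out_overlap[0], out_overlap[1], adjacent


# ---------------------------------------------------------------------------
# single-junction prediction
# ---------------------------------------------------------------------------

def predict_fusion(candidate: JunctionCandidate, genes: Sequence[GeneModel],
                   runthrough_window: int = DEFAULT_RUNTHROUGH_WINDOW
                   ) -> tuple[list, list]:
    """Predict fusions and gene breaks induced by one junction.

    Both derivative reading directions are considered (donor on either
    side). Returns ``(fusions, gene_breaks)``; every gene-overlapping
    breakend not absorbed into a fusion yields exactly one
    :class:`GeneBreak`.
    """
    genes_a, genes_b, adjacent = genes_at_breakpoints(candidate, genes,
                                                      runthrough_window)
    sides = {"a": (candidate.breakend_a, genes_a),
             "b": (candidate.breakend_b, genes_b)}
    fusions: list[FusionPrediction] = []
    used: set[str] = set()

    for donor_key, acceptor_key in (("a", "b"), ("b", "a")):
        dbe, dgenes = sides[donor_key]
        abe, agenes = sides[acceptor_key]
        for donor in dgenes:
            if not (_toward_junction(donor, dbe.side)
                    and _pos_retained(donor.tss, dbe.midpoint, dbe.side)
                    and _gene_broken(donor, dbe.midpoint)):
                continue
            dk = donor_last_exon(donor, dbe.midpoint, dbe.side)
            if dk is None:
                continue
            # direct partner: a broken gene on the far side retaining its
            # stop (a gene rejoined to itself across the junction is the
            # legal identity case)
            direct = []
            for acc in agenes:
                if _away_from_junction(acc, abe.side) and \
                   _pos_retained(acc.tes, abe.midpoint, abe.side) and \
                   _gene_broken(acc, abe.midpoint):
                    am = acceptor_first_exon(acc, abe.midpoint, abe.side)
                    if am is not None:
                        direct.append((acc, am))
            if direct:
                direct.sort(key=lambda t: (t[1], t[0].gene_id))
                acc, am = direct[0]
                fus = _build(donor, dk, acc, am, "direct", [candidate.id],
                             alternatives=[g.gene_id for g, _ in direct[1:]])
                fusions.append(fus)
                used.update((donor.gene_id, acc.gene_id))
                continue
            # run-through partner: intact downstream gene near the junction
            downstream = [g for g in adjacent[acceptor_key]
                          if not _gene_broken(g, abe.midpoint)
                          and g.gene_id not in {x.gene_id for x in agenes}]
            if downstream:
                acc = downstream[0]
                fus = _build(donor, dk, acc, 2, "runthrough", [candidate.id],
                             alternatives=[g.gene_id for g in downstream[1:]])
                fusions.append(fus)
                used.update((donor.gene_id, acc.gene_id))

    genes_by_id = {g.gene_id: g for g in genes}
    for fus in fusions:
        check_frame(fus, genes_by_id)

    breaks = []
    for be, ovs in ((candidate.breakend_a, genes_a), (candidate.breakend_b, genes_b)):
        for g in ovs:
            if g.gene_id in used or not _gene_broken(g, be.midpoint):
                continue
            retained = "five_prime" if _pos_retained(g.tss, be.midpoint, be.side) \
                else "three_prime"
            breaks.append(GeneBreak(g.gene_id, candidate.id, retained))
    return fusions, breaks


def _build(donor: GeneModel, dk: int, acceptor: GeneModel, am: int, kind: str,
           junction_ids: list, alternatives: Optional[list] = None
           ) -> FusionPrediction:
    model = [(donor.gene_id, i) for i in range(1, dk + 1)]
    model += [(acceptor.gene_id, i) for i in range(am, acceptor.n_exons + 1)]
    return FusionPrediction(
        five_prime_gene=donor.gene_id, five_prime_exon=dk,
        three_prime_gene=acceptor.gene_id, three_prime_exon=am,
        kind=kind, junction_ids=list(junction_ids), transcript_model=model,
        alternatives=alternatives or [])


# ---------------------------------------------------------------------------
# multi-junction transcripts along a derivative path
# ---------------------------------------------------------------------------

def trace_multi_junction_transcript(segments: Sequence[Segment],
                                    genes: Sequence[GeneModel],
                                    junction_ids: Optional[Sequence[str]] = None,
                                    runthrough_window: int = DEFAULT_RUNTHROUGH_WINDOW
                                    ) -> list:
    """Walk transcription along an ordered derivative segment path.

    The donor is a gene in the first segment transcribing along the path
    and cut by its 3' boundary. Subsequent segments are traversed while
    they are anonymous (no genes: the insert is intronic); a gene oriented
    against the walk disrupts splicing and aborts the trace. The first
    co-oriented gene whose 3' end survives inside a segment becomes the
    acceptor. Returns a list with zero or one prediction whose
    ``junction_ids`` covers every junction crossed.

    Raises on a cyclic path (a segment repeated exactly).
    """
    segs = list(segments)
    seen = set()
    for s in segs:
        key = (s.chrom, s.start, s.end, s.orient)
        if key in seen:
            raise ValueError(f"cyclic derivative path: segment {key} repeats")
        seen.add(key)
    if junction_ids is None:
        junction_ids = [f"path_j{i + 1}" for i in range(len(segs) - 1)]
    if len(junction_ids) != len(segs) - 1:
        raise ValueError("need one junction id per segment adjacency")

    genes_by_id = {g.gene_id: g for g in genes}

    first = segs[0]
    walk_strand = first.orient
    cut_pos = first.end if first.orient == "+" else first.start
    cut_side = LEFT if first.orient == "+" else RIGHT
    donor = None
    for g in genes:
        if g.chrom != first.chrom or g.strand != walk_strand:
            continue
        if _gene_broken(g, cut_pos) and _pos_retained(g.tss, cut_pos, cut_side):
            donor = g
            break
    if donor is None:
        return []
    dk = donor_last_exon(donor, cut_pos, cut_side)
    if dk is None:
        return []

    for si in range(1, len(segs)):
        seg = segs[si]
        along = seg.orient  # genomic strand that transcribes along the walk
        entry_pos = seg.start if seg.orient == "+" else seg.end
        entry_side = RIGHT if seg.orient == "+" else LEFT
        in_seg = [g for g in genes
                  if g.chrom == seg.chrom and g.start < seg.end and g.end > seg.start]
        if any(g.strand != along for g in in_seg):
            return []  # orientation flip inside the insert disrupts splicing
        acceptors = []
        for g in in_seg:
            tes_inside = seg.start <= g.tes < seg.end
            if not tes_inside:
                continue  # gene cut again at the segment's far end
            am = acceptor_first_exon(g, entry_pos, entry_side)
            if am is not None:
                broken = _gene_broken(g, entry_pos)
                dist = 0 if broken else (g.start - seg.start if seg.orient == "+"
                                         else seg.end - g.end)
                acceptors.append((dist, am, g, broken))
        if acceptors:
            acceptors.sort(key=lambda t: (t[0], t[1], t[2].gene_id))
            dist, am, acc, broken = acceptors[0]
            kind = "direct" if broken else "runthrough"
            fus = _build(donor, dk, acc, am, kind, list(junction_ids[:si]),
                         alternatives=[g.gene_id for _, _, g, _ in acceptors[1:]])
            check_frame(fus, genes_by_id)
            return [fus]
        # anonymous/intronic segment: keep walking
    return []
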