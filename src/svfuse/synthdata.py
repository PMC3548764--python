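"""Seeded synthetic-data generator: toy genomes, gene models, derivative
(rearranged) genomes with copy numbers, paired-end read libraries, CGH-like
probe profiles, and a panel of normals.

The generator produces read pairs directly *as alignments* (reference
coordinates, strand, mapping quality): because the derivative genome's
segment map is known exactly, mapping back to the reference is a coordinate
transform and needs no external aligner. An optional FASTQ emitter lives in
:mod:`svfuse.io` for interoperability.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    LEFT, RIGHT, BreakendPoint, CNProfile, GeneModel, LibrarySpec,
    PAIR_COLUMNS, ReferenceGenome, TruthRecord, revcomp,
)

log = logging.getLogger(__name__)

#: Donor segments shorter than this are folded into the junction between
#: their neighbours as an insert (a "genomic shard") rather than treated as
#: a segment with two junctions of its own.
SHARD_FOLD_MAX = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PlacementError(ValueError):
    """Raised when requested features do not fit in the genome."""


class ConflictError(ValueError):
    """Raised when two events make contradictory demands on the same base."""


# ---------------------------------------------------------------------------
# reference and gene models
# ---------------------------------------------------------------------------

def generate_reference(n_chrom: int, lengths: Sequence[int], gc: float,
                       seed: int) -> ReferenceGenome:
    """Generate ``n_chrom`` random contigs with the given lengths and GC."""
    if len(lengths) != n_chrom:
        raise ValueError(f"expected {n_chrom} lengths, got {len(lengths)}")
    if any(l <= 0 for l in lengths):
        raise ValueError(f"contig lengths must be positive: {list(lengths)}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    probs = np.array([at, gcp, gcp, at])
    contigs = []
    for i, length in enumerate(lengths):
        arr = rng.choice(_BASES, size=int(length), p=probs)
        contigs.append((f"chr{i + 1}", arr.tobytes().decode("ascii")))
    return ReferenceGenome(contigs)


def make_gene(gene_id: str, chrom: str, strand: str, start: int,
              exon_lengths: Sequence[int], intron_lengths: Sequence[int],
              utr5: int = 30, utr3: int = 30, coding: bool = True) -> GeneModel:
    """Deterministic gene-model builder.

    ``start`` is the genomic start of the first (leftmost) exon;
    ``exon_lengths``/``intron_lengths`` are in *transcript* order for a
    ``+`` gene and are mirrored for a ``-`` gene. ``utr5``/``utr3`` are the
    untranslated lengths at the transcript's two ends, each contained in the
    terminal exons (possibly spanning whole terminal exons).
    """
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need one fewer intron than exons")
    lens = list(exon_lengths)
    ints = list(intron_lengths)
    if strand == "-":
        lens, ints = lens[::-1], ints[::-1]
    exons, pos = [], start
    for i, el in enumerate(lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(ints):
            pos += ints[i]
    cds_start = cds_end = None
    if coding:
        # walk utr5 bases into the transcript to find the CDS start
        order = exons if strand == "+" else exons[::-1]
        tot = sum(lens)
        if utr5 + utr3 >= tot:
            raise ValueError("UTRs leave no coding sequence")

        def genomic_at(tpos: int) -> int:
            """Genomic coordinate of transcript offset tpos (0-based)."""
            rem = tpos
            for s, e in order:
                if rem < e - s:
                    return s + rem if strand == "+" else e - 1 - rem
                rem -= e - s
            raise AssertionError

        g5 = genomic_at(utr5)           # first coding base
        g3 = genomic_at(tot - utr3 - 1)  # last coding base
        cds_start, cds_end = (g5, g3 + 1) if strand == "+" else (g3, g5 + 1)
    return GeneModel(gene_id, chrom, strand, tuple(exons), cds_start, cds_end)


def generate_genes(ref: ReferenceGenome, n_genes: int,
                   exons_per_gene: tuple[int, int] = (2, 10), seed: int = 0,
                   avoid: Optional[dict] = None,
                   intergenic_min: int = 1_000) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping random gene models on the genome.

    ``avoid`` maps chrom -> list of (start, end) intervals to keep clear
    (e.g. planned breakpoints). Raises :class:`PlacementError` naming the
    offending contig when a gene cannot be placed.
    """
    lo_ex, hi_ex = exons_per_gene
    if lo_ex < 2:
        raise ValueError("every gene needs >= 2 exons")
    rng = np.random.default_rng(seed)
    occupied = {name: IntervalTree() for name in ref.names}
    for chrom, ivals in (avoid or {}).items():
        for s, e in ivals:
            occupied[chrom].addi(s, e)
    weights = np.array([ref.length(n) for n in ref.names], dtype=float)
    weights /= weights.sum()
    genes: list[GeneModel] = []
    last_contig = ref.names[0]
    for gi in range(n_genes):
        placed = False
        for _ in range(500):
            chrom = rng.choice(ref.names, p=weights)
            last_contig = chrom
            n_ex = int(rng.integers(lo_ex, hi_ex + 1))
            exon_lens = rng.integers(90, 300, size=n_ex).tolist()
            intron_lens = rng.integers(300, 2_500, size=n_ex - 1).tolist()
            span = sum(exon_lens) + sum(intron_lens)
            maxstart = ref.length(chrom) - span - intergenic_min
            if maxstart <= intergenic_min:
                continue
            start = int(rng.integers(intergenic_min, maxstart))
            if occupied[chrom].overlap(start - intergenic_min,
                                       start + span + intergenic_min):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = int(rng.integers(10, max(11, exon_lens[0] - 10)))
            utr3 = int(rng.integers(10, max(11, exon_lens[-1] - 10)))
            gene = make_gene(f"gene{gi + 1:03d}", chrom, strand, start,
                             exon_lens, intron_lens, utr5=utr5, utr3=utr3)
            occupied[chrom].addi(gene.start, gene.end)
            genes.append(gene)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place gene {gi + 1} of {n_genes} "
                f"(last attempted contig: {last_contig})")
    # guarantee both strands appear
    if n_genes >= 2 and len({g.strand for g in genes}) == 1:
        g = genes[-1]
        genes[-1] = GeneModel(g.gene_id, g.chrom,
                              "-" if g.strand == "+" else "+",
                              g.exons, g.cds_start, g.cds_end)
    return genes


# ---------------------------------------------------------------------------
# derivative genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A reference interval with an orientation, as used in derivative paths."""

    chrom: str
    start: int
    end: int
    orient: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.orient not in "+-":
            raise ValueError(f"bad orientation {self.orient!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_sequence(self, ref: ReferenceGenome) -> str:
        seq = ref.sequence(self.chrom, self.start, self.end)
        return seq if self.orient == "+" else revcomp(seq)


@dataclass
class RearrangementEvent:
    """A planted rearrangement, expressed as an ordered donor-segment path.

    ``microhomologies`` maps a 0-based junction index (within this event's
    emitted junctions) to the microhomology length to plant there.
    """

    event_id: str
    kind: str
    segments: list
    copy_number: int = 1
    microhomologies: dict = field(default_factory=dict)

    def __post_init__(self):
        kinds = {"translocation", "deletion", "inversion", "tandem_dup",
                 "amplicon_fragment", "shard_insertion"}
        if self.kind not in kinds:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


# -- convenience constructors ----------------------------------------------

def deletion_event(event_id: str, ref: ReferenceGenome, chrom: str,
                   start: int, end: int, mh: int = 0) -> RearrangementEvent:
    L = ref.length(chrom)
    segs = [Segment(chrom, 0, start), Segment(chrom, end, L)]
    return RearrangementEvent(event_id, "deletion", segs,
                              microhomologies={0: mh} if mh else {})


def inversion_event(event_id: str, ref: ReferenceGenome, chrom: str,
                    start: int, end: int,
                    mh: dict | None = None) -> RearrangementEvent:
    L = ref.length(chrom)
    segs = [Segment(chrom, 0, start), Segment(chrom, start, end, "-"),
            Segment(chrom, end, L)]
    return RearrangementEvent(event_id, "inversion", segs,
                              microhomologies=mh or {})


def tandem_dup_event(event_id: str, ref: ReferenceGenome, chrom: str,
                     start: int, end: int) -> RearrangementEvent:
    L = ref.length(chrom)
    segs = [Segment(chrom, 0, end), Segment(chrom, start, L)]
    return RearrangementEvent(event_id, "tandem_dup", segs)


def translocation_event(event_id: str, ref: ReferenceGenome, chrom_a: str,
                        pos_a: int, chrom_b: str, pos_b: int,
                        mh: int = 0) -> RearrangementEvent:
    segs = [Segment(chrom_a, 0, pos_a),
            Segment(chrom_b, pos_b, ref.length(chrom_b))]
    return RearrangementEvent(event_id, "translocation", segs,
                              microhomologies={0: mh} if mh else {})


def amplicon_event(event_id: str, fragments: Sequence[Segment],
                   copy_number: int,
                   mh: dict | None = None) -> RearrangementEvent:
    return RearrangementEvent(event_id, "amplicon_fragment", list(fragments),
                              copy_number=copy_number,
                              microhomologies=mh or {})


@dataclass
class DerivativePath:
    """One derivative chromosome: an ordered segment list plus its sequence.

    ``inserts[k]`` is the (possibly empty) shard/untemplated sequence sitting
    between segments k and k+1 in the derivative.
    """

    name: str
    segments: list
    copy_number: int
    inserts: list = field(default_factory=list)
    sequence: str = ""
    d_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        if not self.inserts:
            self.inserts = [""] * (len(self.segments) - 1)
        if len(self.inserts) != len(self.segments) - 1:
            raise ValueError("need one insert slot per segment adjacency")

    def realize(self, ref: ReferenceGenome) -> None:
        parts, offs, off = [], [], 0
        for k, seg in enumerate(self.segments):
            offs.append(off)
            parts.append(seg.oriented_sequence(ref))
            off += seg.length
            if k < len(self.segments) - 1:
                parts.append(self.inserts[k])
                off += len(self.inserts[k])
        self.sequence = "".join(parts)
        self.d_starts = np.array(offs, dtype=np.int64)

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments) + sum(map(len, self.inserts))


@dataclass
class DerivativeGenome:
    paths: list
    reference: ReferenceGenome

    def copy_map(self) -> dict:
        """Per-chromosome piecewise-constant copy number implied by the paths."""
        out = {}
        for chrom in self.reference.names:
            L = self.reference.length(chrom)
            cuts = {0, L}
            for p in self.paths:
                for s in p.segments:
                    if s.chrom == chrom:
                        cuts.update((s.start, s.end))
            edges = sorted(cuts)
            pieces = []
            for lo, hi in zip(edges[:-1], edges[1:]):
                cn = sum(p.copy_number for p in self.paths for s in p.segments
                         if s.chrom == chrom and s.start <= lo and s.end >= hi)
                pieces.append((lo, hi, cn))
            # merge equal neighbours
            merged = []
            for lo, hi, cn in pieces:
                if merged and merged[-1][2] == cn:
                    merged[-1] = (merged[-1][0], hi, cn)
                else:
                    merged.append((lo, hi, cn))
            out[chrom] = merged
        return out


# -- junction bookkeeping ---------------------------------------------------

def _trailing_breakend(seg: Segment) -> BreakendPoint:
    """Breakend contributed by the 3' (path-order) end of a segment."""
    if seg.orient == "+":
        return BreakendPoint(seg.chrom, seg.end, LEFT)
    return BreakendPoint(seg.chrom, seg.start, RIGHT)


def _leading_breakend(seg: Segment) -> BreakendPoint:
    """Breakend contributed by the 5' (path-order) end of a segment."""
    if seg.orient == "+":
        return BreakendPoint(seg.chrom, seg.start, RIGHT)
    return BreakendPoint(seg.chrom, seg.end, LEFT)


def _reference_contiguous(a: Segment, b: Segment) -> bool:
    if a.chrom != b.chrom or a.orient != b.orient:
        return False
    return (a.end == b.start) if a.orient == "+" else (a.start == b.end)


class _JunctionFlanks:
    """Orientation-aware access to the retained flanks of one junction.

    Left flank index 1.. counts backwards from the junction (1 = last
    retained base, as it appears in the derivative). Right flank index 0..
    counts forwards from the junction.
    """

    def __init__(self, ref: ReferenceGenome, a: BreakendPoint, b: BreakendPoint):
        self.ref = ref
        self.a, self.b = a, b

    # -- coordinate mapping (derivative orientation -> reference base) --
    def _left_loc(self, i: int) -> tuple[str, int, bool]:
        a = self.a
        if a.side == LEFT:
            return a.chrom, a.pos - i, False
        return a.chrom, a.pos + i - 1, True  # read via complement

    def _right_loc(self, j: int) -> tuple[str, int, bool]:
        b = self.b
        if b.side == RIGHT:
            return b.chrom, b.pos + j, False
        return b.chrom, b.pos - 1 - j, True

    def _get(self, loc) -> str:
        chrom, pos, comp = loc
        base = self.ref.sequence(chrom, pos, pos + 1)
        return _COMP_BASE[base] if comp else base

    def _set(self, loc, base: str) -> None:
        chrom, pos, comp = loc
        if comp:
            base = _COMP_BASE[base]
        seq = self.ref.contigs[chrom]
        self.ref.set_sequence(chrom, seq[:pos] + base + seq[pos + 1:])

    def left(self, i: int) -> str:
        return self._get(self._left_loc(i))

    def right(self, j: int) -> str:
        return self._get(self._right_loc(j))

    def set_right(self, j: int, base: str) -> None:
        self._set(self._right_loc(j), base)

    def plant_microhomology(self, L: int) -> None:
        """Edit the reference so the junction has exactly L bp of homology."""
        for j in range(L):
            self.set_right(j, self.left(L - j))
        # break extension to L+1 homology: the (L+1)-extension requires
        # right(L) == left(1), so force them to differ
        if self.right(L) == self.left(1):
            repl = "A" if self.left(1) != "A" else "C"
            self.set_right(L, repl)

    def measured_mh(self, limit: int = 25) -> int:
        best = 0
        for L in range(1, limit + 1):
            if all(self.right(j) == self.left(L - j) for j in range(L)):
                best = L
        return best


def plant_rearrangements(ref: ReferenceGenome, events: Sequence[RearrangementEvent],
                         seed: int = 0, include_reference: bool = True,
                         reference_copy_number: int = 1,
                         ) -> tuple[DerivativeGenome, list[TruthRecord]]:
    """Realize the events into derivative paths and emit the implied truth.

    Every adjacency between consecutive segments that is not contiguous in
    the reference yields exactly one :class:`TruthRecord`. Microhomology is
    planted by editing the reference bases at the incoming flank, so that
    the homology measured from the final reference equals the request;
    donor segments shorter than ``SHARD_FOLD_MAX`` are folded into the
    junction as a shard insert. Edits never overlap between junctions
    (enforced; a :class:`ConflictError` is raised otherwise).

    The reference passed in is edited in place and shared by the returned
    derivative.
    """
    rng = np.random.default_rng(seed)
    for ev in events:
        for seg in ev.segments:
            if seg.chrom not in ref.contigs:
                raise ValueError(f"event {ev.event_id}: unknown contig {seg.chrom}")
            if seg.end > ref.length(seg.chrom):
                raise ValueError(
                    f"event {ev.event_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"outside contig bounds")

    paths: list[DerivativePath] = []
    truths: list[TruthRecord] = []
    edited: dict[str, set] = {name: set() for name in ref.names}
    jn = 0

    def _claim(be: BreakendPoint, width: int) -> None:
        lo = be.pos - width if be.side == LEFT else be.pos
        span = set(range(lo, lo + width))
        if span & edited[be.chrom]:
            raise ConflictError(
                f"junction edit regions collide on {be.chrom} near {be.pos}")
        edited[be.chrom].update(span)

    for ev in events:
        # fold shard-sized segments into junction inserts
        segs: list[Segment] = []
        between: list[str] = []  # insert between segs[k] and segs[k+1]
        pending = ""
        for seg in ev.segments:
            if seg.length < SHARD_FOLD_MAX and segs:
                pending += seg.oriented_sequence(ref)
            else:
                if segs:
                    between.append(pending)
                    pending = ""
                segs.append(seg)
        if pending:
            raise ValueError(
                f"event {ev.event_id}: trailing shard-sized segment has no "
                f"right-hand neighbour")
        if not segs:
            raise ValueError(f"event {ev.event_id}: no segments of usable size")

        path = DerivativePath(f"der_{ev.event_id}", segs, ev.copy_number,
                              inserts=between)
        ji = 0
        for k in range(len(segs) - 1):
            insert = between[k]
            if not insert and _reference_contiguous(segs[k], segs[k + 1]):
                continue
            a = _trailing_breakend(segs[k])
            b = _leading_breakend(segs[k + 1])
            fl = _JunctionFlanks(ref, a, b)
            mh_req = int(ev.microhomologies.get(ji, 0))
            if insert:
                mh = 0  # inserted junctions are categorically not microhomologous
            else:
                _claim(a, max(mh_req + 1, 2))
                _claim(b, max(mh_req + 1, 2))
                fl.plant_microhomology(mh_req)
                mh = fl.measured_mh()
            jn += 1
            truths.append(TruthRecord(
                junction_id=f"jx{jn:03d}", breakend_a=a, breakend_b=b,
                copy_number=ev.copy_number, event_id=ev.event_id,
                inserted_seq=insert, microhomology_len=mh))
            ji += 1
        paths.append(path)

    if include_reference:
        for name in ref.names:
            paths.append(DerivativePath(
                f"ref_{name}", [Segment(name, 0, ref.length(name))],
                reference_copy_number))

    for p in paths:
        p.realize(ref)

    return DerivativeGenome(paths, ref), truths


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------

def simulate_read_pairs(derivative: DerivativeGenome, lib: LibrarySpec,
                        dup_rate: float = 0.0, offset_dup_rate: float = 0.0,
                        chimera_rate: float = 0.0,
                        mapq_model: Optional[dict] = None, seed: int = 0,
                        with_sequences: bool = False) -> pd.DataFrame:
    """Draw ``lib.n_pairs`` fragments from the derivative and emit alignments.

    Fragments land uniformly along the derivative weighted by copy number,
    so read depth scales with copy number. Fragment lengths are triangular
    on [frag_min, frag_max] with mode frag_median. Reads that would cross a
    junction cannot be placed on the reference and the whole pair is
    dropped (mirroring a 36 bp read failing to align across a breakpoint).

    ``mapq_model`` is ``{"repeat_intervals": {chrom: [(s, e), ...]}}``:
    reads overlapping a repeat interval draw a mapping quality uniformly in
    [0, 30); all other reads score 60. Duplicate injection adds exact
    copies at ``dup_rate`` and copies offset by 1-2 bp at
    ``offset_dup_rate``; ``chimera_rate`` joins two unrelated fragments
    into one artefactual pair (a coligation artefact).
    """
    for name, rate in (("dup_rate", dup_rate), ("offset_dup_rate", offset_dup_rate),
                       ("chimera_rate", chimera_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {rate}")
    rng = np.random.default_rng(seed)
    paths = derivative.paths
    plens = np.array([p.length for p in paths], dtype=np.int64)
    if (plens < lib.frag_max).any():
        raise ValueError("every derivative path must be at least frag_max long")
    weights = np.array([p.copy_number for p in paths], dtype=float) * plens
    weights /= weights.sum()

    n = lib.n_pairs
    path_idx = rng.choice(len(paths), size=n, p=weights)
    flen = np.rint(rng.triangular(lib.frag_min, lib.frag_median, lib.frag_max,
                                  size=n)).astype(np.int64)
    start = np.floor(rng.random(n) * (plens[path_idx] - flen + 1)).astype(np.int64)

    rl = lib.read_length
    d1 = start                      # forward read, leftmost base
    d2 = start + flen - rl          # reverse read, leftmost base

    rec = _map_reads(derivative, path_idx, d1, d2, rl)
    rec["flen"] = flen[rec.index]

    # chimera artefacts: read1 of one fragment paired with read2 of another
    n_chim = rng.binomial(n, chimera_rate)
    if n_chim:
        pi_a = rng.choice(len(paths), size=n_chim, p=weights)
        pi_b = rng.choice(len(paths), size=n_chim, p=weights)
        fa = np.rint(rng.triangular(lib.frag_min, lib.frag_median, lib.frag_max,
                                    size=n_chim)).astype(np.int64)
        fb = np.rint(rng.triangular(lib.frag_min, lib.frag_median, lib.frag_max,
                                    size=n_chim)).astype(np.int64)
        sa = np.floor(rng.random(n_chim) * (plens[pi_a] - fa + 1)).astype(np.int64)
        sb = np.floor(rng.random(n_chim) * (plens[pi_b] - fb + 1)).astype(np.int64)
        chim = _map_reads(derivative, pi_a, sa, sb + fb - rl, rl, path_idx2=pi_b)
        chim["flen"] = fa[chim.index]
        rec = pd.concat([rec, chim], ignore_index=True)

    rec = rec.reset_index(drop=True)
    rec["pair_id"] = [f"{lib.name}:{i:07d}" for i in range(len(rec))]
    rec["library"] = lib.name

    # mapping quality
    rec["mapq1"] = 60
    rec["mapq2"] = 60
    if mapq_model and mapq_model.get("repeat_intervals"):
        for endi in ("1", "2"):
            lowmask = np.zeros(len(rec), dtype=bool)
            lo = np.where(rec[f"strand{endi}"] == "+", rec[f"pos{endi}"],
                          rec[f"pos{endi}"] - rl + 1)
            hi = lo + rl
            for chrom, ivals in mapq_model["repeat_intervals"].items():
                cm = (rec[f"chrom{endi}"] == chrom).to_numpy()
                for s, e in ivals:
                    lowmask |= cm & (lo < e) & (hi > s)
            rec.loc[lowmask, f"mapq{endi}"] = rng.integers(0, 30, size=int(lowmask.sum()))

    # duplicate injection
    extra = []
    ndup = rng.binomial(len(rec), dup_rate)
    if ndup:
        idx = rng.choice(len(rec), size=ndup, replace=False)
        dups = rec.iloc[idx].copy()
        dups["pair_id"] = [f"{p}:dup" for p in dups["pair_id"]]
        extra.append(dups)
    noff = rng.binomial(len(rec), offset_dup_rate)
    if noff:
        idx = rng.choice(len(rec), size=noff, replace=False)
        offs = rec.iloc[idx].copy()
        shift1 = rng.choice([-2, -1, 1, 2], size=noff)
        shift2 = rng.choice([-2, -1, 0, 1, 2], size=noff)
        offs["pos1"] = np.maximum(0, offs["pos1"].to_numpy() + shift1)
        offs["pos2"] = np.maximum(0, offs["pos2"].to_numpy() + shift2)
        offs["pair_id"] = [f"{p}:offdup" for p in offs["pair_id"]]
        extra.append(offs)
    if extra:
        rec = pd.concat([rec] + extra, ignore_index=True)

    if with_sequences:
        _attach_sequences(derivative, rec, rl)

    rec = _canonical_order(rec, derivative.reference, with_sequences)
    cols = PAIR_COLUMNS + (["seq1", "seq2"] if with_sequences else [])
    return rec[cols].reset_index(drop=True)


def _map_reads(derivative, path_idx, d1, d2, rl, path_idx2=None) -> pd.DataFrame:
    """Map derivative read placements back to reference coordinates.

    Returns one row per pair whose two reads both lie inside a single
    segment; rows keep bookkeeping columns (_path1, _d1, ...) used for
    optional sequence extraction.
    """
    if path_idx2 is None:
        path_idx2 = path_idx
    n = len(path_idx)

    def map_end(pis, ds, is_reverse):
        chroms = np.empty(n, dtype=object)
        poss = np.zeros(n, dtype=np.int64)
        strands = np.empty(n, dtype=object)
        good = np.zeros(n, dtype=bool)
        for pi in np.unique(pis):
            path = derivative.paths[pi]
            mask = pis == pi
            d = ds[mask]
            seg_i = np.searchsorted(path.d_starts, d, side="right") - 1
            seg_len = np.array([s.length for s in path.segments])
            seg_end = path.d_starts + seg_len
            inside = (d >= path.d_starts[seg_i]) & (d + rl <= seg_end[seg_i])
            cc = np.empty(mask.sum(), dtype=object)
            pp = np.zeros(mask.sum(), dtype=np.int64)
            ss = np.empty(mask.sum(), dtype=object)
            for si in np.unique(seg_i):
                seg = path.segments[si]
                m2 = seg_i == si
                off = d[m2] - path.d_starts[si]
                if seg.orient == "+":
                    p5 = seg.start + off + (rl - 1 if is_reverse else 0)
                    st = "-" if is_reverse else "+"
                else:
                    p5 = seg.end - 1 - off - (rl - 1 if is_reverse else 0)
                    st = "+" if is_reverse else "-"
                cc[m2] = seg.chrom
                pp[m2] = p5
                ss[m2] = st
            chroms[mask] = cc
            poss[mask] = pp
            strands[mask] = ss
            good[mask] = inside
        return chroms, poss, strands, good

    chrom1, pos1, strand1, ok1 = map_end(path_idx, d1, is_reverse=False)
    chrom2, pos2, strand2, ok2 = map_end(path_idx2, d2, is_reverse=True)
    ok = ok1 & ok2
    df = pd.DataFrame({
        "chrom1": chrom1, "pos1": pos1, "strand1": strand1,
        "chrom2": chrom2, "pos2": pos2, "strand2": strand2,
        "_path1": path_idx, "_d1": d1, "_path2": path_idx2, "_d2": d2,
    })
    return df[ok]


def _attach_sequences(derivative, rec: pd.DataFrame, rl: int) -> None:
    seq1, seq2 = [], []
    for _, row in rec.iterrows():
        p1 = derivative.paths[row["_path1"]]
        p2 = derivative.paths[row["_path2"]]
        s1 = p1.sequence[row["_d1"]:row["_d1"] + rl]
        s2 = revcomp(p2.sequence[row["_d2"]:row["_d2"] + rl])
        seq1.append(s1)
        seq2.append(s2)
    rec["seq1"] = seq1
    rec["seq2"] = seq2


def _canonical_order(rec: pd.DataFrame, ref: ReferenceGenome,
                     with_sequences: bool) -> pd.DataFrame:
    rank = {name: i for i, name in enumerate(ref.names)}
    r1 = rec["chrom1"].map(rank).to_numpy()
    r2 = rec["chrom2"].map(rank).to_numpy()
    swap = (r2 < r1) | ((r2 == r1) & (rec["pos2"].to_numpy() < rec["pos1"].to_numpy()))
    if swap.any():
        cols1 = ["chrom1", "pos1", "strand1", "mapq1"]
        cols2 = ["chrom2", "pos2", "strand2", "mapq2"]
        if with_sequences:
            cols1, cols2 = cols1 + ["seq1"], cols2 + ["seq2"]
        a = rec.loc[swap, cols1].to_numpy()
        rec.loc[swap, cols1] = rec.loc[swap, cols2].to_numpy()
        rec.loc[swap, cols2] = a
    return rec


# ---------------------------------------------------------------------------
# CGH-like probe profile
# ---------------------------------------------------------------------------

def simulate_cgh(copy_map: dict, probe_spacing: int, noise_sd: float,
                 seed: int = 0, baseline_ploidy: float = 2.0,
                 min_cn: float = 0.25) -> CNProfile:
    """Noisy probe log-ratios over the true copy-number map.

    ``copy_map`` maps chrom -> [(start, end, copy_number), ...] tiling each
    chromosome (see :meth:`DerivativeGenome.copy_map`). Each probe reports
    ``log2(max(cn, min_cn) / baseline_ploidy) + N(0, noise_sd)``.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, pieces in copy_map.items():
        extent = pieces[-1][1]
        pos = np.arange(probe_spacing // 2, extent, probe_spacing, dtype=np.int64)
        edges = np.array([p[0] for p in pieces] + [extent])
        cns = np.array([p[2] for p in pieces], dtype=float)
        idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(cns) - 1)
        ratio = np.log2(np.maximum(cns[idx], min_cn) / baseline_ploidy)
        if noise_sd > 0:
            ratio = ratio + rng.normal(0.0, noise_sd, size=len(pos))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "log2_ratio": ratio}))
    return CNProfile(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# panel of normals
# ---------------------------------------------------------------------------

def build_panel_of_normals(ref: ReferenceGenome, n_samples: int = 18,
                           polymorphic_sv_rate: float = 2.0, seed: int = 0,
                           planted: Optional[Sequence[TruthRecord]] = None,
                           ) -> pd.DataFrame:
    """Junction signatures seen in simulated unrelated normal samples.

    A shared pool of polymorphic deletion junctions is drawn (Poisson with
    mean ``polymorphic_sv_rate``); each polymorphism is carried by a random
    non-empty subset of the ``n_samples`` normals. The panel is the union
    of junction signatures across samples. ``planted`` truth records are
    added to every sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_sites = rng.poisson(polymorphic_sv_rate) if polymorphic_sv_rate > 0 else 0
    lens = np.array([ref.length(n) for n in ref.names], dtype=float)
    for _ in range(n_sites):
        chrom = str(rng.choice(ref.names, p=lens / lens.sum()))
        span = int(rng.integers(15_000, 80_000))
        if ref.length(chrom) <= span + 2_000:
            continue
        s = int(rng.integers(1_000, ref.length(chrom) - span - 1_000))
        carriers = rng.random(n_samples) < 0.5
        if not carriers.any():
            carriers[int(rng.integers(n_samples))] = True
        rows.append({"chrom_a": chrom, "pos_a": s, "side_a": LEFT,
                     "chrom_b": chrom, "pos_b": s + span, "side_b": RIGHT,
                     "n_samples": int(carriers.sum())})
    for t in planted or []:
        rows.append({"chrom_a": t.breakend_a.chrom, "pos_a": t.breakend_a.pos,
                     "side_a": t.breakend_a.side, "chrom_b": t.breakend_b.chrom,
                     "pos_b": t.breakend_b.pos, "side_b": t.breakend_b.side,
                     "n_samples": n_samples})
    cols = ["chrom_a", "pos_a", "side_a", "chrom_b", "pos_b", "side_b", "n_samples"]
    return pd.DataFrame(rows, columns=cols)
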