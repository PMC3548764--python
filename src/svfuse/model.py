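"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory. On-disk formats
(GFF3 1-based closed, BEDPE 0-based half-open) are converted in
:mod:`svfuse.io`.

A *breakend* is one side of a rearrangement junction: a reference position
plus which flank of that position is retained in the derivative chromosome
(``left_retained`` or ``right_retained``). A read aligned on the ``+``
strand points rightwards into a junction, so it witnesses a
``left_retained`` breakend; a ``-`` read witnesses ``right_retained``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

LEFT = "left_retained"
RIGHT = "right_retained"

DNA = set("ACGT")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def strand_to_side(strand: str) -> str:
    """Side of the junction a read of this strand retains."""
    return LEFT if strand == "+" else RIGHT


class ReferenceGenome:
    """An ordered collection of named contigs over the ACGT alphabet.

    Sequences are stored as plain upper-case strings; contig order is the
    insertion order and is used as the canonical chromosome sort order.
    """

    def __init__(self, contigs: Iterable[tuple[str, str]]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs:
            if name in self.contigs:
                raise ValueError(f"duplicate contig name: {name!r}")
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} has zero length")
            seq = seq.upper()
            if set(seq) - DNA:
                bad = sorted(set(seq) - DNA)
                raise ValueError(f"contig {name!r} contains non-ACGT symbols: {bad}")
            self.contigs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        seq = self.contigs[chrom]
        if start is None:
            return seq
        if start < 0 or end is None or end > len(seq) or start > end:
            raise IndexError(f"{chrom}:{start}-{end} outside contig bounds (len {len(seq)})")
        return seq[start:end]

    def chrom_rank(self, chrom: str) -> int:
        return self.names.index(chrom)

    def set_sequence(self, chrom: str, seq: str) -> None:
        if chrom not in self.contigs:
            raise KeyError(chrom)
        self.contigs[chrom] = seq

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceGenome) and self.contigs == other.contigs

    def __repr__(self) -> str:
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self.contigs.items())
        return f"ReferenceGenome({parts})"


@dataclass(frozen=True)
class LibrarySpec:
    """Geometry of one paired-end library.

    ``frag_*`` describe the sheared-fragment (insert) length distribution;
    the simulator draws fragment lengths from a triangular distribution on
    ``[frag_min, frag_max]`` with mode ``frag_median``.
    """

    name: str
    read_length: int = 36
    frag_median: int = 504
    frag_min: int = 404
    frag_max: int = 619
    n_pairs: int = 10_000

    def __post_init__(self):
        if not (self.frag_min <= self.frag_median <= self.frag_max):
            raise ValueError(
                f"library {self.name!r}: need frag_min <= frag_median <= frag_max, "
                f"got {self.frag_min}/{self.frag_median}/{self.frag_max}"
            )
        if 2 * self.read_length > self.frag_min:
            raise ValueError(
                f"library {self.name!r}: reads ({self.read_length} bp x2) do not fit "
                f"in the smallest fragment ({self.frag_min} bp)"
            )

    @property
    def cluster_window(self) -> int:
        """Breakpoint-uncertainty window of one read: frag_max - read_length."""
        return self.frag_max - self.read_length


@dataclass
class GeneModel:
    """A single-transcript gene model.

    ``exons`` are 0-based half-open intervals in genomic order (ascending
    coordinates regardless of strand). ``cds_start``/``cds_end`` delimit the
    coding interval in genomic coordinates, or are ``None`` for a
    non-coding gene.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        last = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon {s}-{e}")
            if last is not None and s < last:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            last = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS outside exon span")

    # -- genomic extent ------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """Transcription start position (genomic)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (genomic)."""
        return self.end - 1 if self.strand == "+" else self.start

    # -- transcript-order views ---------------------------------------
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]

    def coding_lengths(self) -> list[int]:
        """Coding bases contributed by each exon, in transcript order."""
        if not self.is_coding:
            return [0] * self.n_exons
        out = []
        for s, e in self.exons_transcript_order():
            out.append(max(0, min(e, self.cds_end) - max(s, self.cds_start)))
        return out

    def exon_phases(self) -> list[int]:
        """Phase at the 5' boundary of each exon's coding part, transcript order.

        phase_{k+1} = (phase_k + cds_len_k) mod 3, with phase_1 = 0.
        """
        phases, cum = [], 0
        for clen in self.coding_lengths():
            phases.append(cum % 3)
            cum += clen
        return phases

    def total_cds_length(self) -> int:
        return sum(self.coding_lengths())

    def cds_sequence(self, ref: ReferenceGenome) -> str:
        """Spliced coding sequence, 5'->3' on the coding strand."""
        if not self.is_coding:
            return ""
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                parts.append(ref.sequence(self.chrom, lo, hi))
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class BreakendPoint:
    """A base-resolved breakend (used by simulator truth and junction-seq)."""

    chrom: str
    pos: int
    side: str  # LEFT or RIGHT

    def __post_init__(self):
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"bad breakend side {self.side!r}")


@dataclass
class TruthRecord:
    """A planted rearrangement junction: the simulator's ground truth.

    A junction is blunt, microhomologous, or carries an untemplated/shard
    insert; the three are mutually exclusive by construction.
    """

    junction_id: str
    breakend_a: BreakendPoint
    breakend_b: BreakendPoint
    copy_number: int = 1
    event_id: str = ""
    inserted_seq: str = ""
    microhomology_len: int = 0

    def __post_init__(self):
        if self.microhomology_len < 0:
            raise ValueError("negative microhomology length")
        if self.inserted_seq and self.microhomology_len > 0:
            raise ValueError("a junction cannot be both inserted and microhomologous")


@dataclass
class Breakend:
    """One side of a clustered junction candidate, with an uncertainty window."""

    chrom: str
    lo: int
    hi: int
    side: str

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"empty breakend interval [{self.lo},{self.hi})")
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"bad breakend side {self.side!r}")

    @property
    def midpoint(self) -> int:
        return (self.lo + self.hi) // 2


@dataclass
class JunctionCandidate:
    """A clustered putative rearrangement junction."""

    id: str
    breakend_a: Breakend
    breakend_b: Breakend
    strand_a: str
    strand_b: str
    support: int
    libraries: set = field(default_factory=set)
    pair_ids: list = field(default_factory=list)
    filter_state: list = field(default_factory=list)
    confirmation: str = "unconfirmed"
    matched_steps: list = field(default_factory=list)
    frag_max: int = 619  # widest contributing library, used as match tolerance

    @property
    def intra(self) -> bool:
        return self.breakend_a.chrom == self.breakend_b.chrom

    @property
    def span(self) -> Optional[int]:
        """Distance between breakend midpoints (intra-chromosomal only)."""
        if not self.intra:
            return None
        return abs(self.breakend_b.midpoint - self.breakend_a.midpoint)


@dataclass
class CNSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_probes: int


@dataclass
class CNStep:
    """A copy-number change-point between two adjacent segments."""

    chrom: str
    lo: int  # last probe position of the left segment
    hi: int  # first probe position of the right segment (exclusive bound)
    delta_log2: float

    @property
    def direction(self) -> str:
        return "up" if self.delta_log2 > 0 else "down"

    @property
    def midpoint(self) -> int:
        return (self.lo + self.hi) // 2


@dataclass
class CNProfile:
    """CGH-like probe profile: a DataFrame with chrom, pos, log2_ratio."""

    probes: "object"  # pandas.DataFrame

    def __post_init__(self):
        cols = list(self.probes.columns)
        for c in ("chrom", "pos", "log2_ratio"):
            if c not in cols:
                raise ValueError(f"probe table missing column {c!r}")


@dataclass
class FusionPrediction:
    """A predicted expressed fusion transcript."""

    five_prime_gene: str
    five_prime_exon: int  # last retained exon (1-based, transcript order)
    three_prime_gene: str
    three_prime_exon: int  # first retained exon (1-based, transcript order)
    kind: str  # "direct" | "runthrough"
    frame: str = "indeterminate"  # "in_frame" | "out_of_frame" | "indeterminate"
    junction_ids: list = field(default_factory=list)
    transcript_model: list = field(default_factory=list)  # [(gene_id, exon_number), ...]
    alternatives: list = field(default_factory=list)  # other possible 3' partners


@dataclass
class GeneBreak:
    """A gene interrupted by a junction breakend without forming a fusion."""

    gene_id: str
    junction_id: str
    retained_end: str  # "five_prime" | "three_prime" | "internal_loss"


@dataclass
class JunctionSequenceReport:
    """Sequence-level characterisation of one resolved junction."""

    junction_id: str
    flank5: str
    flank3: str
    observed: str
    mh_len: int = 0
    inserted: str = ""
    shard: Optional[tuple[str, int, int]] = None
    shard_reason: str = ""

    def __post_init__(self):
        if self.mh_len > 0 and self.inserted:
            raise ValueError("microhomologous and inserted are mutually exclusive")


#: Column order of the pairs table (one row per sequenced fragment).
PAIR_COLUMNS = [
    "pair_id", "library",
    "chrom1", "pos1", "strand1", "mapq1",
    "chrom2", "pos2", "strand2", "mapq2",
]
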