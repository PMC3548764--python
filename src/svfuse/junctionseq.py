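"""Sequence-level characterisation of resolved junctions: microhomology,
untemplated inserts, and genomic shards (small fragments copied from
elsewhere in the genome into the junction).

Microhomology is measured as the ambiguous-placement length: the maximal
``L`` such that the last ``L`` retained reference bases on the 5' side
equal the first ``L`` retained bases on the 3' side, making the exact
breakpoint position ambiguous over ``L`` bases. A junction is blunt,
microhomologous, or inserted — mutually exclusive categories.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

from .model import (
    LEFT, RIGHT, BreakendPoint, JunctionSequenceReport, ReferenceGenome,
    TruthRecord, revcomp,
)

log = logging.getLogger(__name__)

DEFAULT_FLANK = 200
DEFAULT_SHARD_MIN_LEN = 10
MICROHOMOLOGY_BAND = (1, 4)  # the short-homology band reported separately


def _retained_flank(ref: ReferenceGenome, be: BreakendPoint, flank: int,
                    as_left_part: bool) -> str:
    """Retained flank sequence as it appears in the derivative.

    ``as_left_part`` selects whether this breakend forms the 5' (left) or
    3' (right) part of the junction in derivative orientation.
    """
    chrom, pos = be.chrom, be.pos
    if be.side == LEFT:
        if pos - flank < 0:
            raise IndexError(f"flank extends past the start of {chrom}")
        seq = ref.sequence(chrom, pos - flank, pos)
        return seq if as_left_part else revcomp(seq)
    if pos + flank > ref.length(chrom):
        raise IndexError(f"flank extends past the end of {chrom}")
    seq = ref.sequence(chrom, pos, pos + flank)
    return revcomp(seq) if as_left_part else seq


def extract_junction_sequence(junction: Union[TruthRecord, tuple],
                              ref: ReferenceGenome,
                              flank: int = DEFAULT_FLANK
                              ) -> JunctionSequenceReport:
    """Reference flanks and the observed derivative sequence of a junction.

    ``junction`` is a :class:`TruthRecord` (simulation truth) or a
    ``(junction_id, breakend_a, breakend_b, inserted_seq)`` tuple with
    base-resolved breakends. Breakend intervals wider than one base must be
    resolved by the caller first.
    """
    if flank <= 0:
        raise ValueError("flank must be positive (a zero flank is degenerate)")
    if isinstance(junction, TruthRecord):
        jid, a, b, ins = (junction.junction_id, junction.breakend_a,
                          junction.breakend_b, junction.inserted_seq)
    else:
        jid, a, b, ins = junction
    flank5 = _retained_flank(ref, a, flank, as_left_part=True)
    flank3 = _retained_flank(ref, b, flank, as_left_part=False)
    observed = flank5 + ins + flank3
    return JunctionSequenceReport(junction_id=jid, flank5=flank5, flank3=flank3,
                                  observed=observed, inserted=ins)


def measure_microhomology(flank5: str, flank3: str,
                          observed: Optional[str] = None) -> int:
    """Maximal L with ``flank5[-L:] == flank3[:L]`` (0 for blunt junctions).

    When ``observed`` is supplied it must be consistent with the flanks
    (``flank5 + inserted + flank3``); a junction carrying an insert is
    categorically not microhomologous and scores 0.
    """
    if observed is not None:
        if not (observed.startswith(flank5) and observed.endswith(flank3)
                and len(observed) >= len(flank5) + len(flank3)):
            raise ValueError("observed sequence inconsistent with flanks")
        if len(observed) > len(flank5) + len(flank3):
            return 0  # inserted junction
    best = 0
    for L in range(1, min(len(flank5), len(flank3)) + 1):
        if flank5[-L:] == flank3[:L]:
            best = L
    return best


def detect_shard(inserted: str, ref: ReferenceGenome,
                 shard_min_len: int = DEFAULT_SHARD_MIN_LEN
                 ) -> tuple[Optional[tuple], str]:
    """Exact-match search for the insert elsewhere in the genome.

    Returns ``(locus, reason)``: a unique hit of length >= shard_min_len
    gives ``((chrom, start, end), "unique")``; otherwise ``(None, reason)``
    with reason in {"too_short", "not_found", "ambiguous"}. Both strands
    are searched; near-matches are deliberately out of scope.
    """
    if not inserted:
        raise ValueError("empty insert")
    if len(inserted) < shard_min_len:
        return None, "too_short"
    hits = []
    for chrom, seq in ref.contigs.items():
        for probe in (inserted, revcomp(inserted)):
            start = seq.find(probe)
            while start != -1:
                hits.append((chrom, start, start + len(probe)))
                start = seq.find(probe, start + 1)
    hits = sorted(set(hits))
    if not hits:
        return None, "not_found"
    if len(hits) > 1:
        return None, "ambiguous"
    return hits[0], "unique"


def analyze_junction(junction: Union[TruthRecord, tuple], ref: ReferenceGenome,
                     flank: int = DEFAULT_FLANK,
                     shard_min_len: int = DEFAULT_SHARD_MIN_LEN
                     ) -> JunctionSequenceReport:
    """Full per-junction report: flanks, microhomology, insert, shard."""
    rep = extract_junction_sequence(junction, ref, flank)
    if rep.inserted:
        rep.mh_len = 0
        rep.shard, rep.shard_reason = detect_shard(rep.inserted, ref, shard_min_len)
    else:
        rep.mh_len = measure_microhomology(rep.flank5, rep.flank3, rep.observed)
    return rep


def summarize_junction_classes(reports: Sequence[JunctionSequenceReport]) -> dict:
    """Partition junction reports into sequence classes.

    ``microhomologous`` counts the 1-4 bp band (reported separately as the
    hallmark of microhomology-mediated repair); homologies of 5 bp or more
    are ``longer_homology``. Counts always sum to the number of reports.
    """
    lo, hi = MICROHOMOLOGY_BAND
    out = {"microhomologous": 0, "longer_homology": 0, "blunt": 0,
           "inserted": 0, "shard": 0, "total": len(reports)}
    for r in reports:
        if r.inserted:
            out["shard" if r.shard is not None else "inserted"] += 1
        elif r.mh_len == 0:
            out["blunt"] += 1
        elif lo <= r.mh_len <= hi:
            out["microhomologous"] += 1
        else:
            out["longer_homology"] += 1
    return out
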