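"""Read-pair triage: mapping-quality filtering, PCR-duplicate removal
(exact and 1-2 bp offset), normal/aberrant classification, and a k-mer
realignment recheck of aberrant pairs.

The stages run in a fixed order — mapq -> duplicates -> classification ->
recheck — so that stage counts are reproducible. Bulk operations take and
return pandas DataFrames in the :data:`svfuse.model.PAIR_COLUMNS` layout;
:func:`classify_pair` is the single-record form of the classification rule.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .model import LibrarySpec, ReferenceGenome, revcomp

log = logging.getLogger(__name__)

NORMAL = "normal"
ABERRANT = "aberrant"
DISCARDED_LOWMAPQ = "discarded_lowmapq"
DISCARDED_DUPLICATE = "discarded_duplicate"
DISCARDED_NORMAL_RECHECK = "discarded_normal_recheck"


# ---------------------------------------------------------------------------
# mapping quality
# ---------------------------------------------------------------------------

def filter_mapq(pairs: pd.DataFrame, threshold: int = 30
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard pairs in which either read scores below ``threshold``.

    The boundary is strict: a read scoring exactly ``threshold`` is kept.
    """
    if len(pairs) == 0:
        return pairs, pairs
    low = (pairs["mapq1"] < threshold) | (pairs["mapq2"] < threshold)
    return pairs[~low].copy(), pairs[low].copy()


# ---------------------------------------------------------------------------
# PCR duplicates
# ---------------------------------------------------------------------------

def remove_duplicates(pairs: pd.DataFrame, max_offset: int = 2
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse exact and offset PCR duplicates, keeping one copy per group.

    Two pairs are duplicates when both ends share contig and strand and
    both 5' positions differ by at most ``max_offset`` (offset duplicates
    model a PCR primer that lost one or two 3' bases). Duplicate groups are
    the connected components of this relation; within a group the pair with
    the highest summed mapping quality is retained (ties broken by the
    lexicographically smallest pair id).
    """
    n = len(pairs)
    if n == 0:
        return pairs, pairs
    df = pairs.sort_values(
        ["chrom1", "strand1", "chrom2", "strand2", "pos1", "pos2"],
        kind="mergesort").reset_index(drop=True)
    key = (df["chrom1"].astype(str) + "\x00" + df["strand1"].astype(str) + "\x00"
           + df["chrom2"].astype(str) + "\x00" + df["strand2"].astype(str)).to_numpy()
    pos1 = df["pos1"].to_numpy()
    pos2 = df["pos2"].to_numpy()

    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        j = i + 1
        while j < n and key[j] == key[i] and pos1[j] - pos1[i] <= max_offset:
            if abs(int(pos2[j]) - int(pos2[i])) <= max_offset:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
            j += 1

    roots = np.array([find(i) for i in range(n)])
    score = (df["mapq1"] + df["mapq2"]).to_numpy()
    pid = df["pair_id"].to_numpy()
    keep = np.zeros(n, dtype=bool)
    order = np.lexsort((pid, -score, roots))  # per root: best score, then pair_id
    seen: set = set()
    for i in order:
        r = roots[i]
        if r not in seen:
            seen.add(r)
            keep[i] = True
    return df[keep].copy(), df[~keep].copy()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _frag_bounds(pairs: pd.DataFrame, libs: dict
                 ) -> tuple[np.ndarray, np.ndarray]:
    fmin = pairs["library"].map(lambda l: libs[l].frag_min).to_numpy()
    fmax = pairs["library"].map(lambda l: libs[l].frag_max).to_numpy()
    return fmin, fmax


def classify_pairs(pairs: pd.DataFrame, libs: dict) -> pd.Series:
    """Vectorised normal/aberrant call for canonically ordered pairs.

    A pair is normal iff both reads map to the same contig, in inward
    facing (FR) orientation, with an outer span inside the library's
    fragment-length range; anything else is aberrant.
    """
    if len(pairs) == 0:
        return pd.Series([], dtype=object)
    fmin, fmax = _frag_bounds(pairs, libs)
    same = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    fr = ((pairs["strand1"] == "+") & (pairs["strand2"] == "-")).to_numpy()
    span = (pairs["pos2"] - pairs["pos1"] + 1).to_numpy()
    normal = same & fr & (span >= fmin) & (span <= fmax)
    return pd.Series(np.where(normal, NORMAL, ABERRANT), index=pairs.index)


def classify_pair(pair, lib: LibrarySpec) -> str:
    """Single-record classification; ``pair`` is a mapping with the
    PAIR_COLUMNS fields (canonically ordered ends)."""
    same = pair["chrom1"] == pair["chrom2"]
    fr = pair["strand1"] == "+" and pair["strand2"] == "-"
    span = pair["pos2"] - pair["pos1"] + 1
    if same and fr and lib.frag_min <= span <= lib.frag_max:
        return NORMAL
    return ABERRANT


# ---------------------------------------------------------------------------
# realignment recheck (in-repo substitute for an external full aligner pass)
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer seed index over the forward strand of a reference."""

    def __init__(self, ref: ReferenceGenome, k: int = 13):
        self.ref = ref
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in ref.contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((name, i))

    def placements(self, read: str, max_mismatches: int = 2
                   ) -> list[tuple[str, int, str]]:
        """Seed-and-extend placements of ``read`` with <= max_mismatches.

        Returns (chrom, pos_5prime, strand) triples. Seeds are taken at the
        two ends of the read on both strands; a placement is missed only if
        mismatches hit both seed regions.
        """
        k, out = self.k, set()
        for strand, seq in (("+", read), ("-", revcomp(read))):
            cands = set()
            for off in (0, len(seq) - k):
                for chrom, pos in self.index.get(seq[off:off + k], []):
                    cands.add((chrom, pos - off))
            for chrom, start in cands:
                refseq = self.ref.contigs[chrom]
                if start < 0 or start + len(seq) > len(refseq):
                    continue
                mism = sum(a != b for a, b in zip(seq, refseq[start:start + len(seq)]))
                if mism <= max_mismatches:
                    p5 = start if strand == "+" else start + len(seq) - 1
                    out.add((chrom, p5, strand))
        return sorted(out)


def realignment_recheck(aberrant: pd.DataFrame, ref: ReferenceGenome,
                        lib_specs: dict, k: int = 13, max_mismatches: int = 2,
                        index: Optional[KmerIndex] = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard aberrant pairs for which an alternative placement of either
    read yields a concordant (normal) configuration.

    Aligners occasionally place a read on a homologous copy instead of its
    true locus, turning a normal pair into an apparent rearrangement; this
    recheck re-places each read by k-mer seed-and-extend and drops the pair
    if any placement combination classifies as normal. Requires ``seq1``/
    ``seq2`` columns; when sequences are absent the stage is skipped with a
    warning (alignment-level simulation may omit them).
    """
    if len(aberrant) == 0:
        return aberrant, aberrant.head(0)
    if "seq1" not in aberrant.columns or "seq2" not in aberrant.columns:
        log.warning("realignment recheck skipped: pair records carry no sequences")
        return aberrant, aberrant.head(0)
    idx = index if index is not None else KmerIndex(ref, k)
    drop = np.zeros(len(aberrant), dtype=bool)
    for i, (_, row) in enumerate(aberrant.iterrows()):
        lib = lib_specs[row["library"]]
        # read seq is stored as sequenced; reference-strand placements of
        # the raw sequence already cover both orientations
        p1s = set(idx.placements(row["seq1"], max_mismatches))
        p2s = set(idx.placements(row["seq2"], max_mismatches))
        p1s.add((row["chrom1"], int(row["pos1"]), row["strand1"]))
        p2s.add((row["chrom2"], int(row["pos2"]), row["strand2"]))
        if _any_concordant(p1s, p2s, lib):
            drop[i] = True
    return aberrant[~drop].copy(), aberrant[drop].copy()


def _any_concordant(p1s, p2s, lib: LibrarySpec) -> bool:
    for c1, p1, s1 in p1s:
        for c2, p2, s2 in p2s:
            if c1 != c2 or s1 == s2:
                continue
            (pp, ps), (mp, ms) = sorted(((p1, s1), (p2, s2)))
            if ps != "+" or ms != "-":
                continue
            span = mp - pp + 1
            if lib.frag_min <= span <= lib.frag_max:
                return True
    return False


# ---------------------------------------------------------------------------
# staged triage
# ---------------------------------------------------------------------------

def triage_pairs(pairs: pd.DataFrame, lib_specs: dict, mapq_threshold: int = 30,
                 max_offset: int = 2, ref: Optional[ReferenceGenome] = None,
                 recheck_k: int = 13) -> tuple[dict, dict]:
    """Run the fixed mapq -> dedup -> classify -> recheck cascade.

    Returns ``(tables, counts)`` where tables holds the DataFrames for each
    label and counts the per-stage bookkeeping. The label partition is
    exact: every input pair lands in exactly one table.
    """
    kept, lowq = filter_mapq(pairs, mapq_threshold)
    uniq, dups = remove_duplicates(kept, max_offset)
    labels = classify_pairs(uniq, lib_specs)
    normal = uniq[labels == NORMAL]
    aberrant = uniq[labels == ABERRANT]
    if ref is not None and "seq1" in pairs.columns:
        aberrant, rechecked = realignment_recheck(aberrant, ref, lib_specs,
                                                  k=recheck_k)
    else:
        rechecked = aberrant.head(0)
    tables = {NORMAL: normal, ABERRANT: aberrant,
              DISCARDED_LOWMAPQ: lowq, DISCARDED_DUPLICATE: dups,
              DISCARDED_NORMAL_RECHECK: rechecked}
    counts = {
        "input_pairs": len(pairs),
        "post_mapq": len(kept),
        "post_dedup": len(uniq),
        "normal": len(normal),
        "aberrant": len(aberrant),
        "discarded_lowmapq": len(lowq),
        "discarded_duplicate": len(dups),
        "discarded_normal_recheck": len(rechecked),
    }
    return tables, counts
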