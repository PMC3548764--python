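"""Readers and writers for the on-disk formats.

In-memory coordinates are 0-based half-open throughout; GFF3 is converted
to and from its 1-based closed convention on read/write, BEDPE and BED are
written 0-based half-open. All round-trips are identity on valid inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Breakend, GeneModel, JunctionCandidate, LibrarySpec, PAIR_COLUMNS,
    ReferenceGenome,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(ref: ReferenceGenome, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in ref.contigs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # wraps at 60 columns


def read_fasta(path) -> ReferenceGenome:
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("contig %s: lowercase bases uppercased on read", rec.id)
        contigs.append((rec.id, seq.upper()))
    if not contigs:
        log.warning("FASTA file %s contains no sequences", path)
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene/exon/CDS features (1-based closed on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tsvfuse\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsvfuse\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")
            if g.is_coding:
                fh.write(f"{g.chrom}\tsvfuse\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.cds;Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            start, end = int(start) - 1, int(end)  # to 0-based half-open
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                order.append(gid)
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [],
                              "cds": None, "span": (start, end), "line": lineno}
            elif ftype in ("exon", "CDS"):
                gid = fields.get("Parent")
                if gid not in genes:
                    raise FormatError(f"{path}:{lineno}: {ftype} before its gene")
                rec = genes[gid]
                lo, hi = rec["span"]
                if start < lo or end > hi:
                    raise FormatError(
                        f"{path}:{lineno}: {ftype} outside gene span of {gid}")
                if ftype == "exon":
                    rec["exons"].append((start, end))
                else:
                    rec["cds"] = (start, end)
    out = []
    for gid in order:
        rec = genes[gid]
        cds_start, cds_end = rec["cds"] if rec["cds"] else (None, None)
        if rec["cds"] is not None:
            # both CDS endpoints must fall inside exons (introns inside a
            # multi-exon CDS are fine; an endpoint in an intron is not)
            covered = any(s <= cds_start < e for s, e in rec["exons"]) and \
                any(s < cds_end <= e for s, e in rec["exons"])
            if not covered:
                raise FormatError(
                    f"{path}: CDS of {gid} crosses an exon boundary "
                    f"(line {rec['line']})")
        out.append(GeneModel(gid, rec["chrom"], rec["strand"],
                             tuple(sorted(rec["exons"])), cds_start, cds_end))
    return out


# ---------------------------------------------------------------------------
# pairs TSV
# ---------------------------------------------------------------------------

def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pair columns {missing}")
    return df


def read_sam_pairs(path, library: str = "sam") -> pd.DataFrame:
    """Minimal SAM-convention ingestion: RNAME/POS/FLAG-strand/MAPQ of
    primary alignments, paired by QNAME. 1-based POS converted to 0-based
    leftmost; the 5' position is the rightmost base for reverse reads."""
    ends: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos, mapq = f[0], int(f[1]), f[2], int(f[3]), int(f[4])
            if flag & 0x900 or rname == "*":
                continue
            seqlen = len(f[9]) if f[9] != "*" else 0
            strand = "-" if flag & 0x10 else "+"
            p5 = pos - 1 if strand == "+" else pos - 1 + seqlen - 1
            ends.setdefault(qname, []).append((rname, p5, strand, mapq))
    rows = []
    for qname, es in ends.items():
        if len(es) != 2:
            continue
        (c1, p1, s1, q1), (c2, p2, s2, q2) = sorted(es[:2], key=lambda e: (e[0], e[1]))
        rows.append({"pair_id": qname, "library": library,
                     "chrom1": c1, "pos1": p1, "strand1": s1, "mapq1": q1,
                     "chrom2": c2, "pos2": p2, "strand2": s2, "mapq2": q2})
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# BEDPE candidates (+ sidecar TSV with non-BEDPE fields)
# ---------------------------------------------------------------------------

def write_bedpe(candidates: Sequence[JunctionCandidate], path,
                sidecar: Optional[str] = None) -> None:
    rows = []
    side_rows = []
    for c in candidates:
        rows.append([c.breakend_a.chrom, c.breakend_a.lo, c.breakend_a.hi,
                     c.breakend_b.chrom, c.breakend_b.lo, c.breakend_b.hi,
                     c.id, c.support, c.strand_a, c.strand_b])
        side_rows.append({
            "id": c.id, "libraries": ",".join(sorted(c.libraries)),
            "filter_state": ",".join(c.filter_state) or ".",
            "confirmation": c.confirmation,
            "matched_steps": ";".join(f"{s.chrom}:{s.midpoint}" for s in c.matched_steps) or ".",
            "frag_max": c.frag_max,
        })
    pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                                "end2", "id", "support", "strand1", "strand2"]
                 ).to_csv(path, sep="\t", index=False, header=False)
    if sidecar:
        pd.DataFrame(side_rows).to_csv(sidecar, sep="\t", index=False)


def read_bedpe(path, sidecar: Optional[str] = None) -> list[JunctionCandidate]:
    from .model import strand_to_side
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "id", "support", "strand1", "strand2"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom1": str, "chrom2": str})
    meta = None
    if sidecar:
        meta = pd.read_csv(sidecar, sep="\t").set_index("id")
    cands = []
    for _, row in df.iterrows():
        for s, e in ((row["start1"], row["end1"]), (row["start2"], row["end2"])):
            if s >= e:
                raise FormatError(f"{path}: start >= end in record {row['id']}")
        if row["strand1"] not in "+-" or row["strand2"] not in "+-":
            raise FormatError(f"{path}: malformed strand in record {row['id']}")
        c = JunctionCandidate(
            id=str(row["id"]),
            breakend_a=Breakend(row["chrom1"], int(row["start1"]), int(row["end1"]),
                                strand_to_side(row["strand1"])),
            breakend_b=Breakend(row["chrom2"], int(row["start2"]), int(row["end2"]),
                                strand_to_side(row["strand2"])),
            strand_a=row["strand1"], strand_b=row["strand2"],
            support=int(row["support"]))
        if meta is not None and c.id in meta.index:
            m = meta.loc[c.id]
            c.libraries = set(str(m["libraries"]).split(",")) - {""}
            c.confirmation = m["confirmation"]
            if str(m["filter_state"]) != ".":
                c.filter_state = str(m["filter_state"]).split(",")
            c.frag_max = int(m["frag_max"])
        cands.append(c)
    keyed = sorted(cands, key=lambda c: (c.breakend_a.chrom, c.breakend_a.lo,
                                         c.breakend_b.chrom, c.breakend_b.lo))
    if [c.id for c in keyed] != [c.id for c in cands]:
        log.info("BEDPE %s was not canonically sorted; sorted on read", path)
    return keyed


def write_truth_bedpe(truths, path) -> None:
    rows = []
    for t in truths:
        rows.append([t.breakend_a.chrom, t.breakend_a.pos, t.breakend_a.pos + 1,
                     t.breakend_b.chrom, t.breakend_b.pos, t.breakend_b.pos + 1,
                     t.junction_id, t.copy_number,
                     "+" if t.breakend_a.side == "left_retained" else "-",
                     "+" if t.breakend_b.side == "left_retained" else "-"])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# SEG-like probe/segment tables, steps BED
# ---------------------------------------------------------------------------

def write_probes(profile, path) -> None:
    profile.probes.to_csv(path, sep="\t", index=False)


def read_probes(path):
    from .model import CNProfile
    df = pd.read_csv(path, sep="\t")
    return CNProfile(df.sort_values(["chrom", "pos"]).reset_index(drop=True))


def write_segments(segments, path) -> None:
    pd.DataFrame([{"chrom": s.chrom, "start": s.start, "end": s.end,
                   "n_probes": s.n_probes, "mean_log2": s.mean_log2}
                  for s in segments]).to_csv(path, sep="\t", index=False)


def write_steps_bed(steps, path) -> None:
    with open(path, "w") as fh:
        for s in steps:
            fh.write(f"{s.chrom}\t{s.lo}\t{s.hi}\tstep\t{s.delta_log2:.4f}\t.\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------------------
# panel BEDPE, fusion report, JSON reports, FASTQ
# ---------------------------------------------------------------------------

def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fusion_report(fusions, path) -> None:
    """Fusion table: 5'/3' partners, kind F/R, frame, junctions crossed."""
    rows = []
    for f in fusions:
        rows.append({
            "five_prime_gene": f.five_prime_gene,
            "five_prime_exon": f.five_prime_exon,
            "three_prime_gene": f.three_prime_gene,
            "three_prime_exon": f.three_prime_exon,
            "kind": "F" if f.kind == "direct" else "R",
            "in_frame": {"in_frame": "yes", "out_of_frame": "no"}.get(
                f.frame, "indeterminate"),
            "junctions": ",".join(f.junction_ids),
            "alternatives": ",".join(f.alternatives) or ".",
        })
    pd.DataFrame(rows, columns=["five_prime_gene", "five_prime_exon",
                                "three_prime_gene", "three_prime_exon", "kind",
                                "in_frame", "junctions", "alternatives"]
                 ).to_csv(path, sep="\t", index=False)


def write_json_report(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_fastq(pairs: pd.DataFrame, path1, path2) -> None:
    """Optional FASTQ emitter for pairs carrying seq1/seq2 columns."""
    if "seq1" not in pairs.columns:
        raise FormatError("pairs table carries no sequences; simulate with "
                          "with_sequences=True")
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for _, row in pairs.iterrows():
            q = "I" * len(row["seq1"])
            f1.write(f"@{row['pair_id']}/1\n{row['seq1']}\n+\n{q}\n")
            f2.write(f"@{row['pair_id']}/2\n{row['seq2']}\n+\n{q}\n")
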