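"""Reference topologies of the twelve expressed ZR-75-30 fusion genes.

Each fixture reproduces one fusion's topology — direct vs run-through,
donor/acceptor exons, reading-frame outcome, single- or multi-junction path
— on synthetic gene models named after the real partners. Coding sequence
is laid down as a stop-free codon stream so frame calls can be verified by
translating the fused CDS.

These are synthetic stand-ins for the real loci: gene structures are
simplified (uniform 150 bp exons, single transcript per gene) and only the
features that drive fusion prediction are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Breakend, GeneModel, JunctionCandidate, LEFT, RIGHT, ReferenceGenome,
)
from .synthdata import Segment, make_gene

EXON = 150
INTRON = 3_000

#: utr5 length mod 3 controls the coding phase downstream of every exon
#: boundary (exon lengths are multiples of 3): phase = (-utr5) % 3.
_PHASE_UTR5 = {0: 30, 1: 29, 2: 28}


@dataclass
class FusionFixture:
    name: str
    ref: ReferenceGenome
    genes: list
    candidate: Optional[JunctionCandidate] = None
    path: Optional[list] = None           # multi-junction derivative path
    junction_ids: Optional[list] = None
    expected: dict = field(default_factory=dict)


def _codon_stream(n: int) -> str:
    """A stop-free CDS of n bases: GCT repeated, final full codon TAA."""
    s = ("GCT" * (n // 3 + 1))[:n]
    if n >= 3 and n % 3 == 0:
        s = s[:-3] + "TAA"
    return s


def _lay_gene(contig: bytearray, gene: GeneModel) -> None:
    """Write the gene's coding stream into the contig (``+`` genes only)."""
    if not gene.is_coding:
        return
    cds = _codon_stream(gene.total_cds_length())
    i = 0
    for s, e in gene.exons:
        lo, hi = max(s, gene.cds_start), min(e, gene.cds_end)
        if lo < hi:
            contig[lo:hi] = cds[i:i + hi - lo].encode()
            i += hi - lo


def _plain_contig(length: int) -> bytearray:
    return bytearray(b"ACAG" * (length // 4 + 1))[:length]


def _gene(gene_id: str, chrom: str, n_exons: int, phase_key: int,
          start: int = 10_000, utr5_override: Optional[int] = None) -> GeneModel:
    utr5 = utr5_override if utr5_override is not None else _PHASE_UTR5[phase_key]
    return make_gene(gene_id, chrom, "+", start, [EXON] * n_exons,
                     [INTRON] * (n_exons - 1), utr5=utr5, utr3=30)


def _intron_mid(gene: GeneModel, intron_after_exon: int) -> int:
    e_end = gene.exons[intron_after_exon - 1][1]
    n_start = gene.exons[intron_after_exon][0]
    return (e_end + n_start) // 2


def _contig_for(gene: GeneModel, pad: int = 60_000) -> int:
    return gene.end + pad


def _single(name: str, donor_name: str, acceptor_name: str, kind: str,
            donor_exon: int, acceptor_exon: int, frame: str,
            donor_phase: int = 0, acceptor_phase: int = 0,
            donor_utr5: Optional[int] = None,
            decoy_partner: Optional[str] = None) -> FusionFixture:
    cd, ca = f"{name}_chrD", f"{name}_chrA"
    donor = _gene(donor_name, cd, donor_exon + 1, donor_phase,
                  utr5_override=donor_utr5)
    genes = [donor]
    if kind == "direct":
        acceptor = _gene(acceptor_name, ca, acceptor_exon + 1, acceptor_phase)
        bp_a = _intron_mid(acceptor, acceptor_exon - 1)
        genes.append(acceptor)
    else:
        acceptor = _gene(acceptor_name, ca, max(acceptor_exon + 1, 3),
                         acceptor_phase, start=60_000)
        bp_a = 10_000  # intergenic landing upstream of the intact acceptor
        genes.append(acceptor)
        if decoy_partner:
            genes.append(_gene(decoy_partner, ca, 3, 0,
                               start=acceptor.end + 40_000))
    bp_d = _intron_mid(donor, donor_exon)
    contigs = {cd: _plain_contig(_contig_for(donor)),
               ca: _plain_contig(_contig_for(genes[-1]))}
    for g in genes:
        _lay_gene(contigs[g.chrom], g)
    ref = ReferenceGenome([(c, bytes(b).decode()) for c, b in contigs.items()])
    cand = JunctionCandidate(
        id=f"fx_{name}",
        breakend_a=Breakend(cd, bp_d - 50, bp_d + 50, LEFT),
        breakend_b=Breakend(ca, bp_a - 50, bp_a + 50, RIGHT),
        strand_a="+", strand_b="-", support=2)
    return FusionFixture(
        name=name, ref=ref, genes=genes, candidate=cand,
        expected={"five_prime_gene": donor_name, "five_prime_exon": donor_exon,
                  "three_prime_gene": acceptor_name,
                  "three_prime_exon": acceptor_exon,
                  "kind": kind, "frame": frame})


def _multi(name: str, donor_name: str, acceptor_name: str, donor_exon: int,
           acceptor_exon: int, frame: str, donor_phase: int = 0,
           acceptor_phase: int = 0, insert_len: int = 10_400) -> FusionFixture:
    cd, ca, ci = f"{name}_chrD", f"{name}_chrA", f"{name}_chrI"
    donor = _gene(donor_name, cd, donor_exon + 1, donor_phase)
    acceptor = _gene(acceptor_name, ca, acceptor_exon + 1, acceptor_phase)
    bp_d = _intron_mid(donor, donor_exon)
    bp_a = _intron_mid(acceptor, acceptor_exon - 1)
    contigs = {cd: _plain_contig(_contig_for(donor)),
               ca: _plain_contig(_contig_for(acceptor)),
               ci: _plain_contig(insert_len + 20_000)}
    _lay_gene(contigs[cd], donor)
    _lay_gene(contigs[ca], acceptor)
    ref = ReferenceGenome([(c, bytes(b).decode()) for c, b in contigs.items()])
    path = [Segment(cd, 0, bp_d),
            Segment(ci, 5_000, 5_000 + insert_len),
            Segment(ca, bp_a, ref.length(ca))]
    return FusionFixture(
        name=name, ref=ref, genes=[donor, acceptor], path=path,
        junction_ids=[f"fx_{name}_j1", f"fx_{name}_j2"],
        expected={"five_prime_gene": donor_name, "five_prime_exon": donor_exon,
                  "three_prime_gene": acceptor_name,
                  "three_prime_exon": acceptor_exon,
                  "kind": "direct", "frame": frame,
                  "n_junctions": 2})


def build_fixture_bank() -> list[FusionFixture]:
    """The twelve expressed-fusion topologies, frame outcomes as verified."""
    return [
        # complex two-junction fusion with a 10.4 kb genomic insert
        _multi("APPBP2_PHF20L1", "APPBP2", "PHF20L1", 9, 3, "in_frame"),
        _single("COL14A1_SKAP1", "COL14A1", "SKAP1", "direct", 2, 5, "in_frame"),
        _single("TAOK1_PCGF2", "TAOK1", "PCGF2", "direct", 8, 2, "in_frame"),
        _single("USP32_CCDC49", "USP32", "CCDC49", "direct", 5, 3,
                "out_of_frame", donor_phase=1, acceptor_phase=0),
        # donor broken in its 5' UTR: frame cannot be called
        _single("BCAS3_HOXB9", "BCAS3", "HOXB9", "direct", 1, 2,
                "indeterminate", donor_utr5=EXON + 30),
        _single("TRPS1_LASP1", "TRPS1", "LASP1", "runthrough", 3, 2, "in_frame"),
        _single("ERBB2_BCAS3", "ERBB2", "BCAS3", "runthrough", 10, 2,
                "out_of_frame", donor_phase=2, acceptor_phase=0),
        # the true downstream partner is flanked by a farther alternative
        _single("DDX5_DEPDC6", "DDX5", "DEPDC6", "runthrough", 4, 2,
                "in_frame", decoy_partner="DECOY1"),
        _multi("PLEC1_ENPP2", "PLEC1", "ENPP2", 8, 2, "in_frame"),
        _single("TIAM1_NRIP1", "TIAM1", "NRIP1", "direct", 1, 2, "in_frame"),
        _single("ZMYM4_OPRD1", "ZMYM4", "OPRD1", "direct", 26, 2,
                "out_of_frame", donor_phase=1, acceptor_phase=0),
        _single("TIMM23_ARHGAP32", "TIMM23", "ARHGAP32", "runthrough", 6, 2,
                "out_of_frame", donor_phase=2, acceptor_phase=0),
    ]


def run_fixture(fx: FusionFixture, runthrough_window: int = 1_000_000) -> list:
    """Predict the fixture's fusion(s) with the production code paths."""
    from . import fusion as fusion_mod
    if fx.path is not None:
        return fusion_mod.trace_multi_junction_transcript(
            fx.path, fx.genes, junction_ids=fx.junction_ids,
            runthrough_window=runthrough_window)
    fusions, _ = fusion_mod.predict_fusion(fx.candidate, fx.genes,
                                           runthrough_window)
    return fusions


def fixture_concordance(fixtures: Optional[list] = None) -> tuple[int, list]:
    """Count fixtures whose prediction matches the expected outcome."""
    fixtures = fixtures if fixtures is not None else build_fixture_bank()
    ok, failures = 0, []
    for fx in fixtures:
        preds = run_fixture(fx)
        match = False
        for p in preds:
            fields = {"five_prime_gene": p.five_prime_gene,
                      "five_prime_exon": p.five_prime_exon,
                      "three_prime_gene": p.three_prime_gene,
                      "three_prime_exon": p.three_prime_exon,
                      "kind": p.kind, "frame": p.frame}
            if fx.expected.get("n_junctions"):
                fields["n_junctions"] = len(p.junction_ids)
            if fields == fx.expected:
                match = True
        if match:
            ok += 1
        else:
            failures.append((fx.name, preds))
    return ok, failures
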