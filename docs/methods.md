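# Methods

This note documents the models and procedures implemented in `svfuse`, the
assumptions behind them, the parameters that matter, and what the packaged
simulations do and do not demonstrate.

## The analysis

The pipeline reconstructs a genome-wide rearrangement screen of a cancer
genome from paired-end sequencing, in four stages.

**1. Read-pair triage** (`svfuse.readpairs`). Each sequenced fragment is
represented by its two mapped ends (contig, 5' position, strand, mapping
quality). Pairs pass through a fixed cascade:

1. *Mapping quality*: a pair is discarded when either read scores below 30
   (the boundary is strict: 30 itself is kept).
2. *PCR duplicates*: two pairs are duplicates when both ends share contig
   and strand and both 5' positions differ by at most 2 bp — exact
   duplicates plus "offset duplicates" in which a PCR primer lost one or
   two 3' bases. Duplicate groups are connected components of this
   relation; the member with the highest summed mapping quality survives
   (ties broken by smallest pair id).
3. *Classification*: a pair is **normal** iff both reads map to the same
   contig, inward-facing (FR), with an outer span inside the library's
   fragment-length range; anything else is **aberrant**.
4. *Realignment recheck*: aberrant pairs are re-placed by k-mer
   seed-and-extend (k = 13, up to 2 mismatches, both strands); a pair is
   discarded when any alternative placement combination is concordant.
   This catches reads mis-assigned to a homologous copy of their true
   locus. It operates on read sequences and is skipped with a warning when
   the pair records carry none (alignment-level simulation).

The cascade order (mapq → duplicates → classification → recheck) is a
convention fixed so stage counts are reproducible; the underlying filters
are set-membership tests, so the final kept set does not depend on it.

**2. Junction calling** (`svfuse.svcall`). Each read of an aberrant pair
implies a breakpoint interval extending from its 5' position in the read's
facing direction by `frag_max − read_length`. Two pairs are *consistent*
when they share the contig pair and orientation class and both implied
intervals overlap; clusters are maximal consistent groups under transitive
closure, and a candidate needs at least **2** supporting pairs. The
candidate's breakend interval is the intersection of its members' implied
intervals (if a transitive chain empties the intersection, the envelope is
used instead). Candidates then pass three filters, each recording its
removal reason:

* intra-chromosomal candidates spanning **< 10 kb** between breakend
  midpoints (exactly 10 kb is kept) — most such events are polymorphisms
  or outsize fragments;
* candidates matching a **panel of normals** junction (same orientation
  class, both breakends within the widest contributing `frag_max`);
* deletion/duplication-type intra-chromosomal candidates reciprocally
  overlapping a known germline-CNV **blacklist** interval by ≥ 50%.

A surviving candidate is *confirmed* when it is supported by **two or more
libraries**, or when a breakend lies within **10 kb** of a copy-number
step. One-breakend matching is used because the partner breakend of an
unbalanced junction need not leave a step. An externally determined
breakpoint list (e.g. from chromosome-sorting array data) can be supplied
as additional pseudo-steps. Unconfirmed candidates are retained but
flagged, mirroring a downstream orthogonal-validation workflow that is out
of scope here.

**3. Copy-number integration** (`svfuse.cnsteps`). Probe log-ratios are
segmented by transparent recursive binary segmentation: the split
maximising the between-side mean difference is accepted while
`|Δmean| ≥ 0.3` (log2) and both sides keep ≥ 5 probes. This is a
deliberately simple substitute for allele-specific segmentation algorithms:
segmentation is used here only to confirm breakpoint positions, for which a
two-parameter change-point fit suffices. Steps are adjacent-segment pairs
with `|Δmean| ≥ 0.3`; the step interval spans the inter-probe gap between
segments. On noiseless input the fit is exact; under Gaussian noise
(σ = 0.1) a Δ = 1 step is located within one probe spacing in ≥ 95% of
seeded draws (tested).

**4. Fusion prediction** (`svfuse.fusion`). For each confirmed junction we
ask whether an overlapping gene retains its 5' or its 3' end in the
derivative chromosome, considering both reading directions across the
junction:

* a **direct fusion** joins a donor (5' end retained, transcribing into
  the junction) to an acceptor (3' end retained, transcribing away from
  it); the transcript splices the donor's last fully retained exon to the
  first acceptor exon whose splice acceptor lies 3' of the junction;
* a **run-through fusion** forms when the donor lands in gene-free
  sequence: transcription continues into the nearest *intact* downstream
  gene (within a 1 Mb window, configurable) in concordant orientation,
  splicing into its first splice acceptor — exon 2, since exon 1 has no
  acceptor site. When several downstream partners qualify, the nearest is
  reported and the others listed as alternatives (a screen that reports
  only one candidate can obscure the expressed partner — the motivation
  for listing alternatives).
* every gene-overlapping breakend not absorbed into a fusion is reported
  as a **gene break** with the retained end annotated — gene breakage
  being itself a significant mutation class.

**Reading frame** compares the coding phase at the donor's last retained
exon with the phase at the acceptor exon's start; phases are cumulative
CDS length mod 3. The call is *indeterminate* when either side falls
outside translated sequence (donor break in the 5' UTR or past the stop;
acceptor exon upstream of the CDS start or in the 3' UTR) or a partner is
non-coding. Frame arithmetic is corroborated in tests by translating the
concatenated fused CDS and checking for the absence of a premature stop.

**Multi-junction transcripts** (`trace_multi_junction_transcript`) walk
transcription along an ordered derivative segment path: anonymous segments
are traversed as intronic inserts; a gene oriented against the walk inside
an insert disrupts splicing and aborts the trace; the first co-oriented
gene whose 3' end survives inside a segment becomes the acceptor. A
two-segment path reduces exactly to single-junction prediction (tested).

**Junction sequence analysis** (`svfuse.junctionseq`). Microhomology is
measured as the ambiguous-placement length: the maximal L such that the
last L retained bases on the 5' side equal the first L retained bases on
the 3' side. Junctions are blunt, microhomologous, or inserted — mutually
exclusive categories; the 1–4 bp homology band is reported separately as
the hallmark of microhomology-mediated repair. An insert of ≥ 10 bp that
matches the genome exactly and uniquely (both strands searched) is
classified as a **genomic shard** and its donor locus reported;
near-matches are out of scope to keep the classification deterministic.

**Estimators** (`svfuse.estimates`).

* *Physical coverage* N·f/G: breakpoint sampling depth is governed by
  fragment length, not read length. For the subtetraploid breast-cancer
  genome scenario the ploidy-adjusted genome size is fixed at
  4 × 3.1 Gb = 12.4 Gb; with 43 million pairs of 504 bp fragments this
  gives 1.75 ≈ 1.7-fold coverage of single-copy breakpoints. The genome
  size is a documented constant, not a published figure. (The analogous
  arithmetic for a 1.25-million-pair 3 kb mate-pair lane gives ≈ 0.30×,
  not the 0.5× sometimes quoted for such libraries; whether such counts
  are per-lane or summed is ambiguous, so the mate-pair coverage figure is
  not reproduced here.)
* *Detection model*: a junction present in c copies at per-copy coverage λ
  is supported by X ~ Poisson(c·λ) fragments and detected when X ≥ 2. At
  λ = 1.7 this gives P ≈ 0.51 for single-copy junctions and ≈ 1 for a
  20-copy amplicon — the mechanism behind the large sensitivity gap
  between amplified and unamplified breakpoints.
* *Capture–recapture*: two independent incomplete fusion catalogues of
  sizes n₁, n₂ sharing m entries give the Lincoln–Petersen total
  n₁·n₂/m — the uncorrected ratio, reported exact and rounded, with no
  Chapman adjustment and no interval (none is meaningful at these list
  sizes). With catalogues of 9 and 6 sharing 3, the estimate is 18.
* *Extrapolation*: an observed mean count divided by an assumed detection
  sensitivity; the sensitivity is a free input, e.g. 4.2 / 0.40 = 10.5.

## The synthetic-data generator

`svfuse.synthdata` emulates the statistical structure the analysis
assumes, not sequencing chemistry:

* **Genome**: uniform-composition random contigs at a requested GC
  fraction (0.41 by default); desk scale, 2–10 Mb over 3–5 contigs.
* **Gene models**: non-overlapping, both strands, ≥ 2 exons each, with a
  CDS whose exon phases follow the standard recurrence
  `phase_{k+1} = (phase_k + cds_len_k) mod 3`.
* **Derivative genome**: rearrangement events (deletion, inversion, tandem
  duplication, translocation, multi-fragment amplicon, shard insertion)
  are ordered donor-segment paths with a copy number. Every
  non-reference-contiguous adjacency emits exactly one truth record.
  Donor segments shorter than 50 bp fold into the junction as inserts.
  Requested microhomology is planted by editing the bases entering the
  junction's 3' flank, then re-measured from the final reference, so the
  recorded truth is exact by construction; overlapping edit regions raise
  a conflict error.
* **Read pairs**: fragments land uniformly along the derivative weighted
  by copy number (so depth scales with copy number); fragment lengths are
  triangular on [frag_min, frag_max] with mode frag_median (404/504/619 bp
  for the 500 bp library, 2.5/3.0/3.6 kb for mate pairs; 36 bp reads).
  Mapping back to the reference is a coordinate transform through the
  known segment map — reads crossing a junction are dropped, as a 36 bp
  read spanning a breakpoint would fail to align. Artefacts are injected
  at configurable rates: exact and 1–2 bp offset PCR duplicates, and
  coligation chimeras joining two unrelated fragments. No published
  chimera rate exists; the default in example configurations (0.001/pair)
  is a free parameter. Mapping quality is 60 except for reads overlapping
  designated repeat intervals, which draw uniformly from [0, 30) — the
  minimal mechanism that exercises the mapq filter.
* **Probe profile**: probes every `spacing` bp report
  `log2(max(cn, 0.25)/ploidy) + N(0, σ)` over the derivative's true copy
  map.
* **Panel of normals**: a pool of polymorphic deletion junctions, each
  carried by a random non-empty subset of 18 simulated normals.

What the generator does **not** model: GC-dependent coverage, base errors,
aligner behaviour, repeats beyond the designated low-mapq intervals,
allele-specific copy number, isoform structure. Passing tests therefore
demonstrate the correctness of the bespoke computations (triage rules,
clustering geometry, filter logic, fusion/frame calls, junction-sequence
measurement, estimators) under the stated sampling model — not performance
on real libraries, where alignment artefacts and repeat structure dominate
the error budget.

## Packaged scenarios

`svfuse.demo.build_demo` is a desk-scale analogue of a heavily rearranged
breast-cancer cell-line genome: five contigs (2.8 Mb total), a
coamplification of six 20 kb fragments alternating between two chromosomes
at copy number 20, a 160 kb interstitial deletion that fuses two genes in
frame (exon 1 → exon 2), a balanced 100 kb inversion, and a translocation
whose broken gene runs through, out of frame, into an intact gene 30 kb
downstream (exon 6 → exon 2); two further fusions sit on amplicon
junctions. Four of its seven "resolved" junctions carry 1–4 bp planted
microhomology and one carries a unique 15 bp shard. Default sequencing
depth is 15× per-copy physical coverage for the 500 bp library and 8× for
each mate-pair library — deep enough that recovery is limited by the
pipeline, not sampling, so the end-to-end expectation is recall and
precision 1.0 in artifact-free runs. A full run (≈ 230 k pairs, 7 k
probes) completes in a few seconds on one CPU.

`svfuse.demo.build_coverage_scenario` isolates the coverage model: 30
single-copy and 10 twenty-copy inter-chromosomal junctions, with the pair
count chosen analytically so the expected number of *usable* spanning
fragments per single-copy junction (those whose reads clear the junction)
is 1.7. Support-only detection (≥ 2 pairs) on 25 replicates reproduces the
amplified/unamplified sensitivity asymmetry and agrees with the Poisson
model within 3 binomial standard errors.

Simulation sizes throughout (20 end-to-end replicates, 25 calibration
replicates, 2.8 Mb genomes) were chosen as the smallest at which the
binomial error bars are comfortably inside the tested tolerances.

## Numerical and design choices

* Coordinates are 0-based half-open in memory; GFF3 converts to 1-based
  closed on disk; BEDPE and BED are 0-based half-open. Breakend sides are
  `left_retained`/`right_retained`; a `+`-strand read witnesses a
  left-retained breakend.
* Candidate span is measured between breakend interval midpoints;
  "less than 10 kb" is strict.
* Clustering tie-breaks: candidates are ordered and numbered by
  (chrom_a, lo_a, chrom_b, lo_b); duplicate-group ties by smallest pair
  id. All generators and the pipeline are byte-deterministic given seeds.
* Whether the mapq filter precedes duplicate marking is a convention (the
  fixed cascade above); both orders give the same surviving set because
  duplicate-group winners are chosen by mapq.
* Gene models are single-transcript; cryptic exons and isoform selection
  are out of scope. The run-through window (1 Mb) is a configurable
  convention — no principled bound exists for how far downstream
  transcription can productively run.
* Binary segmentation recursion accepts a split only at `|Δmean| ≥ 0.3`
  with ≥ 5 probes per side; chromosomes with < 10 probes return one
  segment with a warning.

## Re-analysis hooks for published per-variant tables

`tests/test_acceptance.py` contains two checks that re-analyse the
published per-variant supplementary tables of the ZR-75-30 screen (125
confirmed variants; seven Sanger-resolved junction sequences). Those
tables are third-party supplementary data and are not redistributed with
this package; the tests fail with instructions until the files are placed
under `data/zr7530/` (`confirmed_variants.tsv` with columns
`chrom1 pos1 chrom2 pos2`; `junction_sequences.tsv` with columns
`junction_id flank5 flank3 observed`).

## Known limitations

* No split-read or local-assembly breakpoint refinement: resolution is
  bounded by fragment geometry (breakend intervals up to
  `frag_max − read_length`).
* The realignment recheck's seed-and-extend can miss an alternative
  placement when mismatches hit both seed k-mers; the exhaustive-scan
  oracle in the tests bounds this on fixtures.
* Shard detection is exact-match only; a mutated shard is reported as an
  untemplated insert.
* The transitive-closure clustering can, in principle, chain pairs that
  are not mutually consistent; on junction-generated clusters all members
  share the junction point and the emitted clusters are verified pairwise
  consistent in tests.
* Capture–recapture assumes the two catalogues sample fusions
  independently with homogeneous capturability; amplified fusions are in
  reality easier for both methods, which biases the estimate downward.
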