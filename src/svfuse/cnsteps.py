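"""Copy-number integration: segment a CGH-like probe profile into
piecewise-constant segments, extract change-points (steps), match junction
candidates to steps, and report detection sensitivity stratified by
amplification.

Segmentation is a transparent recursive binary segmentation: at each level
the split maximising the between-side mean difference is accepted while
``|delta mean| >= step_threshold`` and both sides keep ``min_probes``
probes. An unbalanced rearrangement junction leaves a copy-number step at
its breakpoint, so steps confirm junctions independently of read support.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .model import CNProfile, CNSegment, CNStep, JunctionCandidate, TruthRecord

log = logging.getLogger(__name__)


def _best_split(vals: np.ndarray, min_probes: int) -> tuple[int, float]:
    """Split index t (left = vals[:t]) maximising |mean_l - mean_r|."""
    n = len(vals)
    cum = np.cumsum(vals)
    t = np.arange(min_probes, n - min_probes + 1)
    mean_l = cum[t - 1] / t
    mean_r = (cum[-1] - cum[t - 1]) / (n - t)
    delta = np.abs(mean_l - mean_r)
    best = int(np.argmax(delta))
    return int(t[best]), float(delta[best])


def segment_profile(profile: CNProfile, step_threshold: float = 0.3,
                    min_probes: int = 5) -> list[CNSegment]:
    """Piecewise-constant fit of the probe profile, one chromosome at a time.

    Chromosomes with fewer than ``2 * min_probes`` probes cannot be split;
    they are returned as a single segment with a logged warning. Splits are
    reported in probe-index order; segment bounds run from the first probe
    position to one past the last probe position.
    """
    segments: list[CNSegment] = []
    df = profile.probes
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        vals = sub["log2_ratio"].to_numpy(dtype=float)
        if len(vals) < 2 * min_probes:
            log.warning("chromosome %s has %d probes (< %d); returning one segment",
                        chrom, len(vals), 2 * min_probes)
            segments.append(_leaf(chrom, pos, vals, 0, len(vals)))
            continue
        stack, out = [(0, len(vals))], []
        while stack:
            lo, hi = stack.pop()
            if hi - lo < 2 * min_probes:
                out.append((lo, hi))
                continue
            t, delta = _best_split(vals[lo:hi], min_probes)
            if delta >= step_threshold:
                # push right first so the output comes back in index order
                stack.append((lo + t, hi))
                stack.append((lo, lo + t))
            else:
                out.append((lo, hi))
        for lo, hi in sorted(out):
            segments.append(_leaf(chrom, pos, vals, lo, hi))
    return segments


def _leaf(chrom, pos, vals, lo, hi) -> CNSegment:
    return CNSegment(chrom=chrom, start=int(pos[lo]), end=int(pos[hi - 1]) + 1,
                     mean_log2=float(vals[lo:hi].mean()), n_probes=hi - lo)


def detect_steps(segments: Sequence[CNSegment], step_threshold: float = 0.3
                 ) -> list[CNStep]:
    """One step per adjacent segment pair with ``|delta mean| >= threshold``.

    The step interval runs from the last probe of the left segment to the
    first probe of the right segment (the breakpoint lies somewhere in the
    inter-probe gap).
    """
    steps = []
    for a, b in zip(segments[:-1], segments[1:]):
        if a.chrom != b.chrom:
            continue
        delta = b.mean_log2 - a.mean_log2
        if abs(delta) >= step_threshold:
            steps.append(CNStep(chrom=a.chrom, lo=a.end - 1, hi=b.start,
                                delta_log2=float(delta)))
    return steps


def match_junction_to_steps(candidate: JunctionCandidate,
                            steps: Sequence[CNStep],
                            tolerance: int = 10_000) -> list[CNStep]:
    """Steps within ``tolerance`` of either candidate breakend midpoint."""
    out = []
    for step in steps:
        for be in (candidate.breakend_a, candidate.breakend_b):
            if be.chrom == step.chrom and abs(be.midpoint - step.midpoint) <= tolerance:
                out.append(step)
                break
    return out


def sensitivity_report(truth: Sequence[TruthRecord], confirmed: Sequence,
                       frag_max: int = 619, amplified_threshold: int = 5
                       ) -> dict:
    """Detection fractions stratified by amplification.

    A truth junction counts as detected when some confirmed candidate has
    both breakends within ``frag_max`` of it. Junctions at copy number
    ``>= amplified_threshold`` are the amplified stratum. Raises on empty
    truth — the report would be meaningless.
    """
    from .svcall import candidate_matches_truth
    if not truth:
        raise ValueError("sensitivity report requires a non-empty truth set")
    strata = {"amplified": [0, 0], "unamplified": [0, 0]}
    for t in truth:
        key = "amplified" if t.copy_number >= amplified_threshold else "unamplified"
        strata[key][1] += 1
        if any(candidate_matches_truth(c, t, frag_max) for c in confirmed):
            strata[key][0] += 1
    out = {}
    for key, (det, tot) in strata.items():
        out[key] = {"detected": det, "total": tot,
                    "fraction": det / tot if tot else float("nan")}
    return out
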