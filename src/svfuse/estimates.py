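"""Quantitative side-calculations of the analysis.

* physical (fragment-span) coverage of breakpoints, N*f/G: the expected
  number of sequenced fragments spanning a genomic point;
* a Poisson model of junction detection, P(X >= k) with X ~ Poisson(c*lambda),
  explaining why amplified junctions are sampled far more often than
  single-copy ones;
* the two-list Lincoln-Petersen capture-recapture estimate of a fusion
  total, N_hat = n1*n2/m, from two overlapping incomplete catalogues;
* extrapolation of a mean per-tumour fusion count from an observed mean
  and an assumed detection sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class CoverageInputs:
    n_pairs: int
    fragment_len: int
    genome_size: int

    def __post_init__(self):
        if self.n_pairs < 0 or self.fragment_len <= 0 or self.genome_size <= 0:
            raise ValueError("coverage inputs must be positive (n_pairs >= 0)")


#: Ploidy-adjusted genome size used for the subtetraploid breast-cancer
#: genome scenario: four copies of a 3.1 Gb haploid genome.
SUBTETRAPLOID_GENOME_BP = 4 * 3_100_000_000


def physical_coverage(n_pairs: int, fragment_len: int, genome_size: int) -> float:
    """Fragment-span coverage N*f/G.

    A junction is covered when a sequenced fragment spans it, so breakpoint
    sampling depth is governed by fragment length, not read length.
    """
    inp = CoverageInputs(n_pairs, fragment_len, genome_size)
    return inp.n_pairs * inp.fragment_len / inp.genome_size


def detection_probability(coverage_per_copy: float, copy_number: int = 1,
                          min_pairs: int = 2) -> float:
    """P(X >= min_pairs) with X ~ Poisson(copy_number * coverage_per_copy).

    A junction present in ``copy_number`` copies is spanned by
    proportionally more fragments, so amplified junctions are detected at
    much higher rates than single-copy ones at the same sequencing depth.
    """
    if coverage_per_copy < 0:
        raise ValueError("coverage must be non-negative")
    if copy_number < 1 or min_pairs < 1:
        raise ValueError("copy_number and min_pairs must be >= 1")
    lam = coverage_per_copy * copy_number
    return float(stats.poisson.sf(min_pairs - 1, lam))


@dataclass(frozen=True)
class CaptureRecaptureInputs:
    n1: int
    n2: int
    m: int

    def __post_init__(self):
        if self.m < 0 or self.m > min(self.n1, self.n2):
            raise ValueError("overlap m must satisfy 0 <= m <= min(n1, n2)")


def capture_recapture(n1: int, n2: int, m: int) -> tuple[float, int]:
    """Lincoln-Petersen two-list estimate of a population total.

    Two independent incomplete catalogues of sizes ``n1`` and ``n2`` share
    ``m`` items; the estimated true total is ``n1 * n2 / m`` (uncorrected
    ratio, no Chapman adjustment). Returns ``(exact, rounded)``.
    Disjoint lists (m = 0) leave the estimate undefined.
    """
    inp = CaptureRecaptureInputs(n1, n2, m)
    if inp.m == 0:
        raise ValueError("capture-recapture estimate undefined for disjoint lists (m=0)")
    exact = inp.n1 * inp.n2 / inp.m
    return exact, round(exact)


def extrapolate_mean_fusions(observed_mean: float, sensitivity: float) -> float:
    """Observed mean count corrected for detection sensitivity."""
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError("sensitivity must be in (0, 1]")
    if observed_mean < 0:
        raise ValueError("observed mean must be non-negative")
    return observed_mean / sensitivity


def confirmed_junction_total(by_cn_step: int, by_pcr: int, by_both: int) -> int:
    """Total of independently confirmed junctions from disjoint evidence
    classes (copy-number step only, orthogonal validation only, both)."""
    for v in (by_cn_step, by_pcr, by_both):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return by_cn_step + by_pcr + by_both


def fraction_of_total(verified: int, estimated_total: float) -> float:
    """Share of the estimated true total that the verified set represents."""
    if estimated_total <= 0:
        raise ValueError("estimated total must be positive")
    return verified / estimated_total
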