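"""Rates, genetic maps, positional statistics and tract-length statistics.

The colony-color assay scores a crossover only when the two recombinant
chromatids co-segregate, which happens for half of reciprocal exchanges; the
crossover rate is therefore twice the sectored-colony frequency.  Rates are
also expressed in micro Sterns (1 µS = 10^-6 crossovers/division), a mitotic
analogue of the centiMorgan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .model import (
    CrossoverEvent,
    HYBRID_CLASSES,
    SIMPLE_CLASSES,
    TractClass,
)

MICRO_STERN = 1e-6

# default positional bins: five 200-kb bins from the centromere-proximal
# marker boundary plus the ~70-kb remainder to the arm end
DEFAULT_ARM = (449_000, 1_520_000)


@dataclass
class RateEstimate:
    sector_frequency: float
    crossover_rate: float     # events/division
    microsterns: float        # crossover_rate / 1e-6
    per_kb_rate: Optional[float] = None
    extrapolation_factor: float = 1.0


def crossover_rate(sector_frequency: float, arm_length_kb: Optional[float] = None) -> RateEstimate:
    """Crossover rate from the sectored-colony frequency (rate = 2 x freq)."""
    if not 0 <= sector_frequency <= 0.5:
        raise ValueError("sector frequency must be in [0, 0.5]")
    rate = 2.0 * sector_frequency
    per_kb = rate / arm_length_kb if arm_length_kb else None
    return RateEstimate(sector_frequency, rate, rate / MICRO_STERN, per_kb)


def genome_extrapolation(arm_estimate: RateEstimate, arm_fraction_of_genome: float) -> RateEstimate:
    """Scale an arm rate to the genome assuming proportionality to length."""
    if not 0 < arm_fraction_of_genome <= 1:
        raise ValueError("arm fraction of genome must be in (0, 1]")
    factor = 1.0 / arm_fraction_of_genome
    rate = arm_estimate.crossover_rate * factor
    return RateEstimate(
        arm_estimate.sector_frequency, rate, rate / MICRO_STERN,
        per_kb_rate=arm_estimate.per_kb_rate,
        extrapolation_factor=factor,
    )


# ---------------------------------------------------------------------------
# positional statistics


def default_bin_edges(arm: tuple[int, int] = DEFAULT_ARM, bin_size: int = 200_000) -> np.ndarray:
    lo, hi = arm
    edges = list(range(lo, hi, bin_size))
    edges.append(hi)
    return np.asarray(edges, dtype=np.int64)


@dataclass
class BinTestResult:
    edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


def bin_gof_test(points: Sequence[float], edges: Optional[np.ndarray] = None) -> BinTestResult:
    """Chi-square goodness of fit of event positions against bin lengths.

    Expected counts are proportional to bin lengths, so a uniform event
    density along the arm gives chi2 ~ chi2(df = bins - 1).
    """
    if edges is None:
        edges = default_bin_edges()
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 3:
        raise ValueError("need at least 2 bins")
    points = np.asarray(points, dtype=float)
    if len(points) and (points.min() < edges[0] or points.max() > edges[-1]):
        raise ValueError("points outside the binned arm")
    observed, _ = np.histogram(points, bins=edges)
    lengths = np.diff(edges)
    expected = len(points) * lengths / lengths.sum()
    if np.any(expected < 1):
        warnings.warn("expected count < 1 in some bin; chi-square approximation is weak")
    if len(points) == 0:
        return BinTestResult(edges, observed, expected, 0.0, len(observed) - 1, 1.0)
    chi2, p = scipy.stats.chisquare(observed, f_exp=expected)
    return BinTestResult(edges, observed, expected, float(chi2), len(observed) - 1, float(p))


def genetic_map(
    points: Sequence[float],
    n_regions: int,
    total_microsterns: float,
    arm: tuple[int, int] = DEFAULT_ARM,
) -> np.ndarray:
    """Per-region genetic widths (µS) proportional to event counts.

    The arm is split into ``n_regions`` equal physical regions; each carries
    total_µS x count_i / N.  The widths sum to total_µS exactly (zero when
    there are no events).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    points = np.asarray(points, dtype=float)
    edges = np.linspace(arm[0], arm[1], n_regions + 1)
    counts, _ = np.histogram(points, bins=edges)
    n = counts.sum()
    if n == 0:
        return np.zeros(n_regions)
    return total_microsterns * counts / n


def snp_involvement_profile(
    tract_spans: Sequence[tuple[int, int]],
    positions: np.ndarray,
) -> np.ndarray:
    """Number of conversion tracts covering each marker.

    A marker is involved when it lies between the start and end of a tract
    span; profiles of disjoint tract sets add.
    """
    positions = np.asarray(positions)
    counts = np.zeros(len(positions), dtype=np.int64)
    for lo, hi in tract_spans:
        counts += (positions >= lo) & (positions <= hi)
    return counts


# ---------------------------------------------------------------------------
# medians and rank tests


@dataclass
class MedianCI:
    n: int
    median: float
    lower_rank: int      # 1-based rank of the lower CI bound
    upper_rank: int
    lower: float
    upper: float
    coverage: float      # exact binomial coverage of the rank pair
    method: str


def _rank_coverage(n: int, r: int, s: int) -> float:
    """P(x_(r) <= true median <= x_(s)) = P(r <= Bin(n, 1/2) <= s-1)."""
    return float(
        scipy.stats.binom.cdf(s - 1, n, 0.5) - scipy.stats.binom.cdf(r - 1, n, 0.5)
    )


def median_ci(values: Sequence[float], method: str = "exact", level: float = 0.95) -> MedianCI:
    """Order-statistic confidence interval for the median.

    ``exact``: the tightest symmetric rank pair (r, n+1-r) whose binomial
    coverage sum_{k=r}^{n-r} C(n,k)/2^n reaches ``level`` (valid for n >= 1).
    ``normal``: the large-sample rank approximation
    r = round(n/2 - 1.96*sqrt(n)/2), s = round(1 + n/2 + 1.96*sqrt(n)/2),
    rounding half up (n >= 6).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    if method == "normal":
        if n < 6:
            raise ValueError("normal-approximation method requires n >= 6")
        r = int(np.floor(n / 2 - z * np.sqrt(n) / 2 + 0.5))
        s = int(np.floor(1 + n / 2 + z * np.sqrt(n) / 2 + 0.5))
        r = max(r, 1)
        s = min(s, n)
        coverage = _rank_coverage(n, r, s)
    elif method == "exact":
        if n < 1:
            raise ValueError("exact method requires n >= 1")
        best = None
        for r_try in range(n // 2, 0, -1):
            s_try = n + 1 - r_try
            if s_try <= r_try:
                continue
            cov = _rank_coverage(n, r_try, s_try)
            if cov >= level:
                best = (r_try, s_try, cov)
                break
        if best is None:  # even the widest pair misses the level (tiny n)
            best = (1, n, float(1 - 2 * 0.5 ** n) if n > 1 else 0.0)
        r, s, coverage = best
    else:
        raise ValueError(f"unknown median_ci method: {method!r}")
    return MedianCI(
        n=n, median=float(np.median(x)), lower_rank=r, upper_rank=s,
        lower=float(x[r - 1]), upper=float(x[s - 1]), coverage=coverage,
        method=method,
    )


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the U distribution when n*m <= 400 and there are no
    ties; the normal approximation with tie correction otherwise.  Returns
    (U of the first sample, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def interval_rate_test(
    n_inside: int, n_total: int, inner_len: float, outer_len: float
) -> tuple[float, float]:
    """Test whether events fall in a sub-interval in proportion to its length.

    Used for the hotspot-deletion assay: with markers bracketing a 56-kb
    hotspot interval inside a 568-kb selected interval, ~10% of selected
    recombinants should carry the inner-interval marker if crossovers are
    length-proportional.  Returns (expected fraction, two-sided exact
    binomial p by the minimum-likelihood method).
    """
    if not 0 < inner_len <= outer_len:
        raise ValueError("need 0 < inner_len <= outer_len")
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_inside > n_total:
        raise ValueError("n_inside cannot exceed n_total")
    expected = inner_len / outer_len
    p = scipy.stats.binomtest(n_inside, n_total, expected).pvalue
    return float(expected), float(p)


# ---------------------------------------------------------------------------
# cohort bookkeeping


@dataclass
class CohortSummary:
    n_events: int
    by_class: dict
    by_timing: dict
    by_initiating: dict
    n_with_conversion: int
    fraction_with_conversion: float
    n_simple: int            # simple 3:1 + simple 4:0 + hybrids


def cohort_summary(events: Sequence[CrossoverEvent]) -> CohortSummary:
    by_class: dict[str, int] = {}
    by_timing: dict[str, int] = {}
    by_init: dict[str, int] = {}
    n_conv = 0
    n_simple = 0
    for ev in events:
        cls = ev.tract_class
        by_class[cls.value] = by_class.get(cls.value, 0) + 1
        if cls is not TractClass.NONE:
            n_conv += 1
            t = ev.tract
            by_timing[t.timing.value] = by_timing.get(t.timing.value, 0) + 1
            by_init[t.initiating.value] = by_init.get(t.initiating.value, 0) + 1
            if cls in SIMPLE_CLASSES:
                n_simple += 1
    n = len(events)
    return CohortSummary(
        n_events=n,
        by_class=by_class,
        by_timing=by_timing,
        by_initiating=by_init,
        n_with_conversion=n_conv,
        fraction_with_conversion=(n_conv / n) if n else 0.0,
        n_simple=n_simple,
    )
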