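"""MAG coverage response: quartile-trimmed coverage, depth normalization,
rank-test enrichment calls and the single-copy-gene cell-fraction estimate.

A MAG's abundance in a metagenome is summarized by its Q2Q3 mean coverage —
the mean per-base coverage after discarding the lowest and highest quartiles
of positions, which is robust to conserved genes and genomic islands.  Q2Q3
coverages are normalized to library size (per million reads), log10(x+1)
transformed, and compared between substrate-amended and baseline (t0) sample
groups with a one-sided rank-sum test (amended > t0); the null is evaluated
by exact enumeration of group assignments for small groups, and by the
normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoverageProfile:
    """One MAG's coverage in one sequencing library."""

    mag_id: str
    library_reads: int
    per_base_coverage: np.ndarray | None = None
    q2q3_mean: float | None = None

    def __post_init__(self) -> None:
        if self.library_reads <= 0:
            raise ValueError(f"{self.mag_id}: library_reads must be positive")
        if self.per_base_coverage is not None:
            self.per_base_coverage = np.asarray(self.per_base_coverage, dtype=float)
            if np.any(self.per_base_coverage < 0):
                raise ValueError(f"{self.mag_id}: negative coverage values")
            if self.q2q3_mean is None:
                self.q2q3_mean = q2q3_mean_coverage(self.per_base_coverage)
        if self.q2q3_mean is None:
            raise ValueError(f"{self.mag_id}: need per_base_coverage or q2q3_mean")


@dataclass
class ResponseCall:
    """Enrichment call for one MAG: amended vs t0 normalized coverages."""

    mag_id: str
    amended: list[float]
    t0: list[float]
    p_value: float | None
    enriched: bool
    untestable: bool = False


def q2q3_mean_coverage(per_base_coverage) -> float:
    """Mean coverage over the middle two quartiles of positions.

    Positions are sorted by coverage; the lowest ``floor(n/4)`` and highest
    ``floor(n/4)`` are dropped and the rest averaged.  Requires at least 4
    positions.  Sorting is stable in position order, so ties at the trim
    boundary resolve deterministically.
    """
    cov = np.asarray(per_base_coverage, dtype=float)
    n = cov.size
    if n < 4:
        raise ValueError(f"need >= 4 positions for Q2Q3 trimming, got {n}")
    k = n // 4
    return float(np.mean(np.sort(cov, kind="stable")[k : n - k]))


def normalize_coverage(q2q3: float, library_reads: int) -> float:
    """Coverage per million library reads, log10(x + 1) transformed."""
    return float(np.log10(q2q3 / (library_reads / 1e6) + 1.0))


def exact_rank_sum_p(amended, t0) -> float:
    """One-sided exact rank-sum p-value by enumeration of group assignments.

    Under the null every assignment of the pooled values to the two groups
    is equally likely; the p-value is the fraction of assignments whose
    amended rank sum is at least the observed one.  Midranks handle ties.
    """
    amended = np.asarray(amended, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    pooled = np.concatenate([amended, t0])
    ranks = stats.rankdata(pooled)
    n_a = len(amended)
    observed = ranks[:n_a].sum()
    n = len(pooled)
    hits = sum(
        1 for idx in combinations(range(n), n_a)
        if ranks[list(idx)].sum() >= observed - 1e-9
    )
    return hits / comb(n, n_a)


def rank_sum_test(amended, t0, exact_max_group: int = 8) -> float:
    """One-sided (amended > t0) rank-sum p-value.

    Exact permutation null when both groups have at most ``exact_max_group``
    members, otherwise the tie-corrected normal approximation.
    """
    if max(len(amended), len(t0)) <= exact_max_group:
        return exact_rank_sum_p(amended, t0)
    stat = stats.mannwhitneyu(amended, t0, alternative="greater", method="asymptotic")
    return float(stat.pvalue)


def normalize_and_test(
    profiles: dict[str, dict[str, list[CoverageProfile]]],
    alpha: float = 0.05,
) -> list[ResponseCall]:
    """Depth-normalize grouped coverage profiles and call enrichment per MAG.

    ``profiles`` maps mag_id -> {"amended": [...], "t0": [...]}.  A MAG is
    enriched when the one-sided rank-sum p-value is below ``alpha`` *and*
    the amended median exceeds the t0 median.  Groups with fewer than 2
    samples make the MAG untestable (reported, not dropped).
    """
    calls = []
    for mag_id, groups in profiles.items():
        amended = [
            normalize_coverage(p.q2q3_mean, p.library_reads)
            for p in groups.get("amended", [])
        ]
        t0 = [
            normalize_coverage(p.q2q3_mean, p.library_reads)
            for p in groups.get("t0", [])
        ]
        if len(amended) < 2 or len(t0) < 2:
            calls.append(ResponseCall(mag_id, amended, t0, None, False, untestable=True))
            continue
        p = rank_sum_test(amended, t0)
        enriched = bool(p < alpha and np.median(amended) > np.median(t0))
        calls.append(ResponseCall(mag_id, amended, t0, p, enriched))
    return calls


def calls_to_frame(calls: list[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mag_id": [c.mag_id for c in calls],
            "p_value": [c.p_value for c in calls],
            "enriched": [c.enriched for c in calls],
            "untestable": [c.untestable for c in calls],
        }
    )


def gene_cell_fraction(
    gene_hits: int, total_reads: int, benchmark_fraction: float = 0.001
) -> float:
    """Fraction of cells carrying a gene, from its read fraction.

    Assumes the benchmark gene family makes up ``benchmark_fraction`` of the
    metagenome when present in every cell at one copy, and that each read
    maps to one gene copy; then the carrying cell fraction is the gene's
    read fraction divided by the benchmark.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0.0 < benchmark_fraction < 1.0:
        raise ValueError("benchmark_fraction must be in (0, 1)")
    if gene_hits > total_reads:
        raise ValueError("gene_hits cannot exceed total_reads")
    if gene_hits < 0:
        raise ValueError("gene_hits must be >= 0")
    return (gene_hits / total_reads) / benchmark_fraction
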