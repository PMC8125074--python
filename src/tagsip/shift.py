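"""Per-OTU buoyant-density distributions and the paired density-shift statistic.

For each OTU the per-fraction relative amplicon abundance is scaled by the
DNA mass recovered from that fraction and normalized to sum to 1 across
fractions, giving the OTU's DNA-mass distribution over buoyant density.  The
abundance-weighted mean density (WM) is computed in the labeled (13C) and
control (12C) gradients; a labeled-minus-control difference (delWM) above
0.005 g/ml calls the OTU significantly enriched, provided its distribution
is indistinguishable from a normal band in *both* gradients
(Kolmogorov–Smirnov filter, alpha = 0.05) — the guard against spurious,
multi-banded OTUs.  Each significant shift is annotated with the excess atom
fraction implied by the labeling model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .gradient_io import DEFAULT_MIN_DNA_NG, GradientProfile
from .labeling import DEFAULT_MODEL, LabelingModel, excess_atom_fraction


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the shift analysis.

    ``shift_threshold`` is the minimum labeled-minus-control weighted-mean
    density difference (g/ml) for significance; ``ks_alpha`` the level of
    the normality filter; ``min_total_reads`` the minimum summed read count
    over all fractions of both gradients; ``top_n`` how many of the most
    abundant OTUs are analyzed; ``min_dna_ng`` the DNA floor below which a
    fraction is excluded from distributions.
    """

    shift_threshold: float = 0.005
    ks_alpha: float = 0.05
    min_total_reads: int = 10
    top_n: int = 200
    min_dna_ng: float = DEFAULT_MIN_DNA_NG

    def __post_init__(self) -> None:
        if (
            self.shift_threshold <= 0
            or self.ks_alpha <= 0
            or self.min_total_reads <= 0
            or self.top_n <= 0
        ):
            raise ValueError("all analysis thresholds must be positive")


@dataclass
class OtuDensityDistribution:
    """An OTU's normalized DNA-mass distribution over a gradient's densities."""

    otu_id: str
    densities: np.ndarray
    weights: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.densities.shape != self.weights.shape:
            raise ValueError("densities and weights must have equal length")
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")

    @property
    def n_supporting(self) -> int:
        return int(np.sum(self.weights > 0))


@dataclass
class ShiftResult:
    """Paired statistics for one OTU: weighted means, shift, filter, EAF."""

    otu_id: str
    taxonomy: str | None = None
    wm_12C: float = math.nan
    wm_13C: float = math.nan
    delta_wm: float = math.nan
    ks_p_12C: float = math.nan
    ks_p_13C: float = math.nan
    passed_normality: bool = False
    significant: bool = False
    eaf: float = math.nan
    ape: float = math.nan


def build_distribution(
    profile: GradientProfile,
    otu_id: str,
    min_dna_ng: float = DEFAULT_MIN_DNA_NG,
) -> OtuDensityDistribution | None:
    """Build an OTU's density distribution from one gradient.

    Per analyzed fraction *f* (those with DNA above the floor):
    ``mass_f = (count_otu,f / total counts_f) * dna_mass_f`` and the weights
    are ``mass_f`` normalized to sum to 1.  Returns ``None`` when the OTU is
    absent (zero counts in every analyzed fraction) so that batch callers can
    record an "absent" outcome instead of raising.
    """
    counts = profile.count_matrix()
    if otu_id not in counts.columns:
        return None
    densities = profile.densities
    dna = profile.dna_masses
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    keep = (dna > min_dna_ng) & (totals > 0)
    if not keep.any():
        return None
    otu_counts = counts[otu_id].to_numpy(dtype=float)[keep]
    mass = otu_counts / totals[keep] * dna[keep]
    if mass.sum() == 0:
        return None
    return OtuDensityDistribution(
        otu_id=otu_id,
        densities=densities[keep],
        weights=mass / mass.sum(),
        total_reads=int(otu_counts.sum()),
    )


def weighted_mean_density(dist: OtuDensityDistribution) -> float:
    """Abundance-weighted mean buoyant density, WM = sum_f rho_f * p_f."""
    return float(dist.densities @ dist.weights)


def weighted_sd_density(dist: OtuDensityDistribution) -> float:
    wm = weighted_mean_density(dist)
    return float(np.sqrt(dist.weights @ (dist.densities - wm) ** 2))


def ks_normality(dist: OtuDensityDistribution) -> float | None:
    """Kolmogorov–Smirnov comparison of the weighted distribution to a normal.

    The weighted empirical CDF over fraction densities is compared with the
    normal CDF fitted by the weighted mean and weighted standard deviation;
    the KS statistic is the largest discrepancy evaluated at the fraction
    densities (approaching each step from both sides), and the p-value comes
    from the asymptotic KS distribution with effective sample size equal to
    the number of supporting fractions.  This construction is deterministic —
    no pseudo-sampling of reads.

    Returns ``None`` ("untestable", which fails the filter) for fewer than 4
    supporting fractions or a degenerate (zero-spread) distribution.
    """
    n = dist.n_supporting
    if n < 4:
        return None
    sd = weighted_sd_density(dist)
    if sd == 0:
        return None
    wm = weighted_mean_density(dist)
    ecdf = np.cumsum(dist.weights)
    ecdf_before = ecdf - dist.weights
    ref = stats.norm.cdf((dist.densities - wm) / sd)
    d = max(np.abs(ecdf - ref).max(), np.abs(ecdf_before - ref).max())
    return float(special.kolmogorov(math.sqrt(n) * d))


def rank_by_abundance(labeled: GradientProfile, control: GradientProfile) -> list[str]:
    """OTU ids ranked by summed relative abundance over the gradient pair.

    Relative abundance of an OTU in a gradient is its total reads divided by
    the gradient's total reads; the pair rank sums the two.  Ties break
    lexicographically on OTU id for determinism.
    """
    scores: dict[str, float] = {}
    for prof in (labeled, control):
        counts = prof.count_matrix()
        total = counts.to_numpy().sum()
        if total == 0:
            continue
        for otu, c in counts.sum(axis=0).items():
            scores[otu] = scores.get(otu, 0.0) + c / total
    return sorted(scores, key=lambda o: (-scores[o], o))


def compare_gradients(
    labeled: GradientProfile,
    control: GradientProfile,
    model: LabelingModel = DEFAULT_MODEL,
    cfg: AnalysisConfig = AnalysisConfig(),
    taxonomy: dict[str, str] | None = None,
) -> list[ShiftResult]:
    """Paired shift analysis of a 13C gradient against its 12C control.

    Applies the read filter (>= ``min_total_reads`` summed over both
    gradients), keeps the ``top_n`` most abundant OTUs of the pair, and for
    each computes per-gradient weighted mean densities, the shift delWM, KS
    normality p-values, the significance call and the implied excess atom
    fraction.  OTUs absent from either gradient are reported with null
    statistics rather than dropped.
    """
    labeled.validate_for_analysis(cfg.min_dna_ng)
    control.validate_for_analysis(cfg.min_dna_ng)
    universe = set(labeled.otu_ids) | set(control.otu_ids)
    if not universe:
        raise ValueError("no OTUs shared between the gradient pair")

    lab_counts = labeled.count_matrix().sum(axis=0)
    ctl_counts = control.count_matrix().sum(axis=0)
    total_reads = {
        otu: int(lab_counts.get(otu, 0)) + int(ctl_counts.get(otu, 0))
        for otu in universe
    }
    surviving = [o for o in universe if total_reads[o] >= cfg.min_total_reads]
    ranked = [o for o in rank_by_abundance(labeled, control) if o in set(surviving)]
    selected = ranked[: cfg.top_n]

    taxonomy = taxonomy or {}
    results: list[ShiftResult] = []
    for otu in selected:
        res = ShiftResult(otu_id=otu, taxonomy=taxonomy.get(otu))
        d13 = build_distribution(labeled, otu, cfg.min_dna_ng)
        d12 = build_distribution(control, otu, cfg.min_dna_ng)
        if d13 is None or d12 is None:
            results.append(res)  # absent from one gradient: null statistics
            continue
        res.wm_12C = weighted_mean_density(d12)
        res.wm_13C = weighted_mean_density(d13)
        res.delta_wm = res.wm_13C - res.wm_12C
        p12 = ks_normality(d12)
        p13 = ks_normality(d13)
        res.ks_p_12C = math.nan if p12 is None else p12
        res.ks_p_13C = math.nan if p13 is None else p13
        res.passed_normality = (
            p12 is not None and p13 is not None
            and p12 > cfg.ks_alpha and p13 > cfg.ks_alpha
        )
        res.significant = bool(
            res.passed_normality and res.delta_wm > cfg.shift_threshold
        )
        res.eaf = excess_atom_fraction(res.wm_12C, res.delta_wm, model)
        res.ape = 100.0 * res.eaf
        results.append(res)
    results.sort(key=lambda r: r.otu_id)
    return results


def summarize(results: list[ShiftResult]) -> dict:
    """Machine-readable counts: analyzed / with statistics / passed / significant."""
    return {
        "n_analyzed": len(results),
        "n_with_statistics": sum(1 for r in results if not math.isnan(r.delta_wm)),
        "n_passed_normality": sum(1 for r in results if r.passed_normality),
        "n_significant": sum(1 for r in results if r.significant),
    }
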