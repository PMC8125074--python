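"""Shift statistic: distributions, weighted means, KS filter, paired comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tagsip.labeling import density_shift_for_eaf, gc_to_density
from tagsip.shift import (
    AnalysisConfig,
    OtuDensityDistribution,
    build_distribution,
    compare_gradients,
    ks_normality,
    weighted_mean_density,
)
from tagsip.simulate import GradientSimConfig, SyntheticTaxon, simulate_pair

from conftest import make_profile


def make_dist(weights, densities=None):
    w = np.asarray(weights, float)
    w = w / w.sum()
    if densities is None:
        densities = 1.66 + 0.002 * np.arange(len(w))
    return OtuDensityDistribution("x", np.asarray(densities, float), w, 100)


class TestBuildDistribution:
    def test_equal_depth_equal_dna_is_count_proportional(self, profile_factory):
        # equal per-fraction totals and DNA: weights proportional to counts
        prof = profile_factory(
            [1.69, 1.70, 1.71], [10, 10, 10],
            {"a": [10, 30, 60], "b": [90, 70, 40]},
        )
        d = build_distribution(prof, "a")
        np.testing.assert_allclose(d.weights, [0.1, 0.3, 0.6])

    def test_single_otu_weights_follow_dna_mass(self, profile_factory):
        # a lone OTU has relative abundance 1 everywhere, so its density
        # distribution is the per-fraction DNA-mass distribution
        prof = profile_factory(
            [1.69, 1.70, 1.71], [5.0, 15.0, 30.0], {"a": [10, 30, 60]}
        )
        d = build_distribution(prof, "a")
        np.testing.assert_allclose(d.weights, [0.1, 0.3, 0.6])

    def test_dna_mass_weighting(self, profile_factory):
        prof = profile_factory([1.70, 1.71], [10.0, 30.0], {"a": [50, 50]})
        d = build_distribution(prof, "a")
        np.testing.assert_allclose(d.weights, [0.25, 0.75])

    def test_absent_otu_is_none_not_exception(self, profile_factory):
        prof = profile_factory([1.70, 1.71], [10, 10], {"a": [0, 0], "b": [5, 5]})
        assert build_distribution(prof, "a") is None
        assert build_distribution(prof, "missing") is None

    def test_low_dna_fractions_excluded(self, profile_factory):
        prof = profile_factory(
            [1.69, 1.70, 1.71], [0.05, 10.0, 10.0], {"a": [100, 10, 10]}
        )
        d = build_distribution(prof, "a")
        assert len(d.densities) == 2
        np.testing.assert_allclose(d.weights, [0.5, 0.5])

    @settings(deadline=None, max_examples=30)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=5, max_size=12),
        dna=st.lists(st.floats(0.5, 50), min_size=12, max_size=12),
    )
    def test_weights_always_sum_to_one(self, counts, dna):
        n = len(counts)
        prof = make_profile(
            1.66 + 0.002 * np.arange(n), dna[:n],
            {"a": counts, "b": [7] * n},
        )
        d = build_distribution(prof, "a")
        if d is not None:
            assert d.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestWeightedMeanDensity:
    def test_point_mass(self):
        d = make_dist([0, 1, 0], [1.70, 1.71, 1.72])
        assert weighted_mean_density(d) == 1.71

    def test_hand_dot_product(self):
        d = make_dist([0.25, 0.5, 0.25], [1.70, 1.71, 1.72])
        assert weighted_mean_density(d) == pytest.approx(1.71)

    def test_uniform_weights_give_arithmetic_mean(self):
        rho = [1.68, 1.69, 1.71, 1.76]
        d = make_dist([1, 1, 1, 1], rho)
        assert weighted_mean_density(d) == pytest.approx(np.mean(rho))

    def test_brute_force_expansion_oracle(self, rng):
        """WM equals averaging each density repeated ~1e6 * weight times."""
        for _ in range(20):
            n = rng.integers(5, 30)
            w = rng.dirichlet(np.ones(n))
            rho = np.sort(1.66 + rng.uniform(0, 0.11, n))
            rho = np.unique(rho)
            w = w[: len(rho)] / w[: len(rho)].sum()
            d = make_dist(w, rho)
            reps = np.repeat(rho, np.floor(1e6 * d.weights).astype(int))
            assert weighted_mean_density(d) == pytest.approx(reps.mean(), abs=1e-5)


class TestKsNormality:
    edges = np.linspace(1.66, 1.77, 31)
    mids = 0.5 * (edges[:-1] + edges[1:])

    def test_normal_band_passes(self):
        w = np.diff(stats.norm.cdf(self.edges, loc=1.70, scale=0.008))
        p = ks_normality(make_dist(w, self.mids))
        assert p > 0.05

    def test_bimodal_band_fails(self):
        w = np.diff(stats.norm.cdf(self.edges, 1.675, 0.004)) + np.diff(
            stats.norm.cdf(self.edges, 1.745, 0.004)
        )
        p = ks_normality(make_dist(w, self.mids))
        assert p < 0.05

    def test_point_mass_untestable(self):
        d = make_dist([0, 0, 1, 0, 0], [1.68, 1.69, 1.70, 1.71, 1.72])
        assert ks_normality(d) is None

    def test_sparse_support_untestable(self):
        # only two supporting fractions, below the 4-fraction minimum
        d = make_dist([0.5, 0, 0, 0, 0.5], [1.68, 1.69, 1.70, 1.71, 1.72])
        assert ks_normality(d) is None


class TestCompareGradients:
    def _pair(self):
        densities = np.linspace(1.67, 1.75, 20)
        edges = np.linspace(1.669, 1.751, 21)
        dna = 100 * np.diff(stats.norm.cdf(edges, 1.705, 0.012)) + 1.0
        counts_a = np.round(
            2000 * np.diff(stats.norm.cdf(edges, 1.700, 0.006))
        ).astype(int)
        counts_b = np.round(
            2000 * np.diff(stats.norm.cdf(edges, 1.710, 0.006))
        ).astype(int)
        counts = {"a": counts_a, "b": counts_b}
        return (
            make_profile(densities, dna, counts, isotope="13C"),
            make_profile(densities, dna, counts, isotope="12C"),
        )

    def test_self_comparison_all_zero_shift(self):
        labeled, control = self._pair()
        results = compare_gradients(labeled, control)
        assert results
        for r in results:
            assert r.delta_wm == 0.0
            assert not r.significant

    def test_translation_equivariance(self):
        """Shifting every labeled density by +c raises every delWM by c."""
        labeled, control = self._pair()
        c = 0.004
        shifted = make_profile(
            labeled.densities + c,
            labeled.dna_masses,
            {o: labeled.count_matrix()[o].to_numpy() for o in labeled.otu_ids},
            isotope="13C",
        )
        base = {r.otu_id: r.delta_wm for r in compare_gradients(labeled, control)}
        moved = {r.otu_id: r.delta_wm for r in compare_gradients(shifted, control)}
        for otu in base:
            assert moved[otu] - base[otu] == pytest.approx(c, abs=1e-12)

    def test_min_total_reads_filter(self):
        labeled, control = self._pair()
        # add an OTU with 9 reads total across both gradients
        for prof in (labeled, control):
            for f in prof.fractions:
                f.counts = dict(f.counts)
                f.counts["rare"] = 0
        labeled.fractions[10].counts["rare"] = 5
        control.fractions[10].counts["rare"] = 4
        labeled._counts_cache = None
        control._counts_cache = None
        results = compare_gradients(labeled, control)
        assert "rare" not in {r.otu_id for r in results}

    def test_top_n_limits_output(self):
        labeled, control = self._pair()
        cfg = AnalysisConfig(top_n=1)
        results = compare_gradients(labeled, control, cfg=cfg)
        assert len(results) == 1

    def test_simulated_labeled_taxon_recovers_eaf(self):
        """A taxon labeled at EAF 0.5 in the simulator is recovered."""
        community = [
            SyntheticTaxon("bg", gc=0.50, rel_abundance=0.7, true_eaf=0.0),
            SyntheticTaxon("hot", gc=0.45, rel_abundance=0.3, true_eaf=0.5),
        ]
        cfg = GradientSimConfig(seed=7)
        labeled, control, _ = simulate_pair(community, cfg)
        results = {r.otu_id: r for r in compare_gradients(labeled, control)}
        assert results["hot"].significant
        assert results["hot"].eaf == pytest.approx(0.5, abs=0.03)
        assert not results["bg"].significant
        assert results["bg"].eaf == pytest.approx(0.0, abs=0.01)

    def test_shift_result_identity_invariant(self):
        labeled, control = self._pair()
        for r in compare_gradients(labeled, control):
            if not np.isnan(r.delta_wm):
                assert r.delta_wm == r.wm_13C - r.wm_12C
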