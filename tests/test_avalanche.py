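"""Cluster extraction, log-binned size distributions, power-law and scaling fits."""

import numpy as np
import pytest

from avakit.avalanche import (
    extract_clusters,
    fit_power_law,
    predicted_cutoff,
    size_distribution,
    size_duration_scaling,
)
from avakit.preprocess import shuffle_raster
from tests.conftest import raster_from_mask


def sample_discrete_power_law(tau, n, cutoff, seed):
    """Inverse-CDF sampling oracle for a truncated discrete power law."""
    rng = np.random.default_rng(seed)
    support = np.arange(1, cutoff + 1, dtype=float)
    pmf = support**-tau
    pmf /= pmf.sum()
    return rng.choice(support, size=n, p=pmf)


class TestExtractClusters:
    def test_silent_raster_has_no_clusters(self):
        cs = extract_clusters(raster_from_mask(np.zeros((4, 50))))
        assert len(cs) == 0

    def test_runs_of_active_frames(self):
        mask = np.zeros((3, 12))
        mask[0, [3, 4]] = 1
        mask[1, [5]] = 1
        mask[2, [8]] = 1
        cs = extract_clusters(raster_from_mask(mask))
        assert [(c.start_frame, c.duration) for c in cs] == [(3, 3), (8, 1)]
        assert not any(c.edge for c in cs)

    def test_fully_active_movie_is_one_edge_cluster(self):
        cs = extract_clusters(raster_from_mask(np.ones((2, 30))))
        assert len(cs) == 1
        assert cs.clusters[0].duration == 30
        assert cs.clusters[0].edge

    def test_lambda_conservation(self, sal_raster):
        cs = extract_clusters(sal_raster)
        total = sum(c.size_lambda for c in cs)
        assert total == pytest.approx(sal_raster.lam.sum())

    def test_cluster_count_matches_silent_to_active_transitions(self, sal_raster):
        frame_active = sal_raster.mask.any(axis=0).astype(int)
        transitions = (np.diff(frame_active) == 1).sum() + frame_active[0]
        assert len(extract_clusters(sal_raster)) == transitions


class TestSizeDistribution:
    def test_unit_sizes_mass_in_first_bin(self):
        dist = size_distribution(np.ones(50))
        assert dist.density[0] * (dist.edges[1] - dist.edges[0]) == pytest.approx(1.0)

    def test_density_integrates_to_one(self):
        sizes = sample_discrete_power_law(1.5, 5000, 300, seed=1)
        dist = size_distribution(sizes)
        assert np.sum(dist.density * np.diff(dist.edges)) == pytest.approx(1.0)

    def test_binned_slope_matches_generating_exponent(self):
        sizes = sample_discrete_power_law(1.5, 100_000, 500, seed=2)
        dist = size_distribution(sizes)
        sel = (dist.density > 0) & (dist.edges[1:] <= 500)
        slope = np.polyfit(np.log10(dist.centers[sel]), np.log10(dist.density[sel]), 1)[0]
        assert -slope == pytest.approx(1.5, abs=0.1)


class TestFitPowerLaw:
    @pytest.mark.parametrize("tau", [1.2, 1.5, 2.0])
    def test_exponent_recovery_within_tolerance(self, tau):
        sizes = sample_discrete_power_law(tau, 100_000, 500, seed=3)
        fit = fit_power_law(size_distribution(sizes), cutoff=500)
        assert fit.exponent == pytest.approx(tau, abs=0.05)

    def test_mle_cross_check_agrees_with_least_squares(self):
        sizes = sample_discrete_power_law(1.5, 100_000, 500, seed=4)
        dist = size_distribution(sizes)
        ls = fit_power_law(dist, cutoff=500)
        mle = fit_power_law(dist, cutoff=500, method="mle")
        assert ls.exponent == pytest.approx(mle.exponent, abs=0.05)

    def test_exponential_sizes_have_larger_ks_than_power_law(self):
        rng = np.random.default_rng(5)
        exp_sizes = np.clip(np.round(rng.exponential(10, 20_000)), 1, 500)
        pl_sizes = sample_discrete_power_law(1.5, 20_000, 500, seed=6)
        ks_exp = fit_power_law(size_distribution(exp_sizes), cutoff=500).ks_distance
        ks_pl = fit_power_law(size_distribution(pl_sizes), cutoff=500).ks_distance
        assert ks_exp > ks_pl

    def test_shuffling_increases_ks_distance(self, small_critical_raster):
        orig = extract_clusters(small_critical_raster)
        cutoff = predicted_cutoff(small_critical_raster.n_neurons)
        ks_orig = fit_power_law(size_distribution(orig), cutoff=cutoff).ks_distance
        shuf = extract_clusters(shuffle_raster(small_critical_raster, seed=7))
        ks_shuf = fit_power_law(size_distribution(shuf), cutoff=cutoff).ks_distance
        assert ks_shuf > ks_orig

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(size_distribution(np.array([1.0, 2.0, 1.0])), cutoff=4)


class TestSizeDurationScaling:
    def test_exact_quadratic_relation(self):
        # clusters engineered so size == duration**2 exactly:
        # T active neurons in each of T consecutive frames
        mask = np.zeros((30, 1200))
        t0 = 2
        durs = []
        for T in (1, 2, 3, 4, 5):
            for _ in range(12):
                mask[:T, t0 : t0 + T] = 1
                t0 += T + 3
                durs.append(T)
        cs = extract_clusters(raster_from_mask(mask))
        assert sorted(c.duration for c in cs) == sorted(durs)
        fit = size_duration_scaling(cs, min_per_duration=10)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)

    def test_all_duration_one_is_an_error(self):
        mask = np.zeros((5, 100))
        mask[0, ::5] = 1
        with pytest.raises(ValueError):
            size_duration_scaling(extract_clusters(raster_from_mask(mask)))

    def test_near_critical_scaling_exponent(self, small_critical_raster):
        fit = size_duration_scaling(extract_clusters(small_critical_raster))
        # compact single-movie estimate sits below the asymptotic
        # mean-field value of 2; it must still be clearly supra-linear
        assert 1.3 < fit.exponent < 2.2
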