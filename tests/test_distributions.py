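import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btpcorr.distributions import (
    Distribution1D,
    Distribution2D,
    count_joint_peaks,
    count_peaks_1d,
    distribution_difference,
    heterogeneity_score,
    histogram_1d,
    joint_histogram,
)


def dist1d(p):
    p = np.asarray(p, dtype=float)
    return Distribution1D(p=p / p.sum(), M=1000)


def bump(center, width, mass, n=60):
    """Triangular bump of total `mass` centered at bin `center`."""
    p = np.zeros(n)
    for k in range(-width, width + 1):
        p[(center + k) % n] = width + 1 - abs(k)
    return p / p.sum() * mass


class TestHistogram1D:
    def test_point_mass_lands_in_first_bin(self):
        d = histogram_1d(np.full(10, -179.0))
        assert d.p[0] == 1.0 and d.p[1:].sum() == 0.0

    def test_one_angle_per_bin_is_uniform(self):
        angles = -180.0 + 6.0 * np.arange(60) + 3.0
        d = histogram_1d(angles)
        assert np.allclose(d.p, 1 / 60)

    def test_exactly_180_falls_in_last_bin(self):
        d = histogram_1d(np.array([180.0]))
        assert d.p[59] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            histogram_1d(np.array([-180.0]))
        with pytest.raises(ValueError):
            histogram_1d(np.array([181.0]))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            histogram_1d(np.array([]))


class TestPeaks1D:
    def test_uniform_is_one_peak(self):
        ps = count_peaks_1d(dist1d(np.ones(60)))
        assert ps.n_peaks == 1
        assert not ps.boundaries

    def test_two_bumps_two_boundaries_two_peaks(self):
        p = np.zeros(60)
        p[0:10] = 0.06  # mass 0.6
        p[30:40] = 0.04  # mass 0.4
        ps = count_peaks_1d(Distribution1D(p=p, M=1000))
        assert len(ps.boundaries) == 2
        assert ps.n_peaks == 2

    def test_small_bump_below_threshold_excluded(self):
        p = np.zeros(60)
        p[0:10] = 0.092  # mass 0.92
        p[30:40] = 0.008  # mass 0.08 <= 0.1 -> not a peak
        ps = count_peaks_1d(Distribution1D(p=p, M=1000))
        assert ps.n_peaks == 1

    def test_collective_bin_masses_sum_to_one(self, rng):
        for _ in range(20):
            p = rng.random(60)
            ps = count_peaks_1d(dist1d(p))
            total = sum(mass for _, mass in ps.collective_bins)
            assert total == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(min_value=0, max_value=59), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rotation_invariance(self, shift, seed):
        p = np.random.default_rng(seed).random(60)
        base = count_peaks_1d(dist1d(p))
        rotated = count_peaks_1d(dist1d(np.roll(p, shift)))
        assert rotated.n_peaks == base.n_peaks

    def test_von_mises_mixture_recovery(self):
        """Separated mixtures with component weights > 0.1 are counted exactly."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = int(rng.integers(1, 4))
            centers = (rng.uniform(-180, 180) +
                       np.arange(w) * (360.0 / max(w, 2))) % 360 - 180
            weights = rng.dirichlet(np.full(w, 8.0))  # concentrated -> all > 0.1
            while weights.min() <= 0.12:
                weights = rng.dirichlet(np.full(w, 8.0))
            m = 100_000
            counts = rng.multinomial(m, weights)
            parts = [
                np.degrees(rng.vonmises(np.radians(c), 20.0, size=n))
                for c, n in zip(centers, counts)
            ]
            angles = np.concatenate(parts)
            angles = np.mod(angles + 180, 360) - 180
            angles[angles == -180.0] = 180.0
            assert count_peaks_1d(histogram_1d(angles)).n_peaks == w, f"seed {seed}"


class TestJointHistogram:
    def test_constant_pair_occupies_single_cell(self):
        d = joint_histogram(np.full(5, 10.0), np.full(5, 10.0))
        assert d.p.max() == 1.0 and (d.p > 0).sum() == 1

    def test_marginals_match_1d_histograms(self, rng):
        x = rng.uniform(-179.9, 180, 500)
        y = rng.uniform(-179.9, 180, 500)
        d = joint_histogram(x, y)
        assert np.allclose(d.marginal_x, histogram_1d(x).p)
        assert np.allclose(d.marginal_y, histogram_1d(y).p)

    def test_four_hand_listed_pairs(self):
        x = np.array([-179.0, -179.0, 1.0, 175.0])
        y = np.array([-179.0, 1.0, 1.0, -100.0])
        d = joint_histogram(x, y)
        # bins: (-179->0), (1->30), (175->59), (-100->13)
        for cell in [(0, 0), (0, 30), (30, 30), (59, 13)]:
            assert d.p[cell] == 0.25

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_histogram(np.zeros(3) + 1, np.zeros(4) + 1)


class TestJointPeaks:
    def test_product_of_single_bumps_is_one_peak(self):
        p = np.outer(bump(10, 3, 1.0), bump(40, 3, 1.0))
        ps = count_joint_peaks(Distribution2D(p=p, M=10000))
        assert ps.n_peaks == 1

    def test_nearby_maxima_merge(self):
        p = np.full((60, 60), 1e-9)
        p[10, 10] = 0.5
        p[12, 12] = 0.5  # index distance 2 <= 3 on both axes
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert len(ps.tentative) == 2 and ps.n_peaks == 1

    def test_boundary_merge_distance_is_inclusive(self):
        p = np.full((60, 60), 1e-9)
        p[10, 10] = 0.5
        p[13, 13] = 0.5  # exactly 3 -> merged
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert ps.n_peaks == 1
        p[13, 13] = 0.0
        p[14, 14] = 0.5  # 4 -> separate
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert ps.n_peaks == 2

    def test_distant_maxima_stay_separate(self):
        p = np.full((60, 60), 1e-9)
        p[10, 10] = 0.5
        p[40, 40] = 0.5
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert ps.n_peaks == 2

    def test_transitive_merge_chain(self):
        p = np.full((60, 60), 1e-9)
        for k, v in zip((10, 13, 16), (0.5, 0.3, 0.5)):
            p[k, k] = v  # 10-13 and 13-16 mergeable, 10-16 not directly
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert len(ps.tentative) == 3 and ps.n_peaks == 1

    def test_merge_wraps_toroidally(self):
        p = np.full((60, 60), 1e-9)
        p[0, 0] = 0.5
        p[58, 58] = 0.5  # cyclic distance 2
        ps = count_joint_peaks(Distribution2D(p=p / p.sum(), M=10000))
        assert ps.n_peaks == 1

    def test_plateau_flagged(self):
        p = np.full((60, 60), 1.0 / 3600)
        ps = count_joint_peaks(Distribution2D(p=p, M=10000))
        assert ps.degenerate_plateau and ps.n_peaks == 0

    def test_translation_invariance(self, rng):
        p = rng.random((60, 60))
        p /= p.sum()
        base = count_joint_peaks(Distribution2D(p=p, M=10000)).n_peaks
        for dx, dy in [(7, 0), (0, 13), (31, 59)]:
            shifted = np.roll(np.roll(p, dx, axis=0), dy, axis=1)
            assert count_joint_peaks(Distribution2D(p=shifted, M=10000)).n_peaks == base


class TestDistributionDifference:
    def test_product_input_gives_zero(self):
        p = np.outer(bump(5, 4, 1.0), bump(50, 2, 1.0))
        d = Distribution2D(p=p, M=10000)
        assert np.allclose(distribution_difference(d), 0.0, atol=1e-12)

    def test_perfect_diagonal_closed_form(self):
        p = np.zeros((60, 60))
        np.fill_diagonal(p, 1.0 / 60)
        d = Distribution2D(p=p, M=10000)
        dp = distribution_difference(d)
        assert np.allclose(np.diag(dp), 1 / 60 - 1 / 3600)
        off = dp[~np.eye(60, dtype=bool)]
        assert np.allclose(off, -1 / 3600)

    def test_sums_to_zero_for_random_input(self, rng):
        p = rng.random((60, 60))
        d = Distribution2D(p=p / p.sum(), M=10000)
        assert distribution_difference(d).sum() == pytest.approx(0.0, abs=1e-9)


class TestHeterogeneity:
    @staticmethod
    def planted(centers, n=60, m=100_000):
        """Delta-p-like grid: positive bumps at centers over a negative sea."""
        p = np.zeros((n, n))
        for cx, cy in centers:
            for dx in range(-2, 3):
                for dy in range(-2, 3):
                    p[(cx + dx) % n, (cy + dy) % n] += 0.1 * (3 - max(abs(dx), abs(dy)))
        p /= p.sum()
        # mix with an independent background so Delta p has the planted peaks
        q = np.full((n, n), 1.0 / n**2)
        return Distribution2D(p=0.6 * p + 0.4 * q, M=m)

    def test_two_peaks_is_homogeneous_with_zero_residual(self):
        res = heterogeneity_score(self.planted([(10, 10), (40, 40)]))
        assert res["verdict"] == "homogeneous"
        assert res["residual"] == 0.0

    def test_three_collinear_peaks_homogeneous(self):
        res = heterogeneity_score(self.planted([(10, 10), (25, 25), (40, 40)]))
        assert res["verdict"] == "homogeneous"
        assert res["residual"] == pytest.approx(0.0, abs=0.75)

    def test_l_shaped_peaks_heterogeneous(self):
        res = heterogeneity_score(self.planted([(10, 10), (30, 10), (10, 30)]))
        assert res["verdict"] == "heterogeneous"
        assert res["residual"] > 1.5

    def test_independent_pair_has_no_peaks(self, rng):
        x = rng.uniform(-179.9, 180, 200_000)
        y = rng.uniform(-179.9, 180, 200_000)
        res = heterogeneity_score(joint_histogram(x, y))
        assert res["verdict"] == "independent"
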