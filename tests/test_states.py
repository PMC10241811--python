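"""GS topography, state clustering, node strength and entropies."""

import numpy as np
import pytest
from scipy import stats

from hierflux import (
    cluster_states,
    centroid_contrast,
    connectivity_entropy,
    global_signal,
    gs_topography,
    make_windows,
    node_strength,
    sample_entropy,
    state_entropy_summary,
    window_topographies,
)
from hierflux.core import RegionTimeSeries
from hierflux.states import StateClustering
from hierflux.synth import make_gradient, make_topography_families


class TestGlobalSignal:
    def test_single_region_identity(self, rng):
        x = rng.standard_normal((100, 1))
        assert np.array_equal(global_signal(RegionTimeSeries(x, 1.0)), x[:, 0])

    def test_antiphase_cancellation(self):
        t = np.arange(200) * 1.0
        s = np.sin(2 * np.pi * 0.02 * t)
        ts = RegionTimeSeries(np.column_stack([s, -s]), 1.0)
        assert np.allclose(global_signal(ts), 0.0, atol=1e-12)

    def test_matches_mean_oracle(self, rng):
        x = rng.standard_normal((50, 7))
        assert np.allclose(global_signal(RegionTimeSeries(x, 1.0)), x.mean(axis=1))


class TestGsTopography:
    def test_region_equal_to_gs(self, rng):
        x = rng.standard_normal((60, 3))
        gs = x.mean(axis=1)
        data = np.column_stack([gs, x])
        topo = gs_topography(RegionTimeSeries(data, 1.0))
        # region 0 is not exactly the new GS, but correlates near 1 with it
        oracle = [
            stats.pearsonr(data.mean(axis=1), data[:, i]).statistic for i in range(4)
        ]
        assert np.allclose(topo, oracle, atol=1e-12)

    def test_anti_gs_region(self):
        t = np.arange(100.0)
        base = np.sin(0.3 * t)
        # three copies and one negated: GS = base/2, anticorrelated region -> -1
        data = np.column_stack([base, base, base, -base])
        topo = gs_topography(RegionTimeSeries(data, 1.0))
        assert np.isclose(topo[3], -1.0) and np.allclose(topo[:3], 1.0)

    def test_constant_region_flagged(self, rng):
        data = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        topo = gs_topography(RegionTimeSeries(data, 1.0))
        assert np.isnan(topo[0])


class TestClusterStates:
    def test_planted_families_recovered(self, gradient200):
        topo, labels = make_topography_families(96, 200, gradient200, seed=0)
        cl = cluster_states(topo, k_select=2, seed=0)
        acc = max((cl.labels == labels).mean(), (cl.labels != labels).mean())
        assert acc >= 0.95

    def test_silhouette_prefers_two_planted_families(self, gradient200):
        topo, _ = make_topography_families(96, 200, gradient200, seed=1)
        cl = cluster_states(topo, seed=0)
        assert cl.k == 2
        assert cl.silhouettes[2] > cl.silhouettes[3]

    def test_deterministic_under_fixed_seed(self, gradient200):
        topo, _ = make_topography_families(60, 200, gradient200, seed=2)
        c1 = cluster_states(topo, k_select=2, seed=7)
        c2 = cluster_states(topo, k_select=2, seed=7)
        assert np.array_equal(c1.labels, c2.labels)
        assert np.allclose(c1.centroids, c2.centroids)

    def test_degenerate_identical_topographies_error(self):
        with pytest.raises(ValueError, match="identical"):
            cluster_states(np.ones((20, 5)), k_select=2, seed=0)


class TestCentroidContrast:
    def test_identical_centroids_zero_map(self):
        cl = StateClustering(
            labels=np.array([0, 1, 0, 1]),
            centroids=np.ones((2, 6)),
            k=2,
            silhouettes={2: 0.0},
        )
        g = np.linspace(-1, 1, 6)
        assert np.allclose(centroid_contrast(cl, g), 0.0)

    def test_planted_split_recovers_gradient(self, gradient200):
        topo, _ = make_topography_families(96, 200, gradient200, seed=3)
        cl = cluster_states(topo, k_select=2, seed=0)
        contrast = centroid_contrast(cl, gradient200)
        assert stats.spearmanr(contrast, gradient200).statistic > 0.9

    def test_sign_convention_state1_higher_similarity(self, gradient200):
        topo, _ = make_topography_families(96, 200, gradient200, seed=4)
        cl = cluster_states(topo, k_select=2, seed=0)
        contrast = centroid_contrast(cl, gradient200)
        # contrast = higher-similarity centroid minus the other -> positive slope
        assert stats.spearmanr(contrast, gradient200).statistic > 0

    def test_requires_two_states(self, gradient200):
        topo, _ = make_topography_families(90, 200, gradient200, seed=5)
        cl = cluster_states(topo, k_select=3, seed=0)
        with pytest.raises(ValueError, match="two-state"):
            centroid_contrast(cl, gradient200)


class TestNodeStrength:
    def test_all_ones(self):
        c = np.ones((4, 4))
        assert np.allclose(node_strength(c), 3.0)

    def test_zero_matrix(self):
        assert np.allclose(node_strength(np.zeros((5, 5))), 0.0)

    def test_matches_row_sum_oracle(self, rng):
        a = rng.standard_normal((8, 8))
        c = (a + a.T) / 2
        oracle = np.array([np.delete(c[i], i).sum() for i in range(8)])
        assert np.allclose(node_strength(c), oracle, atol=1e-12)


class TestConnectivityEntropy:
    def test_concentrated_distribution_low_entropy(self):
        # 49 values in the first bin, 1 in the last: H follows the two-bin formula
        v = np.concatenate([np.zeros(49), [1.0]])
        p = np.array([49 / 50, 1 / 50])
        oracle = -(p * np.log(p)).sum() / np.log(10)
        assert abs(connectivity_entropy(v) - oracle) < 1e-12

    def test_exactly_uniform_counts_one(self):
        # 10 values per bin, bins exactly equal width
        v = np.concatenate([np.linspace(i, i + 0.9, 10) for i in range(10)])
        assert np.isclose(connectivity_entropy(v, n_bins=10), 1.0, atol=1e-6)

    def test_matches_bruteforce(self, rng):
        v = rng.standard_normal(199)
        counts, _ = np.histogram(v, bins=10, range=(v.min(), v.max()))
        p = counts / counts.sum()
        p = p[p > 0]
        oracle = -(p * np.log(p)).sum() / np.log(10)
        assert abs(connectivity_entropy(v) - oracle) < 1e-12

    def test_affine_invariance_and_range(self, rng):
        v = rng.standard_normal(200)
        h = connectivity_entropy(v)
        assert 0.0 <= h <= 1.0
        assert np.isclose(connectivity_entropy(3.0 * v - 1.0), h, atol=1e-12)

    def test_constant_row_zero(self):
        assert connectivity_entropy(np.zeros(30)) == 0.0


def sample_entropy_oracle(x, m=2, r_factor=0.5):
    """Exhaustive pair count over all templates (independent of the impl)."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_factor * x.std(ddof=1)

    def count(mm):
        tot = 0
        for i in range(n - mm + 1):
            for j in range(n - mm + 1):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    tot += 1
        return tot // 2

    b, a = count(m), count(m + 1)
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return -np.log(a / b)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(20)) == 0.0

    def test_short_series_matches_exhaustive_oracle(self):
        # a strict ramp has no length-2 matches at r = 0.5 SD: flagged undefined
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert np.isnan(sample_entropy(x)) and np.isnan(sample_entropy_oracle(x))
        # a periodic series has exact template repeats at both lengths
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0])
        got, want = sample_entropy(y), sample_entropy_oracle(y)
        assert np.isfinite(got) and abs(got - want) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_random_series_matches_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(40)
        got, want = sample_entropy(x), sample_entropy_oracle(x)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert abs(got - want) < 1e-12

    def test_noise_more_entropic_than_sine(self, rng):
        wins = 0
        t = np.arange(500)
        for _ in range(20):
            noise = rng.standard_normal(500)
            sine = np.sin(2 * np.pi * t / 50) * noise.std(ddof=1) * np.sqrt(2)
            wins += sample_entropy(noise) > sample_entropy(sine)
        assert wins >= 19

    def test_monotone_in_tolerance(self, rng):
        x = rng.standard_normal(300)
        h = [sample_entropy(x, r_factor=r) for r in (0.2, 0.4, 0.8, 1.6)]
        assert all(a >= b for a, b in zip(h, h[1:]))


class TestStateEntropySummary:
    def test_row_count_matches_windows(self, rng):
        ts = RegionTimeSeries(rng.standard_normal((200, 10)), 1.0)
        windows = make_windows(200, 50)
        out = state_entropy_summary(ts, windows)
        assert len(out["connectivity_entropy"]) == 4
        assert len(out["sample_entropy"]) == 4

    def test_identical_windows_zero_state_difference(self, rng):
        block = rng.standard_normal((50, 8))
        ts = RegionTimeSeries(np.tile(block, (4, 1)), 1.0)
        windows = make_windows(200, 50)
        out = state_entropy_summary(ts, windows)
        assert np.allclose(out["connectivity_entropy"], out["connectivity_entropy"][0])

    def test_planted_high_diversity_state_detected(self, rng):
        # equal-width binning is affine invariant, so diversity means the
        # SHAPE of a node's FC distribution: graded distance-decay coupling
        # spreads values across bins (high H) while a tight two-block
        # structure concentrates them in two bins (low H)
        from scipy.ndimage import gaussian_filter1d

        n_reg, n_fr = 20, 50
        diffs = []
        for rep in range(8):
            graded = gaussian_filter1d(
                rng.standard_normal((n_fr, n_reg)), sigma=3.0, axis=1, mode="wrap"
            )
            block_id = (np.arange(n_reg) >= n_reg // 2).astype(float)
            common = rng.standard_normal((n_fr, 2))
            blocky = common[:, block_id.astype(int)] + 0.2 * rng.standard_normal((n_fr, n_reg))
            ts = RegionTimeSeries(np.vstack([graded, blocky]), 1.0)
            out = state_entropy_summary(ts, make_windows(2 * n_fr, n_fr))
            diffs.append(out["connectivity_entropy"][0] - out["connectivity_entropy"][1])
        assert stats.wilcoxon(diffs, alternative="greater").pvalue < 0.05
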