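import numpy as np
import pytest

from bsmap.cluster import (MCConfig, cluster_threshold, estimate_fwhm,
                           extract_clusters, label_connected,
                           simulate_null_max_clusters, ClusterExtentCorrection,
                           NullDistribution)
from bsmap.preprocess import smooth_map
from bsmap.stats import one_sample_tmap
from conftest import flood_fill_components, full_single_view


class TestLabelConnected:
    def test_diagonal_adjacency(self, full16):
        binary = np.zeros((16, 16), bool)
        binary[3, 3] = binary[4, 4] = True
        _, sizes4 = label_connected(binary, full16, connectivity=4)
        _, sizes8 = label_connected(binary, full16, connectivity=8)
        assert sizes4 == [1, 1]
        assert sizes8 == [2]

    def test_empty_map(self, full16):
        labels, sizes = label_connected(np.zeros((16, 16), bool), full16)
        assert sizes == [] and labels.max() == 0

    def test_clusters_never_span_views(self):
        # fully-masked canvas whose views touch: a bar crossing the
        # panel boundary must still split into one cluster per view
        from bsmap.template import BodyTemplate
        view_labels = np.ones((16, 16), np.uint8)
        view_labels[:, 8:] = 2
        tpl = BodyTemplate(np.ones((16, 16), bool), view_labels)
        binary = np.zeros((16, 16), bool)
        binary[8] = True
        labels, sizes = label_connected(binary, tpl, connectivity=8)
        assert sizes == [8, 8]
        assert {tuple(np.unique(tpl.view_labels[labels == k])) for k in (1, 2)} \
            == {(1,), (2,)}

    def test_labels_ordered_by_size_then_scan_order(self, full16):
        binary = np.zeros((16, 16), bool)
        binary[10:12, 10:12] = True       # size 4
        binary[0, 0] = True               # size 1, first in scan order
        binary[5, 5] = True               # size 1
        labels, sizes = label_connected(binary, full16)
        assert sizes == [4, 1, 1]
        assert labels[0, 0] == 2 and labels[5, 5] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        tpl = full_single_view(12)
        rng = np.random.default_rng(99)
        for _ in range(50):
            binary = rng.random((12, 12)) < 0.4
            labels, sizes = label_connected(binary, tpl, connectivity)
            oracle = set(flood_fill_components(binary, tpl.view_labels, connectivity))
            got = {frozenset(map(tuple, np.argwhere(labels == k)))
                   for k in range(1, len(sizes) + 1)}
            assert got == oracle


class TestMCConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MCConfig(voxel_p=0.0)
        with pytest.raises(ValueError):
            MCConfig(n_iterations=10)
        with pytest.raises(ValueError):
            MCConfig(connectivity=6)

    def test_z_critical_matches_sidedness(self):
        from scipy import stats as sps
        assert MCConfig(two_sided=True).z_critical == pytest.approx(sps.norm.isf(0.025))
        assert MCConfig(two_sided=False).z_critical == pytest.approx(sps.norm.isf(0.05))


class TestNullSimulation:
    def test_suprathreshold_count_matches_binomial_expectation(self):
        tpl = full_single_view(10)
        config = MCConfig(n_iterations=2000, voxel_p=0.05, fwhm_px=0.0,
                          two_sided=False, seed=5)
        null = simulate_null_max_clusters(tpl, config)
        # crude: with p=0.05 on 100 unsmoothed pixels the largest cluster
        # is small but present in most iterations
        assert 0 < null.max_cluster_sizes.mean() < 4

        # direct check of the per-pixel exceedance rate
        rng = np.random.default_rng(6)
        count = 0
        iters = 2000
        for _ in range(iters):
            v = rng.standard_normal(100)
            v = (v - v.mean()) / v.std(ddof=1)
            count += (v > config.z_critical).sum()
        assert count / iters == pytest.approx(5.0, abs=0.5)

    def test_same_seed_reproduces_distribution(self, full16):
        config = MCConfig(n_iterations=300, fwhm_px=3.0, seed=7)
        a = simulate_null_max_clusters(full16, config)
        b = simulate_null_max_clusters(full16, config)
        assert np.array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_different_seeds_differ(self, full16):
        a = simulate_null_max_clusters(full16, MCConfig(n_iterations=300, seed=1))
        b = simulate_null_max_clusters(full16, MCConfig(n_iterations=300, seed=2))
        assert not np.array_equal(a.max_cluster_sizes, b.max_cluster_sizes)


class TestClusterThreshold:
    def test_enumerated_example(self):
        null = NullDistribution(np.array([1, 1, 1, 10] * 25),
                                MCConfig(n_iterations=100))
        thr = cluster_threshold(null, corrected_alpha=0.25)
        assert thr.size == 1 and thr.achieved_alpha == pytest.approx(0.25)

    def test_all_zero_null_gives_zero_threshold(self):
        null = NullDistribution(np.zeros(100, dtype=int), MCConfig(n_iterations=100))
        thr = cluster_threshold(null, corrected_alpha=0.05)
        assert thr.size == 0 and thr.achieved_alpha == 0.0

    def test_threshold_monotone_in_voxel_p_and_fwhm(self, full16):
        def thr(voxel_p, fwhm):
            config = MCConfig(n_iterations=500, voxel_p=voxel_p, fwhm_px=fwhm,
                              seed=42)
            return cluster_threshold(simulate_null_max_clusters(full16, config)).size

        assert thr(0.01, 2.0) <= thr(0.05, 2.0)
        assert thr(0.05, 0.0) <= thr(0.05, 4.0)


class TestExtractClusters:
    def _stat_with_blob(self, tpl, pixels):
        rng = np.random.default_rng(50)
        stack = rng.normal(size=(12, *tpl.shape)) * 0.3
        for r, c in pixels:
            stack[:, r, c] += 3.0
        return one_sample_tmap(stack, tpl)

    def test_no_suprathreshold_pixels_gives_empty_set(self, full16):
        stat = one_sample_tmap(
            np.random.default_rng(8).normal(size=(5, 16, 16)), full16)
        stat.p[:] = 1.0  # force no pixel below the voxel threshold
        cs = extract_clusters(stat, full16, MCConfig(), extent_threshold=0)
        assert cs.n_clusters == 0 and cs.n_surviving == 0

    def test_strict_extent_inequality(self, full16):
        pixels = [(5, 5), (5, 6), (5, 7), (6, 5), (6, 6)]  # blob of 5
        stat = self._stat_with_blob(full16, pixels)
        config = MCConfig(voxel_p=0.001)
        cs4 = extract_clusters(stat, full16, config, extent_threshold=4)
        cs5 = extract_clusters(stat, full16, config, extent_threshold=5)
        assert 5 in [cs4.sizes[i - 1] for i in cs4.surviving_ids]
        assert cs5.n_surviving == 0

    def test_positive_only_drops_negative_clusters(self, full16):
        rng = np.random.default_rng(51)
        stack = rng.normal(size=(12, 16, 16)) * 0.3
        stack[:, 2:4, 2:4] -= 3.0
        stat = one_sample_tmap(stack, full16)
        pos = extract_clusters(stat, full16, MCConfig(positive_only=True), 0)
        both = extract_clusters(stat, full16, MCConfig(positive_only=False), 0)
        for cid in range(1, pos.n_clusters + 1):
            assert stat.t[pos.labels == cid].max() > 0
        assert both.n_clusters >= pos.n_clusters + 1

    def test_peaks_recorded(self, full16):
        stat = self._stat_with_blob(full16, [(9, 9), (9, 10)])
        cs = extract_clusters(stat, full16, MCConfig(voxel_p=0.001), 0)
        df = cs.to_dataframe()
        assert {"id", "size", "peak_z", "peak_row", "peak_col", "view",
                "surviving"} <= set(df.columns)
        top = df.iloc[0]
        assert (top.peak_row, top.peak_col) in [(9, 9), (9, 10)]


def test_estimator_fit_transform_round_trip(full16):
    rng = np.random.default_rng(60)
    stack = rng.normal(size=(10, 16, 16)) * 0.2
    stack[:, 6:10, 6:10] += 2.0
    corr = ClusterExtentCorrection(template=full16, n_iterations=500,
                                   fwhm_px=2.0, seed=3).fit()
    assert corr.extent_threshold_ >= 0
    assert corr.achieved_alpha_ <= 0.05
    cs = corr.transform(one_sample_tmap(stack, full16))
    assert cs.extent_threshold == corr.extent_threshold_
    assert cs.n_surviving >= 1


def test_fwhm_estimate_recovers_smoothing_scale():
    tpl = full_single_view(96)
    rng = np.random.default_rng(70)
    fwhm = 6.0
    stack = np.stack([smooth_map(rng.standard_normal(tpl.shape), fwhm, tpl)
                      for _ in range(12)])
    est = estimate_fwhm(stack, tpl)
    assert est == pytest.approx(fwhm, rel=0.25)
    white = rng.standard_normal((12, 96, 96))
    assert estimate_fwhm(white, tpl) < 1.5
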