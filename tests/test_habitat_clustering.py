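"""Feature extraction, standardization, k-means habitats and region tests."""

import numpy as np
import pytest

import sarcoreg as sr
from sarcoreg.habitat_clustering import (
    holm_adjust,
    significance_stars,
)
from sarcoreg.imaging_io import CHANNEL_ORDER, FormatError


def small_stack(rng, shape=(4, 4, 3), roi_mask=None):
    grid = dict(spacing=(1.0, 1.0, 1.0), origin=np.zeros(3), direction=np.eye(3))
    if roi_mask is None:
        roi_mask = np.zeros(shape, dtype=np.int16)
        roi_mask.flat[: 10] = 1
    roi = sr.Volume(roi_mask.astype(np.int16), **grid)
    channels = {
        name: sr.Volume(rng.uniform(1, 10, shape), **grid) for name in CHANNEL_ORDER
    }
    return sr.ParametricMapStack(channels, roi)


class TestExtractFeatures:
    def test_ten_voxel_roi_gives_10x8_matrix(self, rng):
        stack = small_stack(rng)
        features, idx, dropped = sr.extract_features(stack)
        assert features.shape == (10, 8)
        assert idx.shape == (10, 3)
        assert dropped == 0

    def test_nan_voxel_dropped_and_counted(self, rng):
        stack = small_stack(rng)
        first_roi_voxel = tuple(np.argwhere(stack.roi.data > 0)[0])
        stack.channels["ADC"].data[first_roi_voxel] = np.nan
        features, idx, dropped = sr.extract_features(stack)
        assert features.shape == (9, 8)
        assert dropped == 1

    def test_rows_match_direct_indexing_oracle(self, rng):
        stack = small_stack(rng)
        features, idx, _ = sr.extract_features(stack)
        for row, voxel in zip(features[:5], idx[:5]):
            expected = [stack.channels[c].data[tuple(voxel)] for c in CHANNEL_ORDER]
            np.testing.assert_allclose(row, expected)

    def test_empty_roi_rejected(self, rng):
        stack = small_stack(rng, roi_mask=np.zeros((4, 4, 3), dtype=np.int16))
        with pytest.raises(FormatError, match="empty"):
            sr.extract_features(stack)


class TestStandardize:
    def test_hand_z_score(self):
        x = np.array([[1.0], [2.0], [3.0]])
        z, scaler = sr.standardize(x)
        np.testing.assert_allclose(z[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(0, 1, (200, 4))
        z, _ = sr.standardize(x)
        z2, _ = sr.standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_inverse_round_trip(self, rng):
        x = rng.uniform(-5, 50, (50, 8))
        z, scaler = sr.standardize(x)
        np.testing.assert_allclose(scaler.inverse(z), x, atol=1e-10)

    def test_zero_variance_column_names_channel(self):
        x = np.ones((10, 8))
        x[:, 1:] += np.arange(10)[:, None]
        with pytest.raises(FormatError, match="ADC"):
            sr.standardize(x)


class TestKMeans:
    def test_two_separated_clouds_perfectly_split(self, rng):
        a = rng.normal(0, 1, (50, 8))
        b = rng.normal(100, 1, (50, 8))
        x = np.vstack([a, b])
        labels, inertia, _ = sr.kmeans_cluster(x, k=2, seed=0)
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]
        within = sum(((g - g.mean(0)) ** 2).sum() for g in (a, b))
        assert inertia == pytest.approx(within, rel=1e-9)

    def test_k_equal_n_gives_zero_inertia(self, rng):
        x = rng.uniform(0, 1, (6, 8))
        _, inertia, _ = sr.kmeans_cluster(x, k=6, seed=0)
        assert inertia == pytest.approx(0, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(0, 1, (100, 8))
        l1, i1, _ = sr.kmeans_cluster(x, k=4, seed=3)
        l2, i2, _ = sr.kmeans_cluster(x, k=4, seed=3)
        np.testing.assert_array_equal(l1, l2)
        assert i1 == i2

    def test_invariant_to_voxel_shuffling_up_to_relabeling(self, rng):
        from sklearn.metrics import adjusted_rand_score

        x = np.vstack([rng.normal(m, 0.5, (60, 8)) for m in (0.0, 4.0, 8.0)])
        l1, _, _ = sr.kmeans_cluster(x, k=3, seed=1)
        perm = rng.permutation(len(x))
        l2, _, _ = sr.kmeans_cluster(x[perm], k=3, seed=1)
        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_k_bounds_rejected(self, rng):
        x = rng.uniform(0, 1, (5, 8))
        with pytest.raises(FormatError):
            sr.kmeans_cluster(x, k=1)
        with pytest.raises(FormatError):
            sr.kmeans_cluster(x, k=6)


class TestMapLabels:
    def test_single_cluster_fills_roi_with_label_one(self, rng):
        stack = small_stack(rng)
        _, idx, _ = sr.extract_features(stack)
        vol, _ = sr.map_labels(np.zeros(len(idx), dtype=int), idx, stack.roi)
        assert set(vol.data[stack.roi.data > 0]) == {1}
        assert np.all(vol.data[stack.roi.data == 0] == 0)

    def test_labels_sorted_by_descending_size(self, rng):
        stack = small_stack(rng)
        _, idx, _ = sr.extract_features(stack)
        assignments = np.array([0, 0, 0, 1, 1, 1, 1, 1, 2, 2])
        vol, renumber = sr.map_labels(assignments, idx, stack.roi)
        # cluster 1 (5 voxels) -> label 1, cluster 0 (3) -> 2, cluster 2 (2) -> 3
        assert renumber[1] == 1 and renumber[0] == 2 and renumber[2] == 3

    def test_extract_cluster_map_round_trip(self, rng):
        stack = small_stack(rng, shape=(6, 6, 4), roi_mask=np.ones((6, 6, 4)))
        features, idx, _ = sr.extract_features(stack)
        z, _ = sr.standardize(features)
        assignments, _, _ = sr.kmeans_cluster(z, k=3, seed=0)
        vol, renumber = sr.map_labels(assignments, idx, stack.roi)
        re_extracted = vol.data[tuple(idx.T)]
        np.testing.assert_array_equal(re_extracted, renumber[assignments])


class TestRegionStats:
    def _stack_with_labels(self, values_by_region, rng):
        shape = (4, 4, 2)
        grid = dict(spacing=(1.0, 1.0, 1.0), origin=np.zeros(3), direction=np.eye(3))
        labels = np.zeros(shape, dtype=np.int16)
        flat = labels.ravel()
        pos = 0
        for region, vals in values_by_region.items():
            flat[pos : pos + len(vals)] = region
            pos += len(vals)
        roi = sr.Volume((labels > 0).astype(np.int16), **grid)
        channels = {}
        for name in CHANNEL_ORDER:
            data = np.zeros(shape)
            dflat = data.ravel()
            pos = 0
            for region, vals in values_by_region.items():
                dflat[pos : pos + len(vals)] = vals
                pos += len(vals)
            channels[name] = sr.Volume(data, **grid)
        stack = sr.ParametricMapStack(channels, roi)
        label_vol = sr.Volume(labels, **grid)
        return stack, label_vol

    def test_hand_mean_and_sd(self, rng):
        stack, labels = self._stack_with_labels({1: [300.0, 320.0]}, rng)
        table = sr.region_stats(stack, labels).table
        row = table[(table.region == 1) & (table.channel == "Ktrans")].iloc[0]
        assert row["mean"] == pytest.approx(310.0)
        assert row["sd"] == pytest.approx(np.sqrt(200), abs=0.01)  # ~14.14

    def test_single_voxel_region_flagged_with_zero_sd(self, rng):
        stack, labels = self._stack_with_labels({1: [5.0, 6.0], 2: [9.0]}, rng)
        stats = sr.region_stats(stack, labels)
        row = stats.table[(stats.table.region == 2)].iloc[0]
        assert row["sd"] == 0.0
        assert any("region 2" in f for f in stats.flags)


class TestHolmAndStars:
    def test_holm_matches_brute_force_stepdown(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # brute force: sort, multiply by (m - rank), cumulative max, cap 1
        order = np.argsort(p)
        expected = np.empty(4)
        cummax = 0.0
        for rank, idx in enumerate(order):
            cummax = max(cummax, (4 - rank) * p[idx])
            expected[idx] = min(1.0, cummax)
        np.testing.assert_allclose(holm_adjust(p), expected)
        np.testing.assert_allclose(holm_adjust(p), [0.03, 0.06, 0.06, 0.02])

    def test_holm_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_star_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.00004) == "****"


class TestCompareRegions:
    def test_identical_regions_not_significant(self):
        g = np.arange(10.0)
        report = sr.compare_regions({"ADC": [g, g.copy(), g.copy()]})
        assert (report["p_adjusted"] >= 0.05).all()
        assert (report["stars"] == "ns").all()

    def test_ten_pooled_sd_separation_highly_significant(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)
        report = sr.compare_regions({"Ktrans": [a, b]})
        assert (report["p_adjusted"] < 0.0001).all()
        assert (report["stars"] == "****").all()

    def test_anova_f_matches_hand_sums_of_squares(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([6.0, 7, 8])]
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / 6)
        report = sr.compare_regions({"f": groups}, equal_var=True)
        assert report["anova_F"].iloc[0] == pytest.approx(f_hand)

    def test_degenerate_region_rejected(self):
        with pytest.raises(FormatError, match="fewer than 2"):
            sr.compare_regions({"ADC": [np.array([1.0, 2.0]), np.array([3.0])]})


def brute_force_ari(a, b):
    """Chance-corrected pair-counting agreement between two labelings."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    sum_ij = sum(
        comb(np.sum((a == ca) & (b == cb)), 2)
        for ca in np.unique(a)
        for cb in np.unique(b)
    )
    sum_a = sum(comb(np.sum(a == ca), 2) for ca in np.unique(a))
    sum_b = sum(comb(np.sum(b == cb), 2) for cb in np.unique(b))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestARIOracle:
    def test_sklearn_ari_matches_pair_counting(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(5):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 4, 60)
            assert adjusted_rand_score(a, b) == pytest.approx(
                brute_force_ari(a, b), abs=1e-12
            )
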