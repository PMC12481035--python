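import numpy as np
import pandas as pd
import pytest

import minfluxpair as mp
from minfluxpair.spatial import dbscan, ripley_h

from _oracles import brute_dbscan, brute_nearest_neighbor, brute_ripley_k


def centers_from(points: np.ndarray) -> mp.TraceCenterSet:
    pts = np.asarray(points, dtype=float)
    return mp.TraceCenterSet(df=pd.DataFrame({
        "trace_id": np.arange(len(pts)), "n_locs": np.full(len(pts), 5),
        "x_nm": pts[:, 0], "y_nm": pts[:, 1],
    }))


class TestDbscan:
    def test_single_point_is_noise(self):
        assert dbscan(np.array([[0.0, 0.0]]), 40.0, 2).tolist() == [-1]

    def test_pair_clusters_far_point_noise(self):
        labels = dbscan(np.array([[0.0, 0.0], [18.0, 0.0], [200.0, 0.0]]), 40.0, 2)
        assert labels.tolist() == [0, 0, -1]

    def test_radius_is_inclusive(self):
        labels = dbscan(np.array([[0.0, 0.0], [40.0, 0.0]]), 40.0, 2)
        assert labels.tolist() == [0, 0]

    def test_border_point_joins_lowest_index_core(self):
        # cores at (0,0) and (4,0) (each with two non-core supporters); the
        # point at (2,0) is border to both clusters and must join the cluster
        # of its lowest-index core neighbor
        pts = np.array([
            [0.0, 0.0], [0.0, 2.0], [0.0, -2.0],
            [4.0, 0.0], [4.0, 2.0], [4.0, -2.0],
            [2.0, 0.0],
        ])
        labels = dbscan(pts, 2.6, 4)
        assert labels[0] != labels[3]  # two distinct clusters
        assert labels[6] == labels[0]  # border resolves to the lower core index

    def test_empty_input(self):
        assert dbscan(np.empty((0, 2)), 1.0, 1).size == 0

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 120))
            pts = rng.uniform(0, 200, (n, 2))
            radius = float(rng.uniform(2, 40))
            min_pts = int(rng.integers(1, 6))
            fast = dbscan(pts, radius, min_pts)
            slow = brute_dbscan(pts, radius, min_pts)
            np.testing.assert_array_equal(fast, slow)


class TestNearestNeighbor:
    def test_two_points(self):
        d = mp.nearest_neighbor_distances(centers_from([[0, 0], [18, 0]]))
        np.testing.assert_allclose(d, [18.0, 18.0])

    def test_collinear_points(self):
        d = mp.nearest_neighbor_distances(centers_from([[0, 0], [10, 0], [25, 0]]))
        np.testing.assert_allclose(d, [10.0, 10.0, 15.0])

    def test_single_point_rejected(self):
        with pytest.raises(mp.InsufficientDataError):
            mp.nearest_neighbor_distances(centers_from([[0, 0]]))

    def test_matches_bruteforce_exactly(self, rng):
        pts = rng.uniform(0, 5000, (500, 2))
        np.testing.assert_array_equal(
            mp.nearest_neighbor_distances(centers_from(pts)),
            brute_nearest_neighbor(pts),
        )


class TestIsolatedPairs:
    def test_simple_pair_detected(self):
        pairs = mp.find_isolated_pairs(centers_from([[0, 0], [18, 0], [200, 0]]))
        assert pairs.count == 1
        assert pairs.distances[0] == pytest.approx(18.0)
        row = pairs.pairs.iloc[0]
        assert (row.mid_x_nm, row.mid_y_nm) == (9.0, 0.0)

    def test_chain_of_three_is_not_a_pair(self):
        # 18 -> 50 gap is 32 <= 40, so DBSCAN chains all three
        pairs = mp.find_isolated_pairs(centers_from([[0, 0], [18, 0], [50, 0]]))
        assert pairs.count == 0

    def test_third_center_quenches_pair(self):
        pairs = mp.find_isolated_pairs(centers_from([[0, 0], [18, 0], [18 + 35, 0]]))
        assert pairs.count == 0

    def test_every_pair_is_mutual_nn_and_isolated(self, rng):
        for trial in range(10):
            pts = rng.uniform(0, 2000, (120, 2))
            pairs = mp.find_isolated_pairs(centers_from(pts), 40.0)
            nn = brute_nearest_neighbor(pts)
            for _, row in pairs.pairs.iterrows():
                assert row.third_nn_nm > 40.0
                i = int(row.trace_id_a)
                j = int(row.trace_id_b)
                assert nn[i] == pytest.approx(row.distance_nm)
                assert nn[j] == pytest.approx(row.distance_nm)

    def test_empty_and_too_few_inputs(self):
        assert mp.find_isolated_pairs(centers_from(np.empty((0, 2)))).count == 0


class TestClusterAnalysis:
    def test_square_cluster_geometry(self):
        pts = [[0, 0], [20, 0], [20, 20], [0, 20]]
        clusters = mp.cluster_analysis(centers_from(pts), mp.ClusterParams())
        assert clusters.count == 1
        row = clusters.clusters.iloc[0]
        assert row.composition == 4
        assert row.size_nm == pytest.approx(20 * np.sqrt(2))
        assert row.area_nm2 == pytest.approx(400.0)
        assert row.density_per_nm2 == pytest.approx(0.01)
        assert not row.hull_degenerate

    def test_three_points_below_min_size_no_cluster(self):
        pts = [[0, 0], [10, 0], [0, 10]]
        clusters = mp.cluster_analysis(centers_from(pts), mp.ClusterParams())
        assert clusters.count == 0

    def test_collinear_cluster_uses_ribbon_fallback(self):
        pts = [[0, 0], [10, 0], [20, 0], [30, 0]]
        clusters = mp.cluster_analysis(centers_from(pts), mp.ClusterParams())
        row = clusters.clusters.iloc[0]
        assert row.hull_degenerate
        assert row.area_nm2 == pytest.approx(30.0)  # size x 1 nm

    def test_recovers_simulated_cluster_count(self):
        # compact clusters (sd 10 nm << 40 nm search radius) guarantee every
        # group contains a DBSCAN core; at wider spreads a 4-member Gaussian
        # cluster occasionally has no core and count equality is only
        # statistical
        cfg = mp.SimulationConfig(monomer_density=0, dimer_density=0,
                                  cluster_density=0.4, cluster_size_n=4,
                                  cluster_sigma=10.0, label_efficiency_p=1.0,
                                  sigma_loc=0.0, background_trace_rate=0.0,
                                  locs_per_trace_lambda=20.0,
                                  min_anchor_spacing=300.0, seed=21)
        truth, table = mp.simulate_table(cfg)
        centers = mp.compute_trace_centers(mp.filter_localizations(table))
        clusters = mp.cluster_analysis(centers, mp.ClusterParams())
        assert clusters.count == truth.n_groups("cluster")

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 1000, (80, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([5000.0, -300.0])
        c1 = mp.cluster_analysis(centers_from(pts))
        c2 = mp.cluster_analysis(centers_from(moved))
        assert c1.count == c2.count
        np.testing.assert_allclose(
            np.sort(c1.clusters["composition"]), np.sort(c2.clusters["composition"]))
        np.testing.assert_allclose(
            np.sort(c1.clusters["size_nm"]), np.sort(c2.clusters["size_nm"]), rtol=1e-9)
        p1 = mp.find_isolated_pairs(centers_from(pts))
        p2 = mp.find_isolated_pairs(centers_from(moved))
        np.testing.assert_allclose(np.sort(p1.distances), np.sort(p2.distances), rtol=1e-9)


class TestRipley:
    def test_square_hand_computation(self):
        # 4 corners of a 10-nm square in a 100x100 ROI at r=10:
        # 8 ordered pairs within r -> K = 10000/12 * 8
        pts = np.array([[45, 45], [55, 45], [55, 55], [45, 55]], dtype=float)
        curve = ripley_h(pts, [10.0], (0, 0, 100, 100), "none")
        assert curve.K[0] == pytest.approx(10_000.0 / 12.0 * 8.0)
        assert curve.L[0] == pytest.approx(np.sqrt(curve.K[0] / np.pi))
        assert curve.H[0] == pytest.approx(curve.L[0] - 10.0)

    def test_far_points_give_h_equal_minus_r(self):
        pts = np.array([[10.0, 10.0], [900.0, 900.0]])
        radii = np.arange(5.0, 101.0, 5.0)
        curve = ripley_h(pts, radii, (0, 0, 1000, 1000), "translation")
        np.testing.assert_array_equal(curve.K, 0.0)
        np.testing.assert_allclose(curve.H, -radii)

    @pytest.mark.parametrize("correction", ["none", "translation"])
    def test_matches_direct_count_oracle(self, rng, correction):
        pts = rng.uniform(0, 500, (60, 2))
        radii = np.array([10.0, 50.0, 120.0, 200.0])
        curve = ripley_h(pts, radii, (0, 0, 500, 500), correction)
        ref = brute_ripley_k(pts, radii, (0, 0, 500, 500), correction)
        np.testing.assert_allclose(curve.K, ref, rtol=1e-10)

    def test_identities_hold(self, rng):
        pts = rng.uniform(0, 1000, (100, 2))
        radii = np.arange(10.0, 201.0, 10.0)
        curve = ripley_h(pts, radii, (0, 0, 1000, 1000), "translation")
        np.testing.assert_allclose(curve.L, np.sqrt(curve.K / np.pi))
        np.testing.assert_allclose(curve.H, curve.L - radii)
        assert (np.diff(curve.K) >= 0).all()

    def test_uncorrected_k_nondecreasing(self, rng):
        pts = rng.uniform(0, 1000, (100, 2))
        curve = ripley_h(pts, np.arange(5.0, 501.0, 5.0), (0, 0, 1000, 1000), "none")
        assert (np.diff(curve.K) >= 0).all()

    def test_radius_beyond_half_roi_rejected(self):
        with pytest.raises(mp.DomainError, match="half"):
            ripley_h(np.zeros((3, 2)), [600.0], (0, 0, 1000, 1000), "none")

    def test_too_few_points_rejected(self):
        with pytest.raises(mp.InsufficientDataError):
            ripley_h(np.array([[1.0, 1.0]]), [10.0], (0, 0, 100, 100), "none")

    def test_uncorrected_biased_down_translation_unbiased_on_csr(self, rng):
        # edge losses drag uncorrected H below zero at large r
        radii = np.arange(50.0, 401.0, 50.0)
        roi = (0.0, 0.0, 1000.0, 1000.0)
        h_none, h_trans = [], []
        for _ in range(40):
            pts = rng.uniform(0, 1000, (150, 2))
            h_none.append(ripley_h(pts, radii, roi, "none").H)
            h_trans.append(ripley_h(pts, radii, roi, "translation").H)
        mean_none = np.mean(h_none, axis=0)
        mean_trans = np.mean(h_trans, axis=0)
        assert mean_none[-1] < -20.0
        assert abs(mean_trans[-1]) < abs(mean_none[-1]) / 4


class TestCompareConditions:
    def test_identical_samples_symmetric(self):
        res = mp.compare_conditions([1, 2, 3], [1, 2, 3])
        assert res["U"] == pytest.approx(4.5)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["method"] == "exact-enumeration"

    def test_fully_separated_samples(self):
        res = mp.compare_conditions([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p_value"] == pytest.approx(0.1)

    def test_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 6).tolist()
        b = rng.normal(0.5, 1, 5).tolist()
        r1 = mp.compare_conditions(a, b)
        r2 = mp.compare_conditions(b, a)
        assert r1["U"] + r2["U"] == pytest.approx(len(a) * len(b))
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        res = mp.compare_conditions(a, b)
        assert res["method"] == "normal-approximation"
        from scipy import stats
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res["p_value"] == pytest.approx(float(ref.pvalue))

    def test_exact_agrees_with_scipy_when_no_ties(self, rng):
        a = rng.normal(0, 1, 7).tolist()
        b = rng.normal(1, 1, 6).tolist()
        res = mp.compare_conditions(a, b)
        from scipy import stats
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res["p_value"] == pytest.approx(float(ref.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(mp.InsufficientDataError):
            mp.compare_conditions([], [1.0])
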