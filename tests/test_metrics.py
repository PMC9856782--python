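"""Within-module degree z, participation coefficient, lobe-level connectivity."""

import numpy as np
import pytest

from fdnet import (
    CovarianceNetwork,
    connectivity_ratio,
    link_counts,
    lobe_connectivity,
    node_metrics,
    participation_coefficient,
    within_module_degree_z,
)

from conftest import network_from_edges


class TestWithinModuleDegreeZ:
    def test_star_module(self):
        # 5-node star: degrees (4,1,1,1,1), mean 1.6, population sd 1.2
        net = network_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        z = within_module_degree_z(net, np.ones(5, int))
        assert z[0] == pytest.approx(2.0)
        assert np.allclose(z[1:], -0.5)

    def test_equal_degree_module_all_zero(self):
        net = network_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert np.allclose(within_module_degree_z(net, np.ones(4, int)), 0.0)

    def test_singleton_module_zero(self):
        net = network_from_edges(3, [(0, 1)])
        z = within_module_degree_z(net, np.array([1, 1, 2]))
        assert z[2] == 0.0

    def test_module_zscores_standardized(self, rng):
        """Within any module with sd > 0: mean Z = 0, population sd of Z = 1."""
        n = 20
        w = (rng.random((n, n)) < 0.4).astype(float)
        w = np.triu(w, 1)
        w += w.T
        net = CovarianceNetwork(weights=w, threshold_fraction=1.0)
        labels = rng.integers(1, 4, n)
        z = within_module_degree_z(net, labels)
        for m in np.unique(labels):
            zm = z[labels == m]
            adj = net.adjacency[np.ix_(labels == m, labels == m)]
            if adj.sum(axis=1).std() > 0:
                assert abs(zm.mean()) < 1e-12
                assert abs(zm.std() - 1.0) < 1e-12


class TestParticipationCoefficient:
    def test_all_links_within_own_module_gives_zero(self):
        net = network_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        p = participation_coefficient(net, np.array([1, 1, 1, 2, 2, 2]))
        assert np.allclose(p, 0.0)

    def test_two_links_split_across_two_modules(self):
        net = network_from_edges(4, [(0, 1), (0, 2)])
        p = participation_coefficient(net, np.array([1, 1, 2, 2]))
        assert p[0] == pytest.approx(0.5)

    def test_uniform_spread_over_four_modules(self):
        # node 0 has 4 links, one into each of 4 modules (its own included)
        net = network_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        labels = np.array([1, 1, 2, 3, 4])
        p = participation_coefficient(net, labels)
        assert p[0] == pytest.approx(0.75)

    def test_isolated_node_zero(self):
        net = network_from_edges(3, [(0, 1)])
        assert participation_coefficient(net, np.array([1, 1, 2]))[2] == 0.0

    def test_degree_decomposition_and_upper_bound(self, rng):
        """sum_c K_ci = K_i exactly; P_i <= 1 - 1/n_modules."""
        n = 25
        w = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
        w += w.T
        net = CovarianceNetwork(weights=w, threshold_fraction=1.0)
        labels = rng.integers(1, 5, n)
        k_total = net.adjacency.sum(axis=1)
        k_parts = np.stack(
            [net.adjacency[:, labels == m].sum(axis=1) for m in np.unique(labels)]
        )
        assert np.array_equal(k_parts.sum(axis=0), k_total)
        p = participation_coefficient(net, labels)
        assert np.all(p <= 1 - 1 / len(np.unique(labels)) + 1e-12)
        assert np.all(p >= 0)


class TestLobeConnectivity:
    def frontal_only_network(self, region_table, edges, weights=None):
        n = 68
        w = np.zeros((n, n))
        for k, (i, j) in enumerate(edges):
            w[i, j] = w[j, i] = 1.0 if weights is None else weights[k]
        return CovarianceNetwork(
            weights=w, threshold_fraction=1.0, region_table=region_table
        )

    def test_no_cross_lobe_edges_gives_zero_inter(self, region_table):
        # edges only inside the frontal lobe (nodes 0..27)
        net = self.frontal_only_network(region_table, [(0, 1), (2, 3), (0, 3)])
        report = lobe_connectivity(net, region_table, mode="weight")
        assert np.allclose(report.table["inter"], 0.0)

    def test_literal_mode_mean_z_is_zero_when_sd_positive(self, region_table, rng):
        w = np.triu((rng.random((68, 68)) < 0.2).astype(float) * rng.random((68, 68)), 1)
        w += w.T
        net = CovarianceNetwork(weights=w, threshold_fraction=1.0)
        report = lobe_connectivity(net, region_table, mode="literal")
        # z-scores average to ~0 inside each defining module
        assert np.allclose(report.table["intra_mean_z"], 0.0, atol=1e-12)

    def test_weight_mode_matches_hand_computed_mean(self, region_table):
        edges = [(0, 1), (2, 3), (4, 5)]
        weights = [0.6, 0.4, 0.8]
        net = self.frontal_only_network(region_table, edges, weights)
        report = lobe_connectivity(net, region_table, mode="weight")
        assert report.lobe("frontal")["intra"] == pytest.approx(np.mean(weights))
        assert report.lobe("temporal")["intra"] == 0.0

    def test_unknown_mode_rejected(self, region_table):
        net = self.frontal_only_network(region_table, [(0, 1)])
        with pytest.raises(ValueError, match="mode"):
            lobe_connectivity(net, region_table, mode="median")


class TestLinkCounts:
    def test_bilateral_edge_counted_as_B(self, region_table):
        # region ids 1 (L) and 2 (R), both frontal
        net = network_from_edges(68, [(0, 1)])
        counts = link_counts(net, region_table)
        assert counts.loc["frontal", "links_B"] == 1
        assert counts.loc["frontal", "links_L"] == 0

    def test_empty_network_all_zero(self, region_table):
        net = CovarianceNetwork(weights=np.zeros((68, 68)), threshold_fraction=1.0)
        assert (link_counts(net, region_table).to_numpy() == 0).all()

    def test_hand_counted_frontal_edges(self, region_table):
        # L-L (ids 1,3), R-R (ids 2,4), L-R (ids 1,4): indices are id-1
        net = network_from_edges(68, [(0, 2), (1, 3), (0, 3)])
        counts = link_counts(net, region_table)
        assert counts.loc["frontal"].tolist() == [1, 1, 1]
        total = counts.loc["frontal"].sum()
        # oracle: brute edge scan restricted to the lobe
        idx = set(region_table.lobe_indices("frontal"))
        brute = sum(
            1
            for i in range(68)
            for j in range(i + 1, 68)
            if net.adjacency[i, j] and i in idx and j in idx
        )
        assert total == brute


class TestConnectivityRatio:
    def test_identical_reports_give_100(self, region_table, rng):
        w = np.triu(rng.random((68, 68)) * (rng.random((68, 68)) < 0.3), 1)
        w += w.T
        net = CovarianceNetwork(weights=w, threshold_fraction=1.0)
        report = lobe_connectivity(net, region_table)
        ratios = connectivity_ratio(report, report)
        assert np.allclose(ratios, 100.0)

    def test_halved_within_lobe_weights_give_50(self, region_table):
        within = [(0, 1), (29, 31), (47, 49), (61, 63)]  # one edge per lobe
        cross = [(0, 29), (29, 47), (47, 61), (61, 0)]  # keep inter nonzero
        edges = within + cross
        w_a = [0.8] * 4 + [0.5] * 4
        w_b = [0.4] * 4 + [0.5] * 4
        ra = lobe_connectivity(network_from_edges(68, edges, w_a), region_table)
        rb = lobe_connectivity(network_from_edges(68, edges, w_b), region_table)
        ratios = connectivity_ratio(ra, rb)
        assert np.allclose(ratios["intra_ratio_pct"], 50.0)
        # participation is adjacency-based and the adjacency is unchanged
        assert np.allclose(ratios["inter_ratio_pct"], 100.0)

    def test_zero_reference_rejected(self, region_table):
        net_a = network_from_edges(68, [(0, 1)])
        net_b = network_from_edges(68, [(0, 1)])
        ra = lobe_connectivity(net_a, region_table)
        rb = lobe_connectivity(net_b, region_table)
        with pytest.raises(ValueError, match="zero reference"):
            connectivity_ratio(ra, rb)


def test_node_metrics_frame(region_table, rng):
    w = np.triu((rng.random((68, 68)) < 0.2) * rng.random((68, 68)), 1)
    w += w.T
    net = CovarianceNetwork(weights=w, threshold_fraction=1.0)
    labels = rng.integers(1, 5, 68)
    nm = node_metrics(net, labels)
    df = nm.to_dataframe(region_table)
    assert list(df.columns) == [
        "region_id",
        "abbreviation",
        "degree",
        "z_within_module",
        "participation",
    ]
    assert len(df) == 68
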