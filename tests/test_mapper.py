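import itertools

import networkx as nx
import numpy as np
import pytest

from protmiss.mapper import (
    MapperConfig,
    MapperGraph,
    MapperNode,
    build_cover,
    build_mapper,
    cluster_preimage,
    compare_topologies,
    cover_membership,
    detect_communities,
    distance_matrix,
    enrich_missingness,
    lens_eccentricity,
    lens_ppca_first,
)
from protmiss.matrix import ProteinMatrix
from protmiss.profile import profile_missingness

from _oracles import max_modularity, naive_mapper


class TestDistanceMatrix:
    def test_three_four_five(self):
        m = ProteinMatrix.from_values(np.array([[0.0, 0.0], [3.0, 4.0]]))
        D = distance_matrix(m)
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0 and D[1, 0] == D[0, 1]

    def test_pairwise_complete_scaling(self):
        # one of two proteins co-masked: distance over the shared coordinate × √2
        values = np.array([[0.0, np.nan], [3.0, np.nan]])
        m = ProteinMatrix.from_values(values)
        D = distance_matrix(m, "pairwise_complete_scaled")
        assert D[0, 1] == pytest.approx(3.0 * np.sqrt(2))

    def test_identical_rows_distance_zero(self, rng):
        row = rng.normal(size=6)
        m = ProteinMatrix.from_values(np.vstack([row, row]))
        assert distance_matrix(m)[0, 1] == 0.0

    def test_no_shared_protein_is_an_error(self):
        values = np.array([[1.0, np.nan], [np.nan, 2.0]])
        m = ProteinMatrix.from_values(values)
        with pytest.raises(ValueError, match="share no"):
            distance_matrix(m, "pairwise_complete_scaled")

    def test_complete_only_drops_incomplete_samples(self):
        values = np.array([[1.0, 2.0], [np.nan, 3.0], [0.0, 0.0]])
        D = distance_matrix(ProteinMatrix.from_values(values), "complete_only")
        assert np.isnan(D[1]).all()
        assert D[0, 2] == pytest.approx(np.hypot(1, 2))

    def test_matches_naive_loop_oracle(self, rng):
        from _oracles import naive_pairwise_distance

        values = rng.normal(size=(8, 5))
        mask = rng.random((8, 5)) < 0.25
        mask[:, 0] = False  # guarantee a shared protein for every pair
        values_masked = values.copy()
        values_masked[mask] = np.nan
        m = ProteinMatrix.from_values(values_masked)
        D = distance_matrix(m)
        assert np.allclose(D, naive_pairwise_distance(values, mask), atol=1e-10)


class TestLenses:
    def test_collinear_eccentricity(self):
        D = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        assert lens_eccentricity(D).tolist() == [2.0, 1.0, 2.0]

    def test_identical_points(self):
        assert lens_eccentricity(np.zeros((4, 4))).tolist() == [0.0] * 4

    def test_unit_square_symmetry(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        D = distance_matrix(ProteinMatrix.from_values(pts))
        assert np.allclose(lens_eccentricity(D), np.sqrt(2))

    def test_l1_variant_is_mean_distance(self):
        D = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
        assert np.allclose(lens_eccentricity(D, p=1), [2.0, 1.5, 2.5])

    def test_ppca_lens_recovers_rank1_factor(self, rng):
        u = rng.normal(size=40)
        v = rng.uniform(1, 2, 12)
        m = ProteinMatrix.from_values(np.outer(u, v) + 14)
        scores = lens_ppca_first(m)
        assert abs(np.corrcoef(scores, u)[0, 1]) >= 0.99

    def test_duplicated_samples_get_equal_scores(self, rng):
        row = rng.normal(14, 1, 8)
        other = rng.normal(14, 1, 8)
        m = ProteinMatrix.from_values(np.vstack([row, row, other]))
        scores = lens_ppca_first(m)
        assert scores[0] == pytest.approx(scores[1])

    def test_sign_convention_positive_correlation_with_means(self, rng):
        m = ProteinMatrix.from_values(rng.normal(14, 2, (30, 6)))
        scores = lens_ppca_first(m)
        means = m.values.mean(axis=1)
        assert np.corrcoef(scores, means)[0, 1] > 0


class TestCover:
    def test_two_intervals_half_overlap(self):
        x = np.array([0.0, 1.0])
        cover = build_cover(x, x, intervals=(2, 1), overlap=0.5)
        ax1 = sorted({r1 for (_, _), r1, _ in cover})
        assert ax1[0] == pytest.approx((0.0, 2.0 / 3.0))
        assert ax1[1] == pytest.approx((1.0 / 3.0, 1.0))

    def test_zero_overlap_partitions_range(self):
        x = np.linspace(0, 1, 11)
        cover = build_cover(x, x, intervals=(4, 1), overlap=0.0)
        ax1 = sorted({r1 for (_, _), r1, _ in cover})
        for i, (lo, hi) in enumerate(ax1):
            assert lo == pytest.approx(i * 0.25)
            assert hi == pytest.approx((i + 1) * 0.25)

    def test_single_interval_spans_range(self):
        x = np.array([2.0, 5.0])
        cover = build_cover(x, x, intervals=(1, 1), overlap=0.3)
        assert cover[0][1] == (2.0, 5.0)

    def test_every_point_covered_for_random_configs(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n_pts = rng.integers(2, 40)
            x1 = rng.normal(size=n_pts)
            x2 = rng.normal(size=n_pts)
            n1, n2 = rng.integers(1, 8, 2)
            g = rng.uniform(0, 0.95)
            cover = build_cover(x1, x2, (int(n1), int(n2)), g)
            members = cover_membership(x1, x2, cover)
            covered = set(np.concatenate([mm for mm in members]) if members else [])
            assert covered == set(range(n_pts))

    def test_zero_range_axis_collapses_to_one_interval(self):
        x1 = np.full(5, 3.0)
        x2 = np.arange(5.0)
        cover = build_cover(x1, x2, (4, 2), 0.5)
        assert {i1 for (i1, _), _, _ in cover} == {0}
        members = cover_membership(x1, x2, cover)
        assert set(np.concatenate(members)) == set(range(5))


class TestClusterPreimage:
    def test_gap_separates_two_groups(self, rng):
        a = rng.normal(0, 0.05, (5, 2))
        b = rng.normal(10, 0.05, (4, 2))
        pts = np.vstack([a, b])
        D = distance_matrix(ProteinMatrix.from_values(pts))
        clusters = cluster_preimage(np.arange(9), D, clustering_bins=10)
        assert sorted(map(len, clusters)) == [4, 5]
        assert sorted(clusters[0]) == [0, 1, 2, 3, 4]

    def test_singleton(self):
        assert cluster_preimage(np.array([7]), np.zeros((1, 1)), 10) == [[7]]

    def test_all_equal_distances_stay_one_cluster(self):
        D = np.ones((5, 5)) - np.eye(5)
        clusters = cluster_preimage(np.arange(5), D, clustering_bins=10)
        assert clusters == [[0, 1, 2, 3, 4]]

    def test_zero_heights_stay_one_cluster(self):
        D = np.zeros((3, 3))
        assert cluster_preimage(np.arange(3), D, 10) == [[0, 1, 2]]


def _random_fixture(rng):
    n = int(rng.integers(5, 13))
    p = int(rng.integers(3, 6))
    values = rng.normal(14, 2, (n, p))
    if rng.random() < 0.5:
        mask = rng.random((n, p)) < 0.2
        mask[:, 0] = False
        values[mask] = np.nan
    m = ProteinMatrix.from_values(values)
    intervals = (2, 2) if rng.random() < 0.5 else (3, 2)
    cfg = MapperConfig(
        lens1="l_infinity_eccentricity",
        lens2="ppca_first_component",
        intervals=intervals,
        overlap=float(rng.uniform(0.2, 0.6)),
        clustering_bins=int(rng.integers(5, 12)),
    )
    return m, cfg


def _canonical(graph: MapperGraph, m: ProteinMatrix):
    idx = {s: i for i, s in enumerate(m.sample_ids)}
    keys = [(n.bin_index, frozenset(idx[s] for s in n.members)) for n in graph.nodes]
    nodes = set(keys)
    edges = {frozenset((keys[u], keys[v])) for u, v in graph.edges}
    return nodes, edges


class TestBuildMapper:
    def test_two_blobs_split_into_pure_components(self, rng):
        a = rng.normal(0, 0.3, (12, 4))
        b = rng.normal(20, 0.3, (10, 4))
        m = ProteinMatrix.from_values(np.vstack([a, b]))
        g = build_mapper(m, MapperConfig(intervals=(4, 4), overlap=0.5))
        nxg = g.to_networkx()
        assert nx.number_connected_components(nxg) >= 2
        blob = {s: (0 if int(s[1:]) <= 12 else 1) for s in m.sample_ids}
        for comp in nx.connected_components(nxg):
            samples = {s for nid in comp for s in g.nodes[nid].members}
            assert len({blob[s] for s in samples}) == 1

    def test_single_sample(self):
        m = ProteinMatrix.from_values(np.array([[1.0, 2.0]]))
        g = build_mapper(m, MapperConfig(intervals=(2, 2)))
        assert len(g.nodes) == 1 and g.edges == []
        assert g.nodes[0].members == ["S1"]

    def test_coverage_and_edge_definition(self, rng):
        for _ in range(10):
            m, cfg = _random_fixture(rng)
            g = build_mapper(m, cfg, seed=0)
            covered = {s for n in g.nodes for s in n.members}
            assert covered == set(m.sample_ids)
            member_sets = {n.node_id: set(n.members) for n in g.nodes}
            expected_edges = {
                (u, v)
                for u, v in itertools.combinations(sorted(member_sets), 2)
                if member_sets[u] & member_sets[v]
            }
            assert set(map(tuple, g.edges)) == expected_edges

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            m, cfg = _random_fixture(rng)
            g = build_mapper(m, cfg, seed=1)
            D = distance_matrix(m, cfg.missing_policy)
            lens1 = lens_eccentricity(D)
            lens2 = lens_ppca_first(m, seed=1)
            o_nodes, o_edges = naive_mapper(
                m.values, m.mask, lens1, lens2,
                cfg.intervals, cfg.overlap, cfg.clustering_bins,
            )
            g_nodes, g_edges = _canonical(g, m)
            o_keys = [(b, s) for b, s in o_nodes]
            assert g_nodes == set(o_keys)
            o_edge_keys = {frozenset((o_keys[a], o_keys[b])) for a, b in o_edges}
            assert g_edges == o_edge_keys

    def test_determinism(self, ckd_small_dataset):
        m = ckd_small_dataset.observed.subset_proteins(
            ckd_small_dataset.observed.missing_fraction_per_protein() < 0.5
        ).subset_samples(np.arange(40))
        cfg = MapperConfig(intervals=(4, 4))
        a = build_mapper(m, cfg, seed=3)
        b = build_mapper(m, cfg, seed=3)
        assert [(n.node_id, n.members, n.bin_index) for n in a.nodes] == [
            (n.node_id, n.members, n.bin_index) for n in b.nodes
        ]
        assert a.edges == b.edges


class TestEnrichment:
    def _graph(self, members_per_node):
        nodes = [MapperNode(i, mem, (0, i)) for i, mem in enumerate(members_per_node)]
        samples = sorted({s for mem in members_per_node for s in mem})
        return MapperGraph(nodes=nodes, edges=[], sample_ids=samples)

    def _profile(self, fractions):
        values = np.array([[np.nan if k < int(round(f * 10)) else 14.0 for k in range(10)]
                           for f in fractions])
        m = ProteinMatrix(
            [f"S{i + 1}" for i in range(len(fractions))],
            [f"P{j}" for j in range(10)], values,
        )
        return profile_missingness(m)

    def test_mean_percentage(self):
        g = self._graph([["S1", "S2"]])
        prof = self._profile([0.4, 0.6])
        assert enrich_missingness(g, prof).node_enrichment[0] == pytest.approx(50.0)

    def test_complete_members_are_zero(self):
        g = self._graph([["S1", "S2"]])
        prof = self._profile([0.0, 0.0])
        assert enrich_missingness(g, prof).node_enrichment[0] == 0.0

    def test_singleton_node(self):
        g = self._graph([["S1"], ["S2"]])
        prof = self._profile([0.3, 0.7])
        enriched = enrich_missingness(g, prof)
        assert enriched.node_enrichment[0] == pytest.approx(30.0)
        assert enriched.node_enrichment[1] == pytest.approx(70.0)

    def test_member_without_profile_entry(self):
        g = self._graph([["S1", "S9"]])
        prof = self._profile([0.1])
        with pytest.raises(KeyError, match="S9"):
            enrich_missingness(g, prof)


def _graph_from_nx(nxg: nx.Graph) -> MapperGraph:
    nodes = [MapperNode(i, [f"S{i}"], (0, 0)) for i in nxg.nodes]
    return MapperGraph(
        nodes=nodes,
        edges=[tuple(sorted(e)) for e in nxg.edges],
        sample_ids=[f"S{i}" for i in nxg.nodes],
    )


class TestCommunities:
    def test_two_disconnected_triangles(self):
        nxg = nx.Graph()
        nxg.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        g = detect_communities(_graph_from_nx(nxg))
        labels = g.communities
        assert len(set(labels.values())) == 2
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert g.community_method == "exact"

    @pytest.mark.parametrize("graph_maker", [
        lambda: nx.path_graph(6),
        lambda: nx.cycle_graph(7),
        lambda: nx.complete_graph(5),
        lambda: nx.barbell_graph(3, 1),
        lambda: nx.karate_club_graph().subgraph(range(8)).copy(),
        lambda: nx.star_graph(5),
    ])
    def test_exact_modularity_matches_exhaustive_search(self, graph_maker):
        nxg = graph_maker()
        g = detect_communities(_graph_from_nx(nxg))
        adj = nx.to_numpy_array(nxg, nodelist=sorted(nxg.nodes), weight=None)
        assert g.modularity == pytest.approx(max_modularity(adj), abs=1e-12)

    def test_edgeless_graph_singleton_communities(self):
        nxg = nx.empty_graph(4)
        g = detect_communities(_graph_from_nx(nxg))
        assert sorted(g.communities.values()) == [0, 1, 2, 3]
        assert g.modularity == 0.0


class TestCompareTopologies:
    def test_self_comparison_is_perfect(self, rng):
        m = ProteinMatrix.from_values(rng.normal(14, 1, (15, 4)))
        g = build_mapper(m, MapperConfig(intervals=(3, 3)))
        rec = compare_topologies(g, g)
        assert rec["adjusted_rand_index"] == pytest.approx(1.0)
        assert rec["non_imputed"]["n_nodes"] == len(g.nodes)

    def test_one_block_partition_scores_low(self, rng):
        a = rng.normal(0, 0.3, (10, 3))
        b = rng.normal(15, 0.3, (10, 3))
        m = ProteinMatrix.from_values(np.vstack([a, b]))
        g = build_mapper(m, MapperConfig(intervals=(4, 4)))
        blob = MapperGraph(
            nodes=[MapperNode(0, list(m.sample_ids), (0, 0))],
            edges=[], sample_ids=list(m.sample_ids),
        )
        rec = compare_topologies(g, blob)
        assert rec["adjusted_rand_index"] <= 0.05

    def test_disjoint_sample_sets_rejected(self):
        g1 = MapperGraph(nodes=[MapperNode(0, ["A"], (0, 0))], edges=[], sample_ids=["A"])
        g2 = MapperGraph(nodes=[MapperNode(0, ["B"], (0, 0))], edges=[], sample_ids=["B"])
        with pytest.raises(ValueError, match="disjoint"):
            compare_topologies(g1, g2)
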