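import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import sgascreen as sga
from sgascreen.network import (
    build_network,
    cluster_network,
    gap_statistic,
    kmeans_cluster,
    read_edge_list,
    spectral_embed,
)
from sgascreen.simulate import ValidationError, simulate_module_network


def write_edges(tmp_path, rows, header="node1\tnode2\tcombined_score"):
    path = tmp_path / "edges.tsv"
    lines = [header] + [f"{a}\t{b}\t{s}" for a, b, s in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadEdgeList:
    def test_reciprocal_edges_merged_keeping_max(self, tmp_path):
        path = write_edges(tmp_path, [("A", "B", 900), ("B", "A", 700)])
        net = read_edge_list(path)
        assert net.number_of_edges() == 1
        assert net["A"]["B"]["weight"] == pytest.approx(0.9)

    def test_disconnected_genes_dropped(self, tmp_path):
        path = write_edges(
            tmp_path, [("A", "B", 800), ("B", "C", 700), ("D", "E", 100)]
        )
        net = read_edge_list(path, min_confidence=0.4)
        assert set(net.nodes) == {"A", "B", "C"}

    def test_confidence_threshold_boundary(self, tmp_path):
        path = write_edges(tmp_path, [("A", "B", 0.39), ("C", "D", 0.41)],
                           header="a\tb\tscore")
        net = read_edge_list(path, min_confidence=0.4, score_scale="unit")
        assert set(net.nodes) == {"C", "D"}
        assert net.number_of_edges() == 1

    def test_unit_scale_autodetected(self, tmp_path):
        path = write_edges(tmp_path, [("A", "B", 0.8), ("B", "C", 0.5)],
                           header="a\tb\tscore")
        net = read_edge_list(path)
        assert net["A"]["B"]["weight"] == pytest.approx(0.8)

    def test_whitelist_restricts_nodes(self, tmp_path):
        path = write_edges(tmp_path, [("A", "B", 900), ("B", "C", 900)])
        net = read_edge_list(path, node_whitelist={"A", "B"})
        assert set(net.nodes) == {"A", "B"}

    def test_mostly_malformed_file_rejected(self, tmp_path):
        rows = [("A", "B", 900)] + [("X", "Y", "bad")] * 5
        path = write_edges(tmp_path, rows)
        with pytest.raises(ValidationError):
            read_edge_list(path)

    def test_self_loops_discarded(self, tmp_path):
        path = write_edges(tmp_path, [("A", "A", 900), ("A", "B", 800)])
        net = read_edge_list(path)
        assert net.number_of_edges() == 1


class TestSpectralEmbed:
    def two_cliques(self):
        rows = []
        for block, names in enumerate((list("abcd"), list("wxyz"))):
            for i, u in enumerate(names):
                for v in names[i + 1:]:
                    rows.append((u, v, 0.9))
        return build_network(rows)

    def test_disjoint_cliques_map_to_two_points(self):
        emb = spectral_embed(self.two_cliques(), 2)
        blocks = [emb.loc[list("abcd")].to_numpy(), emb.loc[list("wxyz")].to_numpy()]
        for block in blocks:
            assert np.allclose(block, block[0], atol=1e-9)
        assert not np.allclose(blocks[0][0], blocks[1][0], atol=1e-6)

    def test_single_edge_gives_opposite_equal_coordinates(self):
        net = build_network([("A", "B", 0.7)])
        emb = spectral_embed(net, 1)
        a, b = emb.loc["A", "dim1"], emb.loc["B", "dim1"]
        assert a == pytest.approx(-b)
        assert abs(a) == pytest.approx(1.0)  # row-normalized

    def test_complete_graph_collapses_to_one_point_cluster(self):
        nodes = [f"n{i}" for i in range(6)]
        rows = [(u, v, 0.5) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        net = build_network(rows)
        emb = spectral_embed(net, 2)
        asg = kmeans_cluster(emb, 1, seed=0)
        assert asg.inertia == pytest.approx(
            float(((emb - emb.mean()) ** 2).to_numpy().sum()), abs=1e-9
        )

    def test_dimension_bounds_enforced(self):
        net = build_network([("A", "B", 0.9), ("B", "C", 0.9)])
        with pytest.raises(ValidationError):
            spectral_embed(net, 3)

    def test_deterministic_under_node_permutation(self):
        rows = [("A", "B", 0.9), ("B", "C", 0.8), ("C", "D", 0.7), ("D", "A", 0.6)]
        emb1 = spectral_embed(build_network(rows), 2)
        emb2 = spectral_embed(build_network(rows[::-1]), 2)
        pd.testing.assert_frame_equal(emb1, emb2)


class TestKmeansCluster:
    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        emb = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"))
        asg = kmeans_cluster(emb, 6, seed=0)
        assert asg.inertia == pytest.approx(0.0)
        assert sorted(asg.labels.values()) == [1, 2, 3, 4, 5, 6]

    def test_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        pts = np.vstack([c + 0.01 * rng.standard_normal((20, 2)) for c in centers])
        emb = pd.DataFrame(pts, index=[f"n{i:02d}" for i in range(60)])
        planted = np.repeat([0, 1, 2], 20)
        for seed in range(20):
            asg = kmeans_cluster(emb, 3, seed=seed)
            assert adjusted_rand_score(planted, list(asg.labels.values())) == 1.0

    def test_k_one_inertia_is_total_dispersion(self):
        rng = np.random.default_rng(1)
        emb = pd.DataFrame(rng.normal(size=(30, 3)))
        emb.index = [f"n{i}" for i in range(30)]
        asg = kmeans_cluster(emb, 1, seed=0)
        x = emb.to_numpy()
        assert asg.inertia == pytest.approx(((x - x.mean(0)) ** 2).sum())

    def test_labels_canonical_by_size_then_gene(self):
        emb = pd.DataFrame(
            [[0.0, 0], [0.01, 0], [0.02, 0], [5.0, 0], [5.01, 0]],
            index=["z1", "z2", "z3", "a1", "a2"],
        )
        asg = kmeans_cluster(emb, 2, seed=0)
        assert asg.labels["z1"] == 1  # larger cluster first
        assert asg.labels["a1"] == 2

    def test_invalid_k_rejected(self):
        emb = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"))
        with pytest.raises(ValidationError):
            kmeans_cluster(emb, 0)
        with pytest.raises(ValidationError):
            kmeans_cluster(emb, 5)


def blob_embedding(seed, n_blobs=5, per_blob=30, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 6, (n_blobs, 2))
    pts = np.vstack([c + spread * rng.standard_normal((per_blob, 2)) for c in centers])
    return pd.DataFrame(pts, index=[f"n{i:03d}" for i in range(len(pts))])


class TestGapStatistic:
    def test_planted_five_blobs_selected(self):
        g = gap_statistic(blob_embedding(0), 1, 8, B=20, seed=0)
        assert g.chosen_k == 5

    def test_single_tight_blob_selects_k_min(self):
        rng = np.random.default_rng(0)
        emb = pd.DataFrame(rng.standard_normal((100, 2)) * 0.01)
        emb.index = [f"n{i}" for i in range(100)]
        g = gap_statistic(emb, 1, 6, B=20, seed=0)
        assert g.chosen_k == 1

    def test_choice_stable_in_reference_count(self):
        emb = blob_embedding(3)
        g_small = gap_statistic(emb, 1, 8, B=10, seed=1)
        g_large = gap_statistic(emb, 1, 8, B=50, seed=1)
        assert g_small.chosen_k == g_large.chosen_k == 5

    def test_table_covers_scanned_range(self):
        g = gap_statistic(blob_embedding(1), 2, 6, B=10, seed=0)
        assert list(g.table["k"]) == [2, 3, 4, 5, 6]
        assert (g.table["s_k"] >= 0).all()
        assert 2 <= g.chosen_k <= 6

    def test_within_dispersion_nonincreasing_in_k(self):
        g = gap_statistic(blob_embedding(2), 1, 8, B=10, seed=0)
        log_wk = g.table["log_wk"].to_numpy()
        assert (np.diff(log_wk) <= 1e-9).all()

    def test_parameter_validation(self):
        emb = blob_embedding(0)
        with pytest.raises(ValidationError):
            gap_statistic(emb, 1, len(emb), B=20, seed=0)
        with pytest.raises(ValidationError):
            gap_statistic(emb, 1, 8, B=5, seed=0)
        with pytest.raises(ValidationError):
            gap_statistic(emb, 1, 8, B=20, seed=0, rule="bogus")


class TestClusterNetwork:
    def test_planted_block_model_recovered(self):
        genes = [f"g{i:03d}" for i in range(250)]
        edges, modules = simulate_module_network(genes, 5, 0.5, 0.01, seed=1)
        net = build_network(edges.itertuples(index=False, name=None))
        asg, gap = cluster_network(net, seed=0, B=20)
        assert gap.chosen_k == 5
        ari = adjusted_rand_score(
            [modules[g] for g in asg.labels], list(asg.labels.values())
        )
        assert ari >= 0.95

    def test_forced_k_respected(self):
        genes = [f"g{i:03d}" for i in range(100)]
        edges, _ = simulate_module_network(genes, 4, 0.5, 0.02, seed=0)
        net = build_network(edges.itertuples(index=False, name=None))
        asg, gap = cluster_network(net, k=5, seed=0)
        assert gap is None
        assert asg.k == 5
        assert set(asg.labels.values()) == {1, 2, 3, 4, 5}

    def test_empty_network_rejected(self):
        import networkx as nx

        with pytest.raises(ValidationError):
            cluster_network(nx.Graph())

    def test_every_connected_node_labeled(self):
        genes = [f"g{i:02d}" for i in range(60)]
        edges, _ = simulate_module_network(genes, 3, 0.5, 0.02, seed=2)
        net = build_network(edges.itertuples(index=False, name=None))
        asg, _ = cluster_network(net, k=3, seed=0)
        assert set(asg.labels) == set(net.nodes)
        assert sorted(set(asg.labels.values())) == [1, 2, 3]
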