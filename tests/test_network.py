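"""Prior loading, subnetwork extraction/pruning/merging, centralities and
mutation overrepresentation."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crosstalk import network
import oracles


def _annotated(edges, node_fdr=None, edge_fdr=None):
    """Build an annotated directed graph. ``node_fdr``/``edge_fdr`` map
    elements to FDR values; annotated nodes also get |NES| = 1."""
    g = nx.DiGraph()
    g.add_edges_from(edges)
    for n, f in (node_fdr or {}).items():
        g.add_node(n)
        g.nodes[n]["fdr"] = f
        g.nodes[n]["nes"] = 1.0
    for e, f in (edge_fdr or {}).items():
        g[e[0]][e[1]]["fdr"] = f
    return g


class TestLoadPrior:
    def _write(self, tmp_path, rows):
        path = tmp_path / "prior.tsv"
        header = "ENTITYA\tENTITYB\tEFFECT\tMECHANISM\tRESIDUE\n"
        path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
        return path

    def test_self_loop_dropped(self, tmp_path):
        p = self._write(tmp_path, [
            ("A", "B", "up-regulates", "phosphorylation", "S5"),
            ("B", "C", "down-regulates", "phosphorylation", "T7"),
            ("C", "C", "up-regulates", "phosphorylation", "S9"),
        ])
        g = network.load_prior(p)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_duplicate_edges_union_residues(self, tmp_path):
        p = self._write(tmp_path, [
            ("A", "B", "up-regulates", "phosphorylation", "S5"),
            ("A", "B", "up-regulates", "phosphorylation", "T7"),
        ])
        g = network.load_prior(p)
        assert g["A"]["B"]["residues"] == {"S5", "T7"}

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ENTITYA\tENTITYB\n" + "A\tB\n")
        with pytest.raises(ValueError, match="EFFECT"):
            network.load_prior(path)

    def test_empty_raises(self, tmp_path):
        p = self._write(tmp_path, [])
        with pytest.raises(ValueError, match="no edges"):
            network.load_prior(p)


class TestExtractSubnetwork:
    def test_path_connector_included(self):
        """Perturbed {A, C} joined by the unperturbed chain A->B->C."""
        g = _annotated([("A", "B"), ("B", "C")], node_fdr={"A": 0.01, "C": 0.01})
        sub = network.extract_subnetwork(g)
        assert sub.nodes() == {"A", "B", "C"}
        assert "path_connector" in sub.node_provenance["B"]

    def test_distant_pair_not_connected(self):
        """Distance 3 exceeds the 2-hop cap; only the larger fragment of
        the candidate graph survives the component filter."""
        g = _annotated(
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "X")],
            node_fdr={"A": 0.01, "D": 0.01},
            edge_fdr={("A", "X"): 0.01},
        )
        sub = network.extract_subnetwork(g)
        assert sub.nodes() == {"A", "X"}

    def test_single_perturbed_edge(self):
        g = _annotated([("A", "B"), ("B", "C")], edge_fdr={("A", "B"): 0.04})
        sub = network.extract_subnetwork(g)
        assert sub.nodes() == {"A", "B"}
        assert sub.edges() == {("A", "B")}

    def test_empty_warns(self):
        g = _annotated([("A", "B")])
        with pytest.warns(UserWarning, match="no perturbed"):
            sub = network.extract_subnetwork(g)
        assert sub.empty

    def test_threshold_inclusive(self):
        g = _annotated([("A", "B")], node_fdr={"A": 0.05})
        sub = network.extract_subnetwork(g)
        assert "A" in sub.nodes()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        g = _random_annotated(rng, 20)
        loose = network.extract_subnetwork(g, node_fdr=0.2, edge_fdr=0.2)
        tight = network.extract_subnetwork(g, node_fdr=0.05, edge_fdr=0.05)
        p_tight = {n for n, d in g.nodes(data=True) if d.get("fdr", 1) <= 0.05}
        p_loose = {n for n, d in g.nodes(data=True) if d.get("fdr", 1) <= 0.2}
        assert p_tight <= p_loose
        assert len(loose.nodes()) >= 0  # extraction succeeds at both levels
        del tight

    def test_matches_brute_force_on_random_graphs(self):
        """Element-for-element agreement with the exhaustive-path oracle
        on 50 random annotated graphs (the 200-graph sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            g = _random_annotated(rng, int(rng.integers(5, 30)))
            o_nodes, o_edges = oracles.brute_force_subnetwork(g)
            if not o_nodes:
                continue
            sub = network.extract_subnetwork(g)
            assert sub.nodes() == o_nodes
            assert sub.edges() == o_edges


def _random_annotated(rng, n):
    g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)), directed=True)
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    out = nx.DiGraph()
    out.add_nodes_from(sorted(g.nodes))
    out.add_edges_from(g.edges)
    for node in out.nodes:
        if rng.random() < 0.3:
            out.nodes[node]["fdr"] = float(rng.random() * 0.2)
            out.nodes[node]["nes"] = float(rng.normal())
    for u, v in out.edges:
        if rng.random() < 0.3:
            out[u][v]["fdr"] = float(rng.random() * 0.2)
            out[u][v]["log2fc"] = float(rng.normal())
    return out


class TestPruneRedundantPaths:
    def _diamond(self, annotate_path):
        """A->B->C and A->D->C between perturbed {A, C}; one path carries
        phosphosite annotations."""
        g = _annotated(
            [("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")],
            node_fdr={"A": 0.01, "C": 0.01},
        )
        for u, v in annotate_path:
            g[u][v]["log2fc"] = 1.5
        return network.extract_subnetwork(g)

    def test_unannotated_alternative_removed(self):
        sub = self._diamond([("A", "B"), ("B", "C")])
        pruned = network.prune_redundant_paths(sub)
        assert pruned.nodes() == {"A", "B", "C"}
        assert "D" not in pruned.nodes()
        assert nx.is_connected(pruned.graph.to_undirected(as_view=True))

    def test_nothing_removed_without_annotated_path(self):
        sub = self._diamond([])
        pruned = network.prune_redundant_paths(sub)
        assert pruned.nodes() == sub.nodes()
        assert pruned.edges() == sub.edges()

    def test_shared_connector_kept(self):
        """A connector node serving another retained path survives."""
        g = _annotated(
            [("A", "B"), ("B", "C"), ("A", "D"), ("D", "C"), ("D", "E")],
            node_fdr={"A": 0.01, "C": 0.01, "E": 0.01},
        )
        g["A"]["B"]["log2fc"] = 1.0
        g["B"]["C"]["log2fc"] = 1.0
        sub = network.extract_subnetwork(g)
        pruned = network.prune_redundant_paths(sub)
        # D carries the only route to E: it must stay
        assert "D" in pruned.nodes()
        assert "E" in pruned.nodes()

    def test_never_removes_perturbed_elements(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = _random_annotated(rng, 15)
            try:
                sub = network.extract_subnetwork(g)
            except Exception:
                continue
            if sub.empty:
                continue
            pruned = network.prune_redundant_paths(sub)
            for n, prov in sub.node_provenance.items():
                if "perturbed_node" in prov and n in sub.nodes():
                    assert n in pruned.nodes()
            for e, prov in sub.edge_provenance.items():
                if "perturbed_edge" in prov:
                    assert e in pruned.edges()
            if not pruned.empty:
                assert nx.is_connected(pruned.graph.to_undirected(as_view=True))


class TestMergeSubnetworks:
    def _sub(self, edges, treatment, parent):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return network.Subnetwork(graph=g, treatment=treatment, parent=parent)

    def test_counts_and_union(self):
        parent = nx.DiGraph([("A", "B"), ("C", "D")])
        s1 = self._sub([("A", "B")], "t1", parent)
        s2 = self._sub([("C", "D")], "t2", parent)
        merged = network.merge_subnetworks([s1, s2])
        assert merged.nodes() == {"A", "B", "C", "D"}
        assert all(merged.graph.nodes[n]["n_subgraphs"] == 1 for n in merged.nodes())

    def test_identical_three_times(self):
        parent = nx.DiGraph([("A", "B")])
        subs = [self._sub([("A", "B")], f"t{i}", parent) for i in range(3)]
        merged = network.merge_subnetworks(subs)
        assert merged.graph.nodes["A"]["n_subgraphs"] == 3

    def test_overlap_counts_two(self):
        parent = nx.DiGraph([("A", "B"), ("B", "C")])
        s1 = self._sub([("A", "B")], "t1", parent)
        s2 = self._sub([("B", "C")], "t2", parent)
        merged = network.merge_subnetworks([s1, s2])
        assert merged.graph.nodes["B"]["n_subgraphs"] == 2
        assert merged.graph.nodes["A"]["n_subgraphs"] == 1

    def test_mixed_parents_raise(self):
        s1 = self._sub([("A", "B")], "t1", nx.DiGraph([("A", "B")]))
        s2 = self._sub([("C", "D")], "t2", nx.DiGraph([("C", "D")]))
        with pytest.raises(ValueError, match="different parent"):
            network.merge_subnetworks([s1, s2])


class TestCentralities:
    def _sub_from_edges(self, edges):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return network.Subnetwork(graph=g)

    def test_star_degree(self):
        s = self._sub_from_edges([("hub", f"leaf{i}") for i in range(3)])
        c = network.centralities(s).set_index("node")
        assert c.loc["hub", "degree_centrality"] == pytest.approx(1.0)
        assert c.loc["leaf0", "degree_centrality"] == pytest.approx(1 / 3)

    def test_triangle_eigenvector_symmetric(self):
        s = self._sub_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        c = network.centralities(s)
        assert c["eigenvector_centrality"].to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_single_node_convention(self):
        g = nx.DiGraph()
        g.add_node("A")
        c = network.centralities(network.Subnetwork(graph=g))
        assert c["degree_centrality"].iloc[0] == 0.0
        assert c["eigenvector_centrality"].iloc[0] == 1.0

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = nx.gnp_random_graph(6, 0.6, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            s = network.Subnetwork(graph=nx.DiGraph(g))
            c = network.centralities(s)
            adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str))
            expected = oracles.dense_eigenvector_centrality(adj)
            np.testing.assert_allclose(
                c["eigenvector_centrality"].to_numpy(), expected, atol=1e-8
            )


class TestMutationEnrichment:
    def _case(self, sub_nodes, bg_nodes, mutated):
        prior = nx.DiGraph()
        nodes = list(sub_nodes) + list(bg_nodes)
        prior.add_nodes_from(nodes)
        for a, b in zip(nodes[:-1], nodes[1:]):
            prior.add_edge(a, b)
        g = nx.DiGraph()
        g.add_nodes_from(sub_nodes)
        return network.mutation_enrichment(
            network.Subnetwork(graph=g), prior, set(mutated)
        )

    def test_three_one_table(self):
        """[[3,1],[1,3]] has two-sided p = 34/70 by table enumeration."""
        res = self._case(
            sub_nodes=["s1", "s2", "s3", "s4"],
            bg_nodes=["b1", "b2", "b3", "b4"],
            mutated=["s1", "s2", "s3", "b1"],
        )
        assert res.table.tolist() == [[3, 1], [1, 3]]
        assert res.pvalue == pytest.approx(34 / 70, rel=1e-12)
        assert res.pvalue == pytest.approx(oracles.fisher_two_sided(res.table), rel=1e-9)

    def test_fully_separated_five_five(self):
        """All 5 subnetwork nodes mutated, no background mutated: the
        two-sided enumeration gives 2/C(10,5) (both extreme tables)."""
        res = self._case(
            sub_nodes=[f"s{i}" for i in range(5)],
            bg_nodes=[f"b{i}" for i in range(5)],
            mutated=[f"s{i}" for i in range(5)],
        )
        expected = oracles.fisher_two_sided(res.table)
        assert expected == pytest.approx(2 / math.comb(10, 5), rel=1e-12)
        assert res.pvalue == pytest.approx(expected, rel=1e-9)

    def test_no_mutations_p_one(self):
        res = self._case(["s1", "s2"], ["b1", "b2"], [])
        assert res.pvalue == 1.0

    def test_swap_invariance(self):
        """Fisher p is invariant under swapping both rows and columns."""
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            p1 = fisher_exact(t)[1]
            p2 = fisher_exact(t[::-1, ::-1])[1]
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_background_raises(self):
        prior = nx.DiGraph([("A", "B")])
        g = nx.DiGraph([("A", "B")])
        with pytest.raises(ValueError, match="background"):
            network.mutation_enrichment(network.Subnetwork(graph=g), prior, {"A"})
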