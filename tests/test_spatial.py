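"""Voronoi neighborhoods, permutation interaction tests, Stouffer
combination and microaggregates."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crosstalk import spatial, synth
from crosstalk.spatial import CellMap
import oracles


def _cellmap(xy, phenotypes=None, frame=(10.0, 10.0), markers=None):
    n = len(xy)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "roi_id": "R",
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "phenotype": phenotypes or ["a"] * n,
        }
    )
    for m, vals in (markers or {}).items():
        df[m] = vals
    return CellMap(df, frame_um=frame)


def _chain_graph(n):
    g = nx.Graph()
    g.add_nodes_from([f"c{i}" for i in range(n)])
    g.add_edges_from([(f"c{i}", f"c{i+1}") for i in range(n - 1)])
    return g


class TestMarkerPositive:
    @pytest.mark.parametrize("frac,expected", [(0.12, True), (0.10, True), (0.0, False)])
    def test_inclusive_threshold(self, frac, expected):
        cm = _cellmap([(1, 1), (2, 2), (3, 1)], markers={"PD1": [frac, 0.5, 0.5]})
        assert spatial.marker_positive(cm, "PD1").loc["c0"] == expected

    def test_unknown_marker_raises(self):
        cm = _cellmap([(1, 1), (2, 2), (3, 1)])
        with pytest.raises(KeyError):
            spatial.marker_positive(cm, "nope")


class TestDensities:
    def test_unit_conversion(self):
        cm, _ = synth.gen_cell_map(200, {"a": 1.0}, seed=0, frame_um=(1000.0, 1000.0))
        assert spatial.densities(cm).loc["a"] == pytest.approx(200.0)

    def test_small_frame(self):
        cm, _ = synth.gen_cell_map(50, {"a": 1.0}, seed=0, frame_um=(500.0, 500.0))
        assert spatial.densities(cm).loc["a"] == pytest.approx(200.0)


class TestVoronoiNeighbors:
    def test_grid_center_has_four_neighbors(self):
        """On a square lattice, Voronoi cells touch only laterally; the
        diagonal point contacts are excluded."""
        xy = [(float(i % 3), float(i // 3)) for i in range(9)]
        g = spatial.voronoi_neighbors(_cellmap(xy, frame=(2.0, 2.0)))
        assert sorted(g.neighbors("c4")) == ["c1", "c3", "c5", "c7"]

    def test_two_cells_raise(self):
        with pytest.raises(ValueError, match=">= 3"):
            spatial.voronoi_neighbors(_cellmap([(1, 1), (2, 2)]))

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            spatial.voronoi_neighbors(_cellmap([(1, 1), (2, 2), (3, 3), (4, 4)]))

    def test_duplicates_jittered(self):
        g = spatial.voronoi_neighbors(_cellmap([(1, 1), (1, 1), (2, 5), (7, 3)]))
        assert g.number_of_nodes() == 4

    def test_symmetric_no_self_edges(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, size=(60, 2))
        cm = _cellmap([tuple(p) for p in xy], frame=(100.0, 100.0))
        g = spatial.voronoi_neighbors(cm)
        assert all(u != v for u, v in g.edges)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_polygon_clipping_oracle(self, seed):
        """Adjacency equals the half-plane polygon construction clipped to
        the frame (independent shapely oracle)."""
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 200, size=(40, 2))
        cm = _cellmap([tuple(p) for p in xy], frame=(200.0, 200.0))
        g = spatial.voronoi_neighbors(cm)
        got = {tuple(sorted((int(u[1:]), int(v[1:])))) for u, v in g.edges}
        expected = oracles.clipped_voronoi_adjacency(xy, (200.0, 200.0))
        assert got == expected


class TestInteractionTest:
    def test_single_phenotype_degenerate(self):
        cm, _ = synth.gen_cell_map(30, {"a": 1.0}, seed=1)
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        res = spatial.interaction_test(g, labels, n_iter=100, seed=0)
        assert (res["call"] == "degenerate").all()

    def test_symmetry_of_pair_order(self):
        """Counting is unordered: the (a, b) row covers b->a contacts."""
        cm, _ = synth.gen_cell_map(200, {"a": 0.5, "b": 0.5}, seed=2)
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        res = spatial.interaction_test(g, labels, n_iter=200, seed=3)
        pairs = set(zip(res["phenotype_a"], res["phenotype_b"]))
        assert ("a", "b") in pairs and ("b", "a") not in pairs
        obs = res.set_index(["phenotype_a", "phenotype_b"]).loc[("a", "b"), "observed"]
        manual = sum(1 for u, v in g.edges if {labels[u], labels[v]} == {"a", "b"})
        assert obs == manual

    def test_p_never_zero_and_reproducible(self):
        cm, _ = synth.gen_cell_map(300, {"a": 0.5, "b": 0.5}, [("a", "b")], strength=8.0, seed=4)
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        r1 = spatial.interaction_test(g, labels, n_iter=300, seed=5)
        r2 = spatial.interaction_test(g, labels, n_iter=300, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["pvalue"].dropna() > 0).all()

    def test_planted_attraction_called(self):
        cm, _ = synth.gen_cell_map(
            500, {"a": 0.4, "b": 0.3, "c": 0.3}, [("a", "b")], strength=6.0, seed=6
        )
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        res = spatial.interaction_test(g, labels, n_iter=1000, seed=7)
        row = res.set_index(["phenotype_a", "phenotype_b"]).loc[("a", "b")]
        assert row["call"] == "attraction"

    def test_null_counts_preserved_by_construction(self):
        """The permutation engine shuffles the label vector in place, so
        phenotype multiplicities are preserved exactly; verify via the
        null mean of the total over all pairs (equal to the edge count)."""
        cm, _ = synth.gen_cell_map(150, {"a": 0.5, "b": 0.3, "c": 0.2}, seed=8)
        g = spatial.voronoi_neighbors(cm)
        labels = cm.cells.set_index("cell_id")["phenotype"]
        res = spatial.interaction_test(g, labels, n_iter=200, seed=9)
        assert res["null_mean"].sum() == pytest.approx(g.number_of_edges())
        assert res["observed"].sum() == g.number_of_edges()


class TestStouffer:
    @pytest.mark.parametrize(
        "zs,expected", [([2, 2, 2, 2], 4.0), ([1.7], 1.7), ([1.5, -1.5], 0.0)]
    )
    def test_formula(self, zs, expected):
        assert spatial.stouffer_combine(zs) == pytest.approx(expected)

    def test_empty_is_missing(self):
        assert np.isnan(spatial.stouffer_combine([]))


class TestMicroaggregates:
    def test_chain_fixture(self):
        """Chain [PDL1tum, PD1imm, other, PDL1tum, other]: one qualifying
        aggregate of cells 0-1; the isolated PDL1+ tumor cell at index 3
        does not qualify."""
        g = _chain_graph(5)
        tum = pd.Series([True, False, False, True, False], index=[f"c{i}" for i in range(5)])
        imm = pd.Series([False, True, False, False, False], index=[f"c{i}" for i in range(5)])
        aggs = spatial.microaggregates(g, tum, imm)
        assert len(aggs) == 1
        assert aggs[0].cells == {"c0", "c1"}
        assert (aggs[0].n_pdl1_tumor, aggs[0].n_pd1_immune) == (1, 1)

    def test_no_pd1_cells_empty(self):
        g = _chain_graph(4)
        idx = [f"c{i}" for i in range(4)]
        aggs = spatial.microaggregates(
            g, pd.Series(True, index=idx), pd.Series(False, index=idx)
        )
        assert aggs == []

    def test_alternating_path_single_aggregate(self):
        g = _chain_graph(6)
        idx = [f"c{i}" for i in range(6)]
        tum = pd.Series([i % 2 == 0 for i in range(6)], index=idx)
        imm = pd.Series([i % 2 == 1 for i in range(6)], index=idx)
        aggs = spatial.microaggregates(g, tum, imm)
        assert len(aggs) == 1
        assert len(aggs[0].cells) == 6


class TestMicroaggregateTest:
    def test_zero_flags_degenerate(self):
        g = _chain_graph(10)
        idx = [f"c{i}" for i in range(10)]
        z, p = spatial.microaggregate_test(
            g, pd.Series(False, index=idx), pd.Series(False, index=idx),
            n_iter=100, seed=0,
        )
        assert np.isnan(z) and np.isnan(p)

    def test_planted_coclusters_significant(self):
        """Sparse PD-L1+ tumor / PD-1+ immune populations planted in
        contact pairs yield a significantly positive microaggregate count
        (the count statistic is informative when the flagged populations
        are rare and form many small heterotypic contacts)."""
        hits = 0
        for s in range(10):
            cm, _ = synth.gen_cell_map(
                500,
                {"tumor_pdl1": 0.05, "immune_pd1": 0.05, "tumor": 0.25,
                 "immune": 0.25, "other": 0.4},
                [("tumor_pdl1", "immune_pd1")], strength=6.0, seed=s,
                pattern="pair",
                markers={"PDL1": {"tumor_pdl1": (8.0, 2.0)},
                         "PD1": {"immune_pd1": (8.0, 2.0)}},
            )
            g = spatial.voronoi_neighbors(cm)
            phen = cm.cells.set_index("cell_id")["phenotype"]
            tum = spatial.marker_positive(cm, "PDL1") & phen.isin(["tumor_pdl1", "tumor"])
            imm = spatial.marker_positive(cm, "PD1") & phen.isin(["immune_pd1", "immune"])
            z, p = spatial.microaggregate_test(g, tum, imm, n_iter=300, seed=100 + s)
            hits += (z > 0) and (p < 0.05)
        assert hits >= 9

    def test_reproducible(self):
        cm, _ = synth.gen_cell_map(200, {"t": 0.5, "i": 0.5}, seed=3)
        g = spatial.voronoi_neighbors(cm)
        phen = cm.cells.set_index("cell_id")["phenotype"]
        tum = phen == "t"
        imm = phen == "i"
        r1 = spatial.microaggregate_test(g, tum, imm, n_iter=200, seed=11)
        r2 = spatial.microaggregate_test(g, tum, imm, n_iter=200, seed=11)
        assert r1 == r2
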