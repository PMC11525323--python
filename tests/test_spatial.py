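"""Adjacency construction, GAL I/O, and ICAR quadratic-form/density checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sharedmap.spatial import (
    AdjacencyGraph,
    GALParseError,
    build_lattice_adjacency,
    check_centered,
    connected_components,
    enumerate_labeled_graphs,
    graph_from_id_lists,
    greedy_coloring,
    icar_logdensity,
    icar_pairwise_ss,
    read_adjacency_gal,
    write_adjacency_gal,
)


def brute_force_lattice_edges(nrows, ncols, rule):
    """Oracle: count cell pairs at Chebyshev distance 1 (queen) or rook-adjacent."""
    cells = list(itertools.product(range(nrows), range(ncols)))
    count = 0
    for (r1, c1), (r2, c2) in itertools.combinations(cells, 2):
        dr, dc = abs(r1 - r2), abs(c1 - c2)
        if rule == "queen" and max(dr, dc) == 1:
            count += 1
        if rule == "rook" and dr + dc == 1:
            count += 1
    return count


class TestLattice:
    @pytest.mark.parametrize(
        "nrows,ncols,rule,n_edges",
        [(1, 1, "rook", 0), (2, 2, "rook", 4)],
    )
    def test_small_lattices(self, nrows, ncols, rule, n_edges):
        g = build_lattice_adjacency(nrows, ncols, rule)
        assert g.n_areas == nrows * ncols
        assert g.n_edges == n_edges

    @pytest.mark.parametrize("nrows,ncols", [(3, 3), (2, 5), (4, 4)])
    @pytest.mark.parametrize("rule", ["rook", "queen"])
    def test_edge_count_matches_pair_enumeration(self, nrows, ncols, rule):
        g = build_lattice_adjacency(nrows, ncols, rule)
        assert g.n_edges == brute_force_lattice_edges(nrows, ncols, rule)

    @pytest.mark.parametrize("nrows,ncols", [(0, 3), (3, 0), (-1, 2)])
    def test_invalid_dimensions(self, nrows, ncols):
        with pytest.raises(ValueError):
            build_lattice_adjacency(nrows, ncols, "rook")

    def test_invalid_rule(self):
        with pytest.raises(ValueError, match="rook"):
            build_lattice_adjacency(2, 2, "hexagon")


class TestGraphValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            AdjacencyGraph(2, ["a", "b"], [np.array([1]), np.array([], dtype=int)])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            AdjacencyGraph(1, ["a"], [np.array([0])])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            AdjacencyGraph(2, ["a", "a"], [np.array([], dtype=int)] * 2)


class TestGAL:
    def test_path_graph_from_text(self, tmp_path):
        f = tmp_path / "p.gal"
        f.write_text("# a 3-node path\n3\na 1\nb\nb 2\na c\nc 1\nb\n")
        g = read_adjacency_gal(f)
        assert g.n_areas == 3
        assert g.n_edges == 2
        assert g.area_ids == ["a", "b", "c"]

    def test_asymmetric_listing_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.gal"
        f.write_text("2\na 1\nb\nb 0\n")
        with pytest.raises(GALParseError, match="asymmetric"):
            read_adjacency_gal(f)

    def test_unknown_id_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.gal"
        f.write_text("2\na 1\nz\nb 0\n")
        with pytest.raises(GALParseError, match="unknown"):
            read_adjacency_gal(f)

    def test_malformed_header_names_line(self, tmp_path):
        f = tmp_path / "bad.gal"
        f.write_text("2\na one two three\nb 0\n")
        with pytest.raises(GALParseError, match=":2"):
            read_adjacency_gal(f)

    @pytest.mark.parametrize("rule", ["rook", "queen"])
    def test_round_trip(self, tmp_path, rule):
        g = build_lattice_adjacency(3, 4, rule)
        f = tmp_path / "lattice.gal"
        write_adjacency_gal(g, f)
        g2 = read_adjacency_gal(f)
        assert g2.area_ids == g.area_ids
        for a, b in zip(g.neighbors, g2.neighbors):
            assert np.array_equal(a, b)


class TestComponents:
    def test_lattice_is_connected(self, lattice_2x2):
        labels, c = connected_components(lattice_2x2)
        assert c == 1
        assert set(labels) == {0}

    def test_edgeless_graph(self):
        g = AdjacencyGraph(3, ["a", "b", "c"], [np.array([], dtype=int)] * 3)
        _, c = connected_components(g)
        assert c == 3

    def test_path_plus_isolate(self):
        g = graph_from_id_lists(
            ["a", "b", "c", "d"], {"a": ["b"], "b": ["a", "c"], "c": ["b"], "d": []}
        )
        labels, c = connected_components(g)
        assert c == 2
        assert labels[3] != labels[0]


class TestPairwiseSS:
    def test_path_example(self, path3):
        assert icar_pairwise_ss(np.array([0.0, 1.0, 3.0]), path3) == pytest.approx(5.0)

    def test_constant_vector_is_zero(self, lattice_2x2):
        assert icar_pairwise_ss(np.full(4, 2.7), lattice_2x2) == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, xs, c):
        g = graph_from_id_lists(["a", "b", "c"], {"a": ["b"], "b": ["a", "c"], "c": ["b"]})
        x = np.asarray(xs)
        assert icar_pairwise_ss(x + c, g) == pytest.approx(icar_pairwise_ss(x, g), abs=1e-8)

    def test_length_mismatch(self, path3):
        with pytest.raises(ValueError):
            icar_pairwise_ss(np.zeros(2), path3)

    def test_positive_unless_constant_per_component(self):
        g = graph_from_id_lists(
            ["a", "b", "c", "d"], {"a": ["b"], "b": ["a"], "c": ["d"], "d": ["c"]}
        )
        assert icar_pairwise_ss(np.array([1.0, 1.0, -2.0, -2.0]), g) == 0.0
        assert icar_pairwise_ss(np.array([1.0, 1.1, -2.0, -2.0]), g) > 0.0


def eigen_logdensity(x, graph, tau):
    """Oracle: degenerate-Gaussian log density via Laplacian eigendecomposition,
    dropping the x-independent constant but keeping the tau-dependent part."""
    lap = graph.laplacian()
    evals, evecs = np.linalg.eigh(lap)
    keep = evals > 1e-9 * max(float(evals.max()), 1.0)
    proj = evecs[:, keep].T @ x
    quad = float(np.sum(evals[keep] * proj**2))
    return 0.5 * keep.sum() * np.log(tau) - 0.5 * tau * quad


class TestICARLogDensity:
    def test_zero_vector_value(self, lattice_2x2):
        n, c = 4, 1
        assert icar_logdensity(np.zeros(4), lattice_2x2, 2.0) == pytest.approx(
            0.5 * (n - c) * np.log(2.0)
        )

    def test_matches_eigen_oracle_on_path(self):
        g = graph_from_id_lists(
            ["a", "b", "c", "d"],
            {"a": ["b"], "b": ["a", "c"], "c": ["b", "d"], "d": ["c"]},
        )
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(4)
        x1 -= x1.mean()
        x2 = rng.standard_normal(4)
        x2 -= x2.mean()
        for tau in (0.5, 1.0, 7.3):
            diff = icar_logdensity(x1, g, tau) - icar_logdensity(x2, g, tau)
            oracle = eigen_logdensity(x1, g, tau) - eigen_logdensity(x2, g, tau)
            assert diff == pytest.approx(oracle, abs=1e-10)

    def test_relabeling_invariance(self):
        # the 4-cycle has a rotation automorphism
        g = graph_from_id_lists(
            ["a", "b", "c", "d"],
            {"a": ["b", "d"], "b": ["a", "c"], "c": ["b", "d"], "d": ["c", "a"]},
        )
        x = np.array([1.0, -0.5, 0.25, -0.75])
        rotated = np.roll(x, 1)
        assert icar_logdensity(x, g, 2.0) == pytest.approx(
            icar_logdensity(rotated, g, 2.0)
        )

    def test_centering_precondition(self, path3):
        with pytest.raises(ValueError, match="sum to zero"):
            icar_logdensity(np.array([1.0, 1.0, 1.0]), path3, 1.0)

    def test_tau_must_be_positive(self, path3):
        with pytest.raises(ValueError):
            icar_logdensity(np.zeros(3), path3, 0.0)

    def test_per_component_centering(self):
        g = graph_from_id_lists(
            ["a", "b", "c", "d"], {"a": ["b"], "b": ["a"], "c": ["d"], "d": ["c"]}
        )
        # centered overall but not per component
        assert not check_centered(np.array([1.0, 1.0, -1.0, -1.0]), g)
        assert check_centered(np.array([1.0, -1.0, 2.0, -2.0]), g)


class TestColoring:
    @pytest.mark.parametrize("rule", ["rook", "queen"])
    def test_classes_partition_and_are_independent(self, rule):
        g = build_lattice_adjacency(4, 5, rule)
        classes = greedy_coloring(g)
        seen = np.concatenate(classes)
        assert sorted(seen.tolist()) == list(range(g.n_areas))
        edge_set = {tuple(e) for e in g.edges.tolist()}
        for cls in classes:
            for i, j in itertools.combinations(cls.tolist(), 2):
                assert (i, j) not in edge_set and (j, i) not in edge_set


def test_labeled_graph_enumeration_counts():
    # connected labelled graphs on 3 and 4 nodes: classical counts 4 and 38
    assert sum(1 for _ in enumerate_labeled_graphs(3)) == 4
    assert sum(1 for _ in enumerate_labeled_graphs(4)) == 38
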