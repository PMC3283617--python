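"""Alignment graph construction, bounded paths, extension and full runs."""

import numpy as np
import pytest

from conftest import make_net
from netalign.alignment import (
    AlignParams,
    align,
    bounded_best_path,
    build_initial_graph,
    connected_components,
    extend_graph,
)
from netalign.evolution import fit_conservation_model
from netalign.homology import HomologPair
from netalign.significance import EdgeType
from oracles import best_bounded_path_bruteforce, components_bruteforce


def pairs_for(*specs):
    """HomologPairs from (query, target, vertex_probability[, distance])."""
    out = []
    for s in specs:
        p = HomologPair(s[0], s[1])
        p.vertex_probability = s[2]
        if len(s) > 3:
            p.distance = s[3]
        out.append(p)
    return out


def loose_params(**kw):
    kw.setdefault("vertex_prob_threshold", 0.0)
    kw.setdefault("edge_prob_threshold", 0.0)
    kw.setdefault("n_random_scores", 200)
    return AlignParams(**kw)


class TestBuildInitialGraph:
    def test_conserved_edge_full_probability(self):
        qnet = make_net([("a1", "a2", 1.0)])
        tnet = make_net([("b1", "b2", 1.0)], "target")
        g = build_initial_graph(
            qnet, tnet, pairs_for(("a1", "b1", 1.0), ("a2", "b2", 1.0)), None, loose_params()
        )
        assert len(g.edges) == 1
        (edge,) = g.edges.values()
        assert edge.edge_type is EdgeType.CONSERVED and edge.probability == 1.0

    def test_one_sided_interaction_needs_prediction(self):
        qnet = make_net([("a1", "a2", 1.0)])
        tnet = make_net([("b1", "z", 1.0), ("b2", "w", 1.0)], "target")
        ps = pairs_for(("a1", "b1", 1.0, 0.5), ("a2", "b2", 1.0, 0.52))
        off = build_initial_graph(qnet, tnet, ps, None, loose_params())
        assert len(off.edges) == 0
        model = fit_conservation_model([0.02] * 50, np.abs(np.random.default_rng(0).normal(0, 0.5, 500)).tolist())
        on = build_initial_graph(
            qnet, tnet, ps, model, loose_params(predict_likely_conserved=True)
        )
        assert len(on.edges) == 1
        (edge,) = on.edges.values()
        assert edge.edge_type is EdgeType.LIKELY_CONSERVED_QUERY
        assert edge.probability == pytest.approx(1.0 * 0.9)

    def test_vertex_threshold_removes_vertex_and_edges(self):
        qnet = make_net([("a1", "a2", 1.0)])
        tnet = make_net([("b1", "b2", 1.0)], "target")
        g = build_initial_graph(
            qnet,
            tnet,
            pairs_for(("a1", "b1", 0.2), ("a2", "b2", 1.0)),
            None,
            loose_params(vertex_prob_threshold=0.5),
        )
        assert set(g.vertices) == {("a2", "b2")} and not g.edges

    def test_edge_threshold_monotone(self):
        rng = np.random.default_rng(5)
        qnet = make_net([(f"a{i}", f"a{j}", float(rng.uniform(0.2, 1))) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.6])
        tnet = make_net([(f"b{i}", f"b{j}", float(rng.uniform(0.2, 1))) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.6], "target")
        ps = pairs_for(*[(f"a{i}", f"b{i}", 1.0) for i in range(6)])
        counts = []
        for thr in (0.0, 0.3, 0.6, 0.9):
            g = build_initial_graph(qnet, tnet, ps, None, loose_params(edge_prob_threshold=thr))
            counts.append(len(g.edges))
        assert counts == sorted(counts, reverse=True)

    def test_inconsistent_namespaces_rejected(self):
        qnet = make_net([("a1", "a2", 1.0)])
        tnet = make_net([("b1", "b2", 1.0)], "target")
        with pytest.raises(ValueError, match="namespace"):
            build_initial_graph(
                qnet, tnet, pairs_for(("x1", "y1", 1.0)), None, loose_params()
            )

    def test_self_interaction_alignment(self):
        """A conserved self-interaction links two vertices sharing a protein."""
        qnet = make_net([("a", "a", 1.0)])
        tnet = make_net([("b1", "b2", 1.0)], "target")
        g = build_initial_graph(
            qnet, tnet, pairs_for(("a", "b1", 1.0), ("a", "b2", 1.0)), None, loose_params()
        )
        assert len(g.edges) == 1
        (edge,) = g.edges.values()
        assert edge.edge_type is EdgeType.CONSERVED


class TestConnectedComponents:
    def test_isolated_vertices_discarded(self):
        qnet = make_net([("a1", "a2", 1.0)])
        tnet = make_net([("b1", "b2", 1.0)], "target")
        ps = pairs_for(("a1", "b1", 1.0), ("a2", "b2", 1.0), ("a1", "b2", 1.0))
        g = build_initial_graph(qnet, tnet, ps, None, loose_params())
        comps = connected_components(g)
        assert comps == [{("a1", "b1"), ("a2", "b2")}]

    def test_empty_graph(self):
        from netalign.alignment import AlignmentGraph

        assert connected_components(AlignmentGraph()) == []

    def test_matches_transitive_closure_oracle(self, rng):
        from netalign.alignment import AlignmentGraph, AlignmentEdge, AlignmentVertex

        for _ in range(60):
            n = int(rng.integers(2, 13))
            density = rng.uniform(0.05, 0.4)
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < density
            ]
            g = AlignmentGraph()
            verts = [AlignmentVertex(HomologPair(f"q{i:02d}", f"t{i:02d}"), 1.0) for i in range(n)]
            for v in verts:
                g.add_vertex(v)
            for i, j in edges:
                g.add_edge(AlignmentEdge(verts[i], verts[j], EdgeType.CONSERVED, 1.0))
            got = {frozenset(k[0] for k in comp) for comp in connected_components(g)}
            expected = {
                frozenset(f"q{i:02d}" for i in comp)
                for comp in components_bruteforce(n, edges)
            }
            assert got == expected


class TestBoundedBestPath:
    def test_simple_chain(self):
        net = make_net([("a", "x", 1.0), ("x", "b", 1.0)])
        path, prob = bounded_best_path(net, "a", "b", 3)
        assert path == ("a", "x", "b") and prob == 1.0

    def test_longer_more_reliable_path_wins(self):
        net = make_net(
            [("a", "x", 0.9), ("x", "b", 0.9),
             ("a", "u", 0.99), ("u", "v", 0.99), ("v", "b", 0.99)]
        )
        path, prob = bounded_best_path(net, "a", "b", 3)
        assert path == ("a", "u", "v", "b")
        assert prob == pytest.approx(0.99**3)

    def test_direct_edge_not_a_path(self):
        net = make_net([("a", "b", 1.0)])
        assert bounded_best_path(net, "a", "b", 3) is None

    def test_absent_protein_rejected(self):
        net = make_net([("a", "b", 1.0)])
        with pytest.raises(KeyError):
            bounded_best_path(net, "a", "zz", 3)

    def test_matches_exhaustive_oracle(self, rng):
        levels = [0.25, 0.5, 0.75, 1.0]  # exactly representable products
        for _ in range(60):
            n = int(rng.integers(3, 13))
            names = [f"n{i:02d}" for i in range(n)]
            adj = {}
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        r = float(rng.choice(levels))
                        edges.append((names[i], names[j], r))
                        adj.setdefault(names[i], {})[names[j]] = r
                        adj.setdefault(names[j], {})[names[i]] = r
            net = make_net(edges) if edges else None
            if net is None:
                continue
            max_len = int(rng.integers(2, 5))
            nodes = sorted(net.proteins)
            for _ in range(4):
                a, b = rng.choice(len(nodes), 2, replace=False)
                a, b = nodes[a], nodes[b]
                got = bounded_best_path(net, a, b, max_len)
                expected = best_bounded_path_bruteforce(adj, a, b, max_len)
                if expected is None:
                    assert got is None
                else:
                    assert got is not None
                    assert got[1] == pytest.approx(expected[1])
                    assert got[0] == expected[0]


class TestExtendGraph:
    def _two_seed_setup(self, target_gap=True):
        """Two 2-vertex seeds; a2/a3 direct in query, b2..b3 two-hop in target."""
        qnet = make_net(
            [("a1", "a2", 1.0), ("a3", "a4", 1.0), ("a2", "a3", 0.9)]
        )
        tedges = [("b1", "b2", 1.0), ("b3", "b4", 1.0), ("b2", "x", 0.8), ("x", "b3", 0.5)]
        if not target_gap:
            tedges.append(("b2", "b3", 0.7))
        tnet = make_net(tedges, "target")
        ps = pairs_for(*[(f"a{i}", f"b{i}", 1.0) for i in range(1, 5)])
        g = build_initial_graph(qnet, tnet, ps, None, loose_params())
        seeds = connected_components(g)
        return g, seeds, qnet, tnet

    def test_gap_edge_between_seeds(self):
        g, seeds, qnet, tnet = self._two_seed_setup()
        assert len(seeds) == 2
        ext = extend_graph(g, seeds, qnet, tnet, loose_params())
        new = {k: e for k, e in ext.edges.items() if k not in g.edges}
        # the direct a2-a3 / indirect b2..b3 pair gets the gap edge; the
        # remaining inter-seed pairs are indirect on both sides (mismatch)
        e = new[(("a2", "b2"), ("a3", "b3"))]
        assert e.edge_type is EdgeType.GAP_TARGET
        assert e.target_path == ("b2", "x", "b3")
        assert e.probability == pytest.approx(0.9 * 0.8 * 0.5)
        assert all(
            o.edge_type is EdgeType.MISMATCH
            for k, o in new.items()
            if k != (("a2", "b2"), ("a3", "b3"))
        )

    def test_mismatch_edge_when_indirect_both_sides(self):
        qnet = make_net(
            [("a1", "a2", 1.0), ("a3", "a4", 1.0), ("a2", "y", 0.9), ("y", "a3", 0.9)]
        )
        tnet = make_net(
            [("b1", "b2", 1.0), ("b3", "b4", 1.0), ("b2", "x", 0.8), ("x", "b3", 0.5)],
            "target",
        )
        ps = pairs_for(*[(f"a{i}", f"b{i}", 1.0) for i in range(1, 5)])
        g = build_initial_graph(qnet, tnet, ps, None, loose_params())
        seeds = connected_components(g)
        ext = extend_graph(g, seeds, qnet, tnet, loose_params())
        new = {k: e for k, e in ext.edges.items() if k not in g.edges}
        assert {e.edge_type for e in new.values()} == {EdgeType.MISMATCH}
        e = new[(("a2", "b2"), ("a3", "b3"))]
        assert e.probability == pytest.approx(0.9 * 0.9 * 0.8 * 0.5)

    def test_no_edges_within_a_seed(self):
        # one seed of 3 vertices: a1-a2-a3 conserved chain; a1/a3 are
        # indirectly connected in both networks but share the seed
        qnet = make_net([("a1", "a2", 1.0), ("a2", "a3", 1.0)])
        tnet = make_net([("b1", "b2", 1.0), ("b2", "b3", 1.0)], "target")
        ps = pairs_for(*[(f"a{i}", f"b{i}", 1.0) for i in range(1, 4)])
        g = build_initial_graph(qnet, tnet, ps, None, loose_params())
        seeds = connected_components(g)
        assert len(seeds) == 1
        ext = extend_graph(g, seeds, qnet, tnet, loose_params())
        assert set(ext.edges) == set(g.edges)

    def test_initial_edges_preserved(self):
        g, seeds, qnet, tnet = self._two_seed_setup()
        ext = extend_graph(g, seeds, qnet, tnet, loose_params())
        assert set(g.edges) <= set(ext.edges)


class TestAlign:
    def _planted(self):
        qnet = make_net(
            [("a1", "a2", 1.0), ("a2", "a3", 1.0),
             ("c1", "c2", 1.0), ("c2", "c3", 1.0)]
        )
        tnet = make_net(
            [("b1", "b2", 1.0), ("b2", "b3", 1.0),
             ("d1", "d2", 1.0), ("d2", "d3", 1.0)],
            "target",
        )
        ps = pairs_for(
            *[(f"a{i}", f"b{i}", 1.0) for i in range(1, 4)],
            *[(f"c{i}", f"d{i}", 1.0) for i in range(1, 4)],
        )
        return qnet, tnet, ps

    def test_recovers_disjoint_planted_modules(self):
        qnet, tnet, ps = self._planted()
        sols = align(qnet, tnet, ps, params=loose_params(p_threshold=1.0), seed=0)
        assert len(sols) == 2
        assert {frozenset(s.query_proteins) for s in sols} == {
            frozenset({"a1", "a2", "a3"}), frozenset({"c1", "c2", "c3"})
        }

    def test_empty_pairs_give_no_solutions(self):
        qnet, tnet, _ = self._planted()
        assert align(qnet, tnet, [], params=loose_params(), seed=0) == []

    def test_deterministic_under_seed(self):
        qnet, tnet, ps = self._planted()
        a = align(qnet, tnet, ps, params=loose_params(p_threshold=1.0), seed=11)
        b = align(qnet, tnet, ps, params=loose_params(p_threshold=1.0), seed=11)
        assert [(s.score, s.p_value, sorted(s.vertex_keys)) for s in a] == [
            (s.score, s.p_value, sorted(s.vertex_keys)) for s in b
        ]

    def test_solutions_vertex_disjoint(self, rng):
        from netalign.synthetic import SyntheticConfig, generate
        from netalign.cli import run_pipeline

        data = generate(SyntheticConfig(
            n_proteins_query=80, n_proteins_target=80, n_planted_modules=4,
            module_size_range=(3, 5), n_background_orthologs=25, rng_seed=3,
        ))
        from netalign import evolution
        dists = {k: evolution.grishin_distance(v, tolerance=1e-9)
                 for k, v in data.identity_table.items()}
        sols = run_pipeline(
            data.query_net, data.target_net, data.pairs,
            loose_params(edge_prob_threshold=0.3, p_threshold=1.0), 5,
            null_evalues=data.null_evalues, distances=dists,
        )
        seen = set()
        for s in sols:
            assert not (s.vertex_keys & seen)
            seen |= s.vertex_keys
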