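"""Alignment-graph construction, seed extension and solution discovery.

The aligner overlays two interaction networks on a set of homolog pairs:

1. vertices = homolog pairs passing the vertex-probability threshold;
2. initial edges = conserved interactions (direct in both networks) and,
   optionally, likely-conserved interactions (direct in exactly one
   network, predicted conserved from the similarity of the two pairs'
   evolutionary distances);
3. seeds = connected components of the initial graph (depth-first search);
4. extension = gap/mismatch edges between vertices of *different* seeds
   whose proteins are connected indirectly (bounded best paths) in one or
   both networks;
5. solutions = connected components of the extended graph, scored and
   assigned Monte-Carlo p-values.

Solutions are maximal by construction: no homolog pair belongs to two
solutions.  A protein may appear in many vertices (one-to-many and
many-to-many homology), and paths realising gaps or mismatches may pass
through proteins without homologs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .evolution import ConservationModel, conservation_probability, delta_distance
from .homology import HomologPair
from .network_io import Interactome
from .significance import (
    EdgeType,
    ProbabilityPools,
    ScoringConfig,
    edge_probability,
    permutation_pvalue,
    solution_score,
)

__all__ = [
    "AlignParams",
    "AlignmentVertex",
    "AlignmentEdge",
    "AlignmentGraph",
    "AlignmentSolution",
    "build_initial_graph",
    "connected_components",
    "bounded_best_path",
    "bounded_paths_from",
    "extend_graph",
    "align",
]


@dataclasses.dataclass
class AlignParams:
    """Tunable alignment parameters with package defaults."""

    vertex_prob_threshold: float = 0.2
    edge_prob_threshold: float = 0.1
    predict_likely_conserved: bool = False
    max_path_length: int = 3  # edge-count cap for gap/mismatch paths
    alpha: float = 0.5
    p_threshold: float = 0.05
    n_random_scores: int = 10_000
    mode: str = "i2i"  # one of i2i, c2i, p2i
    intra_species: bool = False

    def __post_init__(self) -> None:
        if self.max_path_length < 2:
            raise ValueError("max_path_length must be >= 2 (indirect paths)")
        if self.mode not in ("i2i", "c2i", "p2i"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass(frozen=True)
class AlignmentVertex:
    pair: HomologPair
    probability: float

    @property
    def key(self) -> tuple[str, str]:
        return self.pair.key


@dataclasses.dataclass(frozen=True)
class AlignmentEdge:
    u: AlignmentVertex
    v: AlignmentVertex
    edge_type: EdgeType
    probability: float
    query_path: tuple[str, ...] | None = None
    target_path: tuple[str, ...] | None = None


class AlignmentGraph:
    """Vertices keyed by (query, target) pairs, with typed weighted edges."""

    def __init__(self) -> None:
        self.vertices: dict[tuple[str, str], AlignmentVertex] = {}
        self.edges: dict[tuple, AlignmentEdge] = {}
        self.adjacency: dict[tuple[str, str], set[tuple[str, str]]] = {}
        #: conservation probabilities of every likely-conserved candidate
        #: considered during construction (pre-threshold); feeds the
        #: significance-test conservation pool.
        self.conservation_probs: list[float] = []

    def add_vertex(self, vertex: AlignmentVertex) -> None:
        self.vertices[vertex.key] = vertex
        self.adjacency.setdefault(vertex.key, set())

    def add_edge(self, edge: AlignmentEdge) -> None:
        ku, kv = edge.u.key, edge.v.key
        key = (ku, kv) if ku <= kv else (kv, ku)
        self.edges[key] = edge
        self.adjacency.setdefault(ku, set()).add(kv)
        self.adjacency.setdefault(kv, set()).add(ku)

    def has_edge(self, ku: tuple[str, str], kv: tuple[str, str]) -> bool:
        return ((ku, kv) if ku <= kv else (kv, ku)) in self.edges

    def degree(self, key: tuple[str, str]) -> int:
        nb = self.adjacency.get(key, set())
        self_loop = 1 if key in nb else 0
        return len(nb) + self_loop

    def copy(self) -> "AlignmentGraph":
        g = AlignmentGraph()
        g.vertices = dict(self.vertices)
        g.edges = dict(self.edges)
        g.adjacency = {k: set(v) for k, v in self.adjacency.items()}
        g.conservation_probs = list(self.conservation_probs)
        return g

    def edges_within(self, keys: set[tuple[str, str]]) -> list[AlignmentEdge]:
        return [e for (ku, kv), e in self.edges.items() if ku in keys and kv in keys]


@dataclasses.dataclass
class AlignmentSolution:
    """A connected component of the extended graph, scored and p-valued."""

    vertices: list[AlignmentVertex]
    edges: list[AlignmentEdge]
    score: float = 0.0
    p_value: float | None = None

    @property
    def query_proteins(self) -> set[str]:
        return {v.pair.query_protein for v in self.vertices}

    @property
    def target_proteins(self) -> set[str]:
        return {v.pair.target_protein for v in self.vertices}

    @property
    def vertex_keys(self) -> set[tuple[str, str]]:
        return {v.key for v in self.vertices}


# -- initial graph ---------------------------------------------------------

def build_initial_graph(
    query_net: Interactome,
    target_net: Interactome,
    pairs: Sequence[HomologPair],
    cons_model: ConservationModel | None,
    params: AlignParams,
) -> AlignmentGraph:
    """Overlay the two networks: conserved (+ likely-conserved) edges.

    Vertices are homolog pairs at or above the vertex-probability
    threshold whose proteins exist in the respective networks.  A
    conserved edge joins two vertices whose query proteins interact in the
    query network *and* whose target proteins interact in the target
    network; with prediction enabled, an interaction present in exactly
    one network yields a likely-conserved edge weighted by the
    conservation probability of the pairs' Δd.  Edges below the
    edge-probability threshold are dropped.
    """
    graph = AlignmentGraph()
    kept = [p for p in pairs if p.vertex_probability >= params.vertex_prob_threshold]
    present = [
        p for p in kept if p.query_protein in query_net and p.target_protein in target_net
    ]
    if kept and not present:
        raise ValueError(
            "no homolog pair references proteins of both input networks; "
            "identifier namespaces appear inconsistent"
        )
    for p in sorted(present, key=lambda p: p.key):
        graph.add_vertex(AlignmentVertex(p, p.vertex_probability))

    if params.predict_likely_conserved and cons_model is None:
        raise ValueError("likely-conserved prediction requires a conservation model")

    qmap: dict[str, list[tuple[str, str]]] = {}
    tmap: dict[str, list[tuple[str, str]]] = {}
    for key in graph.vertices:
        qmap.setdefault(key[0], []).append(key)
        tmap.setdefault(key[1], []).append(key)

    def vertex_pairs_for_edge(
        a1: str, a2: str, index: Mapping[str, list[tuple[str, str]]]
    ) -> Iterable[tuple[tuple[str, str], tuple[str, str]]]:
        seen: set[tuple] = set()
        for k1 in index.get(a1, ()):
            for k2 in index.get(a2, ()):
                key = (k1, k2) if k1 <= k2 else (k2, k1)
                if key in seen:
                    continue
                seen.add(key)
                yield key

    def likely_prob(k1: tuple[str, str], k2: tuple[str, str]) -> float | None:
        d1 = graph.vertices[k1].pair.distance
        d2 = graph.vertices[k2].pair.distance
        if d1 is None or d2 is None:
            return None
        assert cons_model is not None
        return conservation_probability(delta_distance(d1, d2), cons_model)

    # conserved + query-observed likely-conserved edges
    for a1, a2 in sorted(query_net.edge_keys()):
        r_q = query_net.reliability(a1, a2)
        for k1, k2 in vertex_pairs_for_edge(a1, a2, qmap):
            b1, b2 = k1[1], k2[1]
            if k1 == k2:
                # self-loop: needs self-interactions on both sides
                if a1 != a2:
                    continue
            t_edge = target_net.get(b1, b2)
            if t_edge is not None:
                p = edge_probability(EdgeType.CONSERVED, [r_q], [t_edge.reliability])
                if p >= params.edge_prob_threshold:
                    graph.add_edge(
                        AlignmentEdge(
                            graph.vertices[k1],
                            graph.vertices[k2],
                            EdgeType.CONSERVED,
                            p,
                            query_path=(a1, a2),
                            target_path=(b1, b2),
                        )
                    )
            elif params.predict_likely_conserved:
                cp = likely_prob(k1, k2)
                if cp is None:
                    continue
                graph.conservation_probs.append(cp)
                p = edge_probability(
                    EdgeType.LIKELY_CONSERVED_QUERY, [r_q], [], cons_prob=cp
                )
                if p >= params.edge_prob_threshold:
                    graph.add_edge(
                        AlignmentEdge(
                            graph.vertices[k1],
                            graph.vertices[k2],
                            EdgeType.LIKELY_CONSERVED_QUERY,
                            p,
                            query_path=(a1, a2),
                        )
                    )

    # target-observed likely-conserved edges (query side missing)
    if params.predict_likely_conserved:
        for b1, b2 in sorted(target_net.edge_keys()):
            r_t = target_net.reliability(b1, b2)
            for k1, k2 in vertex_pairs_for_edge(b1, b2, tmap):
                a1, a2 = k1[0], k2[0]
                if k1 == k2 and b1 != b2:
                    continue
                if query_net.has_interaction(a1, a2):
                    continue  # conserved or query-observed, handled above
                cp = likely_prob(k1, k2)
                if cp is None:
                    continue
                graph.conservation_probs.append(cp)
                p = edge_probability(
                    EdgeType.LIKELY_CONSERVED_TARGET, [], [r_t], cons_prob=cp
                )
                if p >= params.edge_prob_threshold:
                    graph.add_edge(
                        AlignmentEdge(
                            graph.vertices[k1],
                            graph.vertices[k2],
                            EdgeType.LIKELY_CONSERVED_TARGET,
                            p,
                            target_path=(b1, b2),
                        )
                    )
    return graph


def connected_components(graph: AlignmentGraph) -> list[set[tuple[str, str]]]:
    """Maximal connected vertex sets of the alignment graph (DFS).

    Isolated vertices (no incident edge, not even a self-loop) are
    discarded: a solution must contain at least one edge to represent
    conserved interaction structure.  The returned list is deterministic:
    components are discovered from lexicographically sorted roots and the
    list is sorted by each component's sorted vertex keys.
    """
    seen: set[tuple[str, str]] = set()
    components: list[set[tuple[str, str]]] = []
    for root in sorted(graph.vertices):
        if root in seen or graph.degree(root) == 0:
            continue
        comp: set[tuple[str, str]] = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(nb for nb in graph.adjacency[node] if nb not in comp)
        seen |= comp
        components.append(comp)
    components.sort(key=lambda c: sorted(c))
    return components


# -- bounded best paths ----------------------------------------------------

def bounded_paths_from(
    net: Interactome, source: str, max_len: int
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Best indirect simple paths from ``source`` up to ``max_len`` edges.

    Returns, for every protein reachable by a simple path of 2..max_len
    edges, the path maximising the product of edge reliabilities
    (equivalently minimising the sum of -log reliabilities), with ties
    broken by the lexicographically smallest node sequence.  The direct
    neighbour relation is *not* included: endpoints at path length 1 only
    appear if a longer, indirect route also reaches them.
    """
    if source not in net:
        raise KeyError(f"protein {source!r} not in network")
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    path = [source]
    on_path = {source}

    def dfs(node: str, product: float, depth: int) -> None:
        if depth >= max_len:
            return
        for nb in sorted(net.neighbors(node)):
            if nb in on_path:
                continue
            p = product * net.reliability(node, nb)
            new_depth = depth + 1
            if new_depth >= 2:
                cur = best.get(nb)
                cand = (p, tuple(path) + (nb,))
                if cur is None or p > cur[0] or (p == cur[0] and cand[1] < cur[1]):
                    best[nb] = cand
            path.append(nb)
            on_path.add(nb)
            dfs(nb, p, new_depth)
            path.pop()
            on_path.remove(nb)

    dfs(source, 1.0, 0)
    return best


def bounded_best_path(
    net: Interactome, a: str, b: str, max_len: int = 3
) -> tuple[tuple[str, ...], float] | None:
    """Best indirect path (2..max_len edges) between two proteins, if any.

    Maximises the product of edge reliabilities; deterministic tie-break
    by lexicographic node sequence.  Returns (path, probability) or None.
    """
    if a not in net:
        raise KeyError(f"protein {a!r} not in network")
    if b not in net:
        raise KeyError(f"protein {b!r} not in network")
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    hit = bounded_paths_from(net, a, max_len).get(b)
    if hit is None:
        return None
    product, path = hit
    return path, product


# -- extension -------------------------------------------------------------

def _path_reliabilities(net: Interactome, path: tuple[str, ...]) -> list[float]:
    return [net.reliability(x, y) for x, y in zip(path, path[1:])]


def extend_graph(
    graph: AlignmentGraph,
    seeds: Sequence[set[tuple[str, str]]],
    query_net: Interactome,
    target_net: Interactome,
    params: AlignParams,
) -> AlignmentGraph:
    """Add gap and mismatch edges between vertices of different seeds.

    For a vertex pair in *different* seeds (never within one seed): a gap
    edge is added when the proteins interact directly in one network and
    indirectly (best bounded path) in the other; a mismatch edge when both
    networks connect them only indirectly.  Probabilities are joint
    products of the reliabilities involved; edges below the threshold are
    dropped.  All initial edges are preserved untouched.
    """
    out = graph.copy()
    seed_of: dict[tuple[str, str], int] = {}
    for i, comp in enumerate(seeds):
        for key in comp:
            seed_of[key] = i

    seed_keys = sorted(seed_of)
    qcache: dict[str, dict[str, tuple[float, tuple[str, ...]]]] = {}
    tcache: dict[str, dict[str, tuple[float, tuple[str, ...]]]] = {}

    def qreach(p: str) -> dict[str, tuple[float, tuple[str, ...]]]:
        if p not in qcache:
            qcache[p] = bounded_paths_from(query_net, p, params.max_path_length)
        return qcache[p]

    def treach(p: str) -> dict[str, tuple[float, tuple[str, ...]]]:
        if p not in tcache:
            tcache[p] = bounded_paths_from(target_net, p, params.max_path_length)
        return tcache[p]

    # index seed vertices by query protein for candidate pruning
    qindex: dict[str, list[tuple[str, str]]] = {}
    for key in seed_keys:
        qindex.setdefault(key[0], []).append(key)

    for ku in seed_keys:
        a1, b1 = ku
        q_direct = query_net.neighbors(a1)
        q_indirect = qreach(a1)
        t_direct = target_net.neighbors(b1)
        t_indirect = treach(b1)
        candidate_qproteins = set(q_direct) | set(q_indirect)
        for a2 in sorted(candidate_qproteins):
            for kv in qindex.get(a2, ()):
                if kv <= ku or seed_of[kv] == seed_of[ku]:
                    continue
                b2 = kv[1]
                direct_q = query_net.has_interaction(a1, a2)
                direct_t = target_net.has_interaction(b1, b2)
                if direct_q and direct_t:
                    continue  # a conserved candidate, not a gap/mismatch
                if direct_q:
                    hit = t_indirect.get(b2)
                    if hit is None:
                        continue
                    _, tpath = hit
                    p = edge_probability(
                        EdgeType.GAP_TARGET,
                        [query_net.reliability(a1, a2)],
                        _path_reliabilities(target_net, tpath),
                    )
                    if p >= params.edge_prob_threshold:
                        out.add_edge(
                            AlignmentEdge(
                                out.vertices[ku],
                                out.vertices[kv],
                                EdgeType.GAP_TARGET,
                                p,
                                query_path=(a1, a2),
                                target_path=tpath,
                            )
                        )
                elif direct_t:
                    hit = q_indirect.get(a2)
                    if hit is None:
                        continue
                    _, qpath = hit
                    p = edge_probability(
                        EdgeType.GAP_QUERY,
                        _path_reliabilities(query_net, qpath),
                        [target_net.reliability(b1, b2)],
                    )
                    if p >= params.edge_prob_threshold:
                        out.add_edge(
                            AlignmentEdge(
                                out.vertices[ku],
                                out.vertices[kv],
                                EdgeType.GAP_QUERY,
                                p,
                                query_path=qpath,
                                target_path=(b1, b2),
                            )
                        )
                else:
                    qhit = q_indirect.get(a2)
                    thit = t_indirect.get(b2)
                    if qhit is None or thit is None:
                        continue
                    _, qpath = qhit
                    _, tpath = thit
                    p = edge_probability(
                        EdgeType.MISMATCH,
                        _path_reliabilities(query_net, qpath),
                        _path_reliabilities(target_net, tpath),
                    )
                    if p >= params.edge_prob_threshold:
                        out.add_edge(
                            AlignmentEdge(
                                out.vertices[ku],
                                out.vertices[kv],
                                EdgeType.MISMATCH,
                                p,
                                query_path=qpath,
                                target_path=tpath,
                            )
                        )
    return out


# -- full run --------------------------------------------------------------

def build_pools(
    query_net: Interactome,
    target_net: Interactome,
    pairs: Sequence[HomologPair],
    conservation_probs: Sequence[float],
) -> ProbabilityPools:
    """Assemble the permutation-test pools from the alignment inputs."""
    return ProbabilityPools(
        vertex_pool=np.array([p.vertex_probability for p in pairs], dtype=float),
        reliability_pool_query=np.array(
            [it.reliability for it in query_net.interactions], dtype=float
        ),
        reliability_pool_target=np.array(
            [it.reliability for it in target_net.interactions], dtype=float
        ),
        conservation_pool=np.array(conservation_probs, dtype=float),
    )


def align(
    query_net: Interactome,
    target_net: Interactome,
    pairs: Sequence[HomologPair],
    cons_model: ConservationModel | None = None,
    params: AlignParams | None = None,
    seed: int = 0,
) -> list[AlignmentSolution]:
    """Run the full alignment and return significant, ranked solutions.

    Pairs must already carry vertex probabilities (and distances when
    likely-conserved prediction is enabled).  Solutions are the connected
    components of the extended alignment graph, scored, p-valued against
    topology-preserving random backgrounds, filtered at the p-value
    threshold and sorted by decreasing score (ties: lexicographic vertex
    list).  Vertex sets of the returned solutions are pairwise disjoint.
    """
    if params is None:
        params = AlignParams()
    initial = build_initial_graph(query_net, target_net, pairs, cons_model, params)
    seeds = connected_components(initial)
    extended = extend_graph(initial, seeds, query_net, target_net, params)
    components = connected_components(extended)

    pools = build_pools(query_net, target_net, pairs, extended.conservation_probs)
    config = ScoringConfig(
        alpha=params.alpha, n_random_scores=params.n_random_scores, rng_seed=seed
    )
    child_seeds = np.random.SeedSequence(seed).spawn(max(len(components), 1))

    solutions: list[AlignmentSolution] = []
    for comp, child in zip(components, child_seeds):
        vertices = [extended.vertices[k] for k in sorted(comp)]
        edges = extended.edges_within(comp)
        sol = AlignmentSolution(vertices=vertices, edges=edges)
        sol.score = solution_score(sol, config)
        sol.p_value = permutation_pvalue(
            sol, pools, config, rng=np.random.default_rng(child)
        )
        if sol.p_value <= params.p_threshold:
            solutions.append(sol)
    solutions.sort(key=lambda s: (-s.score, sorted(v.key for v in s.vertices)))
    return solutions
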