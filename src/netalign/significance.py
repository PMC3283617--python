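"""Edge probabilities, solution scoring and Monte-Carlo significance.

A solution's score combines vertex probabilities (sequence similarity of
the homolog pairs) and edge probabilities (joint reliability/conservation
of the interactions realising each edge) through a user-controlled
vertex-to-edge balance α:

    S = α Σ_v log(1 + p_v) + (1 − α) Σ_e log(1 + p_e)

Adding one inside the logarithm only keeps scores positive; it does not
change the ranking of solutions.  Significance is assessed by a fast
Monte-Carlo permutation test that preserves the solution's topology and
edge types: random backgrounds of scores are built by resampling vertex
probabilities, interaction reliabilities and conservation probabilities
from pools drawn from the actual inputs — the input networks are never
rewired and homology relationships are never randomised.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Sequence

import numpy as np

__all__ = [
    "EdgeType",
    "ScoringConfig",
    "ProbabilityPools",
    "edge_probability",
    "solution_score",
    "permutation_pvalue",
]


class EdgeType(enum.Enum):
    """Alignment-graph edge classes.

    The ``_query`` / ``_target`` suffix names the network on which the
    distinguishing evidence lies: a *likely-conserved* edge is suffixed by
    the network in which the interaction was actually observed, while a
    *gap* edge is suffixed by the network holding the indirect path (the
    other network has the direct interaction).
    """

    CONSERVED = "conserved"
    LIKELY_CONSERVED_QUERY = "likely_conserved_query"
    LIKELY_CONSERVED_TARGET = "likely_conserved_target"
    GAP_QUERY = "gap_query"
    GAP_TARGET = "gap_target"
    MISMATCH = "mismatch"


LIKELY_CONSERVED = (EdgeType.LIKELY_CONSERVED_QUERY, EdgeType.LIKELY_CONSERVED_TARGET)
GAPS = (EdgeType.GAP_QUERY, EdgeType.GAP_TARGET)


@dataclasses.dataclass
class ScoringConfig:
    """Scoring and significance parameters."""

    alpha: float = 0.5  # vertex-to-edge score balance
    n_random_scores: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_random_scores < 1:
            raise ValueError("n_random_scores must be >= 1")


@dataclasses.dataclass
class ProbabilityPools:
    """Input-derived sampling pools for the permutation test.

    ``vertex_pool`` holds the vertex probabilities of *all* homolog pairs
    of the species pair (before threshold filtering); the reliability
    pools hold all interaction reliabilities of each input network; the
    conservation pool holds the conservation probabilities of all
    candidate interactions.
    """

    vertex_pool: np.ndarray
    reliability_pool_query: np.ndarray
    reliability_pool_target: np.ndarray
    conservation_pool: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_pool = np.asarray(self.vertex_pool, dtype=float)
        self.reliability_pool_query = np.asarray(self.reliability_pool_query, dtype=float)
        self.reliability_pool_target = np.asarray(self.reliability_pool_target, dtype=float)
        self.conservation_pool = np.asarray(self.conservation_pool, dtype=float)


def edge_probability(
    edge_type: EdgeType,
    query_reliabilities: Sequence[float] = (),
    target_reliabilities: Sequence[float] = (),
    cons_prob: float | None = None,
) -> float:
    """Joint probability of the interactions realising an alignment edge.

    Assuming mutual independence of the individual terms:

    - conserved: r_query * r_target (one direct interaction per side);
    - likely conserved: product of the observed side's reliabilities times
      the conservation probability of the unobserved interaction;
    - gap: reliability of the direct interaction times the product of the
      reliabilities along the indirect path on the other side;
    - mismatch: product of the path reliabilities on both sides.
    """
    q = [float(r) for r in query_reliabilities]
    t = [float(r) for r in target_reliabilities]
    for r in q + t:
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"reliability {r} outside [0, 1]")
    if edge_type is EdgeType.CONSERVED:
        if len(q) != 1 or len(t) != 1:
            raise ValueError("conserved edge needs exactly one reliability per side")
        return q[0] * t[0]
    if edge_type in LIKELY_CONSERVED:
        if cons_prob is None:
            raise ValueError("likely-conserved edge requires a conservation probability")
        observed = q if edge_type is EdgeType.LIKELY_CONSERVED_QUERY else t
        if not observed:
            raise ValueError("likely-conserved edge missing observed-side reliability")
        return math.prod(observed) * cons_prob
    if edge_type in GAPS:
        # suffix names the indirect (path) side; the other side is direct
        path, direct = (q, t) if edge_type is EdgeType.GAP_QUERY else (t, q)
        if len(direct) != 1 or len(path) < 2:
            raise ValueError(
                "gap edge needs one direct reliability and a path of length >= 2"
            )
        return direct[0] * math.prod(path)
    if edge_type is EdgeType.MISMATCH:
        if len(q) < 2 or len(t) < 2:
            raise ValueError("mismatch edge needs paths of length >= 2 on both sides")
        return math.prod(q) * math.prod(t)
    raise ValueError(f"unknown edge type {edge_type!r}")


def solution_score(solution, config: ScoringConfig) -> float:
    """Score a solution: α-balanced log-probability sums over V and E."""
    vertices = list(solution.vertices)
    if not vertices:
        raise ValueError("cannot score an empty solution")
    a = config.alpha
    vs = sum(math.log1p(v.probability) for v in vertices)
    es = sum(math.log1p(e.probability) for e in solution.edges)
    return a * vs + (1.0 - a) * es


def _edge_random_probs(edge, pools: ProbabilityPools, rng, n: int) -> np.ndarray:
    """Random edge probabilities preserving the edge's type and path lengths."""

    def draw(pool: np.ndarray, count: int) -> np.ndarray:
        if pool.size == 0:
            raise ValueError(
                f"empty pool needed for edge type {edge.edge_type.value!r}"
            )
        return pool[rng.integers(0, pool.size, size=(n, count))]

    et = edge.edge_type
    nq = len(edge.query_path) - 1 if edge.query_path else 0
    nt = len(edge.target_path) - 1 if edge.target_path else 0
    if et is EdgeType.CONSERVED:
        return draw(pools.reliability_pool_query, 1)[:, 0] * draw(
            pools.reliability_pool_target, 1
        )[:, 0]
    if et in LIKELY_CONSERVED:
        pool, count = (
            (pools.reliability_pool_query, max(nq, 1))
            if et is EdgeType.LIKELY_CONSERVED_QUERY
            else (pools.reliability_pool_target, max(nt, 1))
        )
        obs = draw(pool, count).prod(axis=1)
        return obs * draw(pools.conservation_pool, 1)[:, 0]
    if et is EdgeType.GAP_QUERY:
        return draw(pools.reliability_pool_query, max(nq, 2)).prod(axis=1) * draw(
            pools.reliability_pool_target, 1
        )[:, 0]
    if et is EdgeType.GAP_TARGET:
        return draw(pools.reliability_pool_target, max(nt, 2)).prod(axis=1) * draw(
            pools.reliability_pool_query, 1
        )[:, 0]
    if et is EdgeType.MISMATCH:
        return draw(pools.reliability_pool_query, max(nq, 2)).prod(axis=1) * draw(
            pools.reliability_pool_target, max(nt, 2)
        ).prod(axis=1)
    raise ValueError(f"unknown edge type {et!r}")


def permutation_pvalue(
    solution,
    pools: ProbabilityPools,
    config: ScoringConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Topology-preserving Monte-Carlo p-value for one solution.

    Builds ``n_random_scores`` random scores on the solution's own graph:
    each vertex receives a fresh draw from the vertex pool and each edge a
    fresh probability assembled from pool draws according to its type (and
    path lengths, for gaps and mismatches).  The p-value is
    (1 + #{random >= observed}) / (1 + N); ties count as exceedances, and
    the +1 correction keeps p in [1/(N+1), 1].
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_random_scores
    vertices = list(solution.vertices)
    if not vertices:
        raise ValueError("cannot test an empty solution")
    if pools.vertex_pool.size == 0:
        raise ValueError("empty vertex pool")
    a = config.alpha
    observed = solution_score(solution, config)
    draws = pools.vertex_pool[rng.integers(0, pools.vertex_pool.size, size=(n, len(vertices)))]
    scores = a * np.log1p(draws).sum(axis=1)
    for edge in solution.edges:
        scores += (1.0 - a) * np.log1p(_edge_random_probs(edge, pools, rng, n))
    exceed = int(np.count_nonzero(scores >= observed - 1e-12))
    return (1 + exceed) / (1 + n)
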