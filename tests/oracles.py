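"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the implementation paths they check: monotone
regression by exhaustive enumeration of pooling patterns, the identity
solver by bisection, components by transitive closure, and best bounded
paths by exhaustive simple-path enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import brentq


def monotone_projection_bruteforce(values, weights=None, direction="nonincreasing"):
    """Exhaustive weighted least-squares projection onto the monotone cone.

    The projection is piecewise constant on consecutive blocks with each
    block at its weighted mean; enumerate all 2^(n-1) block partitions,
    keep the monotone candidates, return the one with minimal weighted SSE.
    Feasible for n <= ~12.
    """
    y = np.asarray(values, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n = len(y)
    best, best_sse = None, math.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        fitted = np.empty(n)
        start = 0
        blocks = []
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, n))
        for a, b in blocks:
            fitted[a:b] = np.average(y[a:b], weights=w[a:b])
        diffs = np.diff(fitted)
        ok = (
            np.all(diffs <= 1e-12)
            if direction == "nonincreasing"
            else np.all(diffs >= -1e-12)
        )
        if not ok:
            continue
        sse = float(np.sum(w * (y - fitted) ** 2))
        if sse < best_sse - 1e-15:
            best_sse, best = sse, fitted.copy()
    return best


def grishin_bisection(q: float, xtol: float = 1e-12) -> float:
    """Solve q = ln(1+2d)/(2d) by bracketed bisection."""
    if q == 1.0:
        return 0.0
    f = lambda d: math.log1p(2.0 * d) - 2.0 * d * q
    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, 1e-15, hi, xtol=xtol))


def components_bruteforce(n_vertices, edges):
    """Connected components by transitive closure of the reachability matrix.

    Vertices are 0..n-1; vertices with no incident edge are dropped, as a
    component must contain interaction structure.
    """
    reach = np.eye(n_vertices, dtype=bool)
    has_edge = np.zeros(n_vertices, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
        has_edge[u] = has_edge[v] = True
    for _ in range(n_vertices):
        reach = reach | (reach @ reach)
    comps = []
    seen = set()
    for i in range(n_vertices):
        if i in seen or not has_edge[i]:
            continue
        comp = {j for j in range(n_vertices) if reach[i, j] and has_edge[j]}
        seen |= comp
        comps.append(comp)
    return comps


def enumerate_simple_paths(adj_rel, a, b, max_len):
    """All simple a->b paths of 2..max_len edges with their reliability
    products.  ``adj_rel`` maps node -> {neighbor: reliability}."""
    out = []

    def walk(node, path, product):
        if len(path) - 1 > max_len:
            return
        if node == b and len(path) - 1 >= 2:
            out.append((tuple(path), product))
            return
        if len(path) - 1 == max_len:
            return
        for nb, r in adj_rel.get(node, {}).items():
            if nb in path:
                continue
            walk(nb, path + [nb], product * r)

    for nb, r in adj_rel.get(a, {}).items():
        walk(nb, [a, nb], r)
    return out


def best_bounded_path_bruteforce(adj_rel, a, b, max_len):
    """Best indirect path by exhaustive enumeration; ties by lexicographic
    node sequence.  Returns (path, product) or None."""
    paths = enumerate_simple_paths(adj_rel, a, b, max_len)
    if not paths:
        return None
    top = max(p for _, p in paths)
    cands = sorted(path for path, p in paths if p == top)
    return cands[0], top
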