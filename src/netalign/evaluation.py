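"""Benchmark construction rules and performance scoring.

Benchmarks are non-redundant sets of conserved complex or pathway pairs.
Redundancy is removed by single-linkage clustering on member overlap
(Jaccard distance, threshold 0.5); a query/target pair is *conserved*
when at least 2 and at least 25% of each side's components have a homolog
in the other side's set, in both directions.  An alignment solution
*covers* a target set when its target-side proteins include at least 2
and at least 50% (complexes) or one third (pathways) of the members.
Performance is reported as precision, recall and F measure at the
set, protein and (for pathways) interaction level.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

from .alignment import AlignmentSolution
from .homology import HomologPair
from .network_io import MoleculeSet, canonical_pair
from .significance import EdgeType

__all__ = [
    "BenchmarkPair",
    "PerformanceReport",
    "set_distance",
    "cluster_nonredundant",
    "conserved_pair",
    "select_representative_pairs",
    "covers",
    "evaluate",
    "write_reports",
]

COMPLEX_COVER_FRAC = 0.5
PATHWAY_COVER_FRAC = 1.0 / 3.0


@dataclasses.dataclass
class BenchmarkPair:
    query_set: MoleculeSet
    target_set: MoleculeSet
    kind: str = "complex"

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.query_set.set_id, self.target_set.set_id)


@dataclasses.dataclass
class PerformanceReport:
    level: str  # set, protein or interaction
    tp: int
    fp: int
    fn: int
    precision: float = 0.0
    recall: float = 0.0
    f_measure: float = 0.0
    degenerate: bool = False  # precision undefined (no predictions)

    @classmethod
    def from_counts(cls, level: str, tp: int, fp: int, fn: int) -> "PerformanceReport":
        degenerate = (tp + fp) == 0
        precision = tp / (tp + fp) if not degenerate else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        return cls(level, tp, fp, fn, precision, recall, f, degenerate)


def set_distance(a: set[str], b: set[str]) -> float:
    """Jaccard distance between two member sets: 1 - |a∩b| / |a∪b|."""
    if not a or not b:
        raise ValueError("set distance requires non-empty sets")
    return 1.0 - len(a & b) / len(a | b)


def cluster_nonredundant(
    sets: Sequence[MoleculeSet], threshold: float = 0.5
) -> list[list[MoleculeSet]]:
    """Single-linkage clustering of molecule sets on member overlap.

    Two sets join the same cluster when connected by a chain of pairwise
    distances strictly below the threshold.  Clusters are returned sorted
    by their lexicographically smallest member id.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    parent = list(range(len(sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(sets)), 2):
        if set_distance(sets[i].members, sets[j].members) < threshold:
            parent[find(i)] = find(j)
    clusters: dict[int, list[MoleculeSet]] = {}
    for i, ms in enumerate(sets):
        clusters.setdefault(find(i), []).append(ms)
    out = [sorted(c, key=lambda m: m.set_id) for c in clusters.values()]
    out.sort(key=lambda c: c[0].set_id)
    return out


def _homolog_index(pairs: Sequence[HomologPair]) -> tuple[dict, dict]:
    q2t: dict[str, set[str]] = {}
    t2q: dict[str, set[str]] = {}
    for p in pairs:
        q2t.setdefault(p.query_protein, set()).add(p.target_protein)
        t2q.setdefault(p.target_protein, set()).add(p.query_protein)
    return q2t, t2q


def conserved_pair(
    query_set: MoleculeSet,
    target_set: MoleculeSet,
    pairs: Sequence[HomologPair],
    min_count: int = 2,
    min_frac: float = 0.25,
) -> bool:
    """Reciprocal conservation test for a query/target set pair.

    True iff at least ``min_count`` and at least ``min_frac`` of the query
    members have a homolog among the target members, and vice versa.
    """
    if not query_set.members or not target_set.members:
        raise ValueError("conserved_pair requires non-empty sets")
    q2t, t2q = _homolog_index(pairs)
    matched_q = {
        m for m in query_set.members if q2t.get(m, set()) & target_set.members
    }
    matched_t = {
        m for m in target_set.members if t2q.get(m, set()) & query_set.members
    }
    ok_q = len(matched_q) >= min_count and len(matched_q) >= min_frac * len(query_set.members)
    ok_t = len(matched_t) >= min_count and len(matched_t) >= min_frac * len(target_set.members)
    return ok_q and ok_t


def _unmatched_counts(
    qset: MoleculeSet, tset: MoleculeSet, q2t: Mapping, t2q: Mapping
) -> tuple[int, int]:
    """(unmatched, matched) component counts across both sides of a pair."""
    mq = sum(1 for m in qset.members if q2t.get(m, set()) & tset.members)
    mt = sum(1 for m in tset.members if t2q.get(m, set()) & qset.members)
    matched = mq + mt
    unmatched = len(qset.members) + len(tset.members) - matched
    return unmatched, matched


def select_representative_pairs(
    query_clusters: Sequence[Sequence[MoleculeSet]],
    target_clusters: Sequence[Sequence[MoleculeSet]],
    pairs: Sequence[HomologPair],
    min_count: int = 2,
    min_frac: float = 0.25,
    kind: str = "complex",
) -> list[BenchmarkPair]:
    """Build the non-redundant benchmark: one representative pair per
    cluster pair satisfying the conserved-pair criterion.

    The representative minimises the number of unmatched components, with
    ties broken by maximising matched components and then
    lexicographically by set identifiers.
    """
    q2t, t2q = _homolog_index(pairs)
    out: list[BenchmarkPair] = []
    for qc in query_clusters:
        for tc in target_clusters:
            candidates = []
            for qs in qc:
                for ts in tc:
                    if conserved_pair(qs, ts, pairs, min_count, min_frac):
                        unmatched, matched = _unmatched_counts(qs, ts, q2t, t2q)
                        candidates.append(
                            (unmatched, -matched, qs.set_id, ts.set_id, qs, ts)
                        )
            if candidates:
                _, _, _, _, qs, ts = min(candidates)
                out.append(BenchmarkPair(qs, ts, kind=kind))
    return out


def covers(
    solution: AlignmentSolution | set[str],
    target: MoleculeSet,
    min_count: int = 2,
    min_frac: float = COMPLEX_COVER_FRAC,
) -> bool:
    """Coverage rule: does a solution recover a target complex/pathway?

    True iff the solution's target-side proteins include at least
    ``min_count`` and at least ``min_frac`` of the target members
    (0.5 for complexes, 1/3 for pathways).
    """
    proteins = (
        solution if isinstance(solution, set) else solution.target_proteins
    )
    overlap = proteins & target.members
    return len(overlap) >= min_count and len(overlap) >= min_frac * len(target.members)


def _cover_frac(kind: str) -> float:
    return PATHWAY_COVER_FRAC if kind == "pathway" else COMPLEX_COVER_FRAC


def _solution_target_edges(sol: AlignmentSolution) -> set[tuple[str, str]]:
    """Target-side direct interactions realised by the solution's edges."""
    out: set[tuple[str, str]] = set()
    for e in sol.edges:
        if e.edge_type in (EdgeType.CONSERVED, EdgeType.GAP_QUERY) and e.target_path:
            out.add(canonical_pair(e.target_path[0], e.target_path[-1]))
        elif e.edge_type is EdgeType.LIKELY_CONSERVED_TARGET and e.target_path:
            out.add(canonical_pair(e.target_path[0], e.target_path[-1]))
    return out


def evaluate(
    solutions: Sequence[AlignmentSolution],
    benchmark: Sequence[BenchmarkPair],
    mode: str = "i2i",
) -> list[PerformanceReport]:
    """Score solutions against a benchmark of conserved set pairs.

    In ``"i2i"`` mode every (already significance-filtered) solution is
    matched to its best benchmark pair by minimising the total number of
    unmatched proteins, and counts are: TP = distinct benchmark pairs
    covered, FP = solutions covering no pair, FN = pairs not covered.  In
    ``"query"`` mode only the top-ranked solution is evaluated against the
    query's benchmark pairs.  Protein-level counts pool the overlaps
    between each solution and the pair it covers; pathway benchmarks with
    explicit interaction lists additionally get an interaction-level
    report.
    """
    if not benchmark:
        raise ValueError("benchmark must be non-empty")
    if mode not in ("i2i", "query"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    kind = benchmark[0].kind
    frac = _cover_frac(kind)

    considered = list(solutions)
    if mode == "query" and considered:
        considered = [considered[0]]  # highest-ranked significant solution

    covered_pairs: set[tuple[str, str]] = set()
    sol_assignment: list[tuple[AlignmentSolution, BenchmarkPair | None]] = []
    for sol in considered:
        candidates = []
        for bp in benchmark:
            if not covers(sol, bp.target_set, min_frac=frac):
                continue
            unmatched = len(sol.target_proteins - bp.target_set.members) + len(
                bp.target_set.members - sol.target_proteins
            )
            unmatched += len(sol.query_proteins - bp.query_set.members) + len(
                bp.query_set.members - sol.query_proteins
            )
            candidates.append((unmatched, bp.pair_id, bp))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1]))
            best = candidates[0][2]
            sol_assignment.append((sol, best))
            # one solution may cover several distinct benchmark pairs
            for unm, pid, bp in candidates:
                covered_pairs.add(pid)
        else:
            sol_assignment.append((sol, None))

    tp = len(covered_pairs)
    fp = sum(1 for _, bp in sol_assignment if bp is None)
    fn = sum(1 for bp in benchmark if bp.pair_id not in covered_pairs)
    reports = [PerformanceReport.from_counts(kind, tp, fp, fn)]

    # protein level: overlaps with the covered pairs
    overlap_proteins: set[str] = set()
    solution_proteins: set[str] = set()
    covered_set_proteins: set[str] = set()
    for sol, bp in sol_assignment:
        solution_proteins |= {f"t:{p}" for p in sol.target_proteins}
        solution_proteins |= {f"q:{p}" for p in sol.query_proteins}
        if bp is None:
            continue
        overlap_proteins |= {f"t:{p}" for p in sol.target_proteins & bp.target_set.members}
        overlap_proteins |= {f"q:{p}" for p in sol.query_proteins & bp.query_set.members}
        covered_set_proteins |= {f"t:{p}" for p in bp.target_set.members}
        covered_set_proteins |= {f"q:{p}" for p in bp.query_set.members}
    p_tp = len(overlap_proteins)
    p_fp = len(solution_proteins - covered_set_proteins)
    p_fn = len(covered_set_proteins - solution_proteins)
    reports.append(PerformanceReport.from_counts("protein", p_tp, p_fp, p_fn))

    if kind == "pathway":
        i_tp = i_fp = i_fn = 0
        o_edges: set = set()
        s_edges: set = set()
        c_edges: set = set()
        for sol, bp in sol_assignment:
            sedges = _solution_target_edges(sol)
            s_edges |= sedges
            if bp is None or bp.target_set.interactions is None:
                continue
            o_edges |= sedges & bp.target_set.interactions
            c_edges |= bp.target_set.interactions
        i_tp = len(o_edges)
        i_fp = len(s_edges - c_edges)
        i_fn = len(c_edges - s_edges)
        reports.append(PerformanceReport.from_counts("interaction", i_tp, i_fp, i_fn))
    return reports


def write_reports(reports: Sequence[PerformanceReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("level\ttp\tfp\tfn\tprecision\trecall\tf_measure\tdegenerate\n")
        for r in reports:
            fh.write(
                f"{r.level}\t{r.tp}\t{r.fp}\t{r.fn}\t{r.precision:.6f}"
                f"\t{r.recall:.6f}\t{r.f_measure:.6f}\t{int(r.degenerate)}\n"
            )
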