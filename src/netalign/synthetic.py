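"""Synthetic paired interactomes with planted conserved modules.

The generator emulates the statistical structure the aligner exploits,
with known ground truth:

- *planted modules*: connected subgraphs present with mirrored topology
  in both networks (the conserved complexes/pathways to recover), whose
  member pairs are deeply conserved orthologs (very low E-values) with
  correlated evolutionary distances (small Δd within a module);
- *background*: Erdős–Rényi edges in each network, background ortholog
  pairs with moderate E-values and independent distances, and decoy
  (non-homologous) pairs with poor E-values to exercise the vertex
  threshold;
- *degradation*: rewiring (a fraction of planted conserved edges moved to
  random endpoints on one side) and optional one-sided deletion of
  planted edges (missing interactions that likely-conserved prediction
  should rescue);
- *reliabilities*: planted (curated-complex) interactions carry more
  supporting publications than background (high-throughput) edges.

Everything is deterministic under the configured seed, and the emitted
file formats are exactly those the I/O modules consume.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .evaluation import BenchmarkPair
from .evolution import identity_from_distance, write_identities
from .homology import HomologPair, write_homologs
from .network_io import (
    Interaction,
    Interactome,
    MoleculeSet,
    canonical_pair,
    reliability_from_publications,
    write_interactions,
    write_molecule_sets,
)

__all__ = [
    "SyntheticConfig",
    "PlantedModule",
    "GroundTruth",
    "SyntheticData",
    "generate",
    "rewire",
    "benchmark_from_truth",
    "write_dataset",
]


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator (defaults documented
    in the methods note)."""

    n_proteins_query: int = 400
    n_proteins_target: int = 400
    n_planted_modules: int = 20
    module_size_range: tuple[int, int] = (3, 8)
    extra_module_edge_prob: float = 0.3  # density beyond the spanning tree
    background_edge_density: float = 0.01
    rewiring_fraction: float = 0.1
    one_side_deletion_fraction: float = 0.0
    decoy_fraction: float = 0.2  # decoys as a fraction of all homolog pairs
    n_background_orthologs: int = 150
    n_null_evalues: int = 2000
    # publication-count models: count = offset + Geometric(p).  Planted
    # (curated-complex) interactions are literature-rich; background
    # (high-throughput) interactions are overwhelmingly single-publication.
    planted_pub_geom_p: float = 0.5
    planted_pub_offset: int = 3
    background_pub_geom_p: float = 0.75
    background_pub_offset: int = 0
    # log10 E-value models (mean, sd, clip_lo, clip_hi)
    planted_log10e: tuple[float, float, float, float] = (-45.0, 3.0, -80.0, -15.0)
    background_log10e: tuple[float, float, float, float] = (-20.0, 5.0, -60.0, -10.5)
    decoy_log10e: tuple[float, float, float, float] = (-3.0, 1.5, -8.0, 1.0)
    null_log10e: tuple[float, float, float, float] = (0.5, 1.0, -6.0, 1.3)
    # evolutionary-distance model (substitutions per site)
    module_base_distance_range: tuple[float, float] = (0.4, 1.2)
    module_distance_noise: float = 0.05
    background_distance_range: tuple[float, float] = (0.2, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("module sizes must be >= 2 and min <= max")
        for frac in (
            self.background_edge_density,
            self.rewiring_fraction,
            self.one_side_deletion_fraction,
            self.decoy_fraction,
            self.extra_module_edge_prob,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.n_planted_modules * hi > min(
            self.n_proteins_query, self.n_proteins_target
        ):
            raise ValueError(
                "planted modules cannot exceed the number of proteins; "
                "reduce n_planted_modules or module sizes"
            )


@dataclasses.dataclass
class PlantedModule:
    #: members in generation order: query_members[i] and target_members[i]
    #: are the orthologous partners
    query_members: tuple[str, ...]
    target_members: tuple[str, ...]
    #: conserved edges as ((query_a, query_b), (target_a, target_b)),
    #: recorded before any rewiring or deletion
    conserved_edges: list[tuple[tuple[str, str], tuple[str, str]]]

    @property
    def member_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.query_members, self.target_members))


@dataclasses.dataclass
class GroundTruth:
    planted_modules: list[PlantedModule]
    homolog_map: set[tuple[str, str]]  # true ortholog pairs


@dataclasses.dataclass
class SyntheticData:
    query_net: Interactome
    target_net: Interactome
    pairs: list[HomologPair]
    identity_table: dict[tuple[str, str], float]
    null_evalues: np.ndarray
    truth: GroundTruth
    config: SyntheticConfig


def _draw_evalue(rng: np.random.Generator, model: tuple[float, float, float, float]) -> float:
    mean, sd, lo, hi = model
    return float(10.0 ** np.clip(rng.normal(mean, sd), lo, hi))


def _pub_count(rng: np.random.Generator, offset: int, p: float) -> int:
    return offset + int(rng.geometric(p))


def generate(config: SyntheticConfig | None = None) -> SyntheticData:
    """Generate paired networks, homology data and ground truth."""
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.rng_seed)
    qprot = [f"q{i:04d}" for i in range(config.n_proteins_query)]
    tprot = [f"t{i:04d}" for i in range(config.n_proteins_target)]

    query_net = Interactome("query")
    target_net = Interactome("target")
    for p in qprot:
        query_net.add_protein(p)
    for p in tprot:
        target_net.add_protein(p)

    # -- planted modules -------------------------------------------------
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_planted_modules)
    qperm = rng.permutation(config.n_proteins_query)
    tperm = rng.permutation(config.n_proteins_target)
    modules: list[PlantedModule] = []
    planted_edges: list[tuple[tuple[str, str], tuple[str, str]]] = []
    offset = 0
    for m in sizes:
        qm = [qprot[i] for i in qperm[offset : offset + m]]
        tm = [tprot[i] for i in tperm[offset : offset + m]]
        offset += m
        edges_idx: set[tuple[int, int]] = set()
        for i in range(1, m):
            j = int(rng.integers(0, i))
            edges_idx.add((j, i))
        for i in range(m):
            for j in range(i + 1, m):
                if (i, j) not in edges_idx and rng.random() < config.extra_module_edge_prob:
                    edges_idx.add((i, j))
        mod_edges = []
        for i, j in sorted(edges_idx):
            qe = canonical_pair(qm[i], qm[j])
            te = canonical_pair(tm[i], tm[j])
            n_pub_q = _pub_count(rng, config.planted_pub_offset, config.planted_pub_geom_p)
            n_pub_t = _pub_count(rng, config.planted_pub_offset, config.planted_pub_geom_p)
            query_net.add_interaction(
                Interaction(*qe, reliability_from_publications(n_pub_q), n_pub_q)
            )
            target_net.add_interaction(
                Interaction(*te, reliability_from_publications(n_pub_t), n_pub_t)
            )
            mod_edges.append((qe, te))
        planted_edges.extend(mod_edges)
        modules.append(PlantedModule(tuple(qm), tuple(tm), mod_edges))

    # -- degrade planted edges: rewiring, then one-sided deletion --------
    # removed slots stay empty: neither reattachment nor background
    # sampling may refill them, so ground truth remains unambiguous
    removed: dict[int, set[tuple[str, str]]] = {0: set(), 1: set()}
    n_edges = len(planted_edges)
    n_rewire = round(config.rewiring_fraction * n_edges)
    order = rng.permutation(n_edges)
    rewired = set(order[:n_rewire].tolist())
    for idx in sorted(rewired):
        qe, te = planted_edges[idx]
        side = 0 if rng.random() < 0.5 else 1
        net, edge, prots = (
            (query_net, qe, qprot) if side == 0 else (target_net, te, tprot)
        )
        old = net.get(*edge)
        if old is None:
            continue
        net.remove_interaction(*edge)
        removed[side].add(edge)
        while True:
            i, j = rng.choice(len(prots), size=2, replace=False)
            key = canonical_pair(prots[i], prots[j])
            if key not in removed[side] and not net.has_interaction(*key):
                break
        net.add_interaction(Interaction(*key, old.reliability, old.n_publications))
    if config.one_side_deletion_fraction > 0:
        intact = [i for i in range(n_edges) if i not in rewired]
        n_del = round(config.one_side_deletion_fraction * len(intact))
        chosen = rng.permutation(len(intact))[:n_del]
        for k in sorted(chosen.tolist()):
            qe, te = planted_edges[intact[k]]
            side = 0 if rng.random() < 0.5 else 1
            net, edge = (query_net, qe) if side == 0 else (target_net, te)
            if net.get(*edge) is not None:
                net.remove_interaction(*edge)
                removed[side].add(edge)

    # -- background edges ------------------------------------------------
    for side, (net, prots) in enumerate(((query_net, qprot), (target_net, tprot))):
        n = len(prots)
        n_bg = round(config.background_edge_density * n * (n - 1) / 2)
        added = 0
        while added < n_bg:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = canonical_pair(prots[i], prots[j])
            if net.has_interaction(a, b) or (a, b) in removed[side]:
                continue
            n_pub = _pub_count(rng, config.background_pub_offset, config.background_pub_geom_p)
            net.add_interaction(
                Interaction(a, b, reliability_from_publications(n_pub), n_pub)
            )
            added += 1

    # -- homolog pairs ---------------------------------------------------
    pairs: list[HomologPair] = []
    identity: dict[tuple[str, str], float] = {}
    homolog_map: set[tuple[str, str]] = set()

    def add_pair(q: str, t: str, emodel, distance: float) -> None:
        pairs.append(
            HomologPair(
                q,
                t,
                evalue_qt=_draw_evalue(rng, emodel),
                evalue_tq=_draw_evalue(rng, emodel),
            )
        )
        identity[(q, t)] = identity_from_distance(distance)

    for mod in modules:
        base = rng.uniform(*config.module_base_distance_range)
        for q, t in mod.member_pairs:
            d = max(0.01, base + rng.normal(0.0, config.module_distance_noise))
            add_pair(q, t, config.planted_log10e, d)
            homolog_map.add((q, t))

    free_q = [qprot[i] for i in qperm[offset:]]
    free_t = [tprot[i] for i in tperm[offset:]]
    n_bg_orth = min(config.n_background_orthologs, len(free_q), len(free_t))
    for q, t in zip(free_q[:n_bg_orth], free_t[:n_bg_orth]):
        d = rng.uniform(*config.background_distance_range)
        add_pair(q, t, config.background_log10e, d)
        homolog_map.add((q, t))

    n_true = len(pairs)
    if config.decoy_fraction > 0:
        n_decoys = round(config.decoy_fraction / (1.0 - config.decoy_fraction) * n_true)
        existing = {p.key for p in pairs}
        made = 0
        while made < n_decoys:
            q = qprot[int(rng.integers(0, len(qprot)))]
            t = tprot[int(rng.integers(0, len(tprot)))]
            if (q, t) in existing:
                continue
            d = rng.uniform(*config.background_distance_range)
            add_pair(q, t, config.decoy_log10e, d)
            existing.add((q, t))
            made += 1

    null_evalues = np.array(
        [_draw_evalue(rng, config.null_log10e) for _ in range(config.n_null_evalues)]
    )
    truth = GroundTruth(planted_modules=modules, homolog_map=homolog_map)
    return SyntheticData(
        query_net, target_net, pairs, identity, null_evalues, truth, config
    )


def rewire(net: Interactome, fraction: float, seed: int) -> Interactome:
    """Move a deterministic fraction of edges to random endpoints.

    Exactly ``round(fraction * n_edges)`` edges are removed and
    re-attached to uniformly drawn endpoint pairs, keeping their
    reliabilities.  Degree inflation of the new endpoints is allowed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = net.copy()
    keys = sorted(net.edge_keys())
    prots = sorted(net.proteins)
    n_move = round(fraction * len(keys))
    chosen = rng.permutation(len(keys))[:n_move]
    for idx in sorted(chosen.tolist()):
        key = keys[idx]
        old = out.get(*key)
        if old is None:
            continue
        out.remove_interaction(*key)
        while True:
            i, j = rng.integers(0, len(prots), size=2)
            if i == j:
                continue
            a, b = canonical_pair(prots[i], prots[j])
            if not out.has_interaction(a, b):
                break
        out.add_interaction(Interaction(a, b, old.reliability, old.n_publications))
    return out


def benchmark_from_truth(truth: GroundTruth, kind: str = "complex") -> list[BenchmarkPair]:
    """Planted modules as a benchmark of conserved set pairs."""
    out = []
    for i, mod in enumerate(truth.planted_modules):
        qs = MoleculeSet(f"module{i:03d}_q", set(mod.query_members), kind=kind)
        ts = MoleculeSet(f"module{i:03d}_t", set(mod.target_members), kind=kind)
        out.append(BenchmarkPair(qs, ts, kind=kind))
    return out


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the TSV formats the I/O modules consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "query": outdir / "query_interactions.tsv",
        "target": outdir / "target_interactions.tsv",
        "homologs": outdir / "homologs.tsv",
        "identities": outdir / "identities.tsv",
        "null_evalues": outdir / "null_evalues.txt",
        "benchmark_query": outdir / "benchmark_query_sets.tsv",
        "benchmark_target": outdir / "benchmark_target_sets.tsv",
    }
    write_interactions(data.query_net, paths["query"], support="count")
    write_interactions(data.target_net, paths["target"], support="count")
    write_homologs(data.pairs, paths["homologs"])
    write_identities(data.identity_table, paths["identities"])
    with open(paths["null_evalues"], "w") as fh:
        for e in data.null_evalues:
            fh.write(f"{e:.6g}\n")
    bench = benchmark_from_truth(data.truth)
    write_molecule_sets([bp.query_set for bp in bench], paths["benchmark_query"])
    write_molecule_sets([bp.target_set for bp in bench], paths["benchmark_target"])
    return paths
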