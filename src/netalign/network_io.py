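"""Interactome data model and file I/O.

Interactomes are undirected protein-protein interaction networks in which
every interaction carries a reliability in [0, 1], derived from the number
of publications supporting it or supplied directly.  Protein identifiers
are opaque strings (UniProt accessions in practice); no identifier mapping
is performed.  Self-interactions are legal throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Interaction",
    "Interactome",
    "MoleculeSet",
    "reliability_from_publications",
    "read_interactions",
    "write_interactions",
    "read_molecule_sets",
    "write_molecule_sets",
    "build_query_network",
    "write_solutions",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a protein pair lexicographically so {a, b} has one key."""
    return (a, b) if a <= b else (b, a)


def reliability_from_publications(n: int) -> float:
    """Map a supporting-publication count to an interaction reliability.

    Uses r = 1 - 2**(-n): each independent publication halves the residual
    doubt about the interaction.  Monotone non-decreasing, r(0) = 0, and
    bounded in [0, 1).
    """
    if n < 0:
        raise ValueError(f"publication count must be non-negative, got {n}")
    return 1.0 - 2.0 ** (-n)


@dataclasses.dataclass(frozen=True)
class Interaction:
    """A single undirected interaction with canonicalised endpoints."""

    protein_a: str
    protein_b: str
    reliability: float
    n_publications: int | None = None

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if not (0.0 <= self.reliability <= 1.0):
            raise ValueError(
                f"reliability must be in [0, 1], got {self.reliability!r} "
                f"for pair ({a}, {b})"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self(self) -> bool:
        return self.protein_a == self.protein_b


class Interactome:
    """An undirected PPI network: proteins plus reliability-weighted edges.

    Duplicate pairs merge by keeping the maximum support (publication count
    or reliability), matching union semantics when interaction lists from
    several sources are concatenated.
    """

    def __init__(self, species_tag: str = "", interactions: Iterable[Interaction] = ()):
        self.species_tag = species_tag
        self._edges: dict[tuple[str, str], Interaction] = {}
        self._adj: dict[str, set[str]] = {}
        for it in interactions:
            self.add_interaction(it)

    # -- construction ----------------------------------------------------
    def add_protein(self, protein: str) -> None:
        self._adj.setdefault(protein, set())

    def add_interaction(self, interaction: Interaction) -> None:
        key = interaction.pair
        old = self._edges.get(key)
        if old is not None:
            # merge by maximum support
            if old.n_publications is not None and interaction.n_publications is not None:
                n = max(old.n_publications, interaction.n_publications)
                r = max(old.reliability, interaction.reliability)
                interaction = Interaction(*key, reliability=r, n_publications=n)
            elif interaction.reliability < old.reliability:
                interaction = old
        self._edges[key] = interaction
        a, b = key
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    # -- queries ---------------------------------------------------------
    @property
    def proteins(self) -> set[str]:
        return set(self._adj)

    @property
    def interactions(self) -> list[Interaction]:
        return list(self._edges.values())

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, protein: str) -> bool:
        return protein in self._adj

    def has_interaction(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self._edges

    def get(self, a: str, b: str) -> Interaction | None:
        return self._edges.get(canonical_pair(a, b))

    def reliability(self, a: str, b: str) -> float:
        it = self._edges.get(canonical_pair(a, b))
        if it is None:
            raise KeyError(f"no interaction between {a!r} and {b!r}")
        return it.reliability

    def neighbors(self, protein: str) -> set[str]:
        return set(self._adj.get(protein, ()))

    def edge_keys(self) -> Iterator[tuple[str, str]]:
        return iter(self._edges)

    def copy(self) -> "Interactome":
        out = Interactome(self.species_tag)
        out._edges = dict(self._edges)
        out._adj = {p: set(nb) for p, nb in self._adj.items()}
        return out

    def remove_interaction(self, a: str, b: str) -> None:
        key = canonical_pair(a, b)
        if key not in self._edges:
            raise KeyError(f"no interaction between {a!r} and {b!r}")
        del self._edges[key]
        a, b = key
        self._adj[a].discard(b)
        self._adj[b].discard(a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self._edges == other._edges and self.proteins == other.proteins


@dataclasses.dataclass
class MoleculeSet:
    """A protein complex or pathway: an identifier plus its member proteins.

    Pathways may carry an explicit binary-interaction list whose endpoints
    must lie inside the member set.
    """

    set_id: str
    members: set[str]
    kind: str = "complex"
    interactions: set[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"molecule set {self.set_id!r} has no members")
        if self.kind not in ("complex", "pathway"):
            raise ValueError(f"kind must be 'complex' or 'pathway', got {self.kind!r}")
        if self.interactions is not None:
            canon = {canonical_pair(a, b) for a, b in self.interactions}
            for a, b in canon:
                if a not in self.members or b not in self.members:
                    raise ValueError(
                        f"interaction ({a}, {b}) of set {self.set_id!r} "
                        "has an endpoint outside the member set"
                    )
            self.interactions = canon


# -- interaction files ----------------------------------------------------

def read_interactions(
    path: str | Path,
    support: str = "count",
    species_tag: str = "",
) -> Interactome:
    """Read a tab-separated interaction list into an Interactome.

    Format: ``proteinA<TAB>proteinB[<TAB>support]``.  The ``support``
    dialect declares the optional third column: ``"count"`` (integer
    publication count, converted via :func:`reliability_from_publications`)
    or ``"reliability"`` (float in [0, 1]).  A missing third column means
    one publication under the count dialect and reliability 1.0 under the
    reliability dialect.  Duplicate pairs merge by maximum support.
    """
    if support not in ("count", "reliability"):
        raise ValueError(f"unknown support dialect {support!r}")
    net = Interactome(species_tag)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated input
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty protein identifier")
            n_pub: int | None = None
            if support == "count":
                if len(fields) >= 3:
                    try:
                        n_pub = int(fields[2])
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: non-integer publication "
                            f"count {fields[2]!r}"
                        ) from None
                else:
                    n_pub = 1
                r = reliability_from_publications(n_pub)
            else:
                r = float(fields[2]) if len(fields) >= 3 else 1.0
                if not (0.0 <= r <= 1.0):
                    raise ValueError(
                        f"{path}: line {lineno}: reliability {r} outside [0, 1]"
                    )
            net.add_interaction(Interaction(a, b, reliability=r, n_publications=n_pub))
    return net


def write_interactions(net: Interactome, path: str | Path, support: str = "reliability") -> None:
    """Write an interactome back to the TSV interaction format."""
    if support not in ("count", "reliability"):
        raise ValueError(f"unknown support dialect {support!r}")
    with open(path, "w") as fh:
        for key in sorted(net.edge_keys()):
            it = net.get(*key)
            assert it is not None
            if support == "count":
                if it.n_publications is None:
                    raise ValueError(
                        f"interaction {key} has no publication count to write"
                    )
                fh.write(f"{key[0]}\t{key[1]}\t{it.n_publications}\n")
            else:
                fh.write(f"{key[0]}\t{key[1]}\t{it.reliability:.9g}\n")


# -- complex / pathway files ----------------------------------------------

def read_molecule_sets(
    path: str | Path,
    kind: str = "complex",
    edges_path: str | Path | None = None,
) -> list[MoleculeSet]:
    """Read ``set_id<TAB>member1,member2,...`` records.

    An optional companion edge list (``set_id<TAB>a<TAB>b``) attaches
    explicit interactions to pathway sets.
    """
    edge_map: dict[str, set[tuple[str, str]]] = {}
    if edges_path is not None:
        with open(edges_path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{edges_path}: line {lineno}: expected 3 columns")
                edge_map.setdefault(fields[0], set()).add(
                    canonical_pair(fields[1], fields[2])
                )
    sets: list[MoleculeSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            set_id = fields[0]
            members = {m for m in fields[1].split(",") if m}
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {set_id!r} has no members")
            sets.append(
                MoleculeSet(set_id, members, kind=kind, interactions=edge_map.get(set_id))
            )
    return sets


def write_molecule_sets(sets: Sequence[MoleculeSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ms in sets:
            fh.write(f"{ms.set_id}\t{','.join(sorted(ms.members))}\n")


def build_query_network(mset: MoleculeSet, interactome: Interactome) -> Interactome:
    """Build the network representation of a complex/pathway query.

    Induces the subnetwork on the member proteins using the interactome's
    edges; every member left without an induced edge receives a
    self-interaction with reliability 0, so complex composition is
    preserved even for singletons.
    """
    if not mset.members:
        raise ValueError("empty member set")
    net = Interactome(species_tag=interactome.species_tag)
    covered: set[str] = set()
    for a in sorted(mset.members):
        for b in sorted(mset.members):
            if a > b:
                continue
            it = interactome.get(a, b)
            if it is not None:
                net.add_interaction(it)
                covered.update((a, b))
    for m in sorted(mset.members - covered):
        net.add_interaction(Interaction(m, m, reliability=0.0, n_publications=0))
    return net


# -- alignment solution export --------------------------------------------

def _solution_sort_key(sol) -> tuple:
    return (-sol.score, sorted(v.key for v in sol.vertices))


def _node_label(vertex) -> str:
    return f"{vertex.pair.query_protein}|{vertex.pair.target_protein}"


def write_solutions(solutions: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Export scored alignment solutions as TSV, SIF or GraphML.

    Nodes are ``queryID|targetID`` homolog pairs; edge types (conserved,
    likely-conserved, gap, mismatch) are the SIF relation / a GraphML edge
    attribute.  Ordering is deterministic: decreasing score, ties broken by
    the lexicographic vertex list.
    """
    ordered = sorted(solutions, key=_solution_sort_key)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("rank\tscore\tp_value\tn_vertices\tn_edges\tvertices\tedges\n")
            for rank, sol in enumerate(ordered, start=1):
                verts = ";".join(sorted(_node_label(v) for v in sol.vertices))
                edges = ";".join(
                    sorted(
                        f"{_node_label(e.u)}--{e.edge_type.value}--{_node_label(e.v)}"
                        for e in sol.edges
                    )
                )
                pv = "NA" if sol.p_value is None else f"{sol.p_value:.6g}"
                fh.write(
                    f"{rank}\t{sol.score:.6f}\t{pv}\t{len(sol.vertices)}"
                    f"\t{len(sol.edges)}\t{verts}\t{edges}\n"
                )
    elif format == "sif":
        with open(path, "w") as fh:
            for sol in ordered:
                lines = sorted(
                    f"{_node_label(e.u)}\t{e.edge_type.value}\t{_node_label(e.v)}"
                    for e in sol.edges
                )
                for line in lines:
                    fh.write(line + "\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for rank, sol in enumerate(ordered, start=1):
            for v in sorted(sol.vertices, key=lambda v: v.key):
                g.add_node(
                    _node_label(v),
                    query=v.pair.query_protein,
                    target=v.pair.target_protein,
                    probability=float(v.probability),
                    solution_rank=rank,
                )
            for e in sol.edges:
                g.add_edge(
                    _node_label(e.u),
                    _node_label(e.v),
                    edge_type=e.edge_type.value,
                    probability=float(e.probability),
                )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown solution format {format!r}")
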