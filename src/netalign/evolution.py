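"""Evolutionary distances and interaction-conservation probabilities.

Interacting proteins evolve at correlated rates, so two homolog pairs that
flank a conserved interaction tend to have similar evolutionary distances.
This module estimates per-pair distances from fraction identity under
Grishin's substitution model (rate variation across both sites and residue
types) and converts the absolute difference of distances (Δd) between two
homolog pairs into the probability that the interaction they flank is
conserved, calibrated so the most similar pairs reach probability 0.9.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .homology import HomologPair, LikelihoodRatioTable, fit_likelihood_ratios

__all__ = [
    "grishin_distance",
    "identity_from_distance",
    "delta_distance",
    "ConservationModel",
    "fit_conservation_model",
    "conservation_probability",
    "build_conservation_model",
    "read_identities",
    "write_identities",
    "attach_distances",
]

_MAX_ITER = 10_000


def grishin_distance(q: float, tolerance: float = 1e-3) -> float:
    """Substitutions per site from fraction identity q.

    Solves Grishin's relation q = ln(1 + 2d) / (2d), which allows the
    substitution rate to vary both among sites and among residue types.
    The solution is found by iterating the contractive rearrangement
    d <- ln(1 + 2d) / (2q) from the sites-only starting point
    d0 = (1 - q)/q, until successive estimates differ by less than
    ``tolerance``; a bracketed root search is used as a fallback if the
    iteration cap is reached (the contraction slows as q -> 1).
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"fraction identity must be in (0, 1], got {q}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if q == 1.0:
        return 0.0
    d = (1.0 - q) / q
    for _ in range(_MAX_ITER):
        d_next = math.log1p(2.0 * d) / (2.0 * q)
        if abs(d_next - d) < tolerance:
            return d_next
        d = d_next
    # fallback: bracketed solve of ln(1+2d) - 2 d q = 0 on (0, hi]
    f = lambda x: math.log1p(2.0 * x) - 2.0 * x * q
    hi = max(2.0 * d, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError(f"distance iteration failed to converge for q={q}")
    return float(brentq(f, 1e-12, hi, xtol=min(tolerance, 1e-9)))


def identity_from_distance(d: float) -> float:
    """Inverse of :func:`grishin_distance`: q = ln(1 + 2d) / (2d)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d == 0:
        return 1.0
    return math.log1p(2.0 * d) / (2.0 * d)


def delta_distance(d1: float, d2: float) -> float:
    """Absolute difference of two evolutionary distances (symmetric)."""
    if d1 < 0 or d2 < 0:
        raise ValueError("distances must be non-negative")
    return abs(d1 - d2)


@dataclasses.dataclass
class ConservationModel:
    """Likelihood-ratio model over Δd bins for interaction conservation.

    Δd values are binned at ``bin_width`` substitutions per site; the
    smoothed ratio of the conservation model (homolog pairs flanking a
    conserved interaction) to the null model (random homolog pairs) is
    scaled so the maximal-ratio bin maps to ``target_max`` (default 0.9).
    """

    lr_table: LikelihoodRatioTable | None = None
    bin_width: float = 0.1
    target_max: float = 0.9
    null_sample_size: int = 100_000

    @property
    def fitted(self) -> bool:
        return self.lr_table is not None

    def bin(self, delta: float) -> int:
        if delta < 0:
            raise ValueError("delta distance must be non-negative")
        return int(math.floor(delta / self.bin_width))


def fit_conservation_model(
    conserved_deltas: Sequence[float],
    null_deltas: Sequence[float],
    bin_width: float = 0.1,
    target_max: float = 0.9,
) -> ConservationModel:
    """Fit the Δd likelihood-ratio table from conserved vs null samples."""
    if len(conserved_deltas) == 0 or len(null_deltas) == 0:
        raise ValueError("conserved and null Δd samples must both be non-empty")
    model = ConservationModel(bin_width=bin_width, target_max=target_max)
    model.lr_table = fit_likelihood_ratios(
        conserved_deltas, null_deltas, bin_func=model.bin
    )
    return model


def conservation_probability(delta: float, model: ConservationModel) -> float:
    """Probability that an interaction flanked by pairs at Δd is conserved."""
    if not model.fitted:
        raise ValueError("conservation model has not been fitted")
    assert model.lr_table is not None
    lr = model.lr_table.lookup(model.bin(delta))
    mx = model.lr_table.max_ratio
    if mx <= 0:
        raise ValueError("conservation model has max_ratio 0")
    return float(min(model.target_max, model.target_max * lr / mx))


def build_conservation_model(
    query_net,
    target_net,
    pairs: Sequence[HomologPair],
    seed: int,
    bin_width: float = 0.1,
    target_max: float = 0.9,
    null_sample_size: int = 100_000,
) -> ConservationModel:
    """Fit a conservation model directly from the alignment inputs.

    The conservation sample is the Δd of every two homolog pairs that
    flank an interaction present in *both* networks; the null sample is
    ``null_sample_size`` random pairs of homolog pairs drawn with a seeded
    generator.  Pairs must already carry distances (see
    :func:`attach_distances`).
    """
    usable = [p for p in pairs if p.distance is not None]
    if len(usable) < 2:
        raise ValueError("need at least two homolog pairs with distances")
    by_query: dict[str, list[HomologPair]] = {}
    for p in usable:
        by_query.setdefault(p.query_protein, []).append(p)

    conserved: list[float] = []
    for a1, a2 in query_net.edge_keys():
        for p1 in by_query.get(a1, ()):
            for p2 in by_query.get(a2, ()):
                if p1 is p2:
                    continue
                if target_net.has_interaction(p1.target_protein, p2.target_protein):
                    conserved.append(delta_distance(p1.distance, p2.distance))
    if not conserved:
        raise ValueError("no conserved interactions available to fit the model")

    rng = np.random.default_rng(seed)
    dists = np.array([p.distance for p in usable])
    i = rng.integers(0, len(dists), size=null_sample_size)
    j = rng.integers(0, len(dists), size=null_sample_size)
    null = np.abs(dists[i] - dists[j])
    model = fit_conservation_model(
        conserved, null.tolist(), bin_width=bin_width, target_max=target_max
    )
    model.null_sample_size = null_sample_size
    return model


# -- identity / distance tables -------------------------------------------

def read_identities(
    path: str | Path, kind: str = "identity"
) -> dict[tuple[str, str], float]:
    """Read ``query<TAB>target<TAB>value`` per-pair tables.

    ``kind`` declares the third column: ``"identity"`` (fraction of
    identical residues, converted via :func:`grishin_distance`) or
    ``"distance"`` (precomputed substitutions per site, used as-is).
    Returns a mapping from (query, target) to evolutionary distance.
    """
    if kind not in ("identity", "distance"):
        raise ValueError(f"unknown identity-table kind {kind!r}")
    out: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            val = float(fields[2])
            if kind == "identity":
                d = grishin_distance(val, tolerance=1e-9)
            else:
                if val < 0:
                    raise ValueError(f"{path}: line {lineno}: negative distance")
                d = val
            out[(fields[0], fields[1])] = d
    return out


def write_identities(
    table: Mapping[tuple[str, str], float], path: str | Path, kind: str = "identity"
) -> None:
    with open(path, "w") as fh:
        for (q, t), v in sorted(table.items()):
            fh.write(f"{q}\t{t}\t{v:.9g}\n")


def attach_distances(
    pairs: Sequence[HomologPair], distances: Mapping[tuple[str, str], float]
) -> None:
    """Set ``pair.distance`` from a per-pair distance table (in place)."""
    for p in pairs:
        d = distances.get(p.key)
        if d is not None:
            p.distance = d
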