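"""Protein pairing and vertex-probability calibration.

Homolog pairs between the query and target proteomes are the vertices of
the alignment graph.  Each pair is assigned a probabilistic similarity
measure: raw BLAST E-values are binned by order of magnitude, the
likelihood ratio of each bin under a homology model versus a null model
(all protein pairs between the two species) is estimated, smoothed by
monotone (isotonic) regression, and scaled so that the pair with the
highest likelihood ratio receives a vertex probability of 1 by default.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.isotonic import isotonic_regression

__all__ = [
    "UNDERFLOW_BIN",
    "HomologPair",
    "LikelihoodRatioTable",
    "BlastHit",
    "bin_by_magnitude",
    "pava_monotone",
    "fit_likelihood_ratios",
    "vertex_probability",
    "assign_vertex_probabilities",
    "infer_reciprocal_orthologs",
    "read_blast_tabular",
    "read_homologs",
    "write_homologs",
]

#: Bin index for E-values reported as exactly 0 (numeric underflow in
#: BLAST); ordered below every finite order-of-magnitude bin.
UNDERFLOW_BIN: int = -(2**31)


@dataclasses.dataclass
class HomologPair:
    """A query/target protein pairing with its similarity evidence.

    E-values are stored in both search directions; the *worse* (largest)
    of the available ones is used for likelihood-ratio lookup, which makes
    the calibration conservative with respect to reciprocal evidence.
    """

    query_protein: str
    target_protein: str
    evalue_qt: float | None = None
    evalue_tq: float | None = None
    likelihood_ratio: float = 0.0
    vertex_probability: float = 0.0
    distance: float | None = None  # evolutionary distance between the two proteins

    @property
    def key(self) -> tuple[str, str]:
        return (self.query_protein, self.target_protein)

    @property
    def evalue(self) -> float | None:
        """Representative E-value: the maximum of the available directions."""
        vals = [e for e in (self.evalue_qt, self.evalue_tq) if e is not None]
        return max(vals) if vals else None


def bin_by_magnitude(evalue: float) -> int:
    """Order-of-magnitude bin of an E-value: floor(log10 e).

    An E-value of exactly 0 (BLAST underflow) maps to a dedicated lowest
    bin so that monotone ordering over bins is preserved.
    """
    if evalue < 0:
        raise ValueError(f"E-value must be non-negative, got {evalue}")
    if evalue == 0:
        return UNDERFLOW_BIN
    return math.floor(math.log10(evalue))


def pava_monotone(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    direction: str = "nonincreasing",
) -> np.ndarray:
    """Weighted least-squares projection onto the monotone cone (PAVA)."""
    y = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise ValueError(f"length mismatch: {y.shape} values vs {w.shape} weights")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if direction not in ("nonincreasing", "nondecreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    if y.size == 0:
        return y
    return isotonic_regression(y, sample_weight=w, increasing=(direction == "nondecreasing"))


@dataclasses.dataclass
class LikelihoodRatioTable:
    """Smoothed per-bin likelihood ratios over E-value (or Δd) bins.

    ``bins`` are sorted ascending; ``ratios`` are monotone non-increasing
    with increasing bin after PAVA smoothing.  Lookups outside the fitted
    range clamp to the nearest fitted bin.
    """

    bins: np.ndarray  # sorted int bin indices
    ratios: np.ndarray  # same length, >= 0, non-increasing

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.bins.shape != self.ratios.shape:
            raise ValueError("bins and ratios must have equal length")

    @property
    def max_ratio(self) -> float:
        return float(self.ratios.max()) if self.ratios.size else 0.0

    def lookup(self, bin_index: int) -> float:
        i = int(np.searchsorted(self.bins, bin_index))
        if i >= len(self.bins):
            i = len(self.bins) - 1
        elif self.bins[i] != bin_index and i > 0:
            # between fitted bins: use the nearest lower (higher-ratio) side
            i -= 1
        return float(self.ratios[i])

    def lookup_evalue(self, evalue: float) -> float:
        return self.lookup(bin_by_magnitude(evalue))


def fit_likelihood_ratios(
    model_values: Sequence[float],
    null_values: Sequence[float],
    bin_func=bin_by_magnitude,
) -> LikelihoodRatioTable:
    """Estimate per-bin likelihood ratios model/null and smooth with PAVA.

    Counts in every bin receive add-one smoothing so that bins empty under
    the null (common in the far tail, where the model mass concentrates)
    never divide by zero.  The raw per-bin ratios are then replaced by
    their isotonic fit, non-increasing with increasing bin.
    """
    model_values = list(model_values)
    null_values = list(null_values)
    if not model_values or not null_values:
        raise ValueError("model and null samples must both be non-empty")
    mbins = [bin_func(v) for v in model_values]
    nbins = [bin_func(v) for v in null_values]
    bins = sorted(set(mbins) | set(nbins))
    index = {b: i for i, b in enumerate(bins)}
    mcount = np.ones(len(bins))  # add-one smoothing
    ncount = np.ones(len(bins))
    for b in mbins:
        mcount[index[b]] += 1
    for b in nbins:
        ncount[index[b]] += 1
    mfreq = mcount / mcount.sum()
    nfreq = ncount / ncount.sum()
    raw = mfreq / nfreq
    smoothed = pava_monotone(raw, direction="nonincreasing")
    return LikelihoodRatioTable(np.array(bins), smoothed)


def vertex_probability(
    likelihood_ratio: float,
    table: LikelihoodRatioTable,
    target_max: float = 1.0,
) -> float:
    """Scale a likelihood ratio into a probability.

    The pair with the highest likelihood ratio maps to ``target_max``
    (default 1); everything else scales linearly and is clamped to [0, 1].
    The mapping is scale-invariant: multiplying all ratios by a positive
    constant changes nothing.
    """
    if likelihood_ratio < 0:
        raise ValueError("likelihood ratio must be non-negative")
    if not (0.0 < target_max <= 1.0):
        raise ValueError(f"target_max must be in (0, 1], got {target_max}")
    if table.max_ratio <= 0:
        raise ValueError("likelihood-ratio table has max_ratio 0")
    return float(min(1.0, max(0.0, target_max * likelihood_ratio / table.max_ratio)))


def assign_vertex_probabilities(
    pairs: Iterable[HomologPair],
    null_evalues: Sequence[float],
    target_max: float = 1.0,
) -> LikelihoodRatioTable:
    """Fit the E-value likelihood-ratio table and set pair probabilities.

    The homology-model sample is the E-values of the supplied pairs
    themselves; the null sample should represent all protein pairs between
    the two species (or a random sample of them).  Pairs without any
    E-value get probability ``target_max`` (curated-ortholog mode).
    Mutates the pairs in place and returns the fitted table.
    """
    pairs = list(pairs)
    model = [p.evalue for p in pairs if p.evalue is not None]
    if not model:
        for p in pairs:
            p.likelihood_ratio = 1.0
            p.vertex_probability = target_max
        return LikelihoodRatioTable(np.array([0]), np.array([1.0]))
    table = fit_likelihood_ratios(model, null_evalues)
    for p in pairs:
        e = p.evalue
        if e is None:
            p.likelihood_ratio = table.max_ratio
        else:
            p.likelihood_ratio = table.lookup_evalue(e)
        p.vertex_probability = vertex_probability(p.likelihood_ratio, table, target_max)
    return table


# -- reciprocal BLAST ------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    evalue: float
    rank: int  # 1-based rank within the query's hit list


def infer_reciprocal_orthologs(
    hits_qt: Sequence[BlastHit],
    hits_tq: Sequence[BlastHit],
    evalue_cutoff: float = 1e-10,
    top_k: int = 10,
) -> list[HomologPair]:
    """Reciprocal-BLAST ortholog inference.

    A pair (a, b) is kept iff b appears among a's ``top_k`` hits with
    E-value <= cutoff in the query→target search AND a appears among b's
    ``top_k`` hits with E-value <= cutoff in the target→query search.
    One-to-many and many-to-many relationships are retained.  Returned
    pairs are sorted by (query, target) identifier.
    """
    if hits_qt is None or hits_tq is None:
        raise ValueError("both reciprocal hit lists are required")

    def admissible(hits: Sequence[BlastHit]) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for h in hits:
            if h.rank <= top_k and h.evalue <= evalue_cutoff:
                key = (h.query, h.subject)
                if key not in out or h.evalue < out[key]:
                    out[key] = h.evalue
        return out

    fwd = admissible(hits_qt)
    rev = admissible(hits_tq)
    pairs = []
    for (q, t), e_qt in fwd.items():
        e_tq = rev.get((t, q))
        if e_tq is not None:
            pairs.append(HomologPair(q, t, evalue_qt=e_qt, evalue_tq=e_tq))
    pairs.sort(key=lambda p: p.key)
    return pairs


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Read BLAST tabular output (outfmt 6-like: qseqid sseqid ... evalue ...).

    Ranks are assigned by order of appearance within each query, as BLAST
    emits hits sorted by significance.  Only the query, subject and
    E-value (column 11 when 12 columns are present, otherwise the last
    column) are used.
    """
    hits: list[BlastHit] = []
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
            q, s = fields[0], fields[1]
            e_field = fields[10] if len(fields) >= 12 else fields[-1]
            try:
                e = float(e_field)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: bad E-value {e_field!r}"
                ) from None
            counts[q] = counts.get(q, 0) + 1
            hits.append(BlastHit(q, s, e, counts[q]))
    return hits


def read_homologs(path: str | Path) -> list[HomologPair]:
    """Read ``query<TAB>target[<TAB>evalue_qt[<TAB>evalue_tq]]`` records."""
    pairs: list[HomologPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
            e_qt = float(fields[2]) if len(fields) >= 3 else None
            e_tq = float(fields[3]) if len(fields) >= 4 else None
            pairs.append(HomologPair(fields[0], fields[1], e_qt, e_tq))
    return pairs


def write_homologs(pairs: Sequence[HomologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(pairs, key=lambda p: p.key):
            e_qt = "" if p.evalue_qt is None else f"{p.evalue_qt:.6g}"
            e_tq = "" if p.evalue_tq is None else f"{p.evalue_tq:.6g}"
            fh.write(f"{p.query_protein}\t{p.target_protein}\t{e_qt}\t{e_tq}\n")
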