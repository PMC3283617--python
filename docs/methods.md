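# Methods

`netalign` performs pairwise local alignment of protein–protein
interaction (PPI) networks of arbitrary topology: whole interactome
against whole interactome (`i2i`), or a complex/pathway query against an
interactome (`c2i`, `p2i`), between two species or within one. This note
documents the models, the numerical choices, what the synthetic
generator does and does not emulate, and the known limitations.

## The alignment model

**Vertices.** An alignment-graph vertex is a homolog pair (one protein
from each network). Pairs come from a curated ortholog list, from a
paralog list (intra-species), or from reciprocal BLASTP
(`homology.infer_reciprocal_orthologs`: both directions must place the
partner within the top 10 hits at E ≤ 1e-10; one-to-many and
many-to-many relationships are retained).

**Vertex probabilities.** Raw E-values are binned by order of magnitude
(`floor(log10 E)`, with an underflow bin for E = 0). For each bin the
likelihood ratio of the homology model (the supplied pairs) to a null
model (a sample of all inter-species protein pairs) is estimated with
add-one smoothing on all bin counts, then replaced by its isotonic
(monotone non-increasing) regression fit via the pool-adjacent-violators
algorithm (PAVA, delegated to scikit-learn's exact weighted
least-squares implementation). Probabilities are the scaled ratios
`p = t · LR / LR_max` with `t = 1`, so the most similar pair is pinned
at probability 1. A Bayes posterior `LR·π/(LR·π + 1 − π)` cannot reach
1 at finite LR, so the scaled form is the one consistent with that
calibration point; it is monotone in LR and invariant under rescaling
all ratios. A pair with two E-values (both search directions) is binned
by the *worse* one — the conservative reading of reciprocal evidence.

**Interaction reliabilities.** Each interaction's confidence derives
from its number of supporting publications as `r = 1 − 2^(−n)`: every
independent publication halves the residual doubt; `r(0) = 0`, monotone,
bounded below 1. Precomputed reliabilities in the input override the
formula. Duplicate pairs merge by maximum support (union semantics over
merged source databases).

**Evolutionary distances and conservation probabilities.** Interacting
proteins evolve at correlated rates, so the two homolog pairs flanking a
conserved interaction tend to have similar distances. Per-pair distances
`d` (substitutions/site) are estimated from fraction identity `q` under
Grishin's model with rate variation across both sites and residue types,

    q = ln(1 + 2d) / (2d),

and the absolute difference Δd = |d₁ − d₂| between the two pairs
flanking a candidate interaction is converted into a conservation
probability by the same likelihood-ratio machinery: Δd binned at 0.1
substitutions/site, conservation model = Δd of pairs flanking an
interaction present in both networks, null model = Δd of random homolog
pairs (seeded sample, default 10⁵, 2×10⁴ in the shipped experiment
drivers), PAVA-smoothed, scaled so the maximal-ratio bin maps to
`t = 0.9`. The 0.1 bin width mirrors the order-of-magnitude binning
philosophy at a resolution the null sample supports.

**Numerical solution of the distance equation.** The obvious
rearrangement `d ← (e^{2dq} − 1)/2` has derivative `q(1+2d*) > 1` at
every root — always repelling — so the solver iterates the inverted,
contractive form

    d ← ln(1 + 2d) / (2q),

from the sites-only starting point `d₀ = (1 − q)/q`, stopping when
successive estimates differ by less than the tolerance (default 1e-3
substitutions/site, configurable; the acceptance checks run at 1e-9).
The contraction rate `1/(q(1+2d*))` approaches 1 as `q → 1`, so a
bracketed Brent solve of `ln(1+2d) − 2dq = 0` serves as fallback if the
iteration cap (10⁴) is reached. `q = 1` returns `d = 0` exactly.

**Edges.** For two vertices (a₁,b₁), (a₂,b₂):

- *conserved*: a₁–a₂ in the query network and b₁–b₂ in the target;
  probability `r_q · r_t`.
- *likely conserved* (optional): interaction in exactly one network;
  probability `r_observed · P(conserved | Δd)`. These edges participate
  in seed formation, addressing the many false negatives in current
  interactomes.
- *gap*: direct in one network, indirect in the other; *mismatch*:
  indirect in both. Indirect means the best simple path of 2..L edges
  (default L = 3, as interactomes are small-world and longer paths
  connect unrelated proteins) maximising the product of edge
  reliabilities — a bounded Dijkstra-style search with deterministic
  lexicographic tie-breaks. Edge probability is the joint product of all
  participating reliabilities, assuming mutual independence.

All edge probabilities are filtered at the edge-probability threshold;
vertices at the vertex-probability threshold.

**Seeds, extension, solutions.** Seeds are connected components
(iterative depth-first search) of the initial graph (conserved +
likely-conserved edges). Gap/mismatch edges are then added only
*between* different seeds — within a seed nearly every vertex pair is
indirectly connected, so intra-seed gaps would be mostly false
positives. Final solutions are the components of the extended graph;
because components partition the vertex set, no homolog pair can occur
in two solutions (maximality). An isolated vertex is not a solution: a
solution represents conserved interaction structure and must contain at
least one edge (a conserved self-interaction loop counts). Candidate
enumeration for extension is pruned to vertex pairs whose proteins lie
within L edges of each other on both sides; this is exactly equivalent
to exhaustive enumeration because every gap/mismatch edge requires such
proximity by definition.

**Scoring.** With α ∈ [0,1] the vertex-to-edge balance (default 0.5),

    S = α Σ_v log(1 + p_v) + (1 − α) Σ_e log(1 + p_e).

Taking logarithms makes vertex and edge contributions commensurate so α
acts directly as a balance; adding one keeps every term (hence S)
non-negative and the ranking by decreasing score well defined. S is
additive over disjoint unions of components.

**Significance.** Each solution receives a Monte-Carlo permutation
p-value from a random background of N scores (default 10⁴) built on the
solution's own topology: every vertex draws a probability from the pool
of all vertex probabilities of the species pair, and every edge draws
fresh reliabilities (and, for likely-conserved edges, a conservation
probability) according to its type and its support-path lengths. The
input networks are never rewired and homology relationships never
randomised — the test asks whether this interaction structure is more
credible than pool-typical structure of identical shape, which also
prevents large solutions from being automatically significant.
`p = (1 + #{random ≥ observed}) / (1 + N)`; ties count as exceedances
and the +1 correction keeps p ≥ 1/(N+1). Ties against the observed
score are detected with an absolute slack of 1e-12 to absorb
float-summation order. Per-solution generators are spawned from the run
seed, so results are reproducible and independent of solution order.

## Benchmark rules

Benchmark sets are non-redundant conserved complex/pathway pairs:

- overlap distance between two member sets is the Jaccard distance
  `1 − |∩|/|∪|`; sets closer than 0.5 are merged by single-linkage
  clustering (merging strictly below the threshold; the boundary case
  d = 0.5 keeps sets separate).
- a query/target pair is *conserved* when ≥ 2 and ≥ 25% of each side's
  members have a homolog in the other side's set, in both directions;
  per cluster pair, the representative minimises unmatched components
  (ties: maximise matched, then lexicographic ids).
- a solution *covers* a target set when its target-side proteins include
  ≥ 2 and ≥ 50% (complexes) or ≥ 1/3 (pathways) of the members.
- interactome-to-interactome evaluation matches each significant
  solution to the benchmark pair minimising total unmatched proteins;
  TP = distinct pairs covered, FP = solutions covering none,
  FN = pairs not covered. Query-mode evaluation considers only the
  top-ranked significant solution. Protein-level counts pool overlaps
  between solutions and the pairs they cover; pathway benchmarks with
  explicit interaction lists additionally get interaction-level counts.
  Precision with zero predictions is undefined and reported as 0 with an
  explicit degenerate flag.

## Default parameter profiles

Defaults are per task (`profiles.py`), determined with the packaged
calibration driver: grid search maximising the average F measure over
set- and protein-level results, cross-evaluated over generator seeds and
degradation scenarios — the same procedure `netalign calibrate` runs.
The whole-interactome profile needs a strict edge threshold (0.5):
permissive thresholds let mismatch edges through the dense background
chain all seeds into one giant component. Query profiles (`c2i`, `p2i`)
keep a permissive 0.1 threshold with likely-conserved prediction
enabled, since a small query cannot glue unrelated modules. Shared
defaults: vertex threshold 0.2, α = 0.5, max path length 3, p ≤ 0.05,
N = 10⁴ random scores.

## The synthetic generator

`synthetic.generate` emulates the statistical structure the aligner
exploits, with known ground truth. Defaults define the standard study
conditions:

- 400 + 400 proteins; Erdős–Rényi background at density 0.01 (mean
  degree ≈ 4); a scale-free background is deliberately not the default —
  the small-world argument only motivates the gap cap, not a specific
  null.
- 20 planted modules of 3–8 members: a random spanning tree plus extra
  edges at 0.3, mirrored in both networks through the true ortholog map.
- degradation: 10% of planted conserved edges are rewired (removed on
  one random side and reattached elsewhere, keeping their reliability);
  optionally a fraction of the intact planted edges lose one side
  outright (the missing-interaction regime that likely-conserved
  prediction targets). Removed slots are never refilled by background
  sampling, so ground truth stays unambiguous.
- reliabilities: planted (curated-complex) interactions draw 3+Geom(0.5)
  supporting publications (r ≈ 0.94+), background (high-throughput)
  interactions Geom(0.75) (mostly single-publication, r = 0.5) — the
  literature-rich-complex vs single-publication-background contrast that
  reliability weighting exploits in real interactomes.
- homology: planted orthologs draw log₁₀E ~ N(−45, 3) (deeply conserved
  module components), 150 background ortholog pairs N(−20, 5) capped at
  the reciprocal-BLAST cutoff, and 20% decoy pairs N(−3, 1.5) to
  exercise the vertex threshold; the null E-value sample is N(0.5, 1).
- distances: each module has a base distance U(0.4, 1.2) with N(0, 0.05)
  member noise (small within-module Δd); background and decoy pairs draw
  independently from U(0.2, 2.0). Identities are emitted through the
  exact inverse of the distance equation.

What passing tests on these data show — and do not show. The generator
reproduces the *separations* the method assumes (E-value and Δd
contrast, reliability contrast, planted connectivity); it does not
reproduce real interactome topology (degree heavy tails, hubs), study
bias, systematic false-positive structure, or correlated noise between
species. Recovery rates on synthetic data therefore characterise the
algorithm under its own assumptions, not expected performance on real
interactomes.

## Degenerate inputs and tie-breaking

Empty interaction files yield empty networks; an empty homolog set
yields zero solutions. Complex queries add self-interactions with
reliability 0 for members without induced edges, so composition is never
lost. Equal-score solutions order by lexicographic vertex list; equal
path products break ties by lexicographic node sequence; LR lookups
outside the fitted bin range clamp to the nearest fitted bin.

## Limitations

- Pairwise alignment only; no multiple-network alignment.
- The score compares solutions of similar size meaningfully through
  p-values, not raw scores; raw scores grow with solution size.
- The count→reliability mapping is one defensible choice among several;
  supplying precomputed reliabilities bypasses it.
- Identity-based distances saturate for very divergent pairs (q < 0.1),
  where Δd becomes noisy.
- The gap cap is global; per-network caps are not supported.
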