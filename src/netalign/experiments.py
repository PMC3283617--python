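"""Reproducible benchmark experiments on the synthetic study conditions.

These drivers wrap the full pipeline into the standard experiments the
package uses to characterise itself: planted-module recovery under
rewiring/deletion, the prediction-rescue comparison, and the calibration
of permutation p-values.  Problem sizes follow the generator defaults
(20 modules of 3-8 proteins in 400+400-protein networks); the p-value
calibration uses a small fixed solution topology so each replicate is a
single vectorised background computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alignment import AlignmentEdge, AlignmentSolution, AlignmentVertex, AlignParams
from .cli import run_pipeline
from .evaluation import covers, evaluate
from .evolution import grishin_distance
from .homology import HomologPair
from .profiles import profile
from .significance import (
    EdgeType,
    ProbabilityPools,
    ScoringConfig,
    permutation_pvalue,
)
from .synthetic import SyntheticConfig, benchmark_from_truth, generate

__all__ = ["RecoveryResult", "planted_recovery_run", "pvalue_calibration"]


@dataclasses.dataclass
class RecoveryResult:
    n_solutions_total: int
    n_significant: int
    recall_set: float
    recall_protein: float
    precision_set: float
    precision_protein: float
    #: largest p-value among solutions that cover a planted module
    max_planted_p: float
    #: fraction of planted modules covered by a significant solution
    fraction_planted_significant: float


def planted_recovery_run(
    data_seed: int,
    align_seed: int,
    n_random_scores: int = 9_999,
    one_side_deletion_fraction: float = 0.0,
    predict_likely_conserved: bool = False,
    config: SyntheticConfig | None = None,
    params: AlignParams | None = None,
) -> RecoveryResult:
    """Generate a synthetic dataset, align it, score planted recovery.

    The alignment runs with an open p-value threshold so every component
    is observed; recovery statistics are then computed on the solutions
    passing the standard 0.05 significance level.
    """
    if config is None:
        config = SyntheticConfig(
            rng_seed=data_seed,
            one_side_deletion_fraction=one_side_deletion_fraction,
        )
    data = generate(config)
    distances = {
        k: grishin_distance(v, tolerance=1e-9) for k, v in data.identity_table.items()
    }
    if params is None:
        params = profile(
            "i2i",
            n_random_scores=n_random_scores,
            predict_likely_conserved=predict_likely_conserved,
            p_threshold=1.0,  # keep all components; filter below
        )
    solutions = run_pipeline(
        data.query_net,
        data.target_net,
        data.pairs,
        params,
        align_seed,
        null_evalues=data.null_evalues,
        distances=distances,
    )
    benchmark = benchmark_from_truth(data.truth)
    significant = [s for s in solutions if s.p_value is not None and s.p_value <= 0.05]
    set_rep, prot_rep = evaluate(significant, benchmark, mode="i2i")[:2]

    planted_ps = []
    covered_significant = 0
    for bp in benchmark:
        ps = [
            s.p_value
            for s in solutions
            if s.p_value is not None and covers(s, bp.target_set)
        ]
        if ps:
            planted_ps.append(min(ps))
            if min(ps) <= 0.05:
                covered_significant += 1
    return RecoveryResult(
        n_solutions_total=len(solutions),
        n_significant=len(significant),
        recall_set=set_rep.recall,
        recall_protein=prot_rep.recall,
        precision_set=set_rep.precision,
        precision_protein=prot_rep.precision,
        max_planted_p=max(planted_ps) if planted_ps else 1.0,
        fraction_planted_significant=covered_significant / len(benchmark),
    )


def _pool_sampled_solution(rng: np.random.Generator, pools: ProbabilityPools):
    """A three-vertex solution whose probabilities are themselves drawn
    from the pools, so its score is exchangeable with the random
    background scores."""
    vp = rng.choice(pools.vertex_pool, 3)
    vertices = [
        AlignmentVertex(HomologPair(f"q{i}", f"t{i}"), float(vp[i])) for i in range(3)
    ]
    e1 = AlignmentEdge(
        vertices[0],
        vertices[1],
        EdgeType.CONSERVED,
        float(rng.choice(pools.reliability_pool_query) * rng.choice(pools.reliability_pool_target)),
        query_path=("a", "b"),
        target_path=("c", "d"),
    )
    e2 = AlignmentEdge(
        vertices[1],
        vertices[2],
        EdgeType.GAP_TARGET,
        float(
            rng.choice(pools.reliability_pool_query)
            * rng.choice(pools.reliability_pool_target)
            * rng.choice(pools.reliability_pool_target)
        ),
        query_path=("a", "b"),
        target_path=("c", "x", "d"),
    )
    return AlignmentSolution(vertices, [e1, e2])


def pvalue_calibration(
    n_replicates: int = 500, n_random_scores: int = 999, seed: int = 0
) -> np.ndarray:
    """Permutation p-values for pool-sampled observed solutions.

    When the observed solution's probabilities are drawn from the very
    pools the test resamples, its score is exchangeable with the random
    scores and the p-values must be uniform on (0, 1].  Returns the
    p-values of ``n_replicates`` independent replicates.
    """
    root = np.random.default_rng(seed)
    pools = ProbabilityPools(
        vertex_pool=root.uniform(0, 1, 300),
        reliability_pool_query=root.uniform(0, 1, 300),
        reliability_pool_target=root.uniform(0, 1, 300),
        conservation_pool=root.uniform(0, 0.9, 300),
    )
    children = np.random.SeedSequence(seed + 1).spawn(n_replicates)
    config = ScoringConfig(n_random_scores=n_random_scores)
    pvals = np.empty(n_replicates)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sol = _pool_sampled_solution(rng, pools)
        pvals[i] = permutation_pvalue(sol, pools, config, rng=rng)
    return pvals
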