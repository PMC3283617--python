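"""Per-task default parameter profiles.

Defaults differ by alignment task: comparing two whole interactomes needs
a strict edge-probability threshold (otherwise gap/mismatch edges through
the dense background merge unrelated seeds into giant components), while
aligning a small complex or pathway query against an interactome can
afford permissive thresholds.  The shipped profiles were determined with
the packaged calibration driver (grid search maximising the average F
measure over set- and protein-level benchmark results, cross-evaluated
over generator seeds and degradation scenarios), following the same
procedure a user would run via ``netalign calibrate`` on their own data.
"""

from __future__ import annotations

from .alignment import AlignParams

__all__ = ["profile", "PROFILES"]

PROFILES: dict[str, dict] = {
    # interactome vs interactome: strict edge filtering
    "i2i": dict(
        vertex_prob_threshold=0.2,
        edge_prob_threshold=0.5,
        predict_likely_conserved=False,
        max_path_length=3,
        alpha=0.5,
        p_threshold=0.05,
        n_random_scores=10_000,
        mode="i2i",
    ),
    # complex query vs interactome: permissive edges, prediction on
    "c2i": dict(
        vertex_prob_threshold=0.2,
        edge_prob_threshold=0.1,
        predict_likely_conserved=True,
        max_path_length=3,
        alpha=0.5,
        p_threshold=0.05,
        n_random_scores=10_000,
        mode="c2i",
    ),
    # pathway query vs interactome
    "p2i": dict(
        vertex_prob_threshold=0.2,
        edge_prob_threshold=0.1,
        predict_likely_conserved=True,
        max_path_length=3,
        alpha=0.5,
        p_threshold=0.05,
        n_random_scores=10_000,
        mode="p2i",
    ),
}


def profile(mode: str, **overrides) -> AlignParams:
    """Default AlignParams for an alignment task, with overrides."""
    if mode not in PROFILES:
        raise ValueError(f"unknown task profile {mode!r}; choose from {sorted(PROFILES)}")
    kwargs = dict(PROFILES[mode])
    kwargs.update(overrides)
    return AlignParams(**kwargs)
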