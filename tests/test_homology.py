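"""Homolog pairing, E-value binning and likelihood-ratio calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netalign.homology import (
    UNDERFLOW_BIN,
    BlastHit,
    HomologPair,
    assign_vertex_probabilities,
    bin_by_magnitude,
    fit_likelihood_ratios,
    infer_reciprocal_orthologs,
    pava_monotone,
    read_blast_tabular,
    vertex_probability,
)
from oracles import monotone_projection_bruteforce


class TestBinByMagnitude:
    @pytest.mark.parametrize(
        "evalue,expected",
        [(3e-5, -5), (1e-10, -10), (9.9e-10, -10), (1.0, 0), (25.0, 1)],
    )
    def test_floor_log10(self, evalue, expected):
        assert bin_by_magnitude(evalue) == expected

    def test_zero_maps_below_everything(self):
        assert bin_by_magnitude(0.0) == UNDERFLOW_BIN
        assert UNDERFLOW_BIN < bin_by_magnitude(1e-300)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_by_magnitude(-1e-5)


class TestPavaMonotone:
    def test_already_monotone_untouched(self):
        assert pava_monotone([3, 2, 1]).tolist() == [3, 2, 1]

    def test_violation_pooled(self):
        assert pava_monotone([3, 1, 2]).tolist() == pytest.approx([3, 1.5, 1.5])

    def test_constant_fixed_point(self):
        assert pava_monotone([2.0, 2.0, 2.0]).tolist() == [2.0, 2.0, 2.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pava_monotone([1, 2], weights=[1.0])

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.booleans(),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_projection(self, values, nondecreasing, wseed):
        weights = np.random.default_rng(wseed).uniform(0.1, 5.0, size=len(values))
        direction = "nondecreasing" if nondecreasing else "nonincreasing"
        got = pava_monotone(values, weights, direction)
        expected = monotone_projection_bruteforce(values, weights, direction)
        assert np.allclose(got, expected, atol=1e-8)


class TestFitLikelihoodRatios:
    def test_concentrated_model_peaks_and_decreases(self):
        model = [1e-20] * 50
        null = [10.0 ** -k for k in range(0, 21)] * 3
        table = fit_likelihood_ratios(model, null)
        assert table.ratios.argmax() == 0  # most significant bin
        assert np.all(np.diff(table.ratios) <= 1e-12)
        assert table.lookup(-20) == table.max_ratio

    def test_identical_samples_flat(self):
        sample = [10.0 ** -k for k in range(0, 10)] * 5
        table = fit_likelihood_ratios(sample, list(sample))
        assert np.allclose(table.ratios, table.ratios[0])
        assert table.ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_likelihood_ratios([], [1e-5])

    def test_monotone_on_random_samples(self, rng):
        for _ in range(20):
            model = 10.0 ** (-rng.uniform(0, 40, size=rng.integers(1, 50)))
            null = 10.0 ** (-rng.uniform(0, 40, size=rng.integers(1, 50)))
            table = fit_likelihood_ratios(model.tolist(), null.tolist())
            assert np.all(np.diff(table.ratios) <= 1e-12)


class TestVertexProbability:
    def _table(self):
        return fit_likelihood_ratios([1e-20] * 10 + [1e-10] * 5, [1e-3] * 10 + [1e-10] * 5)

    def test_max_ratio_maps_to_target(self):
        table = self._table()
        assert vertex_probability(table.max_ratio, table, 1.0) == pytest.approx(1.0)
        assert vertex_probability(table.max_ratio, table, 0.9) == pytest.approx(0.9)

    def test_zero_ratio_maps_to_zero(self):
        assert vertex_probability(0.0, self._table()) == 0.0

    def test_linear_scaling(self):
        table = self._table()
        assert vertex_probability(table.max_ratio / 2, table, 0.9) == pytest.approx(0.45)

    def test_scale_invariance(self):
        table = self._table()
        scaled = type(table)(table.bins, table.ratios * 37.0)
        for lr in np.linspace(0, table.max_ratio, 7):
            assert vertex_probability(lr, table) == pytest.approx(
                vertex_probability(lr * 37.0, scaled)
            )

    def test_monotone_in_lr(self):
        table = self._table()
        probs = [vertex_probability(lr, table) for lr in np.linspace(0, 2 * table.max_ratio, 25)]
        assert probs == sorted(probs)


class TestAssignVertexProbabilities:
    def test_best_pair_gets_one(self):
        pairs = [
            HomologPair("q1", "t1", 1e-40, 1e-38),
            HomologPair("q2", "t2", 1e-12, 1e-11),
            HomologPair("q3", "t3", 1e-3, 1e-2),
        ]
        null = (10.0 ** -np.random.default_rng(0).uniform(0, 5, 500)).tolist()
        assign_vertex_probabilities(pairs, null)
        assert pairs[0].vertex_probability == pytest.approx(1.0)
        assert pairs[0].vertex_probability >= pairs[1].vertex_probability
        assert pairs[1].vertex_probability >= pairs[2].vertex_probability


class TestReciprocalOrthologs:
    def hits(self, *rows):
        return [BlastHit(*r) for r in rows]

    def test_reciprocal_pair_kept(self):
        pairs = infer_reciprocal_orthologs(
            self.hits(("a", "b", 1e-12, 1)), self.hits(("b", "a", 1e-12, 1))
        )
        assert [(p.query_protein, p.target_protein) for p in pairs] == [("a", "b")]
        assert pairs[0].evalue == 1e-12

    def test_cutoff_enforced(self):
        pairs = infer_reciprocal_orthologs(
            self.hits(("a", "b", 1e-8, 1)), self.hits(("b", "a", 1e-30, 1))
        )
        assert pairs == []

    def test_rank_cap_enforced(self):
        pairs = infer_reciprocal_orthologs(
            self.hits(("a", "b", 1e-30, 11)), self.hits(("b", "a", 1e-30, 1))
        )
        assert pairs == []

    def test_many_to_many_retained(self):
        fwd = self.hits(("a1", "b1", 1e-20, 1), ("a1", "b2", 1e-15, 2), ("a2", "b1", 1e-18, 1))
        rev = self.hits(("b1", "a1", 1e-20, 1), ("b1", "a2", 1e-18, 2), ("b2", "a1", 1e-15, 1))
        pairs = infer_reciprocal_orthologs(fwd, rev)
        assert {(p.query_protein, p.target_protein) for p in pairs} == {
            ("a1", "b1"), ("a1", "b2"), ("a2", "b1")
        }

    def test_reciprocity_symmetric(self, rng):
        qs = [f"a{i}" for i in range(6)]
        ts = [f"b{i}" for i in range(6)]
        fwd, rev = [], []
        for q in qs:
            hits = rng.choice(ts, size=3, replace=False)
            for rank, t in enumerate(hits, 1):
                fwd.append(BlastHit(q, t, float(10.0 ** -rng.uniform(5, 30)), rank))
        for t in ts:
            hits = rng.choice(qs, size=3, replace=False)
            for rank, q in enumerate(hits, 1):
                rev.append(BlastHit(t, q, float(10.0 ** -rng.uniform(5, 30)), rank))
        ab = infer_reciprocal_orthologs(fwd, rev)
        ba = infer_reciprocal_orthologs(rev, fwd)
        assert {(p.query_protein, p.target_protein) for p in ab} == {
            (p.target_protein, p.query_protein) for p in ba
        }

    def test_missing_list_rejected(self):
        with pytest.raises(ValueError):
            infer_reciprocal_orthologs(None, [])


class TestBlastTabular:
    def test_ranks_by_appearance(self, tmp_path):
        p = tmp_path / "hits.tsv"
        rows = [
            "a\tb\t99\t100\t0\t0\t1\t100\t1\t100\t1e-30\t200",
            "a\tc\t90\t100\t5\t0\t1\t100\t1\t100\t1e-20\t150",
            "d\tb\t80\t100\t9\t0\t1\t100\t1\t100\t1e-10\t100",
        ]
        p.write_text("\n".join(rows) + "\n")
        hits = read_blast_tabular(p)
        assert [(h.query, h.subject, h.rank) for h in hits] == [
            ("a", "b", 1), ("a", "c", 2), ("d", "b", 1)
        ]
        assert hits[0].evalue == 1e-30
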