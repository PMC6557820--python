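"""Contact potentials: counting conventions, scores, bootstrap, correlation."""

import numpy as np
import pytest

from tanglescan.gaussian import LoopRecord
from tanglescan.potentials import (
    PairCounts, PotentialMatrix, _TRIU, bootstrap_errors, correlation_analysis,
    count_contacts, count_ensemble, count_entangled_contacts, count_pairs,
    enrichment, potential,
)
from tanglescan.structure_io import AA_INDEX, ChainTrace
from tanglescan.synthetic import make_planted_sequence_ensemble


def labeled_trace(labels, positions=None, contact=None, contact_distance=4.2):
    """Trace with given labels; optionally one engineered side-chain contact."""
    n = len(labels)
    if positions is None:
        positions = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
    side = [positions[i:i + 1].copy() for i in range(n)]
    if contact is not None:
        a, b = contact
        side[b] = np.array([side[a][0] + [0.0, contact_distance, 0.0]])
    return ChainTrace("t", positions, list(labels),
                      [positions[i:i + 1] for i in range(n)], side)


def counts_from_vectors(pairs, contacts, entangled):
    def vec(d):
        v = np.zeros(210)
        slot = {tuple(sorted((a, b))): k for k, (a, b) in enumerate(zip(*_TRIU))}
        for (a, b), c in d.items():
            v[slot[tuple(sorted((AA_INDEX[a], AA_INDEX[b])))]] = c
        return v
    return PairCounts(
        per_protein_pairs=np.array([vec(pairs)]),
        per_protein_contacts=np.array([vec(contacts)]),
        per_protein_entangled=np.array([vec(entangled)]),
    )


class TestCounting:
    def test_generic_pairs_at_minimum_separation(self):
        trace = labeled_trace("A" * 12)
        assert count_pairs(trace).sum() == 3  # (0,10),(0,11),(1,11)

    def test_chain_too_short_for_pairs(self):
        assert count_pairs(labeled_trace("A" * 10)).sum() == 0

    def test_additivity_over_identical_chains(self):
        t = labeled_trace("ACDEFGHIKLMN")
        counts = count_ensemble([t, t], loop_records=[[], []])
        assert counts.N == 2 * count_pairs(t).sum()

    def test_unknown_labels_excluded(self):
        trace = labeled_trace(["X"] + ["A"] * 11)
        # pairs (0,10),(0,11) involve the unknown; only (1,11) counts
        assert count_pairs(trace).sum() == 1

    def test_engineered_sidechain_contact(self):
        trace = labeled_trace("A" * 11 + "C", contact=(0, 11),
                              contact_distance=4.2)
        vec = count_contacts(trace)
        assert vec.sum() == 1
        slot = np.flatnonzero(vec)[0]
        a, b = _TRIU[0][slot], _TRIU[1][slot]
        assert {a, b} == {AA_INDEX["A"], AA_INDEX["C"]}

    def test_contact_beyond_cutoff_not_counted(self):
        trace = labeled_trace("A" * 11 + "C", contact=(0, 11),
                              contact_distance=4.8)
        assert count_contacts(trace).sum() == 0

    def test_entangled_contacts_require_entangled_loop(self):
        trace = labeled_trace("P" + "A" * 10 + "G", contact=(0, 11))
        quiet = LoopRecord(i1=0, i2=11, g=0.4, j1=20, j2=35, side="C")
        loud = LoopRecord(i1=0, i2=11, g=1.4, j1=20, j2=35, side="C")
        assert count_entangled_contacts(trace, [quiet]).sum() == 0
        vec = count_entangled_contacts(trace, [loud])
        assert vec.sum() == 1


class TestScores:
    def test_equal_frequencies_give_zero(self):
        counts = counts_from_vectors(
            pairs={("A", "A"): 50, ("C", "C"): 50},
            contacts={("A", "A"): 5, ("C", "C"): 5},
            entangled={("A", "A"): 1, ("C", "C"): 1},
        )
        e = potential(counts, "norm")
        assert e.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_log_ratio_scale(self):
        # f(A,A) = 1/2 and f_c(A,A) = 1/(2e), so f_c/f = e^-1 -> E = +tau
        e = np.exp(1)
        counts = counts_from_vectors(
            pairs={("A", "A"): 100, ("C", "C"): 100},
            contacts={("A", "A"): 1.0, ("C", "C"): 2 * e - 1},
            entangled={},
        )
        val = potential(counts, "norm").values[0, 0]
        assert val == pytest.approx(100.0, rel=1e-6)

    def test_zero_count_entries_masked(self):
        counts = counts_from_vectors(
            pairs={("A", "A"): 10, ("C", "C"): 10, ("A", "C"): 10},
            contacts={("A", "A"): 2, ("C", "C"): 2},
            entangled={},
        )
        e = potential(counts, "norm")
        assert np.isnan(e.values[AA_INDEX["A"], AA_INDEX["C"]])
        assert e.defined[0, 0]

    def test_enrichment_identity(self, sequence_pool):
        pool, pool_loops = sequence_pool
        traces, loops = make_planted_sequence_ensemble(
            300, enrichment={("D", "K"): 2.0}, pool=pool,
            pool_loops=pool_loops, seed=6)
        counts = count_ensemble(traces, loop_records=loops, cutoff=6.0)
        delta = enrichment(counts).values
        diff = potential(counts, "ge").values - potential(counts, "norm").values
        both = np.isfinite(delta) & np.isfinite(diff)
        np.testing.assert_allclose(delta[both], diff[both], atol=1e-9)
        assert both.sum() > 50

    def test_matrices_symmetric(self, sequence_pool):
        pool, pool_loops = sequence_pool
        traces, loops = make_planted_sequence_ensemble(
            200, pool=pool, pool_loops=pool_loops, seed=7)
        counts = count_ensemble(traces, loop_records=loops, cutoff=6.0)
        for m in (potential(counts, "norm").values, enrichment(counts).values):
            np.testing.assert_array_equal(m, m.T)


class TestBootstrap:
    def test_identical_proteins_have_zero_stderr(self):
        vec_pairs = {("A", "A"): 100, ("C", "C"): 100, ("A", "C"): 40}
        vec_contacts = {("A", "A"): 10, ("C", "C"): 4, ("A", "C"): 4}
        one = counts_from_vectors(vec_pairs, vec_contacts, vec_contacts)
        many = PairCounts(
            per_protein_pairs=np.repeat(one.per_protein_pairs, 20, axis=0),
            per_protein_contacts=np.repeat(one.per_protein_contacts, 20, axis=0),
            per_protein_entangled=np.repeat(one.per_protein_entangled, 20, axis=0),
        )
        errs = bootstrap_errors(many, n_resamples=25, seed=0)
        assert np.nanmax(errs["norm"]) == pytest.approx(0.0, abs=1e-9)

    def test_stderr_shrinks_with_ensemble_size(self, sequence_pool):
        pool, pool_loops = sequence_pool
        traces, loops = make_planted_sequence_ensemble(
            800, pool=pool, pool_loops=pool_loops, seed=8)
        small = count_ensemble(traces[:400], loop_records=loops[:400], cutoff=6.0)
        large = count_ensemble(traces, loop_records=loops, cutoff=6.0)
        e_small = bootstrap_errors(small, n_resamples=40, seed=1)["norm"]
        e_large = bootstrap_errors(large, n_resamples=40, seed=1)["norm"]
        both = np.isfinite(e_small) & np.isfinite(e_large) & (e_small > 0)
        ratio = np.nanmedian(e_large[both] / e_small[both])
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.25)


class TestCorrelation:
    def test_recovers_planted_linear_relation(self):
        rng = np.random.default_rng(15)
        norm_vals = np.full((20, 20), np.nan)
        enr_vals = np.full((20, 20), np.nan)
        iu = np.triu_indices(20)
        x = rng.normal(0, 50, size=210)
        y = -0.12 * x + rng.normal(0, 3, size=210)
        norm_vals[iu] = x
        enr_vals[iu] = y
        rep = correlation_analysis(PotentialMatrix(enr_vals),
                                   PotentialMatrix(norm_vals))
        assert rep.slope == pytest.approx(-0.12, abs=0.02)
        assert rep.pearson_r < -0.8
        assert rep.n_pairs == 210

    def test_too_few_entries_rejected(self):
        m = np.full((20, 20), np.nan)
        m[0, 0] = 1.0
        with pytest.raises(ValueError):
            correlation_analysis(PotentialMatrix(m), PotentialMatrix(m))
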