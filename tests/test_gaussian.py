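"""Gauss double-sum scores: oracle equivalence, symmetries, topology."""

import numpy as np
import pytest

from tanglescan.gaussian import (
    build_kernel, compute_contacts, enumerate_loops,
    gauss_linking_closed, gauss_pair_score, best_thread, protein_entanglement,
    scan_loops,
)
from tanglescan.structure_io import ChainTrace
from tanglescan.synthetic import make_helix_wrap, make_linked_rings, make_random_backbone


def brute_force_gauss(points, loop, other):
    """Direct term-by-term evaluation of the discretized Gauss double sum,
    independent of the kernel/prefix-sum implementation."""
    (i1, i2), (j1, j2) = loop, other
    total = 0.0
    for i in range(i1, i2):
        for j in range(j1, j2):
            ri = 0.5 * (points[i] + points[i + 1])
            rj = 0.5 * (points[j] + points[j + 1])
            dri = points[i + 1] - points[i]
            drj = points[j + 1] - points[j]
            diff = ri - rj
            total += diff.dot(np.cross(dri, drj)) / np.linalg.norm(diff) ** 3
    return total / (4 * np.pi)


def ca_trace(points, trace_id="t"):
    points = np.asarray(points, dtype=float)
    n = len(points)
    return ChainTrace(trace_id, points, ["A"] * n,
                      [points[i:i + 1] for i in range(n)],
                      [points[i:i + 1] for i in range(n)])


def all_disjoint_range_pairs(n, min_bonds=1):
    for i1 in range(n - min_bonds):
        for i2 in range(i1 + min_bonds, n):
            for j1 in range(i2, n - min_bonds):
                for j2 in range(j1 + min_bonds, n):
                    yield (i1, i2), (j1, j2)


class TestGaussPairScore:
    def test_matches_brute_force_on_random_configuration(self):
        rng = np.random.default_rng(5)
        points = rng.normal(scale=5.0, size=(9, 3))
        score = gauss_pair_score(points, (0, 4), (5, 8))
        assert score == pytest.approx(brute_force_gauss(points, (0, 4), (5, 8)),
                                      abs=1e-12)

    def test_prefix_sums_match_direct_summation_exhaustively(self):
        rng = np.random.default_rng(11)
        points = rng.normal(scale=4.0, size=(10, 3))
        kernel = build_kernel(points)
        for loop, other in all_disjoint_range_pairs(10):
            direct = brute_force_gauss(points, loop, other)
            assert kernel.range_score(loop, other) == pytest.approx(
                direct, abs=1e-10)

    def test_overlapping_ranges_rejected(self):
        points = np.random.default_rng(0).normal(size=(12, 3))
        with pytest.raises(ValueError):
            gauss_pair_score(points, (0, 6), (4, 10))

    def test_unlinked_square_loops_score_near_zero(self):
        sq1 = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [0, 0, 1e-3]])
        sq2 = sq1 + np.array([50.0, 0.0, 0.0])
        points = np.vstack([sq1, sq2])
        assert abs(gauss_pair_score(points, (0, 4), (5, 9))) < 0.05

    def test_hopf_link_scores_near_unity(self):
        a, b = make_linked_rings(1, 64)
        g = gauss_linking_closed(a, b)
        assert g == pytest.approx(1.0, rel=0.02)
        assert gauss_linking_closed(a, b[::-1]) == pytest.approx(-g, abs=1e-12)


class TestKernel:
    def test_two_residue_kernel_is_single_zero(self):
        k = build_kernel(np.array([[0, 0, 0], [3.8, 0, 0]]))
        assert k.pair_contributions.shape == (1, 1)
        assert k.pair_contributions[0, 0] == 0.0

    def test_kernel_symmetric_with_zero_diagonal(self):
        pts = np.random.default_rng(2).normal(scale=4, size=(15, 3))
        k = build_kernel(pts).pair_contributions
        np.testing.assert_allclose(k, k.T, atol=1e-14)
        assert np.all(np.diag(k) == 0.0)

    def test_mirror_flips_kernel_sign(self):
        pts = np.random.default_rng(3).normal(scale=4, size=(12, 3))
        k = build_kernel(pts).pair_contributions
        km = build_kernel(pts * np.array([1.0, 1.0, -1.0])).pair_contributions
        np.testing.assert_allclose(km, -k, atol=1e-13)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=4, size=(14, 3))
        # random rotation via QR, with positive determinant
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = pts @ q.T + np.array([12.0, -7.0, 3.0])
        k1 = build_kernel(pts)
        k2 = build_kernel(moved)
        for loop, other in [((0, 5), (6, 13)), ((2, 7), (9, 12))]:
            assert k2.range_score(loop, other) == pytest.approx(
                k1.range_score(loop, other), abs=1e-9)


class TestContactsAndLoops:
    def test_cutoff_boundary(self):
        def two_residue_trace(d):
            pts = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                            [0.0, 3.8, 0.0], [0.0, 0.0, d]])
            return ca_trace(pts)
        assert (0, 4) in compute_contacts(two_residue_trace(4.4)).contacts
        assert (0, 4) not in compute_contacts(two_residue_trace(4.6)).contacts

    def test_loop_separation_threshold(self):
        from tanglescan.gaussian import ContactMap
        cmap = ContactMap(contacts=[(0, 9), (0, 10), (3, 20)],
                          mode="any_heavy", cutoff=4.5)
        assert enumerate_loops(cmap) == [(0, 10), (3, 20)]

    def test_sidechain_mode_falls_back_for_bare_residues(self):
        pts = np.array([[0, 0, 0], [3.8, 0, 0]])
        trace = ChainTrace("g", pts, ["G", "G"],
                           [pts[0:1], pts[1:2]],
                           [np.empty((0, 3)), np.empty((0, 3))])
        cmap = compute_contacts(trace, cutoff=4.5, mode="sidechain_heavy")
        assert cmap.contacts == [(0, 1)]


class TestBestThread:
    def test_helix_fixture_scores_side_and_sign(self):
        for turns, side in [(2, "N"), (-2, "N"), (1, "C")]:
            trace = make_helix_wrap(turns, side)
            recs = [r for r in scan_loops(trace) if r.entangled]
            assert len(recs) == 1
            rec = recs[0]
            assert rec.side == side
            assert np.sign(rec.g) == np.sign(turns)
            assert abs(rec.g) == pytest.approx(abs(turns), rel=0.10)

    def test_mirrored_fixture_flips_chirality_only(self):
        trace = make_helix_wrap(2, "N")
        rec = [r for r in scan_loops(trace) if r.entangled][0]
        mrec = [r for r in scan_loops(trace.mirrored()) if r.entangled][0]
        assert mrec.g == pytest.approx(-rec.g, abs=1e-9)
        assert mrec.side == rec.side

    def test_loop_with_no_admissible_thread_is_flagged(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(scale=4, size=(15, 3))
        kernel = build_kernel(pts)
        rec = best_thread(kernel, (0, 12), n=15)
        assert not rec.has_thread
        assert not rec.entangled


class TestProteinEntanglement:
    def test_straight_chain_has_no_loops(self):
        pts = np.column_stack([np.arange(20) * 3.8, np.zeros(20), np.zeros(20)])
        res = protein_entanglement(ca_trace(pts))
        assert res.empty
        assert res.protein_ge == 0.0

    def test_linking_bounded_by_gaussian_entanglement(self, tight_backbones):
        for trace in tight_backbones[:15]:
            res = protein_entanglement(trace)
            assert abs(res.protein_le) <= abs(res.protein_ge) + 1e-12

    def test_whole_chain_reversal_preserves_scores(self):
        trace = make_helix_wrap(2, "N")
        res = protein_entanglement(trace)
        res_rev = protein_entanglement(trace.reversed())
        assert res_rev.protein_ge == pytest.approx(res.protein_ge, abs=1e-9)
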