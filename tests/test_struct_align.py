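"""Secondary-structure detection, rigid fitting and Qscore alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from strucphy import fixtures as fx
from strucphy.struct_align import (
    AlignParams,
    Status,
    Superposition,
    align_structures,
    assign_sse,
    kabsch,
    qscore,
    refine_alignment,
    seed_transforms,
    self_check,
)


def brute_force_min_rmsd(P, Q, n_starts=12):
    """Independent rigid-fit oracle: numeric minimisation over rotation
    vectors (optimal translation aligns centroids for any rotation)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def objective(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt((((Qc @ R.T) - Pc) ** 2).sum() / len(P))

    rng = np.random.default_rng(0)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestAssignSSE:
    def test_ideal_helix_single_element(self):
        sses = assign_sse(fx.make_ideal_sse("helix", 30))
        assert [s.kind for s in sses] == ["helix"]
        assert sses[0].n_res >= 24

    def test_ideal_strand_single_element(self):
        sses = assign_sse(fx.make_ideal_sse("strand", 12))
        assert [s.kind for s in sses] == ["strand"]

    def test_coil_yields_nothing(self, coil60):
        assert assign_sse(coil60) == []

    def test_short_chain_yields_nothing(self):
        assert assign_sse(fx.make_ideal_sse("helix", 4)) == []

    def test_elements_sorted_and_disjoint(self, histone_like):
        sses = assign_sse(histone_like)
        assert len(sses) >= 2
        for a, b in zip(sses, sses[1:]):
            assert a.end < b.start

    def test_axis_direction_is_unit_and_along_helix(self):
        sses = assign_sse(fx.make_ideal_sse("helix", 30))
        d = sses[0].axis_direction
        assert abs(np.linalg.norm(d) - 1.0) < 1e-9
        assert abs(d @ np.array([0.0, 0.0, 1.0])) > 0.99  # ideal helix runs along z


class TestKabsch:
    def test_identical_sets_give_identity(self):
        P = np.random.default_rng(1).normal(size=(10, 3))
        sup = kabsch(P, P)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(sup.translation, 0.0, atol=1e-12)
        assert sup.rmsd < 1e-12

    def test_recovers_known_rigid_transform(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        Q = (P - t) @ R  # so that R @ q + t == p
        sup = kabsch(P, Q)
        assert sup.rmsd < 1e-9
        np.testing.assert_allclose(sup.apply(Q), P, atol=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        # near-planar mirror-prone configuration
        P = rng.normal(size=(6, 3)) * np.array([1, 1, 0.01])
        Q = rng.normal(size=(6, 3))
        sup = kabsch(P, Q)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-9

    @pytest.mark.parametrize("n,noise,seed", [(5, 0.5, 10), (8, 1.0, 11), (12, 0.2, 12)])
    def test_matches_brute_force_oracle(self, n, noise, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(n, 3)) * 5
        R = Rotation.random(random_state=seed).as_matrix()
        Q = (P @ R) + rng.normal(scale=noise, size=(n, 3))
        sup = kabsch(P, Q)
        assert abs(sup.rmsd - brute_force_min_rmsd(P, Q)) < 1e-6


class TestQscore:
    @pytest.mark.parametrize("n", [10, 45, 200])
    def test_identical_structures_score_one(self, n):
        assert qscore(n, 0.0, n, n) == 1.0

    def test_rmsd_equal_r0_halves_score(self):
        assert qscore(80, 3.0, 80, 80, r0=3.0) == pytest.approx(0.5)

    def test_partial_alignment_example(self):
        assert qscore(50, 3.0, 100, 100, r0=3.0) == pytest.approx(0.125)

    def test_zero_aligned_gives_zero(self):
        assert qscore(0, 0.0, 50, 60) == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            qscore(60, 1.0, 50, 50)
        with pytest.raises(ValueError):
            qscore(10, -1.0, 50, 50)
        with pytest.raises(ValueError):
            qscore(10, 1.0, 50, 50, r0=0.0)

    @given(
        n_aligned=st.integers(1, 100),
        rmsd=st.floats(0.0, 20.0),
        extra=st.integers(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, n_aligned, rmsd, extra):
        n = n_aligned + extra
        q = qscore(n_aligned, rmsd, n, n)
        assert 0.0 <= q <= 1.0
        # decreasing in rmsd
        assert q >= qscore(n_aligned, rmsd + 1.0, n, n)
        # increasing in n_aligned
        if n_aligned + 1 <= n:
            assert qscore(n_aligned + 1, rmsd, n, n) >= q


class TestSeeding:
    def test_self_pairing_contains_identity_seed(self, two_helix):
        sses = assign_sse(two_helix)
        seeds = seed_transforms(sses, sses, two_helix.ca_coords, two_helix.ca_coords)
        best = min(
            np.linalg.norm(s.rotation - np.eye(3)) + np.linalg.norm(s.translation)
            for s in seeds
        )
        assert best < 1e-6

    def test_kind_mismatch_falls_back_to_sliding_window(self):
        helix = fx.synth_chain(fx.ChainSpec(segments=[("helix", 60)], seed=2, entry_id="hx"))
        strand = fx.synth_chain(fx.ChainSpec(segments=[("strand", 8), ("coil", 3)] * 5, seed=5, entry_id="sh"))
        sA, sB = assign_sse(helix), assign_sse(strand)
        # no same-kind SSE pairs exist, yet seeds are still proposed
        assert all(s.kind == "helix" for s in sA)
        assert all(s.kind == "strand" for s in sB)
        seeds = seed_transforms(sA, sB, helix.ca_coords, strand.ca_coords)
        assert len(seeds) > 0

    def test_best_seed_recovers_known_transform(self, two_helix):
        R = Rotation.from_euler("zyx", [30, 50, 10], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 6.0])
        moved = two_helix.ca_coords @ R.T + t
        sses = assign_sse(two_helix)
        seeds = seed_transforms(assign_sse(moved), sses, moved, two_helix.ca_coords)
        endpoint_rmsds = []
        for s in seeds[:10]:
            diff = s.apply(two_helix.ca_coords) - moved
            endpoint_rmsds.append(np.sqrt((diff**2).sum() / len(moved)))
        assert min(endpoint_rmsds) < 0.5


class TestRefineAndAlign:
    def test_exact_copy_full_diagonal(self, two_helix):
        c = two_helix.ca_coords
        res = refine_alignment(c, c, Superposition.identity())
        assert res.status is Status.OK
        assert res.correspondence == [(i, i) for i in range(len(c))]
        assert res.qscore == pytest.approx(1.0)

    def test_noisy_copy_high_qscore(self, two_helix):
        pert = fx.perturb_chain(two_helix, 0.3, seed=5)
        res = refine_alignment(two_helix.ca_coords, pert.ca_coords, Superposition.identity())
        assert res.status is Status.OK
        assert res.qscore > 0.9
        assert res.n_aligned == res.n1 == res.n2

    def test_self_alignment_scores_exactly_one(self, two_helix):
        res = align_structures(two_helix, two_helix)
        assert res.status is Status.OK
        assert res.qscore == 1.0
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_aligned == two_helix.n_resolved

    def test_rigid_copy_recovered(self, two_helix):
        R = Rotation.from_euler("zyx", [40, 20, 70], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved = two_helix.with_coords(two_helix.ca_coords @ R.T + t)
        moved.entry_id = "move"
        res = align_structures(two_helix, moved)
        assert res.qscore > 0.99
        back = res.transform.apply(moved.ca_coords)
        coord_rmsd = np.sqrt(((back - two_helix.ca_coords) ** 2).sum() / len(back))
        assert coord_rmsd < 1e-3

    def test_helix_versus_coil_is_no_similarity(self, coil60):
        helix = fx.synth_chain(fx.ChainSpec(segments=[("helix", 60)], seed=2, entry_id="hx60"))
        res = align_structures(helix, coil60)
        assert res.status is Status.NO_SIMILARITY
        assert res.qscore == -1.0

    def test_symmetry_is_exact(self, two_helix, histone_like):
        r1 = align_structures(two_helix, histone_like)
        r2 = align_structures(histone_like, two_helix)
        assert r1.qscore == r2.qscore
        assert r1.n_aligned == r2.n_aligned
        assert r1.correspondence == [(j, i) for i, j in r2.correspondence]

    def test_correspondence_strictly_increasing(self, two_helix, histone_like):
        res = align_structures(two_helix, histone_like)
        assert res.status is Status.OK
        pairs = res.correspondence
        assert all(a1 < a2 and b1 < b2 for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]))
        assert res.n_aligned <= min(res.n1, res.n2)

    def test_degenerate_chain_is_no_similarity(self, two_helix):
        import numpy as np
        from strucphy.structure_io import ChainRecord

        stub = ChainRecord("stub", "A", "AC", "AC", np.zeros((2, 3)))
        res = align_structures(stub, two_helix)
        assert res.status is Status.NO_SIMILARITY


class TestSelfCheck:
    def test_two_helix_passes(self, two_helix):
        assert self_check(two_helix)

    def test_coil_fails(self, coil60):
        assert not self_check(coil60)

    def test_short_stub_fails(self):
        import numpy as np
        from strucphy.structure_io import ChainRecord

        stub = ChainRecord("stub", "A", "ACDE", "ACDE", np.arange(12, dtype=float).reshape(4, 3))
        assert not self_check(stub)
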