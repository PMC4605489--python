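"""Non-metric MDS, Procrustes superimposition, and bootstrap clouds."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phenostruct.ordination import (
    bootstrap_mds,
    nmds,
    procrustes_superimpose,
)
from phenostruct.rmatrix import FstConfig


def planar_distance_matrix(seed, n=6):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2)) * 2
    return squareform(pdist(X)), X


class TestNmds:
    def test_collinear_points_embed_with_zero_stress(self):
        D = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        conf = nmds(D, seed=0)
        assert conf.stress == pytest.approx(0.0, abs=1e-8)

    def test_planar_points_recovered_with_negligible_stress(self):
        D, _ = planar_distance_matrix(4)
        conf = nmds(D, seed=0)
        assert conf.stress <= 1e-6
        assert conf.coords.shape == (6, 2)
        assert np.isfinite(conf.coords).all()

    def test_stress_history_is_monotone_non_increasing(self):
        rng = np.random.default_rng(7)
        D = squareform(rng.uniform(1, 4, size=45))   # generic 10-point matrix
        conf = nmds(D, seed=3, n_restarts=1)
        assert (np.diff(conf.stress_history) <= 1e-12).all()
        assert 0.0 <= conf.stress <= 1.0

    def test_label_permutation_permutes_coordinates(self):
        D, _ = planar_distance_matrix(11)
        perm = np.array([3, 0, 5, 2, 4, 1])
        a = nmds(D, seed=0, n_restarts=1)
        b = nmds(D[np.ix_(perm, perm)], seed=0, n_restarts=1)
        assert np.allclose(b.coords, a.coords[perm], atol=1e-6)

    def test_matches_reference_smacof_stress(self):
        # independent oracle: sklearn's non-metric SMACOF on the same matrix
        from sklearn.manifold import smacof

        rng = np.random.default_rng(13)
        D = squareform(rng.uniform(1, 3, size=28))   # 8 points, not planar
        ours = nmds(D, seed=0, n_restarts=8)
        _, theirs = smacof(D, metric=False, n_components=2, n_init=8,
                           random_state=0, normalized_stress=True)
        assert ours.stress <= theirs * 1.1 + 1e-6

    def test_invalid_matrices_are_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]) + np.zeros((2, 2)))
        bad = np.array([[0.0, -1.0, 1], [-1.0, 0.0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nmds(bad)
        asym = np.array([[0.0, 1.0, 2], [1.5, 0.0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            nmds(asym)


class TestProcrustes:
    def test_identity_when_target_equals_reference(self):
        _, X = planar_distance_matrix(2)
        fit = procrustes_superimpose(X, X)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(2), atol=1e-10)
        assert fit.scale == pytest.approx(1.0)

    def test_rotated_translated_copy_matches_exactly(self):
        _, X = planar_distance_matrix(5)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        fit = procrustes_superimpose(X, X @ R + [3.0, -2.0])
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.coords, X, atol=1e-10)

    def test_hand_solved_quarter_turn_with_scaling(self):
        ref = np.array([[0.0, 0.0], [1.0, 0.0]])
        tgt = np.array([[0.0, 0.0], [0.0, 2.0]])
        fit = procrustes_superimpose(ref, tgt)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.scale == pytest.approx(0.5)
        assert np.allclose(np.abs(fit.rotation), [[0, 1], [1, 0]], atol=1e-12)

    def test_statistic_invariant_to_common_rigid_motion(self):
        rng = np.random.default_rng(8)
        A, B = rng.standard_normal((2, 7, 2))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s0 = procrustes_superimpose(A, B).statistic
        s1 = procrustes_superimpose(A @ R + 5.0, B @ R + 5.0).statistic
        assert s1 == pytest.approx(s0, rel=1e-10)

    def test_agrees_with_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(15)
        A, B = rng.standard_normal((2, 9, 2))
        _, _, disparity = scipy_procrustes(A, B)
        fit = procrustes_superimpose(A, B)
        assert fit.statistic == pytest.approx(disparity, rel=1e-10)

    def test_reflection_can_be_forbidden(self):
        _, X = planar_distance_matrix(6)
        mirrored = X * [-1.0, 1.0]
        free = procrustes_superimpose(X, mirrored)
        rigid = procrustes_superimpose(X, mirrored, allow_reflection=False)
        assert free.statistic == pytest.approx(0.0, abs=1e-12)
        assert rigid.statistic > 1e-3
        assert np.linalg.det(rigid.rotation) == pytest.approx(1.0)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            procrustes_superimpose(np.zeros((3, 2)), np.zeros((4, 2)))


class TestBootstrap:
    def test_identical_individuals_give_identical_replicates(self):
        # resampling identical rows is a no-op: every replicate configuration
        # superimposes on the original with statistic 0
        groups = {g: np.tile(mu, (8, 1))
                  for g, mu in [("a", [1.0, 2.0]), ("b", [4.0, 2.0]),
                                ("c", [2.5, 6.0]), ("d", [0.0, 5.0])]}

        def mean_distance(gs):
            M = np.vstack([x.mean(axis=0) for x in gs.values()])
            return squareform(pdist(M))

        original, reps, dropped = bootstrap_mds(groups, reps=100, seed=1,
                                                distance=mean_distance)
        assert dropped == 0 and len(reps) == 100
        for rep in reps:
            fit = procrustes_superimpose(original.coords, rep.coords)
            assert fit.statistic == pytest.approx(0.0, abs=1e-10)

    def test_zero_reps_returns_original_only(self, small_panel):
        table, _ = small_panel
        groups = {s: table.series_values(s) for s in table.series_labels()}
        original, reps, dropped = bootstrap_mds(groups, reps=0, seed=0,
                                                fst_config=FstConfig(h2=0.55))
        assert reps == [] and dropped == 0
        assert original.coords.shape == (4, 2)

    def test_well_separated_groups_have_disjoint_clouds(self):
        # four groups at the corners of a large square: every bootstrap
        # point stays nearest its own group's original position
        rng = np.random.default_rng(3)
        corners = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0], [30.0, 30.0]])
        groups = {f"g{i}": 100 + corners[i] + rng.standard_normal((40, 2))
                  for i in range(4)}
        original, reps, _ = bootstrap_mds(groups, reps=20, seed=5,
                                          fst_config=FstConfig(h2=1.0))
        for rep in reps:
            for i in range(4):
                dists = np.linalg.norm(original.coords - rep.coords[i], axis=1)
                assert np.argmin(dists) == i

    def test_fewer_than_three_series_is_an_error(self):
        with pytest.raises(ValueError):
            bootstrap_mds({"a": np.ones((3, 2)), "b": np.ones((3, 2))})
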