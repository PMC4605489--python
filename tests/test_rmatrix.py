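"""R-matrix Fst estimation: oracles, invariances, and standard errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenostruct.rmatrix import (
    FstConfig,
    codivergence,
    estimate_fst,
    fst_from_codivergence,
    fst_standard_error,
    pairwise_fst,
    pooled_within_covariance,
)

OFF = FstConfig(h2=1.0, bias_correction=False)


def random_groups(seed, k=4, n=30, t=5, spread=1.0):
    rng = np.random.default_rng(seed)
    mu = rng.standard_normal((k, t)) * spread + 100.0
    return {f"g{i}": mu[i] + rng.standard_normal((n, t)) for i in range(k)}


class TestPooledCovariance:
    def test_hand_pooled_two_groups(self):
        groups = {"A": np.array([[0.0, 0.0], [2.0, 2.0]]),
                  "B": np.array([[1.0, 0.0], [1.0, 2.0]])}
        W = pooled_within_covariance(groups)
        assert np.allclose(W.matrix, [[1.0, 1.0], [1.0, 2.0]])
        assert W.dof == 2

    def test_identical_group_covariances_pool_to_themselves(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 3))
        S = np.cov(x, rowvar=False)
        W = pooled_within_covariance({"A": x, "B": x.copy()})
        assert np.allclose(W.matrix, S)

    def test_single_group_pools_to_its_sample_covariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 2))
        W = pooled_within_covariance({"A": x})
        assert np.allclose(W.matrix, np.cov(x, rowvar=False))

    def test_undersized_group_is_an_error(self):
        with pytest.raises(ValueError, match="B"):
            pooled_within_covariance({"A": np.zeros((3, 2)) + [[1, 2]],
                                      "B": np.ones((1, 2))})


class TestCodivergence:
    def test_equal_means_give_zero_matrix(self):
        means = np.tile([3.0, 4.0], (3, 1))
        c, w = codivergence(means, np.eye(2), [10, 10, 10], OFF)
        assert np.allclose(c, 0.0)
        assert w.sum() == pytest.approx(1.0)

    def test_single_trait_two_group_hand_arithmetic(self):
        c, _ = codivergence([[0.0], [2.0]], [[1.0]], [10, 10], OFF)
        assert np.allclose(c, [[1.0, -1.0], [-1.0, 1.0]])

    def test_matrix_formula_matches_whitened_trait_accumulation(self):
        # brute force: rotate into the basis where G is the identity and
        # accumulate the outer products trait by trait
        rng = np.random.default_rng(5)
        means = rng.standard_normal((4, 3)) * 2
        A = rng.standard_normal((3, 6))
        W = A @ A.T / 6
        n = np.array([12, 20, 9, 15])
        cfg = FstConfig(h2=0.7, bias_correction=False)
        c, w = codivergence(means, W, n, cfg)
        L = np.linalg.cholesky(cfg.h2 * W)
        dev = means - w @ means
        y = np.linalg.solve(L, dev.T).T          # whitened deviations
        brute = np.zeros((4, 4))
        for k in range(3):
            brute += np.outer(y[:, k], y[:, k])
        assert np.allclose(c, brute / 3, atol=1e-12)

    def test_singular_pooled_covariance_raises_helpful_error(self):
        W = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            codivergence([[0.0, 0], [1, 1]], W, [5, 5], OFF)


class TestFst:
    def test_closed_form_single_trait_oracle(self):
        # mean gap d, unit pooled variance, h2=1, equal n: Fst = d²/(8+d²)
        for d in (0.5, 1.0, 2.0, 3.0):
            c, w = codivergence([[0.0], [d]], [[1.0]], [10, 10], OFF)
            res = fst_from_codivergence(c, w, config=OFF)
            assert res.fst == pytest.approx(d * d / (8 + d * d), abs=1e-14)
        assert 2 * 2 / (8 + 2 * 2) == pytest.approx(1 / 3)   # d = 2

    def test_zero_codivergence_gives_zero_fst(self):
        res = fst_from_codivergence(np.zeros((3, 3)), np.full(3, 1 / 3),
                                    config=OFF)
        assert res.fst == 0.0
        assert np.allclose(res.r, 0.0)

    def test_r_matrix_relation_holds_elementwise(self):
        groups = random_groups(2)
        res = estimate_fst(groups, config=OFF, with_se=False)
        assert np.allclose(res.r, res.c * (1 - res.fst) / 2, atol=1e-14)
        assert 0 <= res.fst < 1

    def test_agrees_with_fixed_point_iteration(self):
        groups = random_groups(8, spread=2.0)
        res = estimate_fst(groups, config=OFF, with_se=False)
        cbar = float(res.weights @ np.diag(res.c))
        f = 0.5
        for _ in range(2000):   # damped iteration of f = cbar (1 - f) / 2
            f = 0.7 * f + 0.3 * cbar * (1 - f) / 2
        assert res.fst == pytest.approx(f, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_under_per_variable_rescaling(self, seed):
        groups = random_groups(seed, k=3, n=20, t=4)
        rng = np.random.default_rng(seed + 1)
        a = rng.uniform(0.2, 5.0, size=4)
        b = rng.uniform(-3.0, 3.0, size=4)
        for cfg in (OFF, FstConfig(h2=0.55, bias_correction=True)):
            f0 = estimate_fst(groups, config=cfg, with_se=False).fst
            f1 = estimate_fst({g: x * a + b for g, x in groups.items()},
                              config=cfg, with_se=False).fst
            assert f1 == pytest.approx(f0, rel=1e-10, abs=1e-12)

    def test_inflating_mean_deviations_increases_fst(self):
        groups = random_groups(3)
        W = pooled_within_covariance(groups).matrix
        means = np.vstack([x.mean(axis=0) for x in groups.values()])
        n = np.array([len(x) for x in groups.values()])
        last = -1.0
        for lam in (1.0, 1.5, 2.0, 4.0):
            w = n / n.sum()
            center = w @ means
            c, w = codivergence(center + lam * (means - center), W, n, OFF)
            fst = fst_from_codivergence(c, w, config=OFF).fst
            assert fst > last
            last = fst

    def test_fst_non_increasing_in_heritability(self):
        groups = random_groups(4)
        fsts = [estimate_fst(groups,
                             config=FstConfig(h2=h2, bias_correction=False),
                             with_se=False).fst
                for h2 in (0.2, 0.4, 0.55, 0.8, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(fsts, fsts[1:]))

    def test_negative_diagonal_handling_modes(self):
        # two groups with equal means and tiny n: the corrected diagonal
        # goes negative; truncate_zero floors Fst at 0, keep lets it go below
        rng = np.random.default_rng(0)
        base = rng.standard_normal((40, 3))
        groups = {"A": base[:20] + 100, "B": base[20:] + 100}
        trunc = estimate_fst(groups, config=FstConfig(h2=0.55), with_se=False)
        keep = estimate_fst(
            groups, config=FstConfig(h2=0.55, negative_diagonal="keep"),
            with_se=False)
        assert trunc.fst >= 0.0
        assert keep.fst <= trunc.fst


class TestStandardError:
    def test_near_duplicate_traits_have_near_zero_se(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(3)[:, None] * 3
        means = 100 + base + rng.standard_normal((3, 4)) * 1e-4
        W = np.eye(4) + 1e-3 * rng.standard_normal((4, 4))
        W = (W + W.T) / 2
        se = fst_standard_error(means, W, np.array([20, 20, 20]), OFF)
        assert se < 1e-3

    def test_se_shrinks_with_trait_count(self):
        # traits are independent replicates of the same divergence process,
        # so the jackknife SE should fall roughly as 1/sqrt(t)
        def se_at(t, seed):
            rng = np.random.default_rng(seed)
            means = 100 + rng.standard_normal((5, t))
            return fst_standard_error(means, np.eye(t),
                                      np.full(5, 50), OFF)

        small = np.mean([se_at(5, s) for s in range(8)])
        large = np.mean([se_at(45, s) for s in range(8)])
        assert large < small / 2

    def test_single_trait_is_an_error(self):
        with pytest.raises(ValueError):
            fst_standard_error(np.array([[0.0], [1.0]]), [[1.0]],
                               np.array([5, 5]), OFF)


class TestPairwise:
    def test_identical_mean_series_have_zero_distance(self):
        rng = np.random.default_rng(9)
        noise = rng.standard_normal((3 * 40, 2))
        groups = {f"g{i}": 100 + noise[i * 40:(i + 1) * 40] -
                  noise[i * 40:(i + 1) * 40].mean(axis=0) for i in range(3)}
        D, labels = pairwise_fst(groups, config=OFF)
        assert np.allclose(D, 0.0, atol=1e-12)

    def test_symmetric_with_zero_diagonal(self):
        groups = random_groups(12, k=5)
        D, labels = pairwise_fst(groups, config=FstConfig(h2=0.55))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all()
        assert labels == list(groups)

    def test_outlier_series_dominates_distances(self):
        # one series displaced far from a tight cluster: its pairwise Fst
        # to every other series exceeds every within-cluster value
        rng = np.random.default_rng(21)
        groups = {f"g{i}": 100 + rng.standard_normal((30, 3)) * 1.0
                  for i in range(4)}
        groups["outlier"] = 112 + rng.standard_normal((30, 3))
        D, labels = pairwise_fst(groups, config=FstConfig(h2=0.55))
        k = labels.index("outlier")
        others = [i for i in range(5) if i != k]
        min_outlier = min(D[k, i] for i in others)
        max_inner = max(D[i, j] for i in others for j in others if i < j)
        assert min_outlier > max_inner


def test_synthetic_recovery_spot_check():
    """Closed-loop: the corrected estimator recovers a known apportionment."""
    from phenostruct.synthetic import SyntheticConfig, simulate_dataset

    ests = []
    for rep in range(30):
        table, _ = simulate_dataset(
            SyntheticConfig(k=10, n=60, t=12, fst=0.15, h2=0.55, seed=500 + rep))
        groups = {s: table.series_values(s) for s in table.series_labels()}
        ests.append(estimate_fst(groups, config=FstConfig(h2=0.55),
                                 with_se=False).fst)
    assert np.mean(ests) == pytest.approx(0.15, abs=0.02)
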