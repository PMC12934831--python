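import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.random_projection import johnson_lindenstrauss_min_dim

import socialpose as sp


class TestZScore:
    def test_hand_computed_population_zscore(self):
        train = np.array([[1.0], [2.0], [3.0]])
        tr_std, std = sp.zscore_fit_apply(train)
        assert np.allclose(tr_std.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        train = np.column_stack([np.arange(4.0), np.full(4, 7.0)])
        tr_std, other, std = sp.zscore_fit_apply(train, train + 1)
        assert np.allclose(tr_std[:, 1], 0.0)
        assert np.allclose(other[:, 1], 0.0)

    def test_stored_map_is_idempotent_on_train(self):
        rng = np.random.default_rng(0)
        train = rng.normal(2, 3, size=(20, 4))
        tr_std, std = sp.zscore_fit_apply(train)
        assert np.allclose(std.transform(train), tr_std)
        assert np.allclose(tr_std.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(tr_std.std(axis=0), 1, atol=1e-12)

    def test_train_statistics_applied_to_others(self):
        train = np.array([[0.0], [2.0]])
        _, other, _ = sp.zscore_fit_apply(train, np.array([[4.0]]))
        assert np.allclose(other, [[3.0]])  # (4-1)/1


class TestGridsAndProjection:
    def test_alpha_grid_endpoints_spacing_and_midpoint(self):
        g = sp.alpha_grid(21)
        assert g[0] == pytest.approx(1e-10) and g[-1] == pytest.approx(1e10)
        assert np.any(np.isclose(g, 1.0))
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, ratios[0])
        with pytest.raises(ValueError):
            sp.alpha_grid(1)

    @pytest.mark.parametrize("n,eps,expected", [
        (250, 0.1, 4732),
        (2, 0.5, 33),
    ])
    def test_jl_min_dim_closed_form(self, n, eps, expected):
        assert sp.jl_min_dim(n, eps) == expected

    def test_jl_min_dim_matches_reference_and_is_monotone(self):
        for n in (10, 50, 250, 1000):
            for eps in (0.05, 0.1, 0.3):
                assert sp.jl_min_dim(n, eps) == int(
                    johnson_lindenstrauss_min_dim(n, eps=eps))
        assert sp.jl_min_dim(100, 0.2) < sp.jl_min_dim(100, 0.1)
        with pytest.raises(ValueError):
            sp.jl_min_dim(100, 1.5)

    def test_srp_noop_below_target_and_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 50))
        assert sp.sparse_random_projection(X, 100, seed=0) is X
        wide = rng.normal(size=(10, 500))
        a = sp.sparse_random_projection(wide, 40, seed=3)
        b = sp.sparse_random_projection(wide, 40, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (10, 40)

    def test_srp_preserves_pairwise_distances_at_jl_dim(self):
        rng = np.random.default_rng(2)
        eps = 0.3
        X = rng.normal(size=(50, 10000))
        k = sp.jl_min_dim(50, eps)
        P = sp.sparse_random_projection(X, k, seed=7)
        diffs = X[:, None, :] - X[None, :, :]
        d_orig = np.einsum("ijk,ijk->ij", diffs, diffs)
        pdiffs = P[:, None, :] - P[None, :, :]
        d_proj = np.einsum("ijk,ijk->ij", pdiffs, pdiffs)
        iu = np.triu_indices(50, k=1)
        ratio = d_proj[iu] / d_orig[iu]
        assert np.all(ratio > 1 - eps) and np.all(ratio < 1 + eps)


class TestRidgeSolve:
    def test_orthonormal_design_alpha_zero_is_ols(self):
        Q, _ = np.linalg.qr(np.random.default_rng(3).normal(size=(20, 5)))
        y = np.random.default_rng(4).normal(size=20)
        w = sp.ridge_solve(Q, y, 0.0)
        assert np.allclose(w, Q.T @ y, atol=1e-10)

    def test_weights_vanish_as_alpha_grows(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(30, 6)), rng.normal(size=30)
        norms = [np.linalg.norm(sp.ridge_solve(X, y, a))
                 for a in (1e-2, 1e2, 1e6, 1e10)]
        assert np.all(np.diff(norms) < 0) and norms[-1] < 1e-8

    def test_matches_direct_objective_minimization(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(20, 5)), rng.normal(size=20)
        alpha = 1.0
        w = sp.ridge_solve(X, y, alpha)

        def obj(v):
            r = y - X @ v
            return r @ r + alpha * v @ v

        def grad(v):
            return 2 * (X.T @ (X @ v - y) + alpha * v)

        opt = minimize(obj, np.zeros(5), jac=grad, method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(w, opt.x, atol=1e-8)

    def test_normal_equations_satisfied(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(25, 8))
            y = rng.normal(size=25)
            alpha = float(10 ** rng.uniform(-4, 4))
            w = sp.ridge_solve(X, y, alpha)
            resid = X.T @ (X @ w - y) + alpha * w
            assert np.max(np.abs(resid)) < 1e-8

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sp.ridge_solve(np.full((3, 2), np.nan), np.zeros(3), 1.0)


class TestPearson:
    def test_exact_values(self):
        assert sp.pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert sp.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_sum_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 40))
        n = len(a)
        num = n * (a * b).sum() - a.sum() * b.sum()
        den = np.sqrt(n * (a ** 2).sum() - a.sum() ** 2) * \
            np.sqrt(n * (b ** 2).sum() - b.sum() ** 2)
        assert sp.pearson_r(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert sp.pearson_r([1, 1, 1], [1, 2, 3]) == 0.0


class TestCVSelect:
    def test_signal_candidate_beats_noise(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=60)
        cands = {"signal": y[:, None] + rng.normal(0, 0.1, (60, 1)),
                 "noise": rng.normal(size=(60, 1))}
        name, alpha, table = sp.cv_select(cands, y, seed=0)
        assert name == "signal"
        assert alpha in sp.alpha_grid()
        assert set(table["candidate"]) == {"noise", "signal"}

    def test_duplicate_candidates_break_ties_lexicographically(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=40)
        X = y[:, None]
        name, alpha, _ = sp.cv_select({"b": X, "a": X.copy()}, y, seed=1)
        assert name == "a"

    def test_informative_layer_selected_consistently(self):
        # at SNR 2 the informative layer should win nearly always
        rng = np.random.default_rng(11)
        wins = 0
        for rep in range(100):
            z = rng.normal(size=80)
            y = z + rng.normal(0, 0.5, size=80)
            cands = {"informative": np.column_stack(
                         [z, rng.normal(size=(80, 2))]),
                     "noise": rng.normal(size=(80, 3))}
            name, _, _ = sp.cv_select(cands, y, seed=rep)
            wins += name == "informative"
        assert wins >= 95

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            sp.cv_select({"x": np.zeros((3, 1))}, np.zeros(3), folds=5)


class TestFitEvaluate:
    def test_perfect_linear_relation_gives_r_one(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 4))
        w = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ w
        r = sp.fit_evaluate(X[:60], y[:60], X[60:], y[60:], 1e-10)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_target_scores_near_zero_on_average(self):
        rng = np.random.default_rng(13)
        rs = []
        for _ in range(60):
            X = rng.normal(size=(100, 5))
            y = rng.normal(size=100)
            rs.append(sp.fit_evaluate(X[:53], y[:53], X[53:], y[53:], 1.0))
        assert abs(np.mean(rs)) < 0.06

    def test_invariant_to_affine_rescaling_of_target(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(70, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.5, 70)
        r1 = sp.fit_evaluate(X[:50], y[:50], X[50:], y[50:], 1.0)
        y2 = 3.5 * y + 11.0
        r2 = sp.fit_evaluate(X[:50], y2[:50], X[50:], y2[50:], 1.0)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_r_approaches_analytic_noise_ceiling(self):
        # y = w.F + e; the best attainable r is sqrt(var_sig / var_total)
        rng = np.random.default_rng(15)
        rs, ceilings = [], []
        for _ in range(50):
            F = rng.normal(size=(250, 12))
            w = rng.normal(size=12)
            signal = F @ w
            noise_sd = 0.5 * np.std(signal)
            y = signal + rng.normal(0, noise_sd, 250)
            ceilings.append(np.sqrt(signal.var()
                                    / (signal.var() + noise_sd ** 2)))
            rs.append(sp.fit_evaluate(F[:200], y[:200], F[200:], y[200:],
                                      1e-6))
        assert np.mean(rs) == pytest.approx(np.mean(ceilings), abs=0.05)


class TestGroupedRidge:
    def _data(self, seed=16, n=100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.3, n)
        split = int(0.8 * n)
        return X, y, split

    def test_separable_case_weights_signal_group(self):
        rng = np.random.default_rng(17)
        n = 100
        y = rng.normal(size=n)
        A = y[:, None] + rng.normal(0, 0.01, (n, 1))
        B = rng.normal(size=(n, 5))
        res = sp.grouped_ridge_search(
            {"sig": A[:80], "noise": B[:80]},
            {"sig": A[80:], "noise": B[80:]},
            y[:80], y[80:], n_gamma=60, seed=0)
        assert res.gamma["sig"] > 0.5
        assert res.test_r > 0.99

    def test_duplicated_groups_match_plain_ridge(self):
        X, y, s = self._data()
        res = sp.grouped_ridge_search(
            {"a": X[:s], "b": X[:s].copy()},
            {"a": X[s:], "b": X[s:].copy()},
            y[:s], y[s:], n_gamma=40, seed=1)
        plain = sp.fit_evaluate(X[:s], y[:s], X[s:], y[s:], res.alpha)
        assert res.test_r == pytest.approx(plain, abs=1e-6)

    def test_complementary_groups_are_superadditive(self):
        rng = np.random.default_rng(18)
        better = 0
        for rep in range(20):
            n = 120
            A = rng.normal(size=(n, 4))
            B = rng.normal(size=(n, 4))
            y = A @ rng.normal(size=4) + B @ rng.normal(size=4) \
                + rng.normal(0, 0.2, n)
            s = 96
            combined = sp.grouped_ridge_search(
                {"a": A[:s], "b": B[:s]}, {"a": A[s:], "b": B[s:]},
                y[:s], y[s:], n_gamma=40, seed=rep)
            ra = sp.encode_feature_set(A, y, np.arange(s), np.arange(s, n),
                                       seed=rep).test_r
            rb = sp.encode_feature_set(B, y, np.arange(s), np.arange(s, n),
                                       seed=rep).test_r
            better += combined.test_r > max(ra, rb)
        assert better >= 16  # superadditive in the clear majority of runs

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.grouped_ridge_search(
                {"a": np.zeros((10, 2)), "b": np.zeros((10, 0))},
                {"a": np.zeros((5, 2)), "b": np.zeros((5, 0))},
                np.zeros(10), np.zeros(5))


class TestNoLeakage:
    def test_test_split_never_influences_selection(self):
        rng = np.random.default_rng(19)
        n = 80
        layers = {f"layer{i}": rng.normal(size=(n, 6)) for i in range(3)}
        y = layers["layer1"][:, 0] + rng.normal(0, 0.5, n)
        tr, te = np.arange(60), np.arange(60, 80)
        res = sp.encode_with_layer_selection(layers, y, tr, te, seed=5)
        y_shuffled = y.copy()
        y_shuffled[te] = rng.permutation(y_shuffled[te])
        res2 = sp.encode_with_layer_selection(layers, y_shuffled, tr, te,
                                              seed=5)
        assert res.chosen_layer == res2.chosen_layer
        assert res.chosen_alpha == res2.chosen_alpha

    def test_grouped_selection_ignores_test_ratings(self):
        rng = np.random.default_rng(20)
        n = 60
        A, B = rng.normal(size=(n, 4)), rng.normal(size=(n, 4))
        y = A @ rng.normal(size=4) + rng.normal(0, 0.5, n)
        s = 48
        res = sp.grouped_ridge_search({"a": A[:s], "b": B[:s]},
                                      {"a": A[s:], "b": B[s:]},
                                      y[:s], y[s:], n_gamma=30, seed=2)
        res2 = sp.grouped_ridge_search({"a": A[:s], "b": B[:s]},
                                       {"a": A[s:], "b": B[s:]},
                                       y[:s], rng.permutation(y[s:]),
                                       n_gamma=30, seed=2)
        assert res.gamma == res2.gamma and res.alpha == res2.alpha
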