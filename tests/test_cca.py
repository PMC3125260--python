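import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fragside as fs
from conftest import feasible_point_oracle


class TestCrossProduct:
    def test_identity(self):
        I = np.eye(2)
        assert np.allclose(fs.cross_product(I, I), I)

    def test_orthogonal_columns_give_zero(self):
        Xn = np.array([[1.0], [1.0]])
        Yn = np.array([[1.0], [-1.0]])
        assert np.allclose(fs.cross_product(Xn, Yn), 0)

    def test_matches_entrywise_loop(self):
        rng = np.random.default_rng(0)
        Xn, Yn = rng.standard_normal((5, 3)), rng.standard_normal((5, 2))
        Z = fs.cross_product(Xn, Yn)
        for j in range(3):
            for k in range(2):
                assert Z[j, k] == pytest.approx(sum(Xn[i, j] * Yn[i, k] for i in range(5)))

    def test_row_mismatch(self):
        with pytest.raises(ValueError, match="row mismatch"):
            fs.cross_product(np.ones((3, 2)), np.ones((4, 2)))


class TestOCCA:
    def test_diagonal_matrix(self):
        A, B, d = fs.occa_fit(np.diag([3.0, 2.0, 1.0]), 2)
        assert np.allclose(d, [3, 2])
        assert np.allclose(np.abs(A), np.eye(3)[:, :2])
        assert np.allclose(np.abs(B), np.eye(3)[:, :2])

    def test_rank1_recovery(self):
        a = np.array([0.6, 0.8, 0.0])
        b = np.array([0.0, 1.0])
        A, B, d = fs.occa_fit(4.0 * np.outer(a, b), 1)
        assert d[0] == pytest.approx(4.0)
        assert np.allclose(np.abs(A[:, 0]), a, atol=1e-12)
        assert np.allclose(np.abs(B[:, 0]), b, atol=1e-12)

    def test_truncation_error_equals_tail_singular_values(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((6, 5))
        A, B, d = fs.occa_fit(Z, 3)
        resid = Z - A @ np.diag(d) @ B.T
        tail = np.linalg.svd(Z, compute_uv=False)[3:]
        assert np.linalg.norm(resid) == pytest.approx(np.linalg.norm(tail))

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            fs.occa_fit(np.eye(3), 4)
        with pytest.raises(ValueError):
            fs.occa_fit(np.eye(3), 0)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "v,delta,expected",
        [
            ([3, -1, 0.5], 1.0, [2, 0, 0]),
            ([3, -1, 0.5], 0.0, [3, -1, 0.5]),
            ([3, -1, 0.5], 3.0, [0, 0, 0]),
        ],
    )
    def test_definition(self, v, delta, expected):
        assert np.allclose(fs.soft_threshold(np.array(v, float), delta), expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8), st.floats(0, 5))
    def test_shrinks_and_preserves_sign(self, v, delta):
        v = np.asarray(v)
        w = fs.soft_threshold(v, delta)
        assert (np.abs(w) <= np.abs(v) + 1e-12).all()
        assert ((w == 0) | (np.sign(w) == np.sign(v))).all()


class TestL1BoundSearch:
    def test_single_nonzero_needs_no_shrinkage(self):
        assert fs.l1_bound_search(np.array([0.0, 1.0, 0.0]), 1.0) == 0.0

    def test_dense_bound_is_inactive(self):
        v = np.array([2.0, -1.0, 1.0])
        assert fs.l1_bound_search(v, np.sqrt(3)) == 0.0

    def test_matches_fine_grid_scan(self):
        v = np.array([2.0, 1.0, 1.0])
        bound = 1.2
        deltas = np.arange(0.0, np.abs(v).max() + 1e-6, 1e-6)
        W = np.sign(v) * np.maximum(np.abs(v)[None, :] - deltas[:, None], 0.0)
        nrm = np.linalg.norm(W, axis=1)
        l1 = np.where(nrm > 0, np.abs(W).sum(axis=1) / np.where(nrm > 0, nrm, 1), 1.0)
        grid_delta = deltas[np.argmax(l1 <= bound)]
        assert fs.l1_bound_search(v, bound) == pytest.approx(grid_delta, abs=1e-4)
        w = fs.soft_threshold(v, fs.l1_bound_search(v, bound))
        w /= np.linalg.norm(w)
        assert np.abs(w).sum() <= bound + 1e-8

    def test_bound_below_one_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            fs.l1_bound_search(np.array([1.0, 2.0]), 0.5)


def l1_feasible(v, c):
    # budgets below 1 clamp to the single-nonzero limit
    return np.abs(v).sum() <= max(c * np.sqrt(len(v)), 1.0) + 1e-8


class TestRank1PMD:
    def test_unconstrained_equals_leading_svd_triple(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((8, 6))
        alpha, beta, d = fs.rank1_pmd(Z, 1.0, 1.0)
        U, s, Vt = np.linalg.svd(Z)
        sign = np.sign(U[np.argmax(np.abs(U[:, 0])), 0])
        assert d == pytest.approx(s[0], abs=1e-6)
        assert np.allclose(alpha * np.sign(alpha[np.argmax(np.abs(alpha))]),
                           U[:, 0] * sign, atol=1e-6)

    def test_recovers_sparse_rank1_factor(self):
        a = np.zeros(10); a[2] = 0.6; a[7] = 0.8
        b = np.zeros(8); b[1] = 1.0
        alpha, beta, d = fs.rank1_pmd(5.0 * np.outer(a, b), 0.5, 0.5)
        assert d == pytest.approx(5.0, abs=1e-8)
        assert np.allclose(np.abs(alpha), a, atol=1e-8)
        assert np.allclose(np.abs(beta), b, atol=1e-8)

    def test_objective_meets_random_search_oracle(self):
        Z = np.diag([4.0, 3.0, 1.0])
        alpha, beta, d = fs.rank1_pmd(Z, 0.6, 0.6)
        best = feasible_point_oracle(Z, 0.6, 0.6, n_samples=100_000, seed=0)
        assert l1_feasible(alpha, 0.6) and l1_feasible(beta, 0.6)
        assert d >= best - 1e-3

    def test_constraints_hold_at_return(self):
        rng = np.random.default_rng(3)
        for c in (0.3, 0.6, 1.0):
            Z = rng.standard_normal((12, 9))
            alpha, beta, _ = fs.rank1_pmd(Z, c, c)
            assert np.linalg.norm(alpha) == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(beta) == pytest.approx(1.0, abs=1e-8)
            assert l1_feasible(alpha, c) and l1_feasible(beta, c)

    def test_objective_nondecreasing_over_iterations(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((10, 7))
        params = fs.SCCAParams(c1=0.5, c2=0.5, max_iter=1)
        prev = -np.inf
        # re-run with growing iteration caps: the alternating maximization
        # must never lower the objective
        for it in range(1, 8):
            params = fs.SCCAParams(c1=0.5, c2=0.5, max_iter=it)
            _, _, d = fs.rank1_pmd(Z, 0.5, 0.5, params)
            assert d >= prev - 1e-10
            prev = d

    def test_monotone_sparsity_in_c1(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((15, 10))
        nnz = []
        for c1 in (1.0, 0.8, 0.6, 0.4, 0.2):
            alpha, _, _ = fs.rank1_pmd(Z, c1, 1.0)
            nnz.append(int((alpha != 0).sum()))
        assert nnz == sorted(nnz, reverse=True)


class TestSCCAFit:
    def test_exact_rank2_deflates_to_zero(self):
        a1 = np.zeros(6); a1[0] = 1.0
        a2 = np.zeros(6); a2[3] = 1.0
        b1 = np.zeros(5); b1[1] = 1.0
        b2 = np.zeros(5); b2[4] = 1.0
        Z = 3.0 * np.outer(a1, b1) + 2.0 * np.outer(a2, b2)
        # with Xn = I the cross-product is exactly the rank-2 target Z
        model = fs.scca_fit(np.eye(6), Z, fs.SCCAParams(c1=1, c2=1, m=2))
        resid = Z - model.A @ np.diag(model.d) @ model.B.T
        assert np.linalg.norm(resid) < 1e-8

    def test_single_component_equals_rank1_pmd(self):
        rng = np.random.default_rng(6)
        Xn, Yn = rng.standard_normal((20, 6)), rng.standard_normal((20, 5))
        model = fs.scca_fit(Xn, Yn, fs.SCCAParams(c1=0.7, c2=0.7, m=1))
        alpha, beta, d = fs.rank1_pmd(fs.cross_product(Xn, Yn), 0.7, 0.7)
        A, B = fs.adjust_signs(alpha[:, None], beta[:, None])
        assert np.allclose(model.A, A) and np.allclose(model.B, B)
        assert model.d[0] == pytest.approx(d)

    def test_deflation_conserves_cross_product(self):
        rng = np.random.default_rng(7)
        Xn, Yn = rng.standard_normal((25, 8)), rng.standard_normal((25, 6))
        Z = fs.cross_product(Xn, Yn)
        model = fs.scca_fit(Xn, Yn, fs.SCCAParams(c1=0.5, c2=0.5, m=4))
        Zk = Z.copy()
        for k in range(model.m):
            Zk -= model.d[k] * np.outer(model.A[:, k], model.B[:, k])
        rebuilt = model.A @ np.diag(model.d) @ model.B.T + Zk
        assert np.linalg.norm(rebuilt - Z) < 1e-8

    def test_svd_limit_matches_occa(self):
        rng = np.random.default_rng(8)
        Xn, Yn = rng.standard_normal((40, 10)), rng.standard_normal((40, 8))
        Z = fs.cross_product(Xn, Yn)
        A0, B0, d0 = fs.occa_fit(Z, 4)
        model = fs.scca_fit(Xn, Yn, fs.SCCAParams(c1=1, c2=1, m=4))
        assert np.abs(model.A - A0).max() < 1e-5
        assert np.abs(model.B - B0).max() < 1e-5
        assert np.allclose(model.d, d0, atol=1e-6)

    def test_planted_components_recovered(self, planted, planted_model):
        _, _, truth = planted
        model = planted_model
        for comp in truth.components[:2]:
            best_sub = best_se = 0
            for k in range(model.m):
                top_sub = set(np.argsort(-np.abs(model.A[:, k]), kind="stable")[:5])
                top_se = set(np.argsort(-np.abs(model.B[:, k]), kind="stable")[:5])
                best_sub = max(best_sub, len(top_sub & comp.sub_support))
                best_se = max(best_se, len(top_se & comp.se_support))
            assert best_sub >= 4 and best_se >= 4

    def test_constraint_satisfaction_across_fits(self):
        rng = np.random.default_rng(9)
        for c in (0.2, 0.5, 1.0):
            Xn, Yn = rng.standard_normal((15, 7)), rng.standard_normal((15, 5))
            model = fs.scca_fit(Xn, Yn, fs.SCCAParams(c1=c, c2=c, m=3))
            for k in range(model.m):
                assert np.linalg.norm(model.A[:, k]) == pytest.approx(1, abs=1e-8)
                assert np.linalg.norm(model.B[:, k]) == pytest.approx(1, abs=1e-8)
                assert l1_feasible(model.A[:, k], c)
                assert l1_feasible(model.B[:, k], c)


class TestAdjustSigns:
    def test_flips_pair_together(self):
        A = np.array([[-0.9], [0.1]])
        B = np.array([[0.3], [-0.4]])
        A2, B2 = fs.adjust_signs(A, B)
        assert np.allclose(A2[:, 0], [0.9, -0.1])
        assert np.allclose(B2[:, 0], [-0.3, 0.4])

    def test_positive_max_untouched(self):
        A = np.array([[0.9], [-0.1]])
        B = np.array([[-0.3], [0.4]])
        A2, B2 = fs.adjust_signs(A, B)
        assert np.allclose(A2, A) and np.allclose(B2, B)

    def test_tie_broken_by_earliest_index(self):
        A = np.array([[0.5], [-0.5]])
        B = np.array([[1.0], [0.0]])
        A2, _ = fs.adjust_signs(A, B)
        assert np.allclose(A2, A)  # earliest maximal entry is +0.5: no flip

    def test_unpaired_mode_flips_beta_alone(self):
        A = np.array([[0.9]])
        B = np.array([[-0.4], [0.1]])
        _, B2 = fs.adjust_signs(A, B, paired=False)
        assert np.allclose(B2[:, 0], [0.4, -0.1])


class TestCanonicalCorrelation:
    def test_identical_components(self):
        rng = np.random.default_rng(10)
        Xn = rng.standard_normal((20, 3))
        alpha = np.array([0.5, 0.5, 0.7])
        assert fs.canonical_correlation(Xn, Xn, alpha, alpha) == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        Xn = rng.standard_normal((20, 3))
        alpha = np.array([1.0, 0.0, 0.0])
        assert fs.canonical_correlation(Xn, -Xn, alpha, alpha) == pytest.approx(-1.0)

    def test_matches_pearson_formula(self):
        Xn = np.array([[1.0, 0], [0, 1], [1, 1], [0, 0]])
        Yn = np.array([[1.0], [2], [0], [1]])
        alpha, beta = np.array([0.8, -0.6]), np.array([1.0])
        rho = fs.canonical_correlation(Xn, Yn, alpha, beta)
        expected = np.corrcoef(Xn @ alpha, Yn @ beta)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        Xn = np.ones((5, 2))
        assert np.isnan(fs.canonical_correlation(Xn, Xn, np.ones(2), np.ones(2)))


class TestPermutationPvalue:
    def test_strong_signal_gives_minimum_p(self, planted):
        X, Y, _ = planted
        xn, yn = fs.fit_normalizer(X), fs.fit_normalizer(Y)
        p = fs.permutation_pvalue(
            fs.apply_normalizer(xn, X.values),
            fs.apply_normalizer(yn, Y.values),
            fs.SCCAParams(c1=0.3, c2=0.3, m=1),
            n_perm=99,
            seed=0,
        )
        assert p == pytest.approx(1 / 100)

    def test_same_seed_same_p(self):
        X, Y = fs.generate_null_dataset(60, 8, 6, rate=0.3, seed=12)
        xn, yn = fs.fit_normalizer(X), fs.fit_normalizer(Y)
        args = (
            fs.apply_normalizer(xn, X.values),
            fs.apply_normalizer(yn, Y.values),
            fs.SCCAParams(c1=0.5, c2=0.5, m=1),
        )
        p1 = fs.permutation_pvalue(*args, n_perm=19, seed=4)
        p2 = fs.permutation_pvalue(*args, n_perm=19, seed=4)
        assert p1 == p2


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path, planted_model):
        fs.save_model(planted_model, tmp_path / "model")
        loaded = fs.load_model(tmp_path / "model")
        assert np.allclose(loaded.A, planted_model.A)
        assert np.allclose(loaded.B, planted_model.B)
        assert np.allclose(loaded.d, planted_model.d)
        assert np.allclose(loaded.rho, planted_model.rho)
        assert np.allclose(loaded.x_norm.means, planted_model.x_norm.means)
        assert loaded.params.c1 == planted_model.params.c1
        assert loaded.x_names == planted_model.x_names
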