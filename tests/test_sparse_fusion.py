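import numpy as np
import pytest

from eegfatigue import (
    SparseDictionary,
    concat_fusion,
    fuse,
    ksvd_atom_update,
    ksvd_learn,
    make_toy_feature_table,
    omp_encode,
    pca_fusion,
)
from eegfatigue.sparse_fusion import _encode_matrix


def _unit_dict(rng, n, m):
    D = rng.standard_normal((n, m))
    return D / np.linalg.norm(D, axis=0)


def _planted_signals(seed, n=40, m=20, k=3, n_sig=200):
    rng = np.random.default_rng(seed)
    D = _unit_dict(rng, n, m)
    Y = np.zeros((n, n_sig))
    for j in range(n_sig):
        idx = rng.choice(m, k, replace=False)
        Y[:, j] = D[:, idx] @ rng.standard_normal(k)
    return D, Y


class TestOmp:
    def test_identity_dictionary_exact_atom(self):
        D = np.eye(3)
        code = omp_encode(D, np.array([0.0, 2.0, 0.0]), T0=1)
        np.testing.assert_allclose(code.alpha, [0, 2, 0])
        assert code.residual_norm == pytest.approx(0.0, abs=1e-12)
        assert list(code.support) == [1]

    def test_recovers_two_atom_combination(self):
        rng = np.random.default_rng(0)
        D = _unit_dict(rng, 30, 10)
        x = 2.0 * D[:, 3] - 1.5 * D[:, 7]
        code = omp_encode(D, x, T0=2)
        assert code.residual_norm < 1e-10
        assert set(code.support) == {3, 7}

    def test_t0_equal_m_matches_least_squares(self):
        rng = np.random.default_rng(1)
        D = _unit_dict(rng, 15, 8)
        x = rng.standard_normal(15)
        code = omp_encode(D, x, T0=8)
        # full-rank least squares via the normal equations
        ls = np.linalg.solve(D.T @ D, D.T @ x)
        resid = np.linalg.norm(x - D @ ls)
        assert code.residual_norm == pytest.approx(resid, abs=1e-10)

    def test_zero_input_gives_empty_code(self):
        D = np.eye(4)
        code = omp_encode(D, np.zeros(4), T0=2)
        assert code.support.size == 0
        np.testing.assert_array_equal(code.alpha, np.zeros(4))

    def test_support_never_exceeds_t0_and_residual_decreases(self):
        rng = np.random.default_rng(2)
        D = _unit_dict(rng, 20, 12)
        x = rng.standard_normal(20)
        prev = np.inf
        for t0 in range(1, 6):
            code = omp_encode(D, x, T0=t0)
            assert len(code.support) <= t0
            assert code.residual_norm <= prev + 1e-12
            prev = code.residual_norm

    def test_matches_sklearn_omp(self):
        from sklearn.linear_model import OrthogonalMatchingPursuit

        rng = np.random.default_rng(3)
        D = _unit_dict(rng, 25, 10)
        x = rng.standard_normal(25)
        code = omp_encode(D, x, T0=4)
        sk = OrthogonalMatchingPursuit(n_nonzero_coefs=4, fit_intercept=False).fit(D, x)
        np.testing.assert_allclose(code.alpha, sk.coef_, atol=1e-8)

    def test_batch_encoder_agrees_with_omp_encode(self):
        rng = np.random.default_rng(4)
        D = _unit_dict(rng, 20, 8)
        Y = rng.standard_normal((20, 15))
        X = _encode_matrix(D, Y, T0=3)
        for j in range(Y.shape[1]):
            np.testing.assert_allclose(X[:, j], omp_encode(D, Y[:, j], T0=3).alpha,
                                       atol=1e-12)


class TestAtomUpdate:
    def test_rank_one_exact_case(self):
        rng = np.random.default_rng(0)
        D = _unit_dict(rng, 10, 4)
        Y = (5.0 * D[:, 2])[:, None]
        X = np.zeros((4, 1))
        X[2, 0] = 1.0  # atom 2 used with coefficient 1; true scale is 5
        d_new, x_new, used = ksvd_atom_update(Y, D, X, 2)
        sign = np.sign(d_new @ D[:, 2])
        np.testing.assert_allclose(sign * d_new, D[:, 2], atol=1e-10)
        assert abs(x_new[0]) == pytest.approx(5.0, abs=1e-10)

    def test_update_never_increases_restricted_residual(self):
        # Eckart-Young: the SVD rank-1 fit is optimal for the restricted residual
        rng = np.random.default_rng(1)
        for trial in range(10):
            D = _unit_dict(rng, 12, 6)
            Y = rng.standard_normal((12, 30))
            X = _encode_matrix(D, Y, T0=3)
            k = trial % 6
            if np.all(X[k] == 0):
                continue
            used = np.flatnonzero(X[k] != 0)
            E = Y[:, used] - D @ X[:, used] + np.outer(D[:, k], X[k, used])
            before = np.linalg.norm(E - np.outer(D[:, k], X[k, used]))
            d_new, x_new, _ = ksvd_atom_update(Y, D, X, k)
            after = np.linalg.norm(E - np.outer(d_new, x_new))
            assert after <= before + 1e-10

    def test_exactly_rank_one_residual_zeroed(self):
        rng = np.random.default_rng(2)
        D = _unit_dict(rng, 8, 3)
        u = rng.standard_normal(8)
        v = rng.standard_normal(5)
        # craft Y so that with X using only atom 0, E_0 = u v^T exactly
        X = np.zeros((3, 5))
        X[0] = 1.0
        Y = D @ X + np.outer(u, v) - np.outer(D[:, 0], X[0])
        d_new, x_new, used = ksvd_atom_update(Y, D, X, 0)
        E = Y - D @ X + np.outer(D[:, 0], X[0])
        assert np.linalg.norm(E - np.outer(d_new, x_new)) == pytest.approx(0.0, abs=1e-9)

    def test_unused_atom_raises(self):
        D = np.eye(4)
        with pytest.raises(ValueError, match="unused"):
            ksvd_atom_update(np.eye(4), D, np.zeros((4, 4)), 1)


class TestKsvdLearn:
    def test_planted_dictionary_recovered(self):
        _, Y = _planted_signals(seed=0)
        D, X = ksvd_learn(Y, M=20, T0=3, max_iters=150, seed=0)
        rel = np.linalg.norm(Y - D.D @ X) / np.linalg.norm(Y)
        assert rel < 0.05

    def test_zero_iterations_returns_initialization(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((10, 30))
        D, X = ksvd_learn(Y, M=5, T0=2, max_iters=0, seed=7)
        norms = np.linalg.norm(D.D, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert np.all(X == 0)
        # initialization columns are (normalized) training columns
        Yn = Y / np.linalg.norm(Y, axis=0)
        for atom in D.D.T:
            assert np.min(np.linalg.norm(Yn - atom[:, None], axis=0)) < 1e-10

    def test_error_trace_non_increasing(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            Y = rng.standard_normal((16, 60))
            D, _ = ksvd_learn(Y, M=8, T0=3, max_iters=15, seed=seed)
            trace = np.array(D.training_error_trace)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_raw_errors_monotone_between_replacements(self):
        rng = np.random.default_rng(200)
        Y = rng.standard_normal((16, 60))
        D, _ = ksvd_learn(Y, M=8, T0=3, max_iters=20, seed=0)
        raw = np.array(D.iteration_errors)
        replaced_iters = {it for it, _ in D.replaced_atoms}
        for i in range(1, len(raw)):
            if (i - 1) not in replaced_iters:
                assert raw[i] <= raw[i - 1] + 1e-9

    def test_too_few_signals_rejected(self):
        with pytest.raises(ValueError, match="training signals"):
            ksvd_learn(np.zeros((10, 4)) + 1.0, M=5, T0=1)


def _split_toy(seed=0, n=120, n_features=40, n_channels=8):
    X = make_toy_feature_table(n_samples=n, n_features=n_features, n_informative=10,
                               class_sep=2.0, seed=seed, n_channels=n_channels)
    tr = X.subset(np.arange(0, n - 20))
    te = X.subset(np.arange(n - 20, n))
    return tr, te


class TestFusionFrontEnds:
    def test_sparse_fusion_reduces_dimension(self):
        tr, te = _split_toy()
        res = fuse(tr, te, M=20, T0=5, max_iters=10, seed=0)
        assert res.train_codes.shape == (100, 20)
        assert res.test_codes.shape == (20, 20)

    def test_overcomplete_limit_reconstructs_training_rows(self):
        tr, te = _split_toy(n=60, n_features=10, n_channels=10)
        res = fuse(tr, te, M=10, T0=10, max_iters=5, seed=0)
        mu, sd = tr.values.mean(0), tr.values.std(0)
        Z = (tr.values - mu) / sd
        recon = res.train_codes @ res.dictionary.D.T
        np.testing.assert_allclose(recon, Z, atol=1e-6)

    def test_identical_rows_get_identical_codes(self):
        tr, te = _split_toy()
        te2 = tr.subset(np.arange(5))
        res = fuse(tr, te2, M=15, T0=4, max_iters=5, seed=1)
        np.testing.assert_allclose(res.test_codes, res.train_codes[:5], atol=1e-12)

    def test_column_mismatch_rejected(self):
        tr, _ = _split_toy()
        other, _ = _split_toy(n_features=20, n_channels=4)
        with pytest.raises(ValueError, match="columns differ"):
            fuse(tr, other)

    def test_concat_is_standardized_passthrough(self):
        tr, te = _split_toy()
        res = concat_fusion(tr, te)
        assert res.train_codes.shape[1] == tr.n_columns
        np.testing.assert_allclose(res.train_codes.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(res.train_codes.std(0), 1.0, atol=1e-10)

    def test_concat_drops_constant_column_with_warning(self):
        tr, te = _split_toy()
        tr.values[:, 0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            res = concat_fusion(tr, te)
        assert res.train_codes.shape[1] == tr.n_columns - 1

    def test_pca_scores_orthogonal_and_variance_ordered(self):
        tr, te = _split_toy()
        res = pca_fusion(tr, te, n_components=10)
        G = res.train_codes.T @ res.train_codes
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        var = res.train_codes.var(axis=0)
        assert np.all(np.diff(var) <= 1e-10)

    def test_pca_full_rank_reconstruction(self):
        tr, te = _split_toy(n=80, n_features=10, n_channels=10)
        res = pca_fusion(tr, te, n_components=10)
        assert res.train_codes.shape[1] == 10
        # projection at full rank preserves pairwise distances
        from scipy.spatial.distance import pdist

        mu, sd = tr.values.mean(0), tr.values.std(0)
        Z = (tr.values - mu) / sd
        np.testing.assert_allclose(pdist(res.train_codes), pdist(Z), rtol=1e-8)

    def test_dictionary_invariant_unit_norm(self):
        tr, te = _split_toy()
        res = fuse(tr, te, M=12, T0=3, max_iters=8, seed=3)
        np.testing.assert_allclose(
            np.linalg.norm(res.dictionary.D, axis=0), 1.0, atol=1e-10
        )

    def test_unit_norm_enforced_by_dataclass(self):
        with pytest.raises(ValueError, match="unit-norm"):
            SparseDictionary(D=np.eye(3) * 2.0)
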