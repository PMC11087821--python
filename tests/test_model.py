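"""Kronecker design construction and the bilinear lasso-logistic fit."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import draphnet as dn
from draphnet.errors import InvalidInputError
from draphnet.softimpute import Decomposition


def _gsm(values):
    values = np.asarray(values, dtype=float)
    return dn.GeneScoreMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        phenotype_ids=[f"p{j}" for j in range(values.shape[1])],
    )


def _assoc(values):
    values = np.asarray(values)
    return dn.AssociationMatrix(
        values=values,
        drug_ids=[f"d{i}" for i in range(values.shape[0])],
        phenotype_ids=[f"p{j}" for j in range(values.shape[1])],
    )


def _random_gene_decomp(n_phenos, r, rng, n_genes=None):
    n_genes = n_genes or n_phenos * 3
    U, _ = np.linalg.qr(rng.standard_normal((n_genes, r)))
    V, _ = np.linalg.qr(rng.standard_normal((n_phenos, r)))
    S = np.sort(rng.random(r) + 0.5)[::-1]
    return Decomposition(U=U, S=S, V=V, rank=r)


class TestDecomposeGeneMatrix:
    def test_diagonal_singular_values(self):
        G = _gsm(np.diag([3.0, 2.0, 1.0]))
        dec = dn.decompose_gene_matrix(G, 2)
        np.testing.assert_allclose(dec.S, [3.0, 2.0], atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        G = _gsm(rng.standard_normal((6, 4)))
        dec = dn.decompose_gene_matrix(G, 4)
        np.testing.assert_allclose(dec.reconstruction(), G.values, atol=1e-8)

    def test_eckart_young_optimum(self, rng):
        X = rng.standard_normal((20, 10))
        dec = dn.decompose_gene_matrix(_gsm(X), 5)
        _, s, _ = np.linalg.svd(X)
        err = np.sum((dec.reconstruction() - X) ** 2)
        assert err == pytest.approx(np.sum(s[5:] ** 2), rel=1e-10)

    def test_rank_exceeding_matrix_rank_truncates_with_warning(self, rng):
        low = rng.standard_normal((8, 2)) @ rng.standard_normal((2, 5))
        with pytest.warns(dn.ConvergenceWarning):
            dec = dn.decompose_gene_matrix(_gsm(low), 4)
        assert dec.rank == 2


class TestBuildDesign:
    def test_scalar_case(self):
        design = dn.build_design(np.array([[2.0]]), np.array([[3.0]]))
        np.testing.assert_allclose(design.X, [[6.0]])

    def test_two_by_two_enumeration(self):
        F = np.array([[2.0], [5.0]])
        V = np.array([[3.0], [7.0]])
        design = dn.build_design(F, V)
        # column-major pair order, drug fastest: (0,0),(1,0),(0,1),(1,1)
        np.testing.assert_allclose(design.X.ravel(), [6.0, 15.0, 14.0, 35.0])
        assert design.pairs == [(0, 0), (1, 0), (0, 1), (1, 1)]

    def test_vec_identity(self, rng):
        for _ in range(10):
            A = rng.standard_normal((4, 2))
            X = rng.standard_normal((2, 3))
            B = rng.standard_normal((5, 3))
            design = dn.build_design(A, B)
            lhs = design.X @ X.ravel(order="F")
            rhs = (A @ X @ B.T).ravel(order="F")
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_subset_rows_match_full(self, rng):
        A = rng.standard_normal((6, 3))
        B = rng.standard_normal((4, 2))
        full = dn.build_design(A, B)
        subset = [(2, 1), (5, 3), (0, 0)]
        part = dn.build_design(A, B, pair_subset=subset)
        for row, (i, j) in zip(part.X, subset):
            np.testing.assert_allclose(row, full.X[j * 6 + i])


class TestFit:
    def test_kronecker_trick_equals_explicit_regression(self, rng):
        # 10 drugs x 6 phenotypes at full ranks: factorized fit must equal an
        # unstructured logistic regression on the expanded outer-product features
        n_d, n_p, r_d, r_p = 10, 6, 3, 2
        DF = rng.standard_normal((n_d, r_d))
        gd = _random_gene_decomp(n_p, r_p, rng)
        Y = _assoc((rng.random((n_d, n_p)) < 0.4).astype(int))
        config = dn.ModelConfig(r_D=r_d, r_P=r_p, l1_strength=0.01, seed=0)
        model = dn.fit(DF, gd, Y, config)

        # independent expansion: explicit per-pair outer products
        rows, labels = [], []
        for j in range(n_p):
            for i in range(n_d):
                rows.append(np.outer(gd.V[j], DF[i]).ravel())
                labels.append(Y.values[i, j])
        X = np.asarray(rows)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (X.shape[0] * 0.01), solver="liblinear",
            intercept_scaling=100.0 * max(1.0, X.shape[0] * 0.01),
            tol=1e-8, max_iter=5000, random_state=0,
        )
        clf.fit(X, labels)
        np.testing.assert_allclose(
            model.W_DP.ravel(order="F"), clf.coef_.ravel(), atol=1e-6
        )
        assert model.intercept == pytest.approx(float(clf.intercept_[0]), abs=1e-6)

    def test_planted_sparse_interaction_recovered(self, rng):
        n_d, n_p, r = 120, 40, 4
        DF = rng.standard_normal((n_d, r))
        gd = _random_gene_decomp(n_p, r, rng)
        W = np.zeros((r, r))
        nz = rng.choice(r * r, size=8, replace=False)
        W.ravel()[nz] = rng.choice([-1.0, 1.0], size=8)
        logits = DF @ W @ gd.V.T
        W *= 2.0 / logits.std()
        logits *= 2.0 / logits.std()
        Y = _assoc((rng.random(logits.shape) < 1 / (1 + np.exp(-logits))).astype(int))
        model = dn.fit(DF, gd, Y, dn.ModelConfig(r_D=r, r_P=r, l1_strength=1e-4))
        mask = W != 0
        agreement = np.mean(np.sign(model.W_DP[mask]) == np.sign(W[mask]))
        assert agreement > 0.8

    def test_infinite_penalty_gives_base_rate(self, rng):
        DF = rng.standard_normal((20, 2))
        gd = _random_gene_decomp(8, 2, rng)
        Y = _assoc((rng.random((20, 8)) < 0.3).astype(int))
        model = dn.fit(DF, gd, Y, dn.ModelConfig(r_D=2, r_P=2, l1_strength=1e6))
        np.testing.assert_allclose(model.W_DP, 0.0, atol=1e-8)
        probs = dn.predict_matrix(model)
        assert np.ptp(probs) < 1e-8
        assert probs.mean() == pytest.approx(Y.values.mean(), abs=0.02)

    def test_duplicated_pairs_leave_fit_unchanged(self, rng):
        DF = rng.standard_normal((12, 2))
        gd = _random_gene_decomp(5, 2, rng)
        Y = _assoc((rng.random((12, 5)) < 0.4).astype(int))
        config = dn.ModelConfig(r_D=2, r_P=2, l1_strength=0.05)
        base = dn.fit(DF, gd, Y, config)
        doubled = dn.fit(
            DF, gd, Y, config, drug_subset=np.r_[np.arange(12), np.arange(12)]
        )
        np.testing.assert_allclose(base.W_DP, doubled.W_DP, atol=1e-6)

    def test_degenerate_labels_rejected(self, rng):
        DF = rng.standard_normal((4, 2))
        gd = _random_gene_decomp(3, 2, rng)
        Y = _assoc(np.zeros((4, 3), dtype=int))
        with pytest.raises(InvalidInputError):
            dn.fit(DF, gd, Y, dn.ModelConfig(r_D=2, r_P=2, l1_strength=0.1))


class TestPredict:
    def test_zero_interaction_gives_intercept(self, rng):
        gd = _random_gene_decomp(5, 2, rng)
        model = dn.FittedModel(
            W_DP=np.zeros((2, 2)),
            intercept=0.7,
            drug_factors=rng.standard_normal((3, 2)),
            gene_decomp=gd,
            drug_ids=["a", "b", "c"],
            phenotype_ids=[f"p{j}" for j in range(5)],
            gene_ids=[f"g{i}" for i in range(gd.U.shape[0])],
        )
        probs = dn.predict_matrix(model)
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(-0.7)), atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        gd = _random_gene_decomp(6, 3, rng)
        W = rng.standard_normal((4, 3))
        F = rng.standard_normal((7, 4))
        model = dn.FittedModel(
            W_DP=W, intercept=-0.3, drug_factors=F, gene_decomp=gd,
            drug_ids=[f"d{i}" for i in range(7)],
            phenotype_ids=[f"p{j}" for j in range(6)],
            gene_ids=[f"g{i}" for i in range(gd.U.shape[0])],
        )
        expected = 1 / (1 + np.exp(-(-0.3 + F @ W @ gd.V.T)))
        np.testing.assert_allclose(dn.predict_matrix(model), expected, atol=1e-12)

    def test_orthogonal_basis_change_invariance(self, rng):
        # rotating (V_P, W_DP) consistently leaves probabilities unchanged
        gd = _random_gene_decomp(6, 3, rng)
        W = rng.standard_normal((4, 3))
        F = rng.standard_normal((7, 4))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        gd_rot = Decomposition(
            U=gd.U, S=gd.S, V=gd.V @ Q, rank=3
        )
        args = dict(intercept=0.1, drug_factors=F,
                    drug_ids=[f"d{i}" for i in range(7)],
                    phenotype_ids=[f"p{j}" for j in range(6)],
                    gene_ids=[f"g{i}" for i in range(gd.U.shape[0])])
        m1 = dn.FittedModel(W_DP=W, gene_decomp=gd, **args)
        m2 = dn.FittedModel(W_DP=W @ Q, gene_decomp=gd_rot, **args)
        np.testing.assert_allclose(
            dn.predict_matrix(m1), dn.predict_matrix(m2), atol=1e-10
        )

    def test_dimension_mismatch(self, small_model):
        with pytest.raises(InvalidInputError):
            dn.predict(small_model, np.ones((2, small_model.W_DP.shape[0] + 1)))


class TestTune:
    def test_single_point_grid(self, small_sim):
        D, G, Y, _, _ = small_sim
        result = dn.tune(D, G, Y, [3], [3], [0.01], cv_fold_count=4, seed=0)
        assert (result.best.r_D, result.best.r_P) == (3, 3)
        assert result.best.l1_strength == 0.01

    def test_prefers_true_rank_over_rank_one(self, small_sim):
        D, G, Y, _, _ = small_sim
        result = dn.tune(D, G, Y, [1, 4], [1, 4], [1e-3], cv_fold_count=4, seed=0)
        assert (result.best.r_D, result.best.r_P) == (4, 4)

    def test_shuffled_labels_give_chance_auc(self, small_sim, rng):
        D, G, Y, _, _ = small_sim
        Y_null = dn.AssociationMatrix(
            values=rng.permutation(Y.values.ravel()).reshape(Y.shape),
            drug_ids=Y.drug_ids, phenotype_ids=Y.phenotype_ids,
        )
        result = dn.tune(D, G, Y_null, [4], [4], [1e-3], cv_fold_count=4, seed=0)
        assert result.table["mean_auc"].iloc[0] == pytest.approx(0.5, abs=0.05)


class TestSerialization:
    def test_round_trip(self, small_model, tmp_path):
        dn.save_model(small_model, tmp_path / "m")
        back = dn.load_model(tmp_path / "m")
        np.testing.assert_allclose(back.W_DP, small_model.W_DP, atol=1e-15)
        np.testing.assert_allclose(
            back.drug_factors, small_model.drug_factors, atol=1e-15
        )
        assert back.drug_ids == small_model.drug_ids
        assert back.gene_ids == small_model.gene_ids
        assert back.intercept == pytest.approx(small_model.intercept, abs=1e-15)
        assert back.config == small_model.config
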