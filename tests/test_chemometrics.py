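"""Ordinations and clustering, cross-checked against independent solvers."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import seedqnmr as sq
from seedqnmr.chemometrics import DegenerateInputError


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(7)
    X = rng.lognormal(0.5, 0.7, size=(12, 8))
    return pd.DataFrame(
        X,
        index=[f"L{i}" for i in range(12)],
        columns=[f"m{j}" for j in range(8)],
    )


class TestPCA:
    def test_rank_one_data_explained_by_single_component(self):
        u = np.arange(1.0, 6.0)
        v = np.array([2.0, -1.0, 0.5])
        res = sq.pca(np.outer(u, v))
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_pct_variance_sums_to_100(self, random_matrix):
        res = sq.pca(random_matrix)
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_small_matrix_matches_brute_force_eigendecomposition(self):
        X = np.array([[1.0, 2.0], [3.0, 5.0], [4.0, 3.0]])
        res = sq.pca(X)
        cov = np.cov(X, rowvar=False)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, expected[: len(res.eigenvalues)], atol=1e-12)

    def test_matches_sklearn(self, random_matrix):
        sklearn = pytest.importorskip("sklearn.decomposition")
        res = sq.pca(random_matrix)
        ref = sklearn.PCA().fit(random_matrix.to_numpy())
        k = len(res.eigenvalues)
        assert np.allclose(res.eigenvalues, ref.explained_variance_[:k], rtol=1e-10)
        assert np.allclose(
            np.abs(res.loadings.to_numpy()), np.abs(ref.components_[:k].T), atol=1e-8
        )

    def test_eigenvalue_sum_equals_total_variance(self, random_matrix):
        res = sq.pca(random_matrix)
        total_var = random_matrix.to_numpy().var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_scores_reproduce_centered_data_at_full_rank(self, random_matrix):
        res = sq.pca(random_matrix)
        A = random_matrix.to_numpy() - random_matrix.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, A, atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            sq.pca(np.full((4, 3), 2.5))

    def test_autoscale_analyses_correlation_structure(self, random_matrix):
        res = sq.pca(random_matrix, scale="autoscale")
        # correlation matrix trace = number of variables
        assert res.eigenvalues.sum() == pytest.approx(
            random_matrix.shape[1], rel=1e-9
        )


class TestPCoA:
    def test_euclidean_distances_recover_pca_scores_up_to_sign(self, random_matrix):
        res_pca = sq.pca(random_matrix)
        D = squareform(pdist(random_matrix.to_numpy()))
        res_pcoa = sq.pcoa(D, labels=list(random_matrix.index))
        k = min(res_pca.scores.shape[1], res_pcoa.scores.shape[1])
        a = res_pca.scores.to_numpy()[:, :k]
        b = res_pcoa.scores.to_numpy()[:, :k]
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_matches_scikit_bio(self, random_matrix):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        D = squareform(pdist(random_matrix.to_numpy()))
        mine = sq.pcoa(D)
        ref = skbio_ord.pcoa(D)
        k = mine.scores.shape[1]
        ref_eigs = np.asarray(ref.eigvals)[:k]
        assert np.allclose(mine.eigenvalues[:k], ref_eigs, rtol=1e-8, atol=1e-10)

    def test_all_zero_distances_give_zero_eigenvalues(self):
        res = sq.pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.scores.shape[1] == 0

    def test_equilateral_triangle_has_two_equal_positive_eigenvalues(self):
        # closed form: the double-centered Gram matrix has trace
        # (1/(2n))·ΣΣd² = 1 split over two equal axes -> (1/2, 1/2, 0)
        D = np.ones((3, 3)) - np.eye(3)
        res = sq.pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert np.allclose(pos, 0.5, atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            sq.pcoa(D)

    def test_negative_eigenvalues_reported_but_excluded_from_pct(self):
        # a non-Euclidean dissimilarity: violates the triangle inequality
        D = np.array(
            [[0.0, 1.0, 1.0, 3.0],
             [1.0, 0.0, 1.0, 1.0],
             [1.0, 1.0, 0.0, 1.0],
             [3.0, 1.0, 1.0, 0.0]]
        )
        res = sq.pcoa(D)
        assert res.eigenvalues.min() < -1e-9
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert len(res.pct_variance) < len(res.eigenvalues)


class TestCorrespondenceAnalysis:
    def test_independent_table_has_zero_inertia(self):
        tab = np.outer([2.0, 3.0, 5.0], [1.0, 4.0, 2.0])
        res = sq.correspondence_analysis(tab)
        assert res.eigenvalues.sum() == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2_table_inertia_one(self):
        res = sq.correspondence_analysis(np.array([[10.0, 0.0], [0.0, 10.0]]))
        assert res.eigenvalues.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(res.eigenvalues) == 1

    def test_inertia_equals_chi2_over_n(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(3)
        tab = rng.integers(1, 30, size=(5, 4)).astype(float)
        res = sq.correspondence_analysis(tab)
        chi2 = scipy_stats.chi2_contingency(tab, correction=False)[0]
        assert res.eigenvalues.sum() == pytest.approx(chi2 / tab.sum(), rel=1e-10)

    def test_row_standard_coordinates_orthonormal_under_margins(self):
        rng = np.random.default_rng(4)
        tab = rng.integers(1, 30, size=(6, 5)).astype(float)
        res = sq.correspondence_analysis(tab)
        P = tab / tab.sum()
        r = P.sum(axis=1)
        std = res.scores.to_numpy() / res.eigenvalues**0.5  # standard coords
        gram = (std * r[:, None]).T @ std
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sq.correspondence_analysis(np.array([[1.0, 0.0], [2.0, 0.0]]))


class TestHClust:
    def test_identical_lines_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        tree = sq.hclust(X, labels=["a", "b", "c"])
        assert tree.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_upgma_example(self):
        # d(A,B)=1, d(A,C)=d(B,C)=4 -> ((A,B),C) at node heights 0.5 and 2.0
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        tree = sq.hclust(D, precomputed=True, labels=["A", "B", "C"])
        assert np.allclose(tree.heights, [0.5, 2.0])
        newick = tree.to_newick()
        assert "A:0.5,B:0.5" in newick or "B:0.5,A:0.5" in newick
        assert "C:2" in newick

    def test_upgma_heights_non_decreasing(self, random_matrix):
        tree = sq.hclust(random_matrix)
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_permutation_equivariance(self, random_matrix):
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(random_matrix))
        t1 = sq.hclust(random_matrix)
        t2 = sq.hclust(random_matrix.iloc[perm])
        assert np.allclose(np.sort(t1.heights), np.sort(t2.heights))
        # flat 2-cluster memberships agree after relabeling
        c1 = t1.cut(2)
        c2 = t2.cut(2)
        pairs1 = {
            frozenset((a, b))
            for a in c1
            for b in c1
            if a < b and c1[a] == c1[b]
        }
        pairs2 = {
            frozenset((a, b))
            for a in c2
            for b in c2
            if a < b and c2[a] == c2[b]
        }
        assert pairs1 == pairs2

    def test_newick_parses_with_dendropy(self, random_matrix):
        dendropy = pytest.importorskip("dendropy")
        tree = sq.hclust(random_matrix)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == len(random_matrix)
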