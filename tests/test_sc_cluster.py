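"""Single-cell QC, TF-IDF selection, Ward clustering, DE and validity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind
from sklearn.metrics import adjusted_rand_score

from neoclust.sc_cluster import (
    CountMatrix,
    EmptyMatrixError,
    ScQcParams,
    de_one_vs_rest,
    dunn_index,
    log_transform,
    qc_filter,
    select_top,
    separation_matrix,
    tfidf_gene_scores,
    ward_cluster,
)
from neoclust.synthetic_data import gen_counts

def toy_matrix(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"Gene{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return CountMatrix(counts=counts, gene_ids=tuple(genes), cell_ids=tuple(cells))


# --- brute-force oracles (tests only) --------------------------------------


def tfidf_oracle(m):
    n_genes, n_cells = m.counts.shape
    scores = np.zeros(n_genes)
    for g in range(n_genes):
        n_expr = sum(1 for c in range(n_cells) if m.counts[g, c] > 0)
        idf = np.log(n_cells / (1 + n_expr))
        acc = 0.0
        for c in range(n_cells):
            tf = m.counts[g, c] / m.counts[:, c].sum()
            acc += tf * idf
        scores[g] = acc / n_cells
    return scores


def dunn_oracle(X, labels):
    labels = np.asarray(labels)
    ks = np.unique(labels)
    inter = np.inf
    intra = 0.0
    for i, a in enumerate(ks):
        pa = X[labels == a]
        for j, b in enumerate(ks):
            pb = X[labels == b]
            for u in pa:
                for v in pb:
                    d = float(np.linalg.norm(u - v))
                    if a == b:
                        intra = max(intra, d)
                    elif i < j:
                        inter = min(inter, d)
    return inter / intra


def separation_oracle(X, labels):
    labels = np.asarray(labels)
    ks = np.unique(labels)
    mat = np.zeros((len(ks), len(ks)))
    for i, a in enumerate(ks):
        for j, b in enumerate(ks):
            if i == j:
                continue
            mat[i, j] = min(
                float(np.linalg.norm(u - v))
                for u in X[labels == a]
                for v in X[labels == b]
            )
    return mat


class TestQcFilter:
    def test_planted_failures_removed(self):
        m, truth = gen_counts(
            n_genes=900, n_cells=60, k=2, seed=0,
            n_qc_fail_low=3, n_qc_fail_mito=3,
        )
        filtered, attrition = qc_filter(m)
        removed = dict(attrition)
        assert removed["cells_gene_count"] >= 3
        assert removed["cells_mito_frac"] >= 1
        assert filtered.n_cells <= 60 - 6
        # the surviving cells are exactly the non-planted ones
        planted = set(list(m.cell_ids)[:6])
        assert planted.isdisjoint(filtered.cell_ids)

    def test_low_support_gene_removed(self):
        counts = np.ones((3, 6), dtype=int) * 5
        counts[2, :] = 0
        counts[2, 0] = 1  # gene expressed in a single cell
        m = toy_matrix(counts)
        p = ScQcParams(min_cells_per_gene=3, min_genes_per_cell=2,
                       max_genes_per_cell=10_000, mito_max_frac=0.30,
                       ribo_min_frac=0.0)
        filtered, _ = qc_filter(m, p)
        assert "Gene2" not in filtered.gene_ids

    def test_high_mito_cell_removed(self):
        counts = np.ones((10, 4), dtype=int)
        counts[0, 1] = 50  # mito gene dominates cell 1
        m = toy_matrix(counts, genes=["mt-1"] + [f"Gene{i}" for i in range(9)])
        p = ScQcParams(min_cells_per_gene=1, min_genes_per_cell=2,
                       max_genes_per_cell=100, mito_max_frac=0.30, ribo_min_frac=0.0)
        filtered, _ = qc_filter(m, p)
        assert "c1" not in filtered.cell_ids
        assert filtered.n_cells == 3

    def test_low_ribo_cell_removed(self):
        counts = np.full((10, 3), 4, dtype=int)
        counts[0, 2] = 0  # cell 2 has no ribosomal counts
        genes = ["Rps1"] + [f"Gene{i}" for i in range(9)]
        p = ScQcParams(min_cells_per_gene=1, min_genes_per_cell=2,
                       max_genes_per_cell=100, mito_max_frac=1.0, ribo_min_frac=0.05)
        filtered, _ = qc_filter(toy_matrix(counts, genes=genes), p)
        assert "c2" not in filtered.cell_ids

    def test_refiltering_is_noop(self):
        m, _ = gen_counts(n_genes=900, n_cells=50, k=2, seed=1)
        once, _ = qc_filter(m)
        twice, attrition = qc_filter(once)
        assert twice.counts.shape == once.counts.shape
        assert all(n == 0 for _, n in attrition)

    def test_empty_result_raises_with_attrition(self):
        counts = np.ones((5, 3), dtype=int)  # every cell expresses 5 genes
        with pytest.raises(EmptyMatrixError) as exc:
            qc_filter(toy_matrix(counts))  # default min 500 genes per cell
        assert dict(exc.value.attrition)["cells_gene_count"] == 3


class TestLogTransform:
    def test_reference_values(self):
        m = toy_matrix([[0, 1, 7]])
        assert log_transform(m).tolist() == [[0.0, 1.0, 3.0]]


class TestTfIdf:
    def test_matches_brute_force_oracle(self, rng):
        counts = rng.poisson(2.0, size=(20, 30)) + (rng.random((20, 30)) < 0.1)
        counts[:, counts.sum(axis=0) == 0] += 1
        m = toy_matrix(counts.astype(int))
        got = tfidf_gene_scores(m)
        assert np.abs(got.to_numpy() - tfidf_oracle(m)).max() < 1e-10

    def test_ubiquitous_gene_scores_negative(self):
        counts = np.ones((4, 10), dtype=int)
        counts[0] = 5  # expressed in every cell
        scores = tfidf_gene_scores(toy_matrix(counts))
        assert (scores < 0).all()  # IDF = log(N/(N+1)) < 0 for all-present genes

    def test_rare_strong_gene_ranks_top(self):
        # one gene expressed strongly in a single cell of a small matrix
        counts = np.array(
            [
                [5, 5, 5, 5],
                [4, 6, 5, 5],
                [0, 0, 40, 0],
                [5, 5, 5, 5],
                [6, 4, 5, 5],
            ]
        )
        scores = tfidf_gene_scores(toy_matrix(counts))
        assert scores.idxmax() == "Gene2"

    def test_select_top_deterministic_tie_break(self):
        scores = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0}, name="tfidf")
        assert select_top(scores, 2) == ["c", "a"]


class TestWardCluster:
    def test_separated_blobs_recovered(self, rng):
        a = rng.normal(0, 0.2, size=(30, 5))
        b = rng.normal(4, 0.2, size=(25, 5))
        X = np.vstack([a, b])
        labels = ward_cluster(X, k=2)
        truth = [0] * 30 + [1] * 25
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(6, 3))
        labels = ward_cluster(X, k=6)
        assert len(set(labels)) == 6

    def test_permutation_invariance(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.3, size=(20, 4)), rng.normal(3, 0.3, size=(20, 4))]
        )
        perm = rng.permutation(len(X))
        l1 = ward_cluster(X, k=2)
        l2 = ward_cluster(X[perm], k=2)
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(rng.normal(size=(5, 2)), k=1)
        with pytest.raises(ValueError):
            ward_cluster(rng.normal(size=(3, 2)), k=5)


class TestDifferentialExpression:
    def test_flat_gene_not_significant(self, rng):
        logm = rng.normal(1.0, 0.5, size=(5, 60))
        labels = np.repeat([1, 2], 30)
        de = de_one_vs_rest(logm, labels)
        assert not de["significant"].any()

    def test_planted_marker_detected(self, rng):
        logm = rng.normal(1.0, 0.5, size=(10, 100))
        labels = np.repeat([1, 2], 50)
        logm[3, labels == 1] += 3.0  # log2 shift of 3 for cluster 1
        de = de_one_vs_rest(logm, labels, gene_ids=[f"g{i}" for i in range(10)])
        hit = de[(de.cluster == 1) & (de.gene == "g3")].iloc[0]
        assert hit.significant
        assert hit.log2_fc == pytest.approx(3.0, abs=0.5)

    def test_welch_statistic_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 2.5, 4.0, 7.0])
        logm = np.vstack([np.concatenate([a, b])])
        de = de_one_vs_rest(logm, [1, 1, 1, 1, 2, 2, 2, 2])
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(t_hand), df_hand)
        assert de[de.cluster == 1].iloc[0].p_value == pytest.approx(p_hand, rel=1e-12)

    def test_zero_variance_equal_means_p_one(self):
        logm = np.ones((1, 8))
        de = de_one_vs_rest(logm, [1, 1, 1, 1, 2, 2, 2, 2])
        assert (de.p_value == 1.0).all()

    def test_gene_order_invariance(self, rng):
        logm = rng.normal(size=(6, 40))
        labels = np.repeat([1, 2], 20)
        de1 = de_one_vs_rest(logm, labels, gene_ids=list("abcdef"))
        de2 = de_one_vs_rest(logm[::-1], labels, gene_ids=list("fedcba"))
        merged = de1.merge(de2, on=["cluster", "gene"], suffixes=("_a", "_b"))
        assert np.allclose(merged.p_value_a, merged.p_value_b)


class TestClusterValidity:
    def test_dunn_hand_geometry(self):
        # two pairs of points: intra-diameter 0.1, inter-distance 1.0
        X = np.array([[0.0, 0.0], [0.1, 0.0], [1.1, 0.0], [1.2, 0.0]])
        labels = [1, 1, 2, 2]
        assert dunn_index(X, labels) == pytest.approx(1.0 / 0.1)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        labels = rng.integers(1, 4, size=50)
        assert dunn_index(X, labels) == pytest.approx(
            dunn_oracle(X, labels), abs=1e-10
        )
        got = separation_matrix(X, labels).to_numpy()
        assert np.abs(got - separation_oracle(X, labels)).max() < 1e-10

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(30, 2))
        labels = rng.integers(1, 3, size=30)
        d1 = dunn_index(X, labels)
        d2 = dunn_index(X * 7.3, labels)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_separation_matrix_symmetric_zero_diagonal(self, rng):
        X = rng.normal(size=(20, 2))
        labels = rng.integers(1, 4, size=20)
        mat = separation_matrix(X, labels).to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_all_singletons_undefined(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            dunn_index(X, [1, 2])
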