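"""Single-cell RNA-seq clustering stage.

QC filtering of a gene × cell UMI matrix, log2(x+1) transform, TF-IDF
ranking of informative genes (cells as documents, genes as terms), Ward
hierarchical clustering on the selected genes, one-vs-rest Welch t-test
differential expression, and cluster-validity diagnostics (Dunn index
and pairwise separation matrix).

QC defaults: genes expressed in fewer than 10 cells are dropped; cells
expressing fewer than 500 or more than 6000 genes, cells with more than
30% mitochondrial UMIs, and cells with less than 5% ribosomal-protein
UMIs are excluded.  Cell filters are applied before the gene filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from scipy.stats import ttest_ind

logger = logging.getLogger(__name__)

MITO_PATTERN = r"^mt-"
RIBO_PATTERN = r"^(Rps|Rpl)"

#: differential-expression significance cut-offs
DE_LOG2FC_CUTOFF = 2.0
DE_P_CUTOFF = 0.01


@dataclass(frozen=True)
class ScQcParams:
    """Quality-control thresholds for cells and genes."""

    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 6000
    mito_max_frac: float = 0.30
    ribo_min_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_genes_per_cell < self.max_genes_per_cell):
            raise ValueError("need 0 < min_genes_per_cell < max_genes_per_cell")
        for f in (self.mito_max_frac, self.ribo_min_frac):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class CountMatrix:
    """Genes × cells UMI count matrix with per-gene mito/ribo flags."""

    counts: np.ndarray  # (n_genes, n_cells) non-negative ints
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    mito: np.ndarray = field(default=None)  # bool per gene
    ribo: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape inconsistent with gene/cell id lists")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        for name, pattern in (("mito", MITO_PATTERN), ("ribo", RIBO_PATTERN)):
            flags = getattr(self, name)
            if flags is None:
                rx = re.compile(pattern)
                flags = np.array([bool(rx.match(g)) for g in self.gene_ids])
            else:
                flags = np.asarray(flags, dtype=bool)
                if flags.shape[0] != len(self.gene_ids):
                    raise ValueError(f"{name} flag length mismatch")
            object.__setattr__(self, name, flags)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, gene_mask: np.ndarray | None = None,
               cell_mask: np.ndarray | None = None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=tuple(np.array(self.gene_ids)[gm]),
            cell_ids=tuple(np.array(self.cell_ids)[cm]),
            mito=self.mito[gm],
            ribo=self.ribo[gm],
        )

    def to_anndata(self):
        """Bridge to an AnnData (cells × genes) for interop with scanpy."""
        import anndata as ad

        adata = ad.AnnData(X=self.counts.T.astype(np.float32))
        adata.obs_names = list(self.cell_ids)
        adata.var_names = list(self.gene_ids)
        adata.var["mito"] = self.mito
        adata.var["ribo"] = self.ribo
        return adata


class EmptyMatrixError(RuntimeError):
    """QC removed every cell or gene; carries a stage attrition report."""

    def __init__(self, attrition: list[tuple[str, int]]):
        self.attrition = attrition
        lines = ", ".join(f"{stage}: -{n}" for stage, n in attrition)
        super().__init__(f"QC left an empty matrix ({lines})")


def qc_filter(
    m: CountMatrix, p: ScQcParams = ScQcParams()
) -> tuple[CountMatrix, list[tuple[str, int]]]:
    """Apply cell QC then gene QC; returns the filtered matrix and attrition.

    Cells are filtered first (gene-count range, then mitochondrial
    fraction, then ribosomal fraction, all computed on the unfiltered
    gene set); genes are then filtered by minimum cell support on the
    surviving cells.  The gene filter depends only on the surviving
    cells, so one pass reaches its fixed point.
    """
    attrition: list[tuple[str, int]] = []
    genes_per_cell = (m.counts > 0).sum(axis=0)
    keep = (genes_per_cell >= p.min_genes_per_cell) & (
        genes_per_cell <= p.max_genes_per_cell
    )
    attrition.append(("cells_gene_count", int((~keep).sum())))

    totals = m.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.counts[m.mito].sum(axis=0) / totals, 0.0)
        ribo_frac = np.where(totals > 0, m.counts[m.ribo].sum(axis=0) / totals, 0.0)
    drop = keep & (mito_frac > p.mito_max_frac)
    attrition.append(("cells_mito_frac", int(drop.sum())))
    keep &= ~drop
    drop = keep & (ribo_frac < p.ribo_min_frac)
    attrition.append(("cells_ribo_frac", int(drop.sum())))
    keep &= ~drop

    cells_kept = m.subset(cell_mask=keep)
    gene_support = (cells_kept.counts > 0).sum(axis=1)
    gene_keep = gene_support >= p.min_cells_per_gene
    attrition.append(("genes_min_cells", int((~gene_keep).sum())))
    out = cells_kept.subset(gene_mask=gene_keep)
    for stage, n in attrition:
        if n:
            logger.info("qc_filter %s removed %d", stage, n)
    if out.n_cells == 0 or out.n_genes == 0:
        raise EmptyMatrixError(attrition)
    return out, attrition


def log_transform(m: CountMatrix | np.ndarray) -> np.ndarray:
    """Elementwise log2(x + 1)."""
    x = m.counts if isinstance(m, CountMatrix) else np.asarray(m)
    return np.log2(x.astype(float) + 1.0)


def tfidf_gene_scores(m: CountMatrix) -> pd.Series:
    """Average TF-IDF score per gene, cells as documents.

    TF(g, c) = count(g, c) / total(c); IDF(g) = log(N / (1 + n_cells
    expressing g)); the gene score is the mean of TF·IDF over cells.
    Ubiquitous genes get a negative IDF and fall to the bottom of the
    ranking.
    """
    totals = m.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run qc_filter first")
    tf = m.counts / totals[None, :]
    n_expressing = (m.counts > 0).sum(axis=1)
    if np.any(n_expressing == 0):
        raise ValueError("genes expressed in zero cells; run qc_filter first")
    idf = np.log(m.n_cells / (1.0 + n_expressing))
    scores = (tf * idf[:, None]).mean(axis=1)
    return pd.Series(scores, index=list(m.gene_ids), name="tfidf")


def select_top(scores: pd.Series, n: int = 500) -> list[str]:
    """Deterministic top-n gene ids by score, ties broken lexicographically."""
    df = scores.rename_axis("gene").reset_index()
    df = df.sort_values(["tfidf", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].head(n).tolist()


def ward_cluster(features: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative Ward clustering of cells; labels 1..k.

    ``features`` is cells × selected-genes (e.g. log-transformed
    expression of top TF-IDF genes); Euclidean distances, deterministic.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} cells")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def de_one_vs_rest(
    logm: np.ndarray,
    labels: Sequence[int],
    gene_ids: Sequence[str] | None = None,
    log2fc_cutoff: float = DE_LOG2FC_CUTOFF,
    p_cutoff: float = DE_P_CUTOFF,
) -> pd.DataFrame:
    """One-vs-rest Welch t-tests per cluster on log2-transformed values.

    ``logm`` is genes × cells.  log2 fold change is the difference of
    in-cluster and rest means (already on log2 scale).  A gene is
    significant for a cluster when |log2FC| >= 2 and p < 0.01.  Genes
    with zero variance on both sides and equal means get p = 1.
    """
    X = np.asarray(logm, dtype=float)
    labels = np.asarray(labels)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(X.shape[0])]
    frames = []
    for k in np.unique(labels):
        inside = X[:, labels == k]
        rest = X[:, labels != k]
        if inside.shape[1] < 2 or rest.shape[1] < 2:
            raise ValueError(f"cluster {k}: need >=2 cells on each side")
        lfc = inside.mean(axis=1) - rest.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = ttest_ind(inside, rest, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
        # zero variance both sides: t undefined; equal means -> p = 1
        pvals = np.where(np.isnan(pvals), np.where(lfc == 0, 1.0, 0.0), pvals)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": k,
                    "gene": list(gene_ids),
                    "log2_fc": lfc,
                    "p_value": pvals,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = (out["log2_fc"].abs() >= log2fc_cutoff) & (
        out["p_value"] < p_cutoff
    )
    return out


def separation_matrix(points: np.ndarray, labels: Sequence[int]) -> pd.DataFrame:
    """k × k matrix of minimum pairwise distances between clusters.

    Entry (i, j) is the single-linkage (minimum Euclidean) distance
    between clusters i and j; the diagonal is 0.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("need at least 2 clusters")
    mat = np.zeros((ks.size, ks.size))
    for a in range(ks.size):
        for b in range(a + 1, ks.size):
            dmin = cdist(X[labels == ks[a]], X[labels == ks[b]]).min()
            mat[a, b] = mat[b, a] = dmin
    return pd.DataFrame(mat, index=ks, columns=ks)


def dunn_index(points: np.ndarray, labels: Sequence[int]) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter.

    Distances are Euclidean; a singleton cluster has diameter 0.  If
    every cluster has zero diameter the index is undefined and an error
    is raised.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("need at least 2 clusters")
    diameters = []
    for k in ks:
        pts = X[labels == k]
        diameters.append(float(pdist(pts).max()) if pts.shape[0] > 1 else 0.0)
    max_diam = max(diameters)
    if max_diam == 0:
        raise ValueError("all clusters have zero diameter; Dunn index undefined")
    sep = separation_matrix(X, labels).to_numpy()
    min_sep = sep[np.triu_indices(ks.size, k=1)].min()
    return float(min_sep / max_diam)


def cluster_pipeline(
    m: CountMatrix,
    k: int = 8,
    n_top_genes: int = 500,
    qc: ScQcParams = ScQcParams(),
) -> dict:
    """Convenience: QC → log transform → TF-IDF selection → Ward → DE/Dunn."""
    filtered, attrition = qc_filter(m, qc)
    logm = log_transform(filtered)
    scores = tfidf_gene_scores(filtered)
    top = select_top(scores, n=min(n_top_genes, filtered.n_genes))
    idx = [filtered.gene_ids.index(g) for g in top]
    feats = logm[idx, :].T  # cells x genes
    labels = ward_cluster(feats, k=k)
    de = de_one_vs_rest(logm, labels, gene_ids=filtered.gene_ids)
    return {
        "matrix": filtered,
        "attrition": attrition,
        "labels": labels,
        "top_genes": top,
        "de": de,
        "dunn": dunn_index(feats, labels),
        "separation": separation_matrix(feats, labels),
    }
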