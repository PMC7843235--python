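"""Synthetic inputs for every pipeline stage.

Generators are pure functions of (spec, seed): the same seed reproduces
the same tables bit-for-bit.  They emulate the structure of the study
data — a bivariate mutant/WT IC50 landscape with a dominant
near-diagonal cloud plus a low-affinity TRMN-enriched component, SNV and
protein tables, and UMI count matrices with planted cell clusters and
marker genes — without claiming realistic peptide–MHC motifs; IC50
values are drawn, not predicted.

Landscape components draw (mutant, WT) IC50 pairs from a bivariate
``normal`` (in nM, truncated below at ``IC50_FLOOR_NM``) or
``lognormal`` distribution.  The named default ``fabf_like_spec``
mirrors the reported cluster geometry of the training tumor with
truncated-normal components: the clustering stage fits axis-aligned
Gaussians to the centered/scaled raw nM values, so the planted
components are Gaussian on that same scale, which keeps the planted
structure identifiable by the model family that must recover it
(heavily skewed components are not).  Means sit at the centers of the
printed per-cluster IC50 ranges and standard deviations put the printed
extremes at ±2σ (high-affinity 2–157 nM, mid 44–2,759 nM, low-affinity
17,930–39,661 nM); weights follow the forced cluster totals 41/91/13 of
n = 145 labeled neoepitopes; per-component TRMN probabilities follow
the strict percentages 55/4/14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sc_cluster import CountMatrix

#: lower truncation for IC50 draws, nM
IC50_FLOOR_NM = 1e-2

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ComponentSpec:
    """One bivariate component of the affinity landscape.

    For ``dist='normal'`` the loc/scale are the mean and SD in nM (draws
    truncated below at ``IC50_FLOOR_NM``); for ``dist='lognormal'`` they
    are the median in nM and the log-scale SD.  ``rho`` correlates the
    mutant and WT draws on the underlying (normal or log) scale.
    """

    name: str
    weight: float
    mut_loc: float
    mut_scale: float
    wt_loc: float
    wt_scale: float
    rho: float = 0.0
    trmn_prob: float = 0.0
    dist: str = "normal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.trmn_prob <= 1.0):
            raise ValueError("trmn_prob must lie in [0, 1]")
        if abs(self.rho) > 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.weight <= 0:
            raise ValueError("component weight must be positive")
        if self.dist not in ("normal", "lognormal"):
            raise ValueError("dist must be 'normal' or 'lognormal'")


@dataclass(frozen=True)
class LandscapeSpec:
    """A mixture of bivariate affinity components with TRMN labels."""

    n_points: int
    components: tuple[ComponentSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {total}")


def fabf_like_spec(n_points: int = 145, seed: int = 0) -> LandscapeSpec:
    """The shipped default landscape mimicking the training tumor."""
    return LandscapeSpec(
        n_points=n_points,
        seed=seed,
        components=(
            # dominant near-diagonal cloud of mid-range affinities:
            # equal mutant/WT marginals keep it symmetric about the diagonal
            ComponentSpec(
                name="bulk_diagonal", weight=91 / 145,
                mut_loc=1400.0, mut_scale=680.0,
                wt_loc=1400.0, wt_scale=680.0,
                trmn_prob=0.04,
            ),
            # strong mutant binders whose WT counterpart binds poorly
            ComponentSpec(
                name="high_affinity", weight=13 / 145,
                mut_loc=80.0, mut_scale=39.0,
                wt_loc=9000.0, wt_scale=2000.0,
                trmn_prob=0.14,
            ),
            # low-affinity TRMN-enriched component
            ComponentSpec(
                name="low_affinity", weight=41 / 145,
                mut_loc=28800.0, mut_scale=5400.0,
                wt_loc=28800.0, wt_scale=5400.0,
                trmn_prob=0.55,
            ),
        ),
    )


def _random_peptide(rng: np.random.Generator, k: int = 9) -> str:
    return "".join(rng.choice(_AA, size=k))


def _draw_pair(rng: np.random.Generator, c: ComponentSpec) -> tuple[float, float]:
    cov = np.array(
        [
            [c.mut_scale**2, c.rho * c.mut_scale * c.wt_scale],
            [c.rho * c.mut_scale * c.wt_scale, c.wt_scale**2],
        ]
    )
    if c.dist == "lognormal":
        z = rng.multivariate_normal([math.log(c.mut_loc), math.log(c.wt_loc)], cov)
        pair = np.exp(z)
        return float(max(pair[0], IC50_FLOOR_NM)), float(max(pair[1], IC50_FLOOR_NM))
    # truncation below the floor by rejection, so no point mass at the floor
    for _ in range(1000):
        pair = rng.multivariate_normal([c.mut_loc, c.wt_loc], cov)
        if pair.min() > IC50_FLOOR_NM:
            return float(pair[0]), float(pair[1])
    raise RuntimeError(f"component {c.name}: truncation rejected 1000 draws")


def gen_landscape(spec: LandscapeSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a labeled affinity table from a landscape spec.

    Returns a DataFrame with columns snv_id, allele, peptide,
    ic50_mut_nM, ic50_wt_nM, verified_epitope, label and the
    ground-truth ``component`` retained for recovery tests.  IC50 draws
    are truncated below at ``IC50_FLOOR_NM``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    weights = np.array([c.weight for c in spec.components])
    comp_idx = rng.choice(len(spec.components), size=spec.n_points, p=weights)
    rows = []
    for i, ci in enumerate(comp_idx):
        c = spec.components[ci]
        mut, wt = _draw_pair(rng, c)
        label = "TRMN" if rng.random() < c.trmn_prob else "non-TRMN"
        rows.append(
            {
                "snv_id": f"snv{i + 1:04d}",
                "allele": "H2-Kb" if rng.random() < 0.5 else "H2-Db",
                "peptide": _random_peptide(rng),
                "ic50_mut_nM": mut,
                "ic50_wt_nM": wt,
                "verified_epitope": False,
                "label": label,
                "component": c.name,
            }
        )
    return pd.DataFrame(rows)


def gen_snv_table(
    n_snvs: int = 20, protein_len: int = 80, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Random SNV records plus matching protein sequences keyed by gene."""
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    rows = []
    for i in range(n_snvs):
        gene = f"Gene{i + 1}"
        seq = "".join(rng.choice(_AA, size=protein_len))
        pos = int(rng.integers(1, protein_len + 1))
        ref = seq[pos - 1]
        alt = str(rng.choice([a for a in _AA if a != ref]))
        proteins[gene] = seq
        rows.append(
            {
                "snv_id": f"snv{i + 1:04d}",
                "gene": gene,
                "protein_pos": pos,
                "ref_aa": ref,
                "alt_aa": alt,
                "expressed": True,
                "validated": bool(rng.random() < 0.85),
            }
        )
    return pd.DataFrame(rows), proteins


def gen_counts(
    n_genes: int = 300,
    n_cells: int = 240,
    k: int = 3,
    marker_effect: float = 3.0,
    seed: int = 0,
    n_markers_per_cluster: int = 10,
    n_mito: int = 5,
    n_ribo: int = 12,
    base_mean: float = 2.0,
    dispersion: float = 0.5,
    n_qc_fail_low: int = 0,
    n_qc_fail_mito: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Negative-binomial UMI counts with k planted cell clusters.

    Marker genes of each cluster have their mean up-shifted by
    2**marker_effect in that cluster's cells (a log2 shift of
    ``marker_effect``); mito- ("mt-") and ribo-prefixed ("Rps/Rpl")
    genes are included so QC paths are exercised.  Optionally plants
    cells that must fail QC: ``n_qc_fail_low`` cells expressing almost
    no genes and ``n_qc_fail_mito`` cells with predominantly
    mitochondrial counts.  Returns the matrix and the ground-truth
    cluster label per cell (0 for planted QC failures).
    """
    if marker_effect < 0 or k < 1:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    gene_ids = (
        [f"mt-G{i}" for i in range(n_mito)]
        + [f"Rps{i}" if i % 2 == 0 else f"Rpl{i}" for i in range(n_ribo)]
        + [f"Gene{i:04d}" for i in range(n_genes - n_mito - n_ribo)]
    )
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    truth = rng.integers(1, k + 1, size=n_cells)

    gene_means = rng.gamma(shape=2.0, scale=base_mean / 2.0, size=n_genes) + 0.05
    # keep mito modest; give ribo genes ~8% of total counts regardless of
    # matrix width so ordinary cells clear the 5% ribo-fraction floor
    gene_means[:n_mito] = base_mean
    gene_means[n_mito : n_mito + n_ribo] = 0.08 * n_genes * base_mean / n_ribo
    mean_mat = np.tile(gene_means[:, None], (1, n_cells))

    ordinary = np.arange(n_mito + n_ribo, n_genes)
    markers = rng.permutation(ordinary)[: k * n_markers_per_cluster]
    marker_sets = markers.reshape(k, n_markers_per_cluster)
    for j in range(k):
        mean_mat[np.ix_(marker_sets[j], truth == j + 1)] *= 2.0**marker_effect

    # NB via gamma-Poisson: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean_mat / shape)
    counts = rng.poisson(lam)

    for i in range(n_qc_fail_low):  # nearly-empty cells
        counts[:, i] = 0
        expressed = rng.permutation(n_genes)[:5]
        counts[expressed, i] = 1
        truth[i] = 0
    for i in range(n_qc_fail_low, n_qc_fail_low + n_qc_fail_mito):
        counts[:n_mito, i] = counts[:, i].sum()  # mito dominates totals
        truth[i] = 0

    m = CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=tuple(gene_ids),
        cell_ids=tuple(cell_ids),
    )
    return m, truth
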