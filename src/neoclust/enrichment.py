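"""Cluster composition and density-position reports.

Given mixture memberships and TRMN/non-TRMN labels, tally per-cluster
composition under two regimes: *strict* (only points inside their MAP
component's confidence ellipse) and *forced* (every labeled point counts
toward its MAP component).  A second report locates each cluster mean in
the 1-D density of scaled mutant IC50 values, quantifying whether a
cluster sits in the sparse low-affinity tail or near the global mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .mixture_model import Membership, MixtureFit

MODES = ("strict", "forced")


@dataclass(frozen=True)
class ClusterCounts:
    """Labeled composition of one cluster."""

    cluster: int
    n_trmn: int
    n_non: int

    @property
    def pct_trmn(self) -> int | None:
        """Percent TRMN rounded half-up to the nearest integer; None if empty."""
        total = self.n_trmn + self.n_non
        if total == 0:
            return None
        return int(math.floor(100.0 * self.n_trmn / total + 0.5))


@dataclass(frozen=True)
class ClusterReport:
    mode: str
    conf_level: float
    clusters: tuple[ClusterCounts, ...]

    @property
    def total_labeled(self) -> int:
        return sum(c.n_trmn + c.n_non for c in self.clusters)


def tally(
    memberships: Sequence[Membership],
    labels: Mapping[str, str],
    mode: str = "forced",
    n_clusters: int | None = None,
) -> ClusterReport:
    """Tally TRMN/non-TRMN counts per cluster.

    Points with label ``unknown`` (or absent from ``labels``) are
    excluded.  In ``strict`` mode only points inside their confidence
    ellipse are counted; in ``forced`` mode every labeled point counts.
    Empty clusters report a percentage of None rather than 0.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if n_clusters is None:
        n_clusters = max((m.map_cluster for m in memberships), default=0)
    counts = {k: [0, 0] for k in range(1, n_clusters + 1)}
    conf = memberships[0].conf_level if memberships else 0.95
    for m in memberships:
        lab = labels.get(m.point_id, "unknown")
        if lab not in ("TRMN", "non-TRMN"):
            continue
        if mode == "strict" and not m.in_ellipse:
            continue
        counts[m.map_cluster][0 if lab == "TRMN" else 1] += 1
    return ClusterReport(
        mode=mode,
        conf_level=conf,
        clusters=tuple(
            ClusterCounts(cluster=k, n_trmn=c[0], n_non=c[1])
            for k, c in sorted(counts.items())
        ),
    )


def density_position(
    scaled_mut: Sequence[float] | np.ndarray,
    cluster_means_x: Sequence[float] | np.ndarray,
    grid_size: int = 2048,
) -> list[float]:
    """Ratio of mutant-IC50 density at each cluster mean to the global peak.

    A Gaussian kernel density (Scott's-rule bandwidth) is fitted to the
    scaled mutant IC50 values; each cluster's x-mean is scored as
    density(mean) / max density.  Ratios near 1 place a cluster at the
    global mode; small ratios place it in a sparse tail.
    """
    x = np.asarray(scaled_mut, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 points for a density profile, got {x.size}")
    kde = gaussian_kde(x)
    span = x.max() - x.min()
    grid = np.linspace(x.min() - 0.1 * span, x.max() + 0.1 * span, grid_size)
    peak = float(kde(grid).max())
    return [float(kde(np.atleast_1d(m))[0]) / peak for m in cluster_means_x]


def report_lines(report: ClusterReport) -> list[str]:
    """Human-readable rendering of a cluster report."""
    out = [f"# mode={report.mode} conf_level={report.conf_level}"]
    for c in report.clusters:
        pct = "NA" if c.pct_trmn is None else f"{c.pct_trmn}%"
        out.append(
            f"cluster {c.cluster}: {c.n_trmn} TRMNs, {c.n_non} non-TRMNs ({pct} TRMNs)"
        )
    return out


def plot_clusters(
    fit: MixtureFit,
    points: np.ndarray,
    labels: Sequence[str] | None = None,
    conf_level: float = 0.95,
    path: str | None = None,
):
    """Scatter of scaled affinity points with fitted confidence ellipses.

    Axis-aligned ellipses are drawn per component at ``conf_level``;
    returns the matplotlib figure (also saved to ``path`` if given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy.stats import chi2

    fig, ax = plt.subplots(figsize=(6, 6))
    X = np.asarray(points, dtype=float)
    if labels is None:
        labels = ["unknown"] * len(X)
    colors = {"TRMN": "tab:red", "non-TRMN": "0.6", "unknown": "0.8"}
    for lab in ("unknown", "non-TRMN", "TRMN"):
        mask = np.array([l == lab for l in labels])
        if mask.any():
            ax.scatter(X[mask, 0], X[mask, 1], s=12, c=colors[lab], label=lab)
    r2 = chi2.ppf(conf_level, df=2)
    for k in range(fit.G):
        w = 2.0 * np.sqrt(r2 * fit.variances[k, 0])
        h = 2.0 * np.sqrt(r2 * fit.variances[k, 1])
        ax.add_patch(
            Ellipse(fit.means[k], width=w, height=h, fill=False, color=f"C{k}", lw=1.5)
        )
        ax.annotate(f"cluster {k + 1}", fit.means[k], color=f"C{k}")
    lim = np.array([X.min(), X.max()])
    ax.plot(lim, lim, "r-", lw=0.8)  # equal-affinity diagonal, DAI = 0
    ax.set_xlabel("scaled mutant IC50")
    ax.set_ylabel("scaled WT IC50")
    ax.legend(frameon=False, fontsize=8)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
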