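"""Parameterized finite Gaussian mixtures on the DAI plane.

Model-based clustering in the mclust tradition, restricted to the
axis-aligned (diagonal, orientation = I) covariance family.  Each
component covariance is decomposed as

    Sigma_k = lambda_k * diag(A_k),   det(A_k) = 1,

where the volume ``lambda`` and shape ``A`` may each be equal (E) or
variable (V) across components:

=====  ================  ==========================
model  covariance        free covariance parameters
=====  ================  ==========================
EII    lambda I          1
VII    lambda_k I        G
EEI    lambda diag(A)    d
VEI    lambda_k diag(A)  G + d - 1
EVI    lambda diag(A_k)  1 + G (d - 1)
VVI    lambda_k diag(A_k)  G d
=====  ================  ==========================

Models are fitted by EM from k-means++ starts, selected by BIC in the
larger-is-better convention BIC = 2 loglik - m log n, and yield both a
maximum-posterior (forced) assignment and a strict confidence-ellipse
membership via the Mahalanobis distance against a chi-square quantile.
External points are projected through the training scaling and the
fitted model without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2
from sklearn.cluster import kmeans_plusplus

from .affinity_dai import AffinityPair, ScalingParams, apply_scaling, points_to_array

MODELS = ("EII", "VII", "EEI", "VEI", "EVI", "VVI")

#: variance floor (scaled units squared) preventing singular components
VARIANCE_FLOOR = 1e-6

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateFitError(RuntimeError):
    """All requested fits failed or were degenerate."""


def n_cov_params(model: str, G: int, d: int = 2) -> int:
    """Free covariance parameters of a parameterization."""
    return {
        "EII": 1,
        "VII": G,
        "EEI": d,
        "VEI": G + d - 1,
        "EVI": 1 + G * (d - 1),
        "VVI": G * d,
    }[model]


def n_free_params(model: str, G: int, d: int = 2) -> int:
    """Total free parameters: weights (G−1) + means (G·d) + covariances."""
    return (G - 1) + G * d + n_cov_params(model, G, d)


@dataclass
class MixtureFit:
    """A fitted parameterized Gaussian mixture (diagonal family)."""

    model: str
    G: int
    weights: np.ndarray  # (G,)
    means: np.ndarray  # (G, d)
    variances: np.ndarray  # (G, d) diagonal covariances
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    seed: int
    n_restarts: int
    n_iter: int = 0
    variance_floored: bool = False
    # per-iteration loglik of the winning restart; diagnostic, not serialized
    loglik_history: list = field(default_factory=list, repr=False, compare=False)

    @property
    def bic(self) -> float:
        return bic(self, self.n_obs)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "G": self.G,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "n_iter": self.n_iter,
            "variance_floored": self.variance_floored,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        d = dict(d)
        for key in ("weights", "means", "variances"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class BicTable:
    """BIC values over the (model, G) grid; larger is better."""

    rows: list[tuple[str, int, float]]
    best: tuple[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty BIC table")
        self.best = max(self.rows, key=lambda r: r[2])[:2]

    def to_records(self) -> list[dict]:
        return [{"model": m, "G": g, "bic": b} for m, g, b in self.rows]


@dataclass(frozen=True)
class Membership:
    """Cluster membership of one point under a fitted mixture."""

    point_id: str
    map_cluster: int  # 1-based component index
    posterior: tuple[float, ...]
    in_ellipse: bool
    conf_level: float


def _log_density(X: np.ndarray, fit_means: np.ndarray, fit_vars: np.ndarray) -> np.ndarray:
    """Per-component diagonal-Gaussian log densities, shape (n, G)."""
    # (n, G, d) broadcast; d is 2 so memory is negligible
    diff = X[:, None, :] - fit_means[None, :, :]
    return -0.5 * (
        _LOG2PI * X.shape[1]
        + np.sum(np.log(fit_vars), axis=1)[None, :]
        + np.sum(diff**2 / fit_vars[None, :, :], axis=2)
    )


def _mstep_variances(model: str, W: np.ndarray, nk: np.ndarray, n: int) -> np.ndarray:
    """Constrained covariance M-step.

    ``W[k]`` holds the diagonal of the weighted scatter matrix of
    component k (sum of responsibilities times squared deviations).
    Returns per-component variance diagonals of shape (G, d) obeying the
    parameterization's equal/variable volume and shape constraints.
    """
    G, d = W.shape
    W = np.maximum(W, 1e-300)  # guard determinants of empty components
    if model == "VVI":
        return W / nk[:, None]
    if model == "EEI":
        return np.tile(W.sum(axis=0) / n, (G, 1))
    if model == "EII":
        return np.full((G, d), W.sum() / (n * d))
    if model == "VII":
        return np.tile((W.sum(axis=1) / (nk * d))[:, None], (1, d))
    if model == "EVI":
        dets = np.prod(W, axis=1) ** (1.0 / d)
        shapes = W / dets[:, None]  # det = 1 per component
        lam = dets.sum() / n
        return lam * shapes
    if model == "VEI":
        # alternate per-component volume and shared shape to a fixed point
        A = np.ones(d)
        lam = np.ones(G)
        for _ in range(50):
            lam = (W / A[None, :]).sum(axis=1) / (d * nk)
            A_new = (W / lam[:, None]).sum(axis=0)
            A_new = A_new / np.prod(A_new) ** (1.0 / d)
            if np.max(np.abs(A_new - A)) < 1e-12:
                A = A_new
                break
            A = A_new
        return lam[:, None] * A[None, :]
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _init_assignments(
    X: np.ndarray, G: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """Initial hard assignments for one EM restart.

    ``ward``: deterministic Ward-agglomeration cut on the coordinates
    (hierarchical initialization in the mclust tradition).
    ``ward_ns``: Ward cut on per-column normal scores (rank-based
    inverse-normal transform); density-equalizing, so clusters of very
    different spread — a tight high-affinity blob next to a diffuse
    low-affinity cloud — are not merged or split by raw distance alone.
    ``kmeanspp``: random k-means++ seeding with nearest-center
    assignment, for restart diversity.
    """
    if mode == "ward":
        from scipy.cluster.hierarchy import fcluster, linkage

        return fcluster(linkage(X, method="ward"), t=G, criterion="maxclust") - 1
    if mode == "ward_ns":
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.stats import norm, rankdata

        Z = norm.ppf(np.apply_along_axis(rankdata, 0, X) / (X.shape[0] + 1))
        return fcluster(linkage(Z, method="ward"), t=G, criterion="maxclust") - 1
    centers, _ = kmeans_plusplus(
        X, n_clusters=G, random_state=int(rng.integers(2**31 - 1))
    )
    dist = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    return np.argmin(dist, axis=1)


def _em_once(
    X: np.ndarray,
    model: str,
    G: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    init: str = "kmeanspp",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, bool, list]:
    n, d = X.shape
    assign = _init_assignments(X, G, rng, init)
    resp = np.zeros((n, G))
    resp[np.arange(n), assign] = 1.0
    # ensure no empty component at start
    resp += 1e-6
    resp /= resp.sum(axis=1, keepdims=True)

    loglik = -np.inf
    floored = False
    weights = np.full(G, 1.0 / G)
    means = np.zeros((G, d))
    variances = np.tile(np.var(X, axis=0), (G, 1))
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        # M-step
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        diff = X[:, None, :] - means[None, :, :]
        W = np.einsum("nk,nkd->kd", resp, diff**2)
        variances = _mstep_variances(model, W, nk, n)
        if np.any(variances < VARIANCE_FLOOR):
            variances = np.maximum(variances, VARIANCE_FLOOR)
            floored = True
        # E-step
        log_r = np.log(weights)[None, :] + _log_density(X, means, variances)
        norm = logsumexp(log_r, axis=1)
        new_loglik = float(norm.sum())
        history.append(new_loglik)
        resp = np.exp(log_r - norm[:, None])
        if np.abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return weights, means, variances, loglik, converged, it, floored, history


def em_fit(
    points: np.ndarray | Sequence[Sequence[float]],
    model: str = "VVI",
    G: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit one parameterized Gaussian mixture by EM, best of restarts.

    The first two restarts seed EM from deterministic hierarchical cuts
    (Ward on the coordinates, then Ward on per-column normal scores);
    remaining restarts use k-means++ centers.  The restart with the highest final
    log-likelihood wins.  The EM log-likelihood is monotone
    non-decreasing by construction; components whose variance collapses
    are floored at ``VARIANCE_FLOOR`` and the fit flagged.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array of shape (n, d)")
    n, d = X.shape
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if n < 2 * G:
        raise ValueError(f"need at least 2 observations per component: n={n}, G={G}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    inits = ["ward", "ward_ns"] + ["kmeanspp"] * max(0, n_restarts - 2)
    for init in inits[: max(1, n_restarts)]:
        res = _em_once(X, model, G, rng, tol, max_iter, init=init)
        # a restart that hit the variance floor is a singular solution;
        # prefer any non-degenerate restart over it regardless of loglik
        if best is None or (best[6], -best[3]) > (res[6], -res[3]):
            best = res
    assert best is not None
    weights, means, variances, loglik, converged, it, floored, history = best
    return MixtureFit(
        model=model,
        G=G,
        weights=weights,
        means=means,
        variances=variances,
        loglik=loglik,
        n_params=n_free_params(model, G, d),
        n_obs=n,
        converged=converged,
        seed=seed,
        n_restarts=n_restarts,
        n_iter=it,
        variance_floored=floored,
        loglik_history=history,
    )


def bic(fit: MixtureFit, n: int) -> float:
    """BIC = 2·loglik − m·log n (larger is better)."""
    return 2.0 * fit.loglik - fit.n_params * np.log(n)


def select_model(
    points: np.ndarray | Sequence[Sequence[float]],
    models: Iterable[str] = MODELS,
    G_range: Iterable[int] = range(1, 10),
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> tuple[MixtureFit, BicTable]:
    """Exhaustive (model, G) grid search, ranked by BIC.

    Grid cells with too few observations per component are skipped.  The
    returned fit maximizes BIC; the full table is kept for reporting.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    rows: list[tuple[str, int, float]] = []
    fits: dict[tuple[str, int], MixtureFit] = {}
    failures: list[str] = []
    for model in models:
        for G in G_range:
            if n < 2 * G:
                continue
            # derive a per-cell seed so the grid is deterministic but cells
            # do not share restart streams
            cell_seed = (seed * 1_000_003 + MODELS.index(model) * 101 + G) % (2**31 - 1)
            try:
                fit = em_fit(
                    X, model=model, G=G, seed=cell_seed, tol=tol,
                    max_iter=max_iter, n_restarts=n_restarts,
                )
            except (ValueError, FloatingPointError) as exc:
                failures.append(f"{model}/G={G}: {exc}")
                continue
            fits[(model, G)] = fit
            rows.append((model, G, bic(fit, n)))
    if not rows:
        raise DegenerateFitError("all fits failed: " + "; ".join(failures))
    # variance-floored fits are singular solutions (typically a spurious
    # near-singleton component); they get no vote in model selection
    # unless every fit is singular
    clean = [r for r in rows if not fits[(r[0], r[1])].variance_floored]
    table = BicTable(rows=clean if clean else rows)
    return fits[table.best], table


def membership(
    fit: MixtureFit,
    points: np.ndarray | Sequence[Sequence[float]],
    conf_level: float = 0.95,
    point_ids: Sequence[str] | None = None,
) -> list[Membership]:
    """Posterior (forced/MAP) and confidence-ellipse (strict) membership.

    A point is ``in_ellipse`` when its squared Mahalanobis distance to
    its MAP component is at most the chi-square(d) quantile at
    ``conf_level``.
    """
    X = np.asarray(points, dtype=float).reshape(-1, fit.means.shape[1])
    n, d = X.shape
    if n == 0:
        return []
    if point_ids is None:
        point_ids = [str(i) for i in range(n)]
    log_r = np.log(fit.weights)[None, :] + _log_density(X, fit.means, fit.variances)
    post = np.exp(log_r - logsumexp(log_r, axis=1)[:, None])
    map_k = np.argmax(post, axis=1)
    thresh = chi2.ppf(conf_level, df=d)
    diff = X - fit.means[map_k]
    maha2 = np.sum(diff**2 / fit.variances[map_k], axis=1)
    return [
        Membership(
            point_id=str(pid),
            map_cluster=int(k) + 1,
            posterior=tuple(float(v) for v in post[i]),
            in_ellipse=bool(maha2[i] <= thresh),
            conf_level=conf_level,
        )
        for i, (pid, k) in enumerate(zip(point_ids, map_k))
    ]


def project(
    fit: MixtureFit,
    scaling: ScalingParams,
    external_pairs: Sequence[AffinityPair],
    conf_level: float = 0.95,
) -> list[Membership]:
    """Project external raw IC50 pairs through the training scaling and fit.

    The training column means/SDs and the fitted mixture parameters are
    reused unchanged: no refitting, no rescaling to the external set.
    """
    if not external_pairs:
        return []
    pts = apply_scaling(scaling, external_pairs)
    X = points_to_array(pts)
    return membership(fit, X, conf_level=conf_level, point_ids=[p.snv_id for p in pts])


def save_model(
    path: str | Path,
    fit: MixtureFit,
    scaling: ScalingParams | None = None,
    bic_table: BicTable | None = None,
) -> None:
    """Serialize a fit (and optionally scaling + BIC grid) to JSON."""
    payload: dict = {"fit": fit.to_dict()}
    if scaling is not None:
        payload["scaling"] = {
            "mean_mut": scaling.mean_mut,
            "sd_mut": scaling.sd_mut,
            "mean_wt": scaling.mean_wt,
            "sd_wt": scaling.sd_wt,
            "log10": scaling.log10,
        }
    if bic_table is not None:
        payload["bic_table"] = bic_table.to_records()
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> tuple[MixtureFit, ScalingParams | None, BicTable | None]:
    """Inverse of :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    fit = MixtureFit.from_dict(payload["fit"])
    scaling = None
    if "scaling" in payload:
        scaling = ScalingParams(**payload["scaling"])
    table = None
    if "bic_table" in payload:
        table = BicTable(rows=[(r["model"], r["G"], r["bic"]) for r in payload["bic_table"]])
    return fit, scaling, table
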