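"""Pooled immunization screen: design, growth, TCI scoring, and the funnel.

Candidate peptides are randomly partitioned into pools of 4–5; cohorts of
mice immunized with each pool are tumor-challenged and their serial
tumor-volume measurements summarized into a tumor control index (TCI),
where higher means better tumor control.  Peptides in pools whose mean
TCI is positive advance to individual testing, and individually positive
peptides advance to a confirmation stage — a classic group-testing
screen.  A simple exponential tumor-growth simulator with multiplicative
lognormal noise generates cohorts for end-to-end exercise of the screen.

The TCI of Corwin et al. is not restated here; the default scorer,
``auc_ratio`` (100 times one minus the ratio of a curve's trapezoidal
AUC to the mean control AUC, clipped below at −100), is a documented
surrogate honoring the qualitative contract that identical-to-control
growth scores 0 and complete rejection scores 100.  Alternative scorers
can be registered by name.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

POOL_SIZES = (4, 5)

#: ELISpot rating bins: (low, high, rating), inclusive bounds, spots per
#: million CD8+ cells
ELISPOT_BINS = (
    (5, 10, "+"),
    (11, 20, "++"),
    (21, 50, "+++"),
    (51, 100, "++++"),
    (101, math.inf, "+++++"),
)


@dataclass(frozen=True)
class PoolDesign:
    """A partition of peptide ids into pools of size 4 or 5."""

    pools: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def pool_of(self) -> dict[str, int]:
        """Map each peptide id to its 0-based pool index."""
        out: dict[str, int] = {}
        for i, pool in enumerate(self.pools):
            for pid in pool:
                if pid in out:
                    raise ValueError(f"peptide {pid} appears in more than one pool")
                out[pid] = i
        return out


@dataclass(frozen=True)
class GrowthCurve:
    """Serial tumor-volume measurements for one mouse."""

    subject_id: str
    group: str
    times: tuple[float, ...]  # days since challenge
    volumes: tuple[float, ...]  # mm^3

    def __post_init__(self) -> None:
        if len(self.times) != len(self.volumes):
            raise ValueError(f"{self.subject_id}: time/volume length mismatch")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"{self.subject_id}: times must be strictly increasing")
        if any(v < 0 for v in self.volumes):
            raise ValueError(f"{self.subject_id}: volumes must be non-negative")


@dataclass(frozen=True)
class TciScore:
    subject_id: str
    score: float


@dataclass(frozen=True)
class FunnelReport:
    """Stage counts of the pooled screen (monotone non-increasing)."""

    pools_tested: int
    pools_positive: int
    peptides_tested_individually: int
    peptides_positive: int
    confirmed: int
    positive_pools: tuple[int, ...] = ()
    advanced_peptides: tuple[str, ...] = ()
    positive_peptides: tuple[str, ...] = ()
    confirmed_peptides: tuple[str, ...] = ()

    @property
    def pool_positive_pct(self) -> float:
        return 100.0 * self.pools_positive / self.pools_tested

    @property
    def individual_positive_pct(self) -> float:
        return 100.0 * self.peptides_positive / self.peptides_tested_individually


def design_pools(
    item_ids: Sequence[str] | int,
    size_range: tuple[int, int] = POOL_SIZES,
    seed: int = 0,
) -> PoolDesign:
    """Randomly partition items into the minimum number of 4/5-size pools.

    Pools of the maximum size (5) are preferred; e.g. 279 items yield 56
    pools: 55 of size 5 and one of size 4.  Item counts that cannot be
    expressed as 4a+5b (fewer than 4, or exactly 6, 7 or 11) fall back
    to near-equal pools with a logged warning.
    """
    if isinstance(item_ids, int):
        item_ids = [f"pep{i + 1}" for i in range(item_ids)]
    ids = list(item_ids)
    n = len(ids)
    lo, hi = min(size_range), max(size_range)
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    if n < lo:
        logger.warning("only %d items: single undersized pool", n)
        return PoolDesign(pools=(tuple(order),), seed=seed)
    p = math.ceil(n / hi)  # minimal pool count
    deficit = hi * p - n  # number of pools shrunk to size lo when lo = hi - 1
    if deficit > p:
        logger.warning(
            "%d items cannot be split into pools of sizes %d-%d; using "
            "near-equal pools",
            n,
            lo,
            hi,
        )
        sizes = [len(chunk) for chunk in np.array_split(np.arange(n), p)]
    else:
        sizes = [lo] * deficit + [hi] * (p - deficit)
    pools: list[tuple[str, ...]] = []
    at = 0
    for s in sizes:
        pools.append(tuple(order[at : at + s]))
        at += s
    return PoolDesign(pools=tuple(pools), seed=seed)


# --- TCI scoring -----------------------------------------------------------

TciScorer = Callable[[GrowthCurve, Sequence[GrowthCurve]], float]

_SCORERS: dict[str, TciScorer] = {}


def register_scorer(name: str) -> Callable[[TciScorer], TciScorer]:
    def deco(fn: TciScorer) -> TciScorer:
        _SCORERS[name] = fn
        return fn

    return deco


def get_scorer(name: str) -> TciScorer:
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(f"unknown TCI scorer {name!r}; known: {sorted(_SCORERS)}")


def _common_grid_auc(curve: GrowthCurve, grid: np.ndarray) -> float:
    v = np.interp(grid, curve.times, curve.volumes)
    return float(np.trapezoid(v, grid))


@register_scorer("auc_ratio")
def auc_ratio_scorer(curve: GrowthCurve, controls: Sequence[GrowthCurve]) -> float:
    """TCI = 100·(1 − AUC(curve)/mean AUC(controls)), clipped at −100.

    Curves are linearly interpolated onto the union of measurement days
    restricted to the overlapping time span before trapezoidal AUC.
    """
    if not controls:
        raise ValueError("at least one control curve required")
    t_lo = max([curve.times[0]] + [c.times[0] for c in controls])
    t_hi = min([curve.times[-1]] + [c.times[-1] for c in controls])
    if t_hi <= t_lo:
        raise ValueError("no overlapping time span between curve and controls")
    all_t = np.unique(
        np.concatenate([curve.times] + [np.asarray(c.times) for c in controls])
    )
    grid = all_t[(all_t >= t_lo) & (all_t <= t_hi)]
    ctrl_auc = float(np.mean([_common_grid_auc(c, grid) for c in controls]))
    if ctrl_auc == 0:
        raise ValueError("mean control AUC is zero; TCI undefined")
    tci = 100.0 * (1.0 - _common_grid_auc(curve, grid) / ctrl_auc)
    return max(tci, -100.0)


def compute_tci(
    curve: GrowthCurve,
    controls: Sequence[GrowthCurve],
    scorer: str | TciScorer = "auc_ratio",
) -> TciScore:
    """Score one growth curve against a control cohort."""
    fn = get_scorer(scorer) if isinstance(scorer, str) else scorer
    return TciScore(subject_id=curve.subject_id, score=fn(curve, controls))


# --- growth simulation -----------------------------------------------------


def simulate_growth(
    effect_size: float = 0.0,
    noise_sd: float = 0.0,
    n_mice: int = 5,
    seed: int = 0,
    group: str = "treated",
    v0: float = 50.0,
    growth_rate: float = 0.25,
    days: Sequence[float] = tuple(range(0, 22, 3)),
    rejection_prob: float = 0.0,
    rejection_effect_min: float = 0.8,
) -> list[GrowthCurve]:
    """Simulate exponential tumor growth V(t) = V0·exp(r·(1−e)·t).

    ``effect_size`` e shrinks the growth rate (e = 0: control-like
    growth; e = 1: static tumor).  Multiplicative lognormal noise with
    log-sd ``noise_sd`` is applied per measurement.  When e is at least
    ``rejection_effect_min``, each mouse rejects its tumor (volumes fall
    to 0 after day 0) with probability ``rejection_prob``.
    """
    if v0 <= 0 or growth_rate < 0 or noise_sd < 0 or n_mice < 1:
        raise ValueError("invalid growth-model parameters")
    rng = np.random.default_rng(seed)
    t = np.asarray(days, dtype=float)
    curves = []
    for i in range(n_mice):
        v = v0 * np.exp(growth_rate * (1.0 - effect_size) * t)
        if noise_sd > 0:
            v = v * rng.lognormal(mean=0.0, sigma=noise_sd, size=t.shape)
        if effect_size >= rejection_effect_min and rng.random() < rejection_prob:
            v = np.where(t > 0, 0.0, v)
        curves.append(
            GrowthCurve(
                subject_id=f"{group}_m{i + 1}",
                group=group,
                times=tuple(t),
                volumes=tuple(float(x) for x in v),
            )
        )
    return curves


# --- funnel ----------------------------------------------------------------


def _positive(scores: Iterable[float], rule: str = "mean") -> bool:
    arr = np.asarray(list(scores), dtype=float)
    stat = float(np.mean(arr)) if rule == "mean" else float(np.median(arr))
    return stat > 0.0


def run_funnel(
    design: PoolDesign,
    pool_tci: Mapping[int, Sequence[float]],
    peptide_tci: Mapping[str, Sequence[float]],
    confirmation_tci: Mapping[str, Sequence[float]] | None = None,
    rule: str = "mean",
) -> FunnelReport:
    """Run the pool → individual → confirmation group-testing funnel.

    ``pool_tci`` maps pool index to cohort TCI scores; a pool is positive
    when its mean (or median) TCI exceeds 0, and every peptide of a
    positive pool is tested individually.  ``peptide_tci`` must cover all
    advancing peptides; individually positive peptides are re-tested in
    the confirmation stage (``confirmation_tci``; peptides absent from it
    count as unconfirmed).
    """
    membership_map = design.pool_of()  # validates disjointness
    positive_pools = tuple(
        i for i in range(design.n_pools) if i in pool_tci and _positive(pool_tci[i], rule)
    )
    advanced = tuple(
        pid for i in positive_pools for pid in design.pools[i]
    )
    missing = [p for p in advanced if p not in peptide_tci]
    if missing:
        raise ValueError(f"no individual TCI scores for advancing peptides: {missing[:5]}")
    positive_peps = tuple(p for p in advanced if _positive(peptide_tci[p], rule))
    if confirmation_tci is None:
        confirmed = positive_peps
    else:
        confirmed = tuple(
            p
            for p in positive_peps
            if p in confirmation_tci and _positive(confirmation_tci[p], rule)
        )
    return FunnelReport(
        pools_tested=design.n_pools,
        pools_positive=len(positive_pools),
        peptides_tested_individually=len(advanced),
        peptides_positive=len(positive_peps),
        confirmed=len(confirmed),
        positive_pools=positive_pools,
        advanced_peptides=advanced,
        positive_peptides=positive_peps,
        confirmed_peptides=confirmed,
    )


def simulate_screen(
    n_peptides: int,
    active_ids: Sequence[str],
    effect_size: float = 0.8,
    noise_sd: float = 0.0,
    n_mice: int = 5,
    seed: int = 0,
    rule: str = "mean",
) -> tuple[PoolDesign, FunnelReport]:
    """End-to-end simulated screen with planted active peptides.

    Pools containing at least one active peptide are immunized with an
    effective vaccine (growth slowed by ``effect_size``); cohort curves
    are scored against a shared simulated control cohort, and the funnel
    is run on the resulting TCI scores.  With ``noise_sd`` 0 the funnel
    recovers exactly the planted active set.
    """
    rng = np.random.default_rng(seed)
    design = design_pools(n_peptides, seed=int(rng.integers(2**31 - 1)))
    active = set(active_ids)
    unknown = active - set(design.pool_of())
    if unknown:
        raise ValueError(f"active ids not among peptides: {sorted(unknown)[:5]}")
    controls = simulate_growth(
        effect_size=0.0, noise_sd=noise_sd, n_mice=n_mice,
        seed=int(rng.integers(2**31 - 1)), group="control",
    )

    def cohort_scores(has_active: bool, tag: str) -> list[float]:
        e = effect_size if has_active else 0.0
        curves = simulate_growth(
            effect_size=e, noise_sd=noise_sd, n_mice=n_mice,
            seed=int(rng.integers(2**31 - 1)), group=tag,
        )
        return [compute_tci(c, controls).score for c in curves]

    pool_tci = {
        i: cohort_scores(any(p in active for p in pool), f"pool{i}")
        for i, pool in enumerate(design.pools)
    }
    all_ids = [p for pool in design.pools for p in pool]
    peptide_tci = {p: cohort_scores(p in active, p) for p in all_ids}
    confirmation = {p: cohort_scores(p in active, f"{p}_conf") for p in all_ids}
    report = run_funnel(design, pool_tci, peptide_tci, confirmation, rule=rule)
    return design, report


def rate_elispot(spots_per_million_cd8: float) -> str:
    """Ordinal rating of an ELISpot response.

    Bins: 5–10 (+), 11–20 (++), 21–50 (+++), 51–100 (++++), more than
    100 (+++++); below 5 rates as ``negative``.
    """
    if spots_per_million_cd8 < 0:
        raise ValueError("spot count must be non-negative")
    for lo, hi, rating in ELISPOT_BINS:
        if lo <= spots_per_million_cd8 <= hi:
            return rating
    return "negative"
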