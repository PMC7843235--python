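"""Affinity features and the differential agretopic index (DAI).

Each SNV is represented by one (mutant IC50, wild-type IC50) pair in nM:
an experimentally verified precise neoepitope when one exists, otherwise
the highest predicted binder (minimum mutant IC50) across all alleles
and candidate windows.  The bivariate features are centered and scaled
per column; DAI is defined on the scaled coordinates as y − x, so a
point on the mutant-equals-WT diagonal has DAI 0 and a mutant that binds
better than its WT counterpart (lower mutant IC50) has DAI > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: conventional strong/moderate vs weak binding cut-off, nM
BINDING_THRESHOLD_NM = 500.0

LABELS = ("TRMN", "non-TRMN", "unknown")


@dataclass(frozen=True)
class AffinityPair:
    """Predicted mutant/WT IC50 for one candidate peptide on one allele."""

    snv_id: str
    allele: str
    peptide: str
    ic50_mut: float
    ic50_wt: float
    verified_epitope: bool = False

    def __post_init__(self) -> None:
        for name, v in (("ic50_mut", self.ic50_mut), ("ic50_wt", self.ic50_wt)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.snv_id}: {name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class ScalingParams:
    """Per-column centering/scaling parameters on the nM scale.

    ``log10`` records whether a log10 pre-transform was applied before
    the moments were computed; projection must reuse the same setting.
    """

    mean_mut: float
    sd_mut: float
    mean_wt: float
    sd_wt: float
    log10: bool = False

    def __post_init__(self) -> None:
        if self.sd_mut <= 0 or self.sd_wt <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class DaiPoint:
    """A scaled affinity point; x = scaled mutant IC50, y = scaled WT IC50."""

    snv_id: str
    x: float
    y: float
    dai: float = field(default=float("nan"))
    label: str = "unknown"

    def __post_init__(self) -> None:
        if math.isnan(self.dai):
            object.__setattr__(self, "dai", self.y - self.x)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def select_representative(pairs: Iterable[AffinityPair]) -> dict[str, AffinityPair]:
    """Pick one representative affinity pair per SNV.

    A pair flagged as an experimentally verified precise neoepitope
    always wins; otherwise the pair with minimum mutant IC50 across all
    alleles and windows is taken, with ties broken by (allele, peptide)
    lexicographic order.
    """
    groups: dict[str, list[AffinityPair]] = {}
    for p in pairs:
        groups.setdefault(p.snv_id, []).append(p)
    if not groups:
        raise ValueError("no affinity pairs supplied")
    reps: dict[str, AffinityPair] = {}
    for snv_id, grp in groups.items():
        if not grp:
            raise ValueError(f"empty affinity group for {snv_id}")
        verified = [p for p in grp if p.verified_epitope]
        pool = verified if verified else grp
        reps[snv_id] = min(pool, key=lambda p: (p.ic50_mut, p.allele, p.peptide))
    return reps


def classify_binding(ic50: float, threshold: float = BINDING_THRESHOLD_NM) -> str:
    """Classify an IC50 as ``strong_or_moderate`` or ``weak``.

    ``weak`` iff ic50 is strictly greater than the threshold (default
    500 nM), so a value of exactly 500 nM is still strong_or_moderate.
    """
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    return "weak" if ic50 > threshold else "strong_or_moderate"


def _columns(pairs: Sequence[AffinityPair], log10: bool) -> tuple[np.ndarray, np.ndarray]:
    mut = np.array([p.ic50_mut for p in pairs], dtype=float)
    wt = np.array([p.ic50_wt for p in pairs], dtype=float)
    if log10:
        mut, wt = np.log10(mut), np.log10(wt)
    return mut, wt


def fit_scaling(pairs: Sequence[AffinityPair], log10: bool = False) -> ScalingParams:
    """Compute per-column means and sample (n−1) standard deviations."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 affinity pairs to fit scaling")
    mut, wt = _columns(pairs, log10)
    sd_mut = float(np.std(mut, ddof=1))
    sd_wt = float(np.std(wt, ddof=1))
    if sd_mut == 0 or sd_wt == 0:
        raise ValueError("zero variance in an IC50 column; cannot scale")
    return ScalingParams(
        mean_mut=float(np.mean(mut)),
        sd_mut=sd_mut,
        mean_wt=float(np.mean(wt)),
        sd_wt=sd_wt,
        log10=log10,
    )


def apply_scaling(
    params: ScalingParams,
    pairs: Sequence[AffinityPair],
    labels: Mapping[str, str] | None = None,
) -> list[DaiPoint]:
    """Center/scale affinity pairs into DAI space.

    x = (mut − mean_mut)/sd_mut, y = (wt − mean_wt)/sd_wt, dai = y − x.
    ``labels`` maps snv_id to TRMN/non-TRMN; absent ids become
    ``unknown``.
    """
    labels = labels or {}
    mut, wt = _columns(pairs, params.log10)
    x = (mut - params.mean_mut) / params.sd_mut
    y = (wt - params.mean_wt) / params.sd_wt
    return [
        DaiPoint(
            snv_id=p.snv_id,
            x=float(xi),
            y=float(yi),
            label=labels.get(p.snv_id, "unknown"),
        )
        for p, xi, yi in zip(pairs, x, y)
    ]


def points_to_array(points: Sequence[DaiPoint]) -> np.ndarray:
    """Stack DaiPoints into an (n, 2) array of (x, y) coordinates."""
    return np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
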