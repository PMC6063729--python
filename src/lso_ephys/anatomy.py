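"""Anatomical quantification: lateromedial position, synaptic coverage, tonotopy.

Positions are expressed as the arc-length fraction (0 = lateral edge,
1 = medial edge) of the soma's nearest point on the LSO centerline polyline.
Somatic synaptic coverage is the percentage of the soma perimeter apposed by
presynaptic terminals in an EM section, averaged over sections (valid when
measured in at least three).  The tonotopy check is a Spearman rank
correlation of CF/BF against normalized position, with an exact permutation
p value at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core_io import ValidationError

__all__ = [
    "CenterlineMap",
    "CoverageMeasurement",
    "CoverageEstimate",
    "normalized_position",
    "coverage_percent",
    "tonotopy_stat",
]


@dataclass
class CenterlineMap:
    """Polyline through the LSO from the lateral to the medial pole (µm)."""

    vertices: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValidationError("centerline needs at least 2 vertices")
        if self.arc_length <= 0:
            raise ValidationError("degenerate centerline: zero arc length")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass
class CoverageMeasurement:
    """Per-section soma perimeter and synaptic apposition lengths (µm)."""

    perimeters: Sequence[float]
    appositions: Sequence[Sequence[float]]  # one list per section

    def __post_init__(self) -> None:
        if len(self.perimeters) < 1:
            raise ValidationError("need at least one section")
        if len(self.perimeters) != len(self.appositions):
            raise ValidationError("perimeters and appositions must align")

    @property
    def n_sections(self) -> int:
        return len(self.perimeters)


@dataclass
class CoverageEstimate:
    percent: float
    valid: bool  # measured in >= 3 sections
    n_sections: int


def normalized_position(
    centerline: CenterlineMap, soma_xy: Sequence[float]
) -> float:
    """Arc-length fraction of the soma's nearest point on the centerline.

    Ties between equidistant segments (polyline corners) resolve to the
    smaller arc length.
    """
    p = np.asarray(soma_xy, dtype=float)
    v = centerline.vertices
    seg = np.diff(v, axis=0)
    seg_len2 = (seg**2).sum(axis=1)
    rel = p - v[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip((rel * seg).sum(axis=1) / seg_len2, 0.0, 1.0)
    t = np.where(seg_len2 == 0, 0.0, t)
    proj = v[:-1] + t[:, None] * seg
    d = np.linalg.norm(proj - p, axis=1)
    total = centerline.arc_length
    if d.min() > 2.0 * total:
        raise ValidationError("soma implausibly far from the centerline")
    best = int(np.argmin(d))  # argmin takes the first (smaller arc) on ties
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    arc = cum[best] + t[best] * math.sqrt(seg_len2[best])
    return float(arc / total)


def coverage_percent(meas: CoverageMeasurement) -> CoverageEstimate:
    """Mean percentage of soma perimeter apposed by synaptic terminals."""
    per_section: List[float] = []
    for perim, apps in zip(meas.perimeters, meas.appositions):
        if perim <= 0:
            raise ValidationError("perimeters must be positive")
        total = float(np.sum(apps)) if len(apps) else 0.0
        if total > perim:
            raise ValidationError(
                "apposition length exceeds soma perimeter in a section"
            )
        per_section.append(100.0 * total / perim)
    return CoverageEstimate(
        percent=float(np.mean(per_section)),
        valid=meas.n_sections >= 3,
        n_sections=meas.n_sections,
    )


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    return float(np.corrcoef(xr, yr)[0, 1])


def tonotopy_stat(
    cells: Sequence[Tuple[float, float]], exact_max_n: int = 8
) -> "TonotopyResult":
    """Spearman correlation of CF/BF against normalized lateromedial position.

    Uses exact permutation p for n <= ``exact_max_n`` (full enumeration of
    n! rank orderings) and the t approximation above it.
    """
    if len(cells) < 5:
        raise ValidationError("tonotopy check needs at least 5 cells")
    pos = np.asarray([c[0] for c in cells], dtype=float)
    cf = np.asarray([c[1] for c in cells], dtype=float)
    if np.unique(pos).size == 1:
        raise ValidationError("all positions tied")
    xr = stats.rankdata(pos)
    yr = stats.rankdata(cf)
    rho = _spearman_rho(xr, yr)
    n = len(cells)
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(yr):
            total += 1
            if abs(_spearman_rho(xr, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(pos, cf).pvalue)
    return TonotopyResult(rho=rho, p_two_tailed=float(p), n=n)


@dataclass
class TonotopyResult:
    rho: float
    p_two_tailed: float
    n: int
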