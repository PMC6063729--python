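"""Cross-cell analysis: feature assembly, classification, group statistics.

Cells are classified as principal vs non-principal in the two-feature space
(log10 upper cutoff frequency, action-potential amplitude), z-scored.  When
anatomically confirmed anchors exist, unlabeled cells are assigned to the
nearest anchor centroid (mirroring assignment of histologically unrecovered
recordings); otherwise a deterministic 2-means clustering is used.

Group comparisons are Student pooled-variance two-sample t tests and
Hedges' g computed either from raw samples or from printed summaries
(mean +/- SEM, n); g uses the (n-1)-weighted pooled SD without the
small-sample correction factor (the corrected variant is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core_io import CellRecord, CurrentStep, ValidationError
from .vm_features import (
    FeatureVector,
    amplitude_spectrum,
    ap_amplitude,
    input_resistance,
    median_evoked,
    peak_to_sustained,
    preprocess_spontaneous,
    upper_cutoff,
)

__all__ = [
    "GroupSummary",
    "TestResult",
    "ClassificationResult",
    "summarize",
    "extract_features",
    "cluster_cells",
    "classify_cohort",
    "pooled_t_from_summaries",
    "pooled_t_from_samples",
    "hedges_g",
    "pearson_r",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, and SEM of one group (SD derived as sem*sqrt(n))."""

    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group summary needs n >= 2")
        if not self.sem > 0:
            raise ValidationError("sem must be positive")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_two_tailed: float
    effect_size: Optional[float] = None


def summarize(values: Sequence[float]) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    return GroupSummary(n=x.size, mean=float(x.mean()),
                        sem=float(x.std(ddof=1) / math.sqrt(x.size)))


# ---------------------------------------------------------------------------
# per-cell feature assembly


def extract_features(
    cell: CellRecord,
    spont_key: str = "spontaneous",
    ipsi_key: str = "ipsi_tone",
    contra_key: str = "contra_tone",
    step_prefix: str = "step_",
) -> FeatureVector:
    """Compose membrane-potential features for one cell.

    The spontaneous and ipsi-tone protocols are required (cutoff and AP
    amplitude); everything else is optional and left absent when the
    protocol is missing or the measurement is undefined for the cell.
    """
    if spont_key not in cell.protocols:
        raise ValidationError(f"missing protocol {spont_key!r}")
    fv = FeatureVector(cell_id=cell.cell_id)
    spont = cell.protocols[spont_key][0]
    spec = amplitude_spectrum(preprocess_spontaneous(spont), spont.sampling_rate)
    fv.upper_cutoff = upper_cutoff(spec)
    if ipsi_key in cell.protocols:
        ipsi = cell.protocols[ipsi_key]
        try:
            fv.ap_amplitude = ap_amplitude(ipsi)
        except ValidationError:
            pass
        try:
            fv.peak_to_sustained_ipsi = peak_to_sustained(ipsi)
        except ValidationError:
            pass
    if contra_key in cell.protocols:
        contra = cell.protocols[contra_key]
        try:
            fv.peak_to_sustained_contra = peak_to_sustained(contra)
        except ValidationError:
            pass
        try:
            med = median_evoked(contra)
            ref = contra[0]
            base = float(np.median(med[ref.window_slice(ref.t0_offset, 0.0)]))
            dur = getattr(ref.stimulus, "duration", 50.0)
            sus = (40.0, 50.0) if dur >= 50.0 else (20.0, 25.0)
            fv.sustained_hyperpol = float(
                np.mean(med[ref.window_slice(*sus)]) - base
            )
        except ValidationError:
            pass
    for name, sweeps in cell.protocols_with_prefix(step_prefix).items():
        stim = sweeps[0].stimulus
        if isinstance(stim, CurrentStep) and stim.amplitude < 0:
            fv.r_in_steady, fv.r_in_peak = input_resistance(sweeps[0], stim)
            break
    return fv


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationResult:
    labels: List[str]  # "principal" | "non_principal" | "unassignable"
    confidence: np.ndarray  # silhouette-style, [0, 1]; ~0 = ambiguous
    centroids: Optional[Dict[str, np.ndarray]] = None  # z-space


def _feature_matrix(features: Sequence[FeatureVector]) -> Tuple[np.ndarray, List[int]]:
    rows, idx = [], []
    for i, fv in enumerate(features):
        if fv.complete_for_classification():
            rows.append([math.log10(fv.upper_cutoff), fv.ap_amplitude])
            idx.append(i)
    return np.asarray(rows), idx


def cluster_cells(
    features: Sequence[FeatureVector],
    anchors: Optional[Sequence[Optional[str]]] = None,
) -> ClassificationResult:
    """Two-class assignment in z-scored (log10 cutoff, AP amplitude) space.

    With ``anchors`` (a per-cell sequence of "principal"/"non_principal"/None)
    unlabeled cells go to the nearest anchor-defined centroid; without
    anchors a deterministic 2-means (farthest-pair initialization) is run and
    the cluster with the higher mean log-cutoff is called principal.
    """
    X, idx = _feature_matrix(features)
    if len(idx) < 4:
        raise ValidationError("need at least 4 cells with complete features")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    if anchors is not None:
        anchor_sub = [anchors[i] for i in idx]
        cents: Dict[str, np.ndarray] = {}
        for lab in ("principal", "non_principal"):
            pts = Z[[j for j, a in enumerate(anchor_sub) if a == lab]]
            if len(pts) < 2:
                raise ValidationError(
                    f"need at least 2 anchor cells for group {lab!r}"
                )
            cents[lab] = pts.mean(axis=0)
        assign = _nearest(Z, cents)
    else:
        assign, cents = _two_means(Z)

    labels = ["unassignable"] * len(features)
    conf = np.zeros(len(features))
    for j, i in enumerate(idx):
        labels[i] = assign[j]
        d_own = np.linalg.norm(Z[j] - cents[assign[j]])
        other = "principal" if assign[j] == "non_principal" else "non_principal"
        d_oth = np.linalg.norm(Z[j] - cents[other])
        denom = max(d_own, d_oth)
        conf[i] = 0.0 if denom == 0 else (d_oth - d_own) / denom
    return ClassificationResult(labels=labels, confidence=conf, centroids=cents)


def _nearest(Z: np.ndarray, cents: Dict[str, np.ndarray]) -> List[str]:
    labs = list(cents)
    D = np.stack([np.linalg.norm(Z - cents[l], axis=1) for l in labs])
    return [labs[k] for k in np.argmin(D, axis=0)]


def _two_means(Z: np.ndarray, max_iter: int = 100) -> Tuple[List[str], Dict[str, np.ndarray]]:
    """Deterministic 2-means: centers start at the farthest pair of points."""
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    c = np.vstack([Z[min(i, j)], Z[max(i, j)]])
    assign = np.zeros(len(Z), dtype=int)
    for _ in range(max_iter):
        d = np.stack([np.linalg.norm(Z - c[k], axis=1) for k in range(2)])
        new = np.argmin(d, axis=0)
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for k in range(2):
            if np.any(assign == k):
                c[k] = Z[assign == k].mean(axis=0)
    # higher mean log-cutoff (first z column) = principal
    mean0 = Z[assign == 0, 0].mean() if np.any(assign == 0) else -np.inf
    mean1 = Z[assign == 1, 0].mean() if np.any(assign == 1) else -np.inf
    names = ("principal", "non_principal") if mean0 >= mean1 else (
        "non_principal", "principal"
    )
    cents = {names[0]: c[0], names[1]: c[1]}
    return [names[k] for k in assign], cents


def classify_cohort(
    cells: Sequence[CellRecord],
    features: Sequence[FeatureVector],
    use_anchors: bool = True,
) -> ClassificationResult:
    """Classify a cohort, using anatomical labels as anchors when available.

    Falls back to unsupervised 2-means when anchors are too few, and marks
    every cell unassignable when fewer than 4 cells have complete features
    (two clusters cannot be supported).
    """
    n_complete = sum(fv.complete_for_classification() for fv in features)
    if n_complete < 4:
        return ClassificationResult(
            labels=["unassignable"] * len(features),
            confidence=np.zeros(len(features)),
        )
    anchors: List[Optional[str]] = []
    for c in cells:
        if c.anatomical_class == "principal":
            anchors.append("principal")
        elif c.anatomical_class in ("class5", "marginal", "multiplanar"):
            anchors.append("non_principal")
        else:
            anchors.append(None)
    if use_anchors:
        n_p = sum(a == "principal" for a in anchors)
        n_np = sum(a == "non_principal" for a in anchors)
        if n_p >= 2 and n_np >= 2:
            return cluster_cells(features, anchors)
    return cluster_cells(features)


# ---------------------------------------------------------------------------
# group statistics


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if var <= 0:
        raise ValidationError("zero pooled variance")
    return math.sqrt(var)


def pooled_t_from_summaries(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Student pooled-variance two-sample t test from group summaries."""
    sp = _pooled_sd(a, b)
    t = (a.mean - b.mean) / (sp * math.sqrt(1.0 / a.n + 1.0 / b.n))
    df = a.n + b.n - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p_two_tailed=float(p))


def pooled_t_from_samples(x: Sequence[float], y: Sequence[float]) -> TestResult:
    return pooled_t_from_summaries(summarize(x), summarize(y))


def hedges_g(a: GroupSummary, b: GroupSummary, corrected: bool = False) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD.

    The small-sample correction J = 1 - 3/(4 df - 1) is off by default
    (the uncorrected convention); pass ``corrected=True`` to apply it.
    """
    g = (a.mean - b.mean) / _pooled_sd(a, b)
    if corrected:
        df = a.n + b.n - 2
        g *= 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(g)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Sample Pearson correlation with two-tailed p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one variable")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=r, df=df, p_two_tailed=float(p), effect_size=r)
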