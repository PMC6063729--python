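"""Spike-train statistics: rasters, windowed rates, regularity, BF.

Regularity analysis targets the "chopper" phenotype: interspike intervals
are pooled across stimulus repetitions into peristimulus time bins (each ISI
assigned to the bin containing its first spike) and per-bin mean, SD, and
coefficient of variation computed.  A bin only counts when at least 20% of
repetitions contribute an interval to it — onset-only cells therefore yield
an empty curve, sustained regular firers a low-CV curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core_io import Sweep, ToneStimulus, ValidationError
from .vm_features import detect_spikes

__all__ = [
    "SpikeTrainSet",
    "RegularityCurve",
    "extract_trains",
    "window_rate",
    "onset_fraction",
    "regularity_curve",
    "bf_from_counts",
]

MIN_REP_FRACTION = 0.2  # bin inclusion criterion


@dataclass
class SpikeTrainSet:
    """Per-repetition ordered spike times (ms re stimulus onset)."""

    trains: List[np.ndarray]
    stimulus: object = None

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(t, dtype=float)) for t in self.trains]

    @property
    def n_reps(self) -> int:
        return len(self.trains)

    def all_times(self) -> np.ndarray:
        return np.concatenate(self.trains) if self.trains else np.empty(0)


@dataclass
class RegularityCurve:
    """Per-bin ISI statistics over repetitions."""

    bin_centers: np.ndarray  # ms
    mean_isi: np.ndarray  # ms
    sd_isi: np.ndarray  # ms
    cv: np.ndarray
    rep_fraction: np.ndarray
    included: np.ndarray  # bool

    def included_cv(self) -> np.ndarray:
        return self.cv[self.included]


def extract_trains(sweeps: Sequence[Sweep], **detect_kwargs) -> SpikeTrainSet:
    """Detect spikes per repetition; times are already re stimulus onset."""
    trains = [
        np.asarray([t for t, _ in detect_spikes(sw, **detect_kwargs)])
        for sw in sweeps
    ]
    stim = sweeps[0].stimulus if sweeps else None
    return SpikeTrainSet(trains=trains, stimulus=stim)


def window_rate(trains: SpikeTrainSet, window: Tuple[float, float]) -> float:
    """Mean firing rate (spikes/s) in the half-open window ``[a, b)`` ms."""
    a, b = window
    if not b > a:
        raise ValidationError("window must have positive duration")
    counts = [np.count_nonzero((t >= a) & (t < b)) for t in trains.trains]
    if not counts:
        return 0.0
    return float(np.mean(counts) / ((b - a) / 1e3))


def onset_fraction(
    trains: SpikeTrainSet, onset: Tuple[float, float] = (0.0, 10.0)
) -> float:
    """Fraction of all stimulus-window spikes that fall in the onset window."""
    stim = trains.stimulus
    dur = stim.duration if isinstance(stim, ToneStimulus) else None
    total = 0
    in_onset = 0
    for t in trains.trains:
        tt = t[(t >= 0.0) & (t < dur)] if dur is not None else t[t >= 0.0]
        total += tt.size
        in_onset += np.count_nonzero((tt >= onset[0]) & (tt < onset[1]))
    if total == 0:
        raise ValidationError("no spikes")
    return in_onset / total


def regularity_curve(
    trains: SpikeTrainSet,
    bin_width: float = 1.0,
    t_start: float = 0.0,
    t_stop: float = None,
) -> RegularityCurve:
    """Per-bin ISI mean/SD/CV pooled over repetitions.

    Each interspike interval is assigned to the bin containing its first
    spike.  Bins are included only when at least 20% of repetitions
    contribute at least one interval.
    """
    if trains.n_reps < 10:
        warnings.warn("regularity analysis below 10 repetitions is unstable")
    if t_stop is None:
        stim = trains.stimulus
        t_stop = stim.duration if isinstance(stim, ToneStimulus) else (
            max((t.max() for t in trains.trains if t.size), default=0.0)
        )
    edges = np.arange(t_start, t_stop + bin_width * 0.5, bin_width)
    if edges.size < 2:
        raise ValidationError("no bins in analysis window")
    nbins = edges.size - 1
    per_bin: Dict[int, List[float]] = {b: [] for b in range(nbins)}
    reps_in_bin = np.zeros(nbins, dtype=int)
    total_isis = 0
    for t in trains.trains:
        if t.size < 2:
            continue
        firsts = t[:-1]
        isis = np.diff(t)
        total_isis += isis.size
        idx = np.floor((firsts - t_start) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < nbins)
        seen = set()
        for b, isi in zip(idx[ok], isis[ok]):
            per_bin[int(b)].append(float(isi))
            seen.add(int(b))
        for b in seen:
            reps_in_bin[b] += 1
    if total_isis == 0:
        raise ValidationError("no intervals")
    mean = np.full(nbins, np.nan)
    sd = np.full(nbins, np.nan)
    for b, isis in per_bin.items():
        if isis:
            mean[b] = np.mean(isis)
            sd[b] = np.std(isis, ddof=1) if len(isis) > 1 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    frac = reps_in_bin / max(trains.n_reps, 1)
    included = frac >= MIN_REP_FRACTION
    return RegularityCurve(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_isi=mean,
        sd_isi=sd,
        cv=cv,
        rep_fraction=frac,
        included=included,
    )


def bf_from_counts(counts_by_frequency: Dict[float, float]) -> float:
    """Best frequency: the frequency eliciting the largest spike/EPSP count.

    Ties are broken toward the lower frequency.
    """
    if len(counts_by_frequency) < 2:
        raise ValidationError("need counts at 2 or more frequencies")
    freqs = sorted(counts_by_frequency)
    counts = [counts_by_frequency[f] for f in freqs]
    if max(counts) <= 0:
        raise ValidationError("all counts are zero")
    return float(freqs[int(np.argmax(counts))])
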