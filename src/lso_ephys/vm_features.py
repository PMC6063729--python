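"""Membrane-potential feature extraction.

The headline statistic is the *upper cutoff frequency* of spontaneous
activity: the spontaneous trace is baseline-subtracted (median of the first
10 ms), high-pass filtered at 10 Hz (linear-phase FIR), wavelet-denoised
(symlet-8, level 5, heuristic-SURE soft thresholding, no rescaling), its
single-sided amplitude spectrum computed by DFT and normalized, and the
frequency where the high-frequency flank first falls to 50% (-6 dB) of the
maximum is reported.  Fast membranes (sub-millisecond PSPs) push this cutoff
into the hundreds of Hz; slow, summing membranes keep it low.

Also here: spike detection by slope threshold, action-potential amplitude
re the first-2-ms baseline, median evoked-potential profiles and their
peak-to-sustained ratio, and input resistance from hyperpolarizing steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve, firwin

from .core_io import CurrentStep, Sweep, ValidationError, baseline_median

__all__ = [
    "SpectrumResult",
    "FeatureVector",
    "preprocess_spontaneous",
    "amplitude_spectrum",
    "upper_cutoff",
    "detect_spikes",
    "ap_amplitude",
    "median_evoked",
    "peak_to_sustained",
    "input_resistance",
]


@dataclass
class SpectrumResult:
    """Normalized single-sided amplitude spectrum."""

    frequencies: np.ndarray  # Hz
    normalized_amplitude: np.ndarray  # max = 1
    upper_cutoff: Optional[float] = None  # Hz
    smoothing: str = "none"


@dataclass
class FeatureVector:
    """Derived physiology features for one cell."""

    cell_id: str = ""
    upper_cutoff: Optional[float] = None  # Hz
    ap_amplitude: Optional[float] = None  # mV
    peak_to_sustained_ipsi: Optional[float] = None
    peak_to_sustained_contra: Optional[float] = None
    r_in_steady: Optional[float] = None  # MOhm
    r_in_peak: Optional[float] = None  # MOhm
    sustained_hyperpol: Optional[float] = None  # mV, contra sustained window

    def complete_for_classification(self) -> bool:
        return self.upper_cutoff is not None and self.ap_amplitude is not None


# ---------------------------------------------------------------------------
# spectral pipeline


def _heursure_threshold(coeffs: np.ndarray) -> float:
    """Heuristic-SURE soft threshold for one coefficient level (sigma = 1).

    Uses the universal threshold sqrt(2 ln n) when the level is sparse, else
    the minimum of the SURE-optimal and universal thresholds.
    """
    n = coeffs.size
    if n == 0:
        return 0.0
    universal = math.sqrt(2.0 * math.log(n))
    eta = (np.sum(coeffs**2) - n) / n
    crit = math.log2(n) ** 1.5 / math.sqrt(n)
    if eta < crit:
        return universal
    sq = np.sort(coeffs**2)
    cumsq = np.cumsum(sq)
    k = np.arange(1, n + 1)
    risk = (n - 2.0 * k + cumsq + (n - k) * sq) / n
    best = int(np.argmin(risk))
    return min(universal, math.sqrt(sq[best]))


def wavelet_denoise(
    trace: np.ndarray, wavelet: str = "sym8", level: int = 5
) -> np.ndarray:
    """Level-wise heuristic-SURE soft-threshold denoising, no rescaling."""
    coeffs = pywt.wavedec(trace, wavelet, level=level)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        thr = _heursure_threshold(detail)
        out.append(pywt.threshold(detail, thr, mode="soft"))
    rec = pywt.waverec(out, wavelet)
    return rec[: trace.size]


def highpass_fir(
    trace: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = 10.0,
    transition_hz: float = 5.0,
) -> np.ndarray:
    """Zero-phase high-pass: centred symmetric FIR applied by FFT convolution."""
    numtaps = int(math.ceil(3.3 * sampling_rate / transition_hz))
    numtaps += 1 - numtaps % 2  # odd for a type-I (zero-phase-capable) filter
    numtaps = min(numtaps, 2 * (trace.size // 2) - 1)
    taps = firwin(numtaps, cutoff_hz, fs=sampling_rate, pass_zero=False)
    return fftconvolve(trace, taps, mode="same")


def preprocess_spontaneous(
    sweep: Sweep,
    highpass_hz: float = 10.0,
    wavelet: str = "sym8",
    level: int = 5,
) -> np.ndarray:
    """Baseline-subtract, high-pass filter, and wavelet-denoise a spontaneous sweep."""
    if sweep.duration_ms < 500.0:
        raise ValidationError(
            "insufficient spontaneous sample: need at least 0.5 s"
        )
    x = sweep.samples - baseline_median(
        sweep, (sweep.t0_offset, sweep.t0_offset + 10.0)
    )
    x = highpass_fir(x, sweep.sampling_rate, cutoff_hz=highpass_hz)
    return wavelet_denoise(x, wavelet=wavelet, level=level)


def amplitude_spectrum(
    trace: np.ndarray,
    sampling_rate: float,
    smooth_octaves: Optional[float] = 1.0 / 24.0,
    min_freq: float = 10.0,
    points_per_octave: int = 48,
) -> SpectrumResult:
    """Normalized single-sided DFT amplitude spectrum.

    With ``smooth_octaves`` set (the default, 1/24 octave), the raw magnitude
    spectrum is reduced to a running median over logarithmically spaced bins
    before normalization — raw multi-second DFTs are far too noisy for a
    stable half-maximum crossing.  Pass ``smooth_octaves=None`` for the raw
    bin-for-bin spectrum.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValidationError("trace too short for a spectrum")
    if np.ptp(trace) == 0:
        raise ValidationError("flat spectrum: constant trace")
    mag = np.abs(np.fft.rfft(trace))
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / sampling_rate)
    mag = mag[1:]  # drop DC
    freqs = freqs[1:]
    if smooth_octaves is None:
        peak = mag.max()
        if peak == 0:
            raise ValidationError("flat spectrum")
        return SpectrumResult(freqs, mag / peak, smoothing="none")

    nyq = sampling_rate / 2.0
    n_oct = math.log2(nyq / min_freq)
    edges = min_freq * 2.0 ** (np.arange(0, n_oct * points_per_octave + 1)
                               / points_per_octave)
    centers = np.sqrt(edges[:-1] * edges[1:])
    half = smooth_octaves / 2.0
    df = freqs[1] - freqs[0]
    # floor on the median support: narrow log windows at low frequency hold
    # a handful of DFT bins whose estimator variance destabilizes the
    # half-maximum crossing
    min_halfwidth_hz = max(15.0, 4.5 * df)
    sm_f: List[float] = []
    sm_a: List[float] = []
    for fc in centers:
        hw = max(fc * (2.0**half - 1.0), min_halfwidth_hz)
        i0, i1 = np.searchsorted(freqs, [fc - hw, fc + hw])
        if i1 > i0:
            sm_f.append(fc)
            sm_a.append(float(np.median(mag[i0:i1])))
    sm_fa = np.asarray(sm_f)
    sm_aa = np.asarray(sm_a)
    peak = sm_aa.max()
    if peak == 0:
        raise ValidationError("flat spectrum")
    return SpectrumResult(
        sm_fa,
        sm_aa / peak,
        smoothing=(
            f"log-median {smooth_octaves:.4g} octave, "
            f"min half-width {min_halfwidth_hz:.3g} Hz"
        ),
    )


def upper_cutoff(spectrum: SpectrumResult, fraction: float = 0.5) -> float:
    """Frequency where the high-frequency flank falls to ``fraction`` of max.

    Searches upward from the global spectral peak (ties broken toward the
    lowest frequency) and linearly interpolates the first downward crossing.
    The result is written back to ``spectrum.upper_cutoff``.
    """
    a = spectrum.normalized_amplitude
    f = spectrum.frequencies
    peak_idx = int(np.argmax(a))
    below = np.flatnonzero(a[peak_idx:] < fraction)
    if below.size == 0:
        raise ValidationError("cutoff not reached below Nyquist")
    j = peak_idx + below[0]
    if j == peak_idx:
        raise ValidationError("spectrum already below fraction at its peak")
    f0, f1 = f[j - 1], f[j]
    a0, a1 = a[j - 1], a[j]
    fc = f0 + (a0 - fraction) / (a0 - a1) * (f1 - f0)
    spectrum.upper_cutoff = float(fc)
    return float(fc)


# ---------------------------------------------------------------------------
# spikes


def detect_spikes(
    sweep: Sweep,
    slope_threshold: float = 10.0,  # mV/ms
    refractory_ms: float = 1.0,
    smooth_ms: float = 0.15,
    min_rise: float = 10.0,  # mV
) -> List[Tuple[float, float]]:
    """Spike times and peak Vm by slope threshold.

    The trace is lightly smoothed (boxcar, ``smooth_ms``) and the slope over
    a 2x``smooth_ms`` span compared against ``slope_threshold``; each
    suprathreshold rise is assigned the raw-trace local maximum within the
    following 1 ms, and detections closer than ``refractory_ms`` are merged
    (first kept).  A candidate must rise at least ``min_rise`` mV above the
    membrane potential at its slope crossing: large sub-millisecond EPSPs
    can match a small action potential's slope, but not its excursion.
    Works for small (~15 mV) and large (~80 mV) spikes.
    """
    v = sweep.samples
    fs_ms = sweep.sampling_rate / 1e3
    w = max(int(round(smooth_ms * fs_ms)), 1)
    sm = uniform_filter1d(v, size=w, mode="nearest")
    k = max(w, 1)
    slope = np.empty_like(sm)
    slope[k:-k] = (sm[2 * k :] - sm[: -2 * k]) / (2 * k / fs_ms)
    slope[:k] = slope[-k:] = 0.0
    above = slope > slope_threshold
    if not above.any():
        return []
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    win = max(int(round(1.0 * fs_ms)), 2)
    peaks: List[int] = []
    for i0 in starts:
        hi = min(i0 + win, v.size)
        if hi - i0 < 2:
            continue
        pk = i0 + int(np.argmax(v[i0:hi]))
        # a peak pinned to the window edge is still rising: extend to the max
        while pk == hi - 1 and hi < min(i0 + 4 * win, v.size):
            hi = min(hi + win, v.size)
            pk = i0 + int(np.argmax(v[i0:hi]))
        if v[pk] - sm[i0] >= min_rise:
            peaks.append(pk)
    # merge detections closer than the refractory period, keeping the
    # tallest peak of each cluster (overlapping candidates mark one spike)
    out: List[Tuple[float, float]] = []
    cluster: List[int] = []
    for pk in sorted(set(peaks)):
        if cluster and (pk - cluster[-1]) / fs_ms < refractory_ms:
            cluster.append(pk)
        else:
            if cluster:
                best = max(cluster, key=lambda i: v[i])
                out.append((sweep.t0_offset + best / fs_ms, float(v[best])))
            cluster = [pk]
    if cluster:
        best = max(cluster, key=lambda i: v[i])
        out.append((sweep.t0_offset + best / fs_ms, float(v[best])))
    return out


def ap_amplitude(sweeps: Sequence[Sweep], **detect_kwargs) -> float:
    """Mean action-potential amplitude over a set of ipsi-tone sweeps.

    Each spike's amplitude is its raw peak Vm minus the median Vm over the
    first 2 ms of the same sweep (pre-stimulus baseline); spikes are pooled
    across all sweeps/levels presented.
    """
    amps: List[float] = []
    for sw in sweeps:
        base = float(np.median(sw.samples[: max(int(2e-3 * sw.sampling_rate), 1)]))
        for _, peak in detect_spikes(sw, **detect_kwargs):
            amps.append(peak - base)
    if not amps:
        raise ValidationError("no APs detected")
    return float(np.mean(amps))


# ---------------------------------------------------------------------------
# evoked profiles


def median_evoked(sweeps: Sequence[Sweep]) -> np.ndarray:
    """Pointwise median membrane potential across repetitions."""
    if len(sweeps) < 3:
        raise ValidationError("median profile needs at least 3 repetitions")
    lengths = {s.n_samples for s in sweeps}
    if len(lengths) > 1:
        raise ValidationError("ragged sweep lengths")
    stack = np.vstack([s.samples for s in sweeps])
    return np.median(stack, axis=0)


def _sustained_window(duration_ms: float) -> Tuple[float, float]:
    return (40.0, 50.0) if duration_ms >= 50.0 else (20.0, 25.0)


def peak_to_sustained(
    sweeps: Sequence[Sweep],
    onset: Tuple[float, float] = (5.0, 15.0),
    sustained: Optional[Tuple[float, float]] = None,
    **detect_kwargs,
) -> float:
    """Peak-to-sustained ratio of the median evoked potential.

    Repetitions with any detected spike inside the onset or sustained window
    are excluded; on the median of the remaining repetitions, peak is the
    maximal |Vm - baseline| in the onset window and sustained the mean
    |Vm - baseline| in the sustained window (baseline = pre-stimulus median).
    """
    if sustained is None:
        stim = sweeps[0].stimulus
        dur = getattr(stim, "duration", 50.0)
        sustained = _sustained_window(dur)
    clean: List[Sweep] = []
    for sw in sweeps:
        times = [t for t, _ in detect_spikes(sw, **detect_kwargs)]
        bad = any(
            onset[0] <= t < onset[1] or sustained[0] <= t < sustained[1]
            for t in times
        )
        if not bad:
            clean.append(sw)
    if len(clean) < 3:
        raise ValidationError("insufficient spike-free repetitions")
    med = median_evoked(clean)
    ref = clean[0]
    base_sl = ref.window_slice(ref.t0_offset, 0.0)
    if base_sl.stop <= base_sl.start:
        raise ValidationError("no pre-stimulus samples for baseline")
    base = float(np.median(med[base_sl]))
    dev = np.abs(med - base)
    peak = float(dev[ref.window_slice(*onset)].max())
    sus = float(dev[ref.window_slice(*sustained)].mean())
    if sus < 0.1:
        raise ValidationError("sustained below noise floor")
    return peak / sus


# ---------------------------------------------------------------------------
# input resistance


def input_resistance(step_sweep: Sweep, step: CurrentStep) -> Tuple[float, float]:
    """Steady-state and peak input resistance from a hyperpolarizing step.

    Steady state uses the median Vm over the last 10% of the step, peak the
    minimal Vm during the step; baseline is the median over the 10 ms before
    onset.  Returns ``(r_steady, r_peak)`` in MOhm.
    """
    if step.amplitude >= 0:
        raise ValidationError("hyperpolarizing steps only")
    base = baseline_median(step_sweep, (-10.0, 0.0))
    d = step.duration
    steady_sl = step_sweep.window_slice(0.9 * d, d)
    v_steady = float(np.median(step_sweep.samples[steady_sl]))
    step_sl = step_sweep.window_slice(0.0, d)
    v_min = float(step_sweep.samples[step_sl].min())
    i_na = step.amplitude * 1e-3  # pA -> nA
    r_steady = (v_steady - base) / i_na
    r_peak = (v_min - base) / i_na
    return float(r_steady), float(r_peak)
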