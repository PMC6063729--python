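"""Synthetic membrane-potential recordings with ground truth.

Generates :class:`~lso_ephys.core_io.CellRecord` objects whose statistical
structure matches the two archetypes the analysis is built to separate:

* **principal** cells — sub-millisecond EPSP half-widths, small
  (non-overshooting) action potentials, a single onset spike to ipsilateral
  tones, and a peaked-then-silent postsynaptic profile;
* **non-principal** cells — slow, summing EPSPs, large overshooting spikes,
  and sustained regular ("chopper") firing throughout the tone.

Postsynaptic potentials are difference-of-exponentials kernels driven by
homogeneous Poisson event trains; chopper spiking is a gamma-renewal process;
contralateral inhibition arrives with a latency that decreases linearly with
sound level (time-intensity trading); binaural spike output follows a
logistic function of ILD whose true parameters are stored in the ground
truth.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .core_io import CellRecord, CurrentStep, Sweep, ToneStimulus, ValidationError

__all__ = [
    "ArchetypeParams",
    "GroundTruth",
    "principal_params",
    "non_principal_params",
    "psp_kernel",
    "ap_template",
    "gen_spontaneous",
    "gen_tone_response",
    "gen_ild_series",
    "gen_current_step",
    "gen_cohort",
]


@dataclass
class ArchetypeParams:
    """Per-cell generative parameters for one archetype.

    Synaptic kinetics are set by PSP half-widths (ms, full width at half
    maximum); subthreshold statistics by Poisson event rates (events/s) and
    amplitude means/jitter SDs (mV).  Spike output is parametric: onset cells
    fire one near-onset spike per repetition with probability gated by a
    logistic function of ILD (midpoint ``ild_midpoint_db``, width
    ``ild_width_db``); chopper cells fire a gamma-renewal train whose rate is
    scaled by the same logistic gate.
    """

    class_label: str  # "principal" | "non_principal"
    epsp_half_width: float  # ms
    ipsp_half_width: float  # ms
    epsp_rate_spont: float = 300.0  # events/s
    ipsp_rate_spont: float = 60.0  # events/s
    epsp_amp: float = 3.5  # mV (mean)
    ipsp_amp: float = 2.5  # mV (mean, magnitude)
    epsp_amp_jitter: float = 1.0  # mV (SD)
    ipsp_amp_jitter: float = 0.8  # mV (SD)
    ap_amp_mean: float = 28.0  # mV above pre-stimulus baseline
    ap_threshold: float = -45.0  # mV
    resting_vm: float = -60.0  # mV
    firing_mode: str = "onset"  # "onset" | "chopper" | "sustained_irregular"
    chopper_isi_mean: float = 4.0  # ms
    chopper_isi_cv: float = 0.2
    ipsp_latency_at_ref: float = 7.0  # ms at ref_level_db
    ipsp_latency_slope: float = 0.12  # ms decrease per dB above ref
    ref_level_db: float = 70.0
    noise_sd: float = 0.3  # mV
    membrane_tau: float = 1.0  # ms
    sag_fraction: float = 0.15
    input_resistance_mohm: float = 45.0
    # evoked-response shape
    onset_epsp_amp: float = 8.0  # mV, stereotyped onset EPSP
    onset_ipsp_amp: float = 5.0  # mV magnitude, stereotyped onset IPSP
    driven_epsp_rate: float = 800.0  # events/s during ipsi tone
    driven_ipsp_rate: float = 150.0  # events/s during contra tone
    driven_epsp_amp: float = 1.2  # mV, sustained barrage events
    driven_ipsp_amp: float = 0.8  # mV magnitude
    epsp_onset_latency: float = 6.0  # ms
    spike_latency: float = 6.8  # ms (onset mode)
    spike_jitter: float = 0.3  # ms SD (onset mode)
    spike_prob_peak: float = 0.97  # onset-mode firing probability, no inhibition
    ild_midpoint_db: float = -10.0
    ild_width_db: float = 4.0
    series_resistance: float = 61.3  # MOhm, recorded as metadata
    crosstalk_db: Optional[float] = None  # interaural attenuation; None = off

    def __post_init__(self) -> None:
        if self.epsp_half_width <= 0 or self.ipsp_half_width <= 0:
            raise ValidationError("PSP half-widths must be positive")
        if not (0.0 <= self.chopper_isi_cv < 1.0):
            raise ValidationError("chopper_isi_cv must lie in [0, 1)")
        if self.ap_amp_mean <= 0:
            raise ValidationError("ap_amp_mean must be positive")


def principal_params(**overrides) -> ArchetypeParams:
    """Default principal archetype: fast, small-spiked, onset-firing."""
    p = ArchetypeParams(
        class_label="principal",
        epsp_half_width=0.6,
        ipsp_half_width=1.5,
        ap_amp_mean=28.0,
        firing_mode="onset",
        membrane_tau=1.0,
        input_resistance_mohm=45.0,
    )
    return replace(p, **overrides)


def non_principal_params(**overrides) -> ArchetypeParams:
    """Default non-principal archetype: slow, large-spiked, chopper-firing."""
    p = ArchetypeParams(
        class_label="non_principal",
        epsp_half_width=4.0,
        ipsp_half_width=5.0,
        epsp_rate_spont=120.0,
        ipsp_rate_spont=30.0,
        ap_amp_mean=66.0,
        firing_mode="chopper",
        membrane_tau=6.0,
        input_resistance_mohm=90.0,
        onset_epsp_amp=10.0,
        onset_ipsp_amp=4.0,
        driven_epsp_rate=500.0,
        driven_epsp_amp=3.0,
        driven_ipsp_rate=300.0,
        driven_ipsp_amp=2.5,
        ild_midpoint_db=-8.0,
        ild_width_db=5.0,
    )
    return replace(p, **overrides)


@dataclass
class GroundTruth:
    """True event times and generative parameters behind a synthetic record."""

    class_label: str
    epsp_times: List[np.ndarray] = field(default_factory=list)  # per rep, ms
    ipsp_times: List[np.ndarray] = field(default_factory=list)
    spike_times: List[np.ndarray] = field(default_factory=list)
    ild_sigmoid: Optional[dict] = None  # midpoint_db, width_db, ceilings
    ipsp_onset_latency: Optional[float] = None  # ms, this condition


# ---------------------------------------------------------------------------
# kernels


def _unit_fwhm(rise_ratio: float) -> float:
    """FWHM of exp(-t) - exp(-t/rise_ratio) (peak-normalized), tau_decay = 1."""
    r = rise_ratio
    t_peak = math.log(1.0 / r) * r / (1.0 - r)
    peak = math.exp(-t_peak) - math.exp(-t_peak / r)

    def half(t: float) -> float:
        return (math.exp(-t) - math.exp(-t / r)) / peak - 0.5

    left = brentq(half, 1e-12, t_peak)
    right = brentq(half, t_peak, 60.0)
    return right - left


def psp_kernel(
    kind: str,
    amplitude: float,
    half_width: float,
    sampling_rate: float,
    rise_ratio: float = 0.2,
) -> np.ndarray:
    """Difference-of-exponentials PSP kernel.

    The decay time constant is solved so the kernel's full width at half
    maximum equals ``half_width`` (ms); the sampled peak equals ``amplitude``
    exactly, negated for ``kind='ipsp'``.
    """
    if kind not in ("epsp", "ipsp"):
        raise ValidationError(f"unknown PSP kind {kind!r}")
    if amplitude <= 0:
        raise ValidationError("amplitude must be positive (sign set by kind)")
    if half_width <= 0:
        raise ValidationError("half_width must be positive")
    dt_ms = 1e3 / sampling_rate
    if half_width < 3 * dt_ms:
        raise ValidationError(
            f"undersampled kernel: half_width {half_width} ms < 3 sample intervals"
        )
    tau_d = half_width / _unit_fwhm(rise_ratio)
    tau_r = rise_ratio * tau_d
    t_peak = tau_d * rise_ratio * math.log(1.0 / rise_ratio) / (1.0 - rise_ratio)
    t_end = t_peak + 8.0 * tau_d
    t = np.arange(0.0, t_end, dt_ms)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k *= amplitude / k.max()
    return k if kind == "epsp" else -k


def ap_template(sampling_rate: float, width_ms: float = 1.0) -> np.ndarray:
    """Stereotyped unit-peak action-potential waveform (fast rise, slower fall)."""
    dt = 1e3 / sampling_rate
    t = np.arange(0.0, width_ms, dt)
    rise_t = 0.25 * width_ms
    shape = np.where(
        t < rise_t,
        np.sin(0.5 * np.pi * t / rise_t) ** 2,
        np.cos(0.5 * np.pi * (t - rise_t) / (width_ms - rise_t)) ** 2,
    )
    return shape / shape.max()  # sampled peak exactly 1


def _events_to_trace(
    times_ms: np.ndarray,
    amps: np.ndarray,
    kernel: np.ndarray,
    n_samples: int,
    t0_offset: float,
    sampling_rate: float,
) -> np.ndarray:
    """Convolve a weighted delta train (event onsets) with a PSP kernel."""
    drive = np.zeros(n_samples)
    if times_ms.size:
        idx = np.round((times_ms - t0_offset) * sampling_rate / 1e3).astype(int)
        keep = (idx >= 0) & (idx < n_samples)
        np.add.at(drive, idx[keep], amps[keep])
        drive = fftconvolve(drive, kernel)[:n_samples]
    return drive


def _poisson_times(
    rng: np.random.Generator, rate_hz: float, t_start: float, t_stop: float
) -> np.ndarray:
    """Homogeneous Poisson event times (ms) on [t_start, t_stop)."""
    span_s = (t_stop - t_start) / 1e3
    if rate_hz <= 0 or span_s <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * span_s)
    return np.sort(rng.uniform(t_start, t_stop, size=n))


def _jittered_amps(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), 0.2 * mean, None)


def _add_spikes(
    vm: np.ndarray,
    spike_times: np.ndarray,
    params: ArchetypeParams,
    t0_offset: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> None:
    """Paste scaled AP templates so each peak reaches resting + ap_amp."""
    if spike_times.size == 0:
        return
    tmpl = ap_template(sampling_rate)
    peak_off = int(np.argmax(tmpl))
    for t_sp in spike_times:
        i0 = int(round((t_sp - t0_offset) * sampling_rate / 1e3)) - peak_off
        i1 = i0 + tmpl.size
        if i0 < 0 or i1 > vm.size:
            continue
        target_peak = params.resting_vm + params.ap_amp_mean
        add_amp = target_peak - vm[i0 + peak_off]
        if add_amp > 0:
            vm[i0:i1] += add_amp * tmpl


# ---------------------------------------------------------------------------
# spontaneous activity


def gen_spontaneous(
    params: ArchetypeParams,
    duration_s: float = 3.0,
    sampling_rate: float = 50_000.0,
    seed: int = 0,
) -> Tuple[Sweep, GroundTruth]:
    """Spontaneous activity: resting Vm + Poisson PSP trains + noise.

    Action potentials are fired (template pasted) wherever the summed
    noise-free synaptic depolarization crosses ``ap_threshold`` upward, with
    a 1 ms refractory period; with default parameters the EPSPs are
    subthreshold and spikes are rare.
    """
    if not (0.5 <= duration_s <= 10.0):
        raise ValidationError("duration_s must lie in [0.5, 10] s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    dur_ms = duration_s * 1e3

    e_times = _poisson_times(rng, params.epsp_rate_spont, 0.0, dur_ms)
    i_times = _poisson_times(rng, params.ipsp_rate_spont, 0.0, dur_ms)
    e_amps = _jittered_amps(rng, params.epsp_amp, params.epsp_amp_jitter, e_times.size)
    i_amps = _jittered_amps(rng, params.ipsp_amp, params.ipsp_amp_jitter, i_times.size)

    ek = psp_kernel("epsp", 1.0, params.epsp_half_width, sampling_rate)
    ik = psp_kernel("ipsp", 1.0, params.ipsp_half_width, sampling_rate)
    vm = params.resting_vm + _events_to_trace(
        e_times, e_amps, ek, n, 0.0, sampling_rate
    )
    vm += _events_to_trace(i_times, i_amps, ik, n, 0.0, sampling_rate)

    # threshold crossings of the noise-free synaptic drive
    above = vm >= params.ap_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    spike_times = []
    last = -np.inf
    for idx in crossings:
        t_ms = idx / sampling_rate * 1e3
        if t_ms - last >= 1.0:
            spike_times.append(t_ms)
            last = t_ms
    spike_times = np.asarray(spike_times)
    _add_spikes(vm, spike_times, params, 0.0, sampling_rate, rng)

    if params.noise_sd > 0:
        vm = vm + rng.normal(0.0, params.noise_sd, size=n)

    sweep = Sweep(
        samples=vm,
        sampling_rate=sampling_rate,
        t0_offset=0.0,
        stimulus="spontaneous",
        series_resistance=params.series_resistance,
        junction_corrected=True,
    )
    gt = GroundTruth(
        class_label=params.class_label,
        epsp_times=[e_times],
        ipsp_times=[i_times],
        spike_times=[spike_times],
    )
    return sweep, gt


# ---------------------------------------------------------------------------
# tone responses


def _ild_gate(params: ArchetypeParams, ild: Optional[float]) -> float:
    """Logistic suppression of spiking by contralateral level (1 = no inhibition)."""
    if ild is None:
        return 1.0
    return 1.0 / (1.0 + math.exp((ild - params.ild_midpoint_db) / params.ild_width_db))


def _ipsp_latency(params: ArchetypeParams, level_contra: float) -> float:
    """Level-dependent IPSP onset latency (time-intensity trading)."""
    lat = params.ipsp_latency_at_ref - params.ipsp_latency_slope * (
        level_contra - params.ref_level_db
    )
    return max(lat, 0.5)


def _gamma_renewal_train(
    rng: np.random.Generator,
    first: float,
    stop: float,
    isi_mean: float,
    isi_cv: float,
) -> np.ndarray:
    """Spike times of a gamma-renewal train starting near ``first`` (ms)."""
    if isi_mean <= 0 or stop <= first:
        return np.empty(0)
    shape = 1.0 / max(isi_cv, 1e-3) ** 2
    scale = isi_mean / shape
    times = [first]
    t = first
    while True:
        t += rng.gamma(shape, scale)
        if t >= stop:
            break
        times.append(t)
    return np.asarray(times)


def gen_tone_response(
    params: ArchetypeParams,
    stimulus: ToneStimulus,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
    t0_offset: float = -10.0,
    post_ms: float = 25.0,
) -> Tuple[List[Sweep], GroundTruth]:
    """Responses to one tone condition (``stimulus.n_reps`` repetitions).

    The ipsilateral ear drives a stereotyped onset EPSP followed by a Poisson
    EPSP barrage for the tone duration; the contralateral ear drives an onset
    IPSP whose latency decreases with level, plus a sustained IPSP barrage.
    Spike output depends on ``params.firing_mode``; for binaural stimuli the
    output is gated by the logistic ILD function stored in the ground truth.
    """
    rng = np.random.default_rng(seed)
    dur = stimulus.duration
    n = int(round((dur + post_ms - t0_offset) * sampling_rate / 1e3))
    ek = psp_kernel("epsp", 1.0, params.epsp_half_width, sampling_rate)
    ik = psp_kernel("ipsp", 1.0, params.ipsp_half_width, sampling_rate)

    drive_ipsi = stimulus.ear in ("ipsi", "binaural")
    drive_contra = stimulus.ear in ("contra", "binaural")
    gate = _ild_gate(params, stimulus.ild) if stimulus.ear == "binaural" else (
        1.0 if drive_ipsi else 0.0
    )

    sweeps: List[Sweep] = []
    gt = GroundTruth(class_label=params.class_label)
    onset_rate = 1e3 / 10.0  # one onset spike per rep over the 0-10 ms window
    sust_rate = (
        1e3 / params.chopper_isi_mean
        if params.firing_mode in ("chopper", "sustained_irregular")
        else 0.0
    )
    gt.ild_sigmoid = {
        "midpoint_db": params.ild_midpoint_db,
        "width_db": params.ild_width_db,
        "onset_ceiling_hz": params.spike_prob_peak * onset_rate,
        "sustained_ceiling_hz": sust_rate,
        "floor_hz": 0.0,
    }
    if drive_contra:
        gt.ipsp_onset_latency = _ipsp_latency(params, stimulus.level_contra)

    for _ in range(stimulus.n_reps):
        e_times = np.empty(0)
        i_times = np.empty(0)
        e_amps = np.empty(0)
        i_amps = np.empty(0)
        if drive_ipsi:
            onset_t = params.epsp_onset_latency + rng.normal(0.0, 0.15)
            barrage = _poisson_times(
                rng, params.driven_epsp_rate, onset_t + 1.0, dur + 2.0
            )
            e_times = np.concatenate([[onset_t], barrage])
            e_amps = np.concatenate(
                [
                    [params.onset_epsp_amp + rng.normal(0.0, 0.5)],
                    _jittered_amps(
                        rng, params.driven_epsp_amp, 0.3 * params.driven_epsp_amp,
                        barrage.size,
                    ),
                ]
            )
        if drive_contra:
            lat = gt.ipsp_onset_latency + rng.normal(0.0, 0.1)
            barrage = _poisson_times(
                rng, params.driven_ipsp_rate, lat + 1.0, dur + 4.0
            )
            i_times = np.concatenate([[lat], barrage])
            i_amps = np.concatenate(
                [
                    [params.onset_ipsp_amp + rng.normal(0.0, 0.4)],
                    _jittered_amps(
                        rng, params.driven_ipsp_amp, 0.3 * params.driven_ipsp_amp,
                        barrage.size,
                    ),
                ]
            )

        vm = params.resting_vm + _events_to_trace(
            e_times, e_amps, ek, n, t0_offset, sampling_rate
        )
        vm += _events_to_trace(i_times, i_amps, ik, n, t0_offset, sampling_rate)

        # parametric spike output
        if not drive_ipsi or gate <= 0.0:
            spikes = np.empty(0)
        elif params.firing_mode == "onset":
            if rng.uniform() < params.spike_prob_peak * gate:
                spikes = np.asarray(
                    [params.spike_latency + rng.normal(0.0, params.spike_jitter)]
                )
            else:
                spikes = np.empty(0)
        elif params.firing_mode == "chopper":
            isi = params.chopper_isi_mean / gate
            if isi > 4.0 * dur:
                spikes = np.empty(0)
            else:
                first = params.spike_latency + rng.normal(0.0, params.spike_jitter)
                spikes = _gamma_renewal_train(
                    rng, first, dur + 2.0, isi, params.chopper_isi_cv
                )
        else:  # sustained_irregular: Poisson train
            rate = gate * sust_rate
            spikes = _poisson_times(rng, rate, params.spike_latency, dur + 2.0)
        # refractory clean-up
        if spikes.size > 1:
            keep = [0]
            for j in range(1, spikes.size):
                if spikes[j] - spikes[keep[-1]] >= 1.0:
                    keep.append(j)
            spikes = spikes[keep]

        _add_spikes(vm, spikes, params, t0_offset, sampling_rate, rng)
        if params.noise_sd > 0:
            vm = vm + rng.normal(0.0, params.noise_sd, size=n)
        sweeps.append(
            Sweep(
                samples=vm,
                sampling_rate=sampling_rate,
                t0_offset=t0_offset,
                stimulus=stimulus,
                series_resistance=params.series_resistance,
                junction_corrected=True,
            )
        )
        gt.epsp_times.append(e_times)
        gt.ipsp_times.append(i_times)
        gt.spike_times.append(spikes)
    return sweeps, gt


def gen_ild_series(
    params: ArchetypeParams,
    frequency: float,
    ipsi_level: float,
    contra_levels: Sequence[float],
    n_reps: int = 30,
    seed: int = 0,
    duration: float = 70.0,
    sampling_rate: float = 50_000.0,
) -> Tuple[Dict[str, List[Sweep]], Dict[str, GroundTruth]]:
    """Binaural sweep sets over a range of contralateral levels.

    Returns a protocol map keyed ``ild_c<level>`` plus per-condition ground
    truth; every ground truth carries the same true ILD sigmoid.
    """
    if len(contra_levels) < 3:
        raise ValidationError("need at least 3 contralateral levels")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(contra_levels))
    protocols: Dict[str, List[Sweep]] = {}
    truths: Dict[str, GroundTruth] = {}
    for lvl, s in zip(contra_levels, child_seeds):
        stim = ToneStimulus(
            ear="binaural",
            frequency=frequency,
            duration=duration,
            level_ipsi=ipsi_level,
            level_contra=float(lvl),
            n_reps=n_reps,
        )
        name = f"ild_c{lvl:g}"
        protocols[name], truths[name] = gen_tone_response(
            params, stim, seed=int(s % (2**31)), sampling_rate=sampling_rate
        )
    return protocols, truths


# ---------------------------------------------------------------------------
# current steps


def _sag_response(
    t_ms: np.ndarray,
    dv_steady: float,
    sag_fraction: float,
    tau: float,
) -> np.ndarray:
    """Step deflection with sag: peak = steady/(1-sag), relaxing to steady.

    Shape is A(1-exp(-t/tau)) - B(1-exp(-t/tau_h)) with A - B = steady; A is
    solved numerically so the extremum equals steady/(1-sag) exactly.
    """
    if sag_fraction <= 0:
        return dv_steady * (1.0 - np.exp(-t_ms / tau))
    tau_h = min(3.0 * tau, 18.0)
    dv_peak = dv_steady / (1.0 - sag_fraction)
    tt = np.linspace(0.0, max(t_ms.max(), 6 * tau_h), 4000)

    def extremum(a_scale: float) -> float:
        a = dv_peak * a_scale
        b = a - dv_steady
        f = a * (1.0 - np.exp(-tt / tau)) - b * (1.0 - np.exp(-tt / tau_h))
        ext = f.min() if dv_steady < 0 else f.max()
        return abs(ext) - abs(dv_peak)

    a_scale = brentq(extremum, 1.0, 50.0)
    a = dv_peak * a_scale
    b = a - dv_steady
    return a * (1.0 - np.exp(-t_ms / tau)) - b * (1.0 - np.exp(-t_ms / tau_h))


def gen_current_step(
    params: ArchetypeParams,
    step: CurrentStep,
    seed: int = 0,
    sampling_rate: float = 50_000.0,
    t0_offset: float = -10.0,
    post_ms: float = 40.0,
) -> Sweep:
    """Single-compartment linear response to a square current step.

    Hyperpolarizing steps show an I_h-style sag (peak deflection equals
    steady-state/(1 - sag_fraction)); depolarizing steps trigger one onset
    spike (onset archetype) or a gamma-renewal train (chopper archetype).
    """
    if abs(step.amplitude) > 3000:
        raise ValidationError("step amplitude must be within +/-3000 pA")
    rng = np.random.default_rng(seed)
    n = int(round((step.duration + post_ms - t0_offset) * sampling_rate / 1e3))
    t = t0_offset + np.arange(n) / sampling_rate * 1e3
    vm = np.full(n, params.resting_vm)
    dv_steady = step.amplitude * 1e-3 * params.input_resistance_mohm  # pA*MOhm -> mV

    in_step = (t >= 0.0) & (t < step.duration)
    ts = t[in_step]
    if step.amplitude < 0:
        vm[in_step] += _sag_response(ts, dv_steady, params.sag_fraction, params.membrane_tau)
    elif step.amplitude > 0:
        vm[in_step] += dv_steady * (1.0 - np.exp(-ts / params.membrane_tau))
    # decay after offset
    post = t >= step.duration
    if step.amplitude != 0 and post.any():
        v_end = vm[in_step][-1] - params.resting_vm if in_step.any() else 0.0
        vm[post] += v_end * np.exp(-(t[post] - step.duration) / params.membrane_tau)

    if step.amplitude >= 100.0:  # suprathreshold depolarization
        if params.firing_mode == "onset":
            spikes = np.asarray([1.5 + rng.normal(0.0, 0.2)])
        else:
            spikes = _gamma_renewal_train(
                rng, 2.0, step.duration, params.chopper_isi_mean, params.chopper_isi_cv
            )
        _add_spikes(vm, spikes, params, t0_offset, sampling_rate, rng)

    if params.noise_sd > 0:
        vm = vm + rng.normal(0.0, params.noise_sd, size=n)
    return Sweep(
        samples=vm,
        sampling_rate=sampling_rate,
        t0_offset=t0_offset,
        stimulus=step,
        series_resistance=params.series_resistance,
        junction_corrected=True,
    )


# ---------------------------------------------------------------------------
# cohorts


DEFAULT_PROTOCOLS = ("spontaneous", "ipsi_tone", "contra_tone", "ild", "step")


def _draw_cell_params(
    rng: np.random.Generator, label: str
) -> ArchetypeParams:
    if label == "principal":
        hw = rng.uniform(0.4, 0.9)
        amp = float(np.clip(rng.normal(28.0, 8.0), 10.0, None))
        return principal_params(
            epsp_half_width=hw,
            ipsp_half_width=rng.uniform(1.0, 2.5),
            ap_amp_mean=amp,
            resting_vm=rng.normal(-60.0, 2.0),
        )
    hw = rng.uniform(2.0, 6.0)
    amp = float(np.clip(rng.normal(66.0, 10.0), 10.0, None))
    return non_principal_params(
        epsp_half_width=hw,
        ipsp_half_width=rng.uniform(3.0, 8.0),
        ap_amp_mean=amp,
        resting_vm=rng.normal(-60.0, 2.0),
        chopper_isi_mean=rng.uniform(3.0, 5.0),
        chopper_isi_cv=rng.uniform(0.15, 0.35),
    )


def gen_cohort(
    n_principal: int = 12,
    n_nonprincipal: int = 12,
    seed: int = 0,
    include_protocols: Sequence[str] = DEFAULT_PROTOCOLS,
    n_reps: int = 30,
    spont_duration_s: float = 3.0,
    sampling_rate: float = 50_000.0,
) -> List[Tuple[CellRecord, Dict[str, GroundTruth]]]:
    """Synthetic cohort with per-cell parameter draws and true labels.

    Principal cells draw EPSP half-widths from U(0.4, 0.9) ms and AP
    amplitudes from N(28, 8) mV truncated above 10 mV; non-principal cells
    from U(2, 6) ms and N(66, 10) mV.  Each cell gets the protocols listed in
    ``include_protocols`` (all five by default).
    """
    if n_principal < 0 or n_nonprincipal < 0 or n_principal + n_nonprincipal < 1:
        raise ValidationError("cohort needs at least one cell")
    ss = np.random.SeedSequence(seed)
    labels = ["principal"] * n_principal + ["non_principal"] * n_nonprincipal
    cells: List[Tuple[CellRecord, Dict[str, GroundTruth]]] = []
    for i, (label, child) in enumerate(zip(labels, ss.spawn(len(labels)))):
        rng = np.random.default_rng(child)
        params = _draw_cell_params(rng, label)
        bf = float(np.exp(rng.uniform(np.log(2e3), np.log(20e3))))
        pos = float(
            np.clip(
                (np.log(bf) - np.log(1e3)) / (np.log(40e3) - np.log(1e3))
                + rng.normal(0.0, 0.04),
                0.0,
                1.0,
            )
        )
        seeds = rng.integers(0, 2**31, size=8)
        protocols: Dict[str, List[Sweep]] = {}
        truths: Dict[str, GroundTruth] = {}
        if "spontaneous" in include_protocols:
            sw, gt = gen_spontaneous(
                params, spont_duration_s, sampling_rate, seed=int(seeds[0])
            )
            protocols["spontaneous"] = [sw]
            truths["spontaneous"] = gt
        if "ipsi_tone" in include_protocols:
            stim = ToneStimulus(
                ear="ipsi", frequency=bf, duration=70.0, level_ipsi=70.0, n_reps=n_reps
            )
            protocols["ipsi_tone"], truths["ipsi_tone"] = gen_tone_response(
                params, stim, seed=int(seeds[1]), sampling_rate=sampling_rate
            )
        if "contra_tone" in include_protocols:
            stim = ToneStimulus(
                ear="contra", frequency=bf, duration=70.0, level_contra=70.0,
                n_reps=n_reps,
            )
            protocols["contra_tone"], truths["contra_tone"] = gen_tone_response(
                params, stim, seed=int(seeds[2]), sampling_rate=sampling_rate
            )
        if "ild" in include_protocols:
            ild_protos, ild_truths = gen_ild_series(
                params,
                frequency=bf,
                ipsi_level=50.0,
                contra_levels=np.arange(20.0, 85.0, 10.0),
                n_reps=n_reps,
                seed=int(seeds[3]),
                sampling_rate=sampling_rate,
            )
            protocols.update(ild_protos)
            truths.update(ild_truths)
        if "step" in include_protocols:
            for amp, s in ((-500.0, seeds[4]), (500.0, seeds[5])):
                step = CurrentStep(amplitude=amp, duration=100.0)
                protocols[f"step_{amp:g}"] = [
                    gen_current_step(
                        params, step, seed=int(s), sampling_rate=sampling_rate
                    )
                ]
        anat = (
            "principal"
            if label == "principal"
            else str(rng.choice(["class5", "marginal", "multiplanar"]))
        )
        cell = CellRecord(
            cell_id=f"synth_{label}_{i:02d}",
            anatomical_class=anat,
            bf=bf,
            normalized_position=pos,
            protocols=protocols,
        )
        truths["_params"] = params  # type: ignore[assignment]
        cells.append((cell, truths))
    return cells
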