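"""Spectral pipeline, spike detection, evoked profiles, input resistance."""

import numpy as np
import pytest

from lso_ephys import synth, vm_features as vf
from lso_ephys.core_io import CurrentStep, Sweep, ToneStimulus, ValidationError

FS = 50_000.0


def _sweep(samples, fs=FS, **kw):
    return Sweep(samples=np.asarray(samples, dtype=float), sampling_rate=fs, **kw)


class TestPreprocess:
    def test_low_frequency_attenuated(self):
        t = np.arange(int(3 * FS)) / FS
        sw = _sweep(5 * np.sin(2 * np.pi * 1.0 * t) - 60.0)
        y = vf.preprocess_spontaneous(sw)
        mid = slice(int(0.5 * FS), int(2.5 * FS))
        atten_db = 20 * np.log10(
            max(np.sqrt(np.mean(y[mid] ** 2)) / (5 / np.sqrt(2)), 1e-12)
        )
        assert atten_db <= -20.0

    def test_zero_trace_passes_through(self):
        y = vf.preprocess_spontaneous(_sweep(np.zeros(int(FS))))
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(int(3 * FS)) / FS
        sw = _sweep(5 * np.sin(2 * np.pi * 300.0 * t))
        y = vf.preprocess_spontaneous(sw)
        mid = slice(int(0.5 * FS), int(2.5 * FS))
        ratio = np.sqrt(np.mean(y[mid] ** 2)) / (5 / np.sqrt(2))
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_short_sample_rejected(self):
        with pytest.raises(ValidationError, match="insufficient"):
            vf.preprocess_spontaneous(_sweep(np.zeros(int(0.3 * FS))))


class TestAmplitudeSpectrum:
    def test_sinusoid_peak_at_exact_bin(self):
        t = np.arange(int(2 * FS)) / FS
        spec = vf.amplitude_spectrum(
            np.sin(2 * np.pi * 100.0 * t), FS, smooth_octaves=None
        )
        assert spec.frequencies[np.argmax(spec.normalized_amplitude)] == 100.0
        assert spec.normalized_amplitude.max() == 1.0

    def test_two_equal_tones_tie_at_unity(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 100.0 * t) + np.sin(2 * np.pi * 400.0 * t)
        spec = vf.amplitude_spectrum(x, FS, smooth_octaves=None)
        a100 = spec.normalized_amplitude[spec.frequencies == 100.0][0]
        a400 = spec.normalized_amplitude[spec.frequencies == 400.0][0]
        assert a100 == pytest.approx(1.0, abs=1e-6)
        assert a400 == pytest.approx(1.0, abs=1e-6)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValidationError, match="flat spectrum"):
            vf.amplitude_spectrum(np.full(1000, -60.0), FS)


class TestUpperCutoff:
    def test_single_pole_profile_hits_minus_6db_point(self):
        f = np.arange(1.0, 2000.0, 2.0)
        spec = vf.SpectrumResult(f, 1.0 / np.sqrt(1.0 + (f / 200.0) ** 2))
        fc = vf.upper_cutoff(spec)
        assert fc == pytest.approx(200.0 * np.sqrt(3.0), abs=2.0)  # one bin
        assert spec.upper_cutoff == fc

    def test_rectangular_spectrum_edge(self):
        f = np.arange(1.0, 1000.0, 1.0)
        a = (f <= 500.0).astype(float)
        fc = vf.upper_cutoff(vf.SpectrumResult(f, a))
        assert 500.0 <= fc <= 501.0

    def test_no_crossing_rejected(self):
        f = np.arange(1.0, 100.0)
        with pytest.raises(ValidationError, match="cutoff not reached"):
            vf.upper_cutoff(vf.SpectrumResult(f, np.ones_like(f)))

    def test_scale_invariance(self):
        """Multiplying the trace by k > 0 leaves the cutoff unchanged."""
        sw, _ = synth.gen_spontaneous(synth.principal_params(), 1.0, FS, seed=0)
        base = vf.upper_cutoff(vf.amplitude_spectrum(sw.samples - sw.samples.mean(), FS))
        for k in (0.1, 7.3):
            fc = vf.upper_cutoff(
                vf.amplitude_spectrum(k * (sw.samples - sw.samples.mean()), FS)
            )
            assert fc == pytest.approx(base, rel=1e-9)

    def test_cutoff_decreases_with_psp_half_width(self):
        """Slower synaptic kinetics must lower the spectral cutoff."""
        means = []
        for hw in (0.5, 1.0, 2.0, 4.0, 8.0):
            fcs = []
            for seed in range(3):
                p = synth.principal_params(epsp_half_width=hw, ipsp_half_width=hw)
                sw, _ = synth.gen_spontaneous(p, 3.0, FS, seed=seed)
                spec = vf.amplitude_spectrum(
                    vf.preprocess_spontaneous(sw), FS
                )
                fcs.append(vf.upper_cutoff(spec))
            means.append(np.mean(fcs))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestDetectSpikes:
    def _trace_with_spikes(self, times_ms, amp=15.0, noise=0.5, seed=0, dur=0.2):
        rng = np.random.default_rng(seed)
        n = int(dur * FS)
        v = np.full(n, -60.0) + rng.normal(0, noise, n)
        tmpl = synth.ap_template(FS)
        for t in times_ms:
            i = int(t * FS / 1e3)
            v[i : i + tmpl.size] += amp * tmpl
        return _sweep(v)

    @pytest.mark.parametrize("amp", [15.0, 80.0])
    def test_inserted_templates_recovered(self, amp):
        truth = [50.0, 90.0, 130.0]
        det = vf.detect_spikes(self._trace_with_spikes(truth, amp=amp))
        assert len(det) == 3
        peak_offset = 0.25  # template peak lag re insertion time
        for (t, _), t0 in zip(det, truth):
            assert abs(t - (t0 + peak_offset)) <= 0.2

    def test_noise_only_yields_nothing(self):
        rng = np.random.default_rng(1)
        sw = _sweep(rng.normal(-60.0, 1.0, int(FS)))
        assert vf.detect_spikes(sw) == []

    def test_refractory_merges_close_pair(self):
        det = vf.detect_spikes(self._trace_with_spikes([50.0, 50.5]))
        assert len(det) == 1


class TestApAmplitude:
    def test_template_spike_arithmetic(self):
        tmpl = synth.ap_template(FS)
        v = np.full(int(0.1 * FS), -58.0)
        i = int(0.05 * FS)
        v[i : i + tmpl.size] += 28.0 * tmpl  # peak at -30 mV
        assert vf.ap_amplitude([_sweep(v)]) == pytest.approx(28.0, abs=1e-9)

    def test_baseline_drift_after_window_ignored(self):
        tmpl = synth.ap_template(FS)
        v = np.full(int(0.1 * FS), -58.0)
        v[int(2e-3 * FS) :] += 5.0  # drift begins after the 2 ms baseline
        i = int(0.05 * FS)
        v[i : i + tmpl.size] += 28.0 * tmpl
        # peak sits at -58 + 5 + 28; baseline median stays -58
        assert vf.ap_amplitude([_sweep(v)]) == pytest.approx(33.0, abs=1e-9)

    def test_no_spikes_rejected(self):
        with pytest.raises(ValidationError, match="no APs"):
            vf.ap_amplitude([_sweep(np.full(1000, -60.0))])

    def test_recovers_configured_amplitude_on_cohort(self, small_cohort):
        errs = []
        for cell, truths in small_cohort:
            params = truths["_params"]
            meas = vf.ap_amplitude(cell.protocols["ipsi_tone"])
            errs.append(meas - params.ap_amp_mean)
        sem = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) <= max(1.0, sem)


class TestMedianEvoked:
    def test_constant_sweeps(self):
        sweeps = [_sweep(np.full(100, v)) for v in (-60.0, -55.0, -70.0)]
        assert np.allclose(vf.median_evoked(sweeps), -60.0)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        sweeps = [_sweep(rng.normal(-60, 3, 500)) for _ in range(7)]
        med = vf.median_evoked(sweeps)
        stack = np.vstack([s.samples for s in sweeps])
        oracle = np.sort(stack, axis=0)[3]  # middle of 7
        assert np.array_equal(med, oracle)

    def test_robust_to_spiking_outlier_rep(self):
        rng = np.random.default_rng(3)
        base = [_sweep(rng.normal(-60, 0.3, 500)) for _ in range(6)]
        spiky = base[0].samples.copy()
        spiky[200:250] += 60.0
        med_clean = vf.median_evoked(base)
        med_with = vf.median_evoked(base[1:] + [_sweep(spiky)])
        assert np.max(np.abs(med_clean - med_with)) < 1.0

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValidationError, match="ragged"):
            vf.median_evoked(
                [_sweep(np.zeros(100)), _sweep(np.zeros(100)), _sweep(np.zeros(99))]
            )


class TestPeakToSustained:
    def test_square_pulse_unity_ratio(self):
        n = int(0.1 * FS)
        sweeps = []
        for _ in range(4):
            v = np.full(n, -60.0)
            sw = Sweep(samples=v, sampling_rate=FS, t0_offset=-10.0)
            v[sw.window_slice(0.0, 80.0)] += 5.0  # flat depolarization
            sweeps.append(
                Sweep(
                    samples=v,
                    sampling_rate=FS,
                    t0_offset=-10.0,
                    stimulus=ToneStimulus(
                        ear="ipsi", frequency=8e3, duration=80.0, level_ipsi=70.0
                    ),
                )
            )
        assert vf.peak_to_sustained(sweeps) == pytest.approx(1.0, abs=1e-9)

    def test_generator_truth_ratio(self):
        """Onset EPSP over Poisson-barrage plateau: kernel-area oracle."""
        p = synth.principal_params(
            spike_prob_peak=0.0, noise_sd=0.1,
            driven_epsp_rate=4000.0, driven_epsp_amp=0.3,
        )
        stim = ToneStimulus(
            ear="ipsi", frequency=8e3, duration=70.0, level_ipsi=70.0, n_reps=30
        )
        sweeps, _ = synth.gen_tone_response(p, stim, seed=2)
        k = synth.psp_kernel("epsp", 1.0, p.epsp_half_width, FS)
        area_ms = k.sum() / (FS / 1e3)
        sustained = p.driven_epsp_rate / 1e3 * p.driven_epsp_amp * area_ms
        expected = p.onset_epsp_amp / sustained
        assert vf.peak_to_sustained(sweeps) == pytest.approx(expected, rel=0.15)

    def test_all_spiking_reps_rejected(self, onset_tone_sweeps):
        sweeps, _ = onset_tone_sweeps
        with pytest.raises(ValidationError, match="spike-free"):
            vf.peak_to_sustained(sweeps)


class TestInputResistance:
    def test_ideal_rc_ohms_law(self):
        p = synth.principal_params(
            noise_sd=0.0, sag_fraction=0.0, input_resistance_mohm=60.0
        )
        step = CurrentStep(-500.0)
        rs, rp = vf.input_resistance(synth.gen_current_step(p, step, seed=0), step)
        assert rs == pytest.approx(60.0, rel=0.01)
        assert rp == pytest.approx(60.0, rel=0.01)

    def test_sag_ratio(self):
        p = synth.principal_params(
            noise_sd=0.0, sag_fraction=0.2, input_resistance_mohm=60.0
        )
        step = CurrentStep(-500.0)
        rs, rp = vf.input_resistance(synth.gen_current_step(p, step, seed=0), step)
        assert rp / rs == pytest.approx(1.25, rel=0.03)

    def test_depolarizing_step_rejected(self):
        p = synth.principal_params()
        step = CurrentStep(500.0)
        sw = synth.gen_current_step(p, step, seed=0)
        with pytest.raises(ValidationError, match="hyperpolarizing"):
            vf.input_resistance(sw, step)
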