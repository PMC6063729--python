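# Methods

This note documents the models, estimators, parameter choices, and known
limitations of the package. Units throughout: membrane potential in mV,
time in ms (time 0 = stimulus or step onset; all analysis windows are
half-open `[a, b)`), sampling rates in Hz, current in pA, sound levels in
dB SPL. ILD = contralateral SPL − ipsilateral SPL, so negative ILDs mean
the excitatory (ipsilateral) ear is louder.

## Trace conventions and corrections

Recordings are stored as per-repetition sweeps grouped into protocols; all
sweeps of a protocol share one sampling rate and stimulus. The liquid
junction potential (10 mV) is subtracted once at ingest and recorded by a
flag; a second application raises an error rather than silently
double-correcting. Baselines are medians over stated windows, never means,
so occasional synaptic events do not bias them.

## Spectral kinetics (upper cutoff frequency)

The pipeline mirrors standard practice for quantifying membrane speed from
spontaneous activity:

1. subtract the median V_m of the first 10 ms;
2. high-pass filter at 10 Hz. The filter is a linear-phase FIR (Hamming
   window, ~5 Hz transition band, ~33 000 taps at 50 kHz) applied as a
   single centred pass by FFT convolution. A symmetric FIR applied centred
   is already exactly zero-phase; a forward–backward pass would only square
   the magnitude response at twice the cost on multi-second traces.
   Stop-band rejection at 1 Hz exceeds 50 dB (the test suite asserts
   ≥ 20 dB);
3. wavelet-denoise with a symlet-8 decomposition at level 5, soft
   thresholding with the heuristic-SURE rule applied per detail level, no
   noise rescaling (thresholds computed with σ = 1, the convention of the
   originating MATLAB `wden` interface). At 50 kHz the level-5 details span
   ≈ 0.8–25 kHz, so the denoiser removes broadband instrument noise while
   leaving the sub-kHz synaptic band essentially untouched (a clean 300 Hz
   test tone passes with < 1 % amplitude error);
4. compute one single-sided DFT magnitude over the full 2–6 s sample and
   smooth it with a running median over log-spaced bins (1/24 octave). The
   median window is floored at ±15 Hz: near 10–100 Hz a pure 1/24-octave
   window holds only a handful of DFT bins, and the estimator variance of a
   raw multi-second DFT (Rayleigh-distributed bin magnitudes) would
   otherwise make the half-maximum crossing unstable. One DFT + smoothing
   was chosen over Welch segment averaging to keep the full spectral
   resolution at low frequencies; the smoothing descriptor is recorded in
   the `SpectrumResult` metadata;
5. normalize to the maximum and report the **upper cutoff**: the linearly
   interpolated first downward crossing of 0.5 (−6 dB, amplitude
   convention) searching upward from the global spectral peak. Ties at the
   maximum break toward the lowest frequency; a spectrum that never crosses
   0.5 below Nyquist is an error, not a sentinel value.

The cutoff is scale-invariant by construction and decreases monotonically
with PSP half-width (tested over half-widths 0.5–8 ms).

## Spike detection and AP amplitude

Spikes are detected by a slope criterion: the trace is lightly smoothed
(0.15 ms boxcar), the slope measured over a 0.3 ms span, and candidates
opened where it exceeds 10 mV/ms. Each candidate takes the raw-trace local
maximum that follows (the search window extends itself while the trace is
still rising); detections within 1 ms merge, keeping the tallest peak. A
candidate must additionally rise ≥ 10 mV above the potential at its slope
crossing: large sub-millisecond EPSPs (~8 mV in ~0.15 ms) can match a small
action potential's slope but not its excursion, and without this floor they
are systematically miscounted as spikes. All three thresholds (slope,
refractory, minimum rise) are keyword arguments.

AP amplitude is the mean over all detected spikes of (peak V_m − median
V_m of the first 2 ms of the same sweep), pooled across every ipsilateral
tone presentation of the cell regardless of level.

## Evoked profiles and input resistance

Median evoked responses are pointwise medians across repetitions (exact
agreement with a sort-based oracle is part of the test suite). The
peak-to-sustained ratio first discards every repetition with a detected
spike inside the onset (5–15 ms) or sustained window (40–50 ms for stimuli
≥ 50 ms, else 20–25 ms), requires at least 3 surviving repetitions, then
takes max |median − baseline| in the onset window over mean
|median − baseline| in the sustained window. The ratio is therefore
*undefined* for cells that spike on nearly every repetition — true of the
onset archetype at high level and of sustained choppers — and the feature
assembly records it as absent rather than substituting a default; a
sustained deviation below 0.1 mV is likewise an error ("below noise
floor") since the quotient would be meaningless.

Input resistance uses hyperpolarizing steps only: baseline is the median
over the 10 ms before onset, steady state the median over the last 10 % of
the step, peak the minimum during the step; R = ΔV/I in MΩ.

## Spike-train statistics

Windowed rates are mean spike counts per repetition divided by window
duration; over a partition of the stimulus they add up exactly. The
regularity analysis assigns each interspike interval to the 1 ms bin
containing its *first* spike (no fractional spreading — the simplest
assignment consistent with a per-bin repetition criterion; the rule is
isolated in one function so alternatives can be swapped in), pools
intervals across repetitions, and computes per-bin mean, SD (ddof = 1),
and CV. A bin is included only when ≥ 20 % of repetitions contribute an
interval; onset-only responses therefore yield an empty curve (or, with
single-spike repetitions, no intervals at all — an explicit error). Bin
width (1 ms) is a parameter. Best frequency is the argmax of per-frequency
spike/EPSP counts, ties toward the lower frequency.

## ILD functions

Rates are computed per binaural condition in the onset (0–10 ms) or
sustained (10–25 ms) window — the sustained bound reflects the shortest
stimulus in the design (25 ms) — with the ipsilateral level required to be
fixed across the series. Fits are least-squares decreasing four-parameter
logistics on *rates* (normalized rates are for display only), with
deterministic initialization from data quantiles and the ILD axis centred
on its median during fitting: a common shift of all levels then changes
the problem bitwise not at all, making midpoint equivariance exact to one
float rounding. The reported slope range is the 20–80 % span,
midpoint ± ln(4)·width (a 10–90 % option exists). An all-equal-rate curve
is rejected as flat — this is the expected outcome for principal cells in
the sustained window and is treated as a result, not a failure.

## Classification and group statistics

Feature space is (log₁₀ cutoff, AP amplitude), z-scored. With anatomical
anchors (≥ 2 per class) unlabeled cells go to the nearest anchor centroid,
mirroring the assignment of histologically unrecovered recordings;
otherwise 2-means with farthest-pair initialization (deterministic,
order-invariant) runs, and the cluster with the higher mean log-cutoff is
called principal. Confidence is silhouette-style, (d_other − d_own)/max;
identical points with conflicting anchors get confidence 0. Cohorts with
fewer than four complete feature vectors are unassignable (two clusters
cannot be supported).

Group comparisons are Student pooled-variance t tests (not Welch) and
Hedges' g with the (n−1)-weighted pooled SD and *no* small-sample
correction: these are the conventions under which the published group
summaries (means ± SEM at n = 5 and 7) reproduce their printed t and g
values; the Welch and corrected variants are available behind flags.
Pearson correlations report two-tailed p from the t transform with
n − 2 df. The tonotopy check is a Spearman rank correlation with an exact
permutation p for n ≤ 8 (full enumeration; the factorial cost is
prohibitive beyond that) and the t approximation above.

## Anatomy

Normalized lateromedial position projects the soma onto the centerline
polyline (per-segment orthogonal projection, ties at corners toward the
smaller arc length) and reports the arc-length fraction from the lateral
end. For a smooth centerline this coincides with the
perpendicular-from-midline construction used at the bench; projection is
well-defined at polyline corners where a perpendicular is not. Somata
farther than twice the arc length are rejected as implausible. Coverage is
100 · Σ(apposition)/perimeter per EM section, averaged over sections, with
a validity flag requiring ≥ 3 sections; an apposition sum exceeding the
perimeter is an error.

## The synthetic generator

The generator produces the statistical structure the analysis consumes —
not biophysics. Its components:

* **PSPs** are difference-of-exponentials kernels (rise τ = 0.2 · decay τ;
  the decay constant is solved numerically so the FWHM equals the requested
  half-width; sampled peak exactly ± amplitude). A difference of
  exponentials was preferred over an alpha function so rise and decay are
  independently controllable while only a half-width must be specified.
* **Spontaneous activity** is resting V_m plus homogeneous-Poisson EPSP and
  IPSP trains convolved with those kernels, plus white Gaussian noise.
  Spikes arise where the noise-free synaptic sum crosses threshold (rare at
  default rates: EPSPs are subthreshold as in the recordings).
* **Tone responses**: the ipsilateral ear drives one stereotyped onset EPSP
  (latency 6 ms) plus a Poisson barrage for the stimulus duration; the
  contralateral ear an onset IPSP whose latency *decreases* linearly with
  level (0.12 ms/dB around a 7 ms reference at 70 dB — time-intensity
  trading) plus a sustained IPSP barrage. Spike output is parametric
  rather than threshold-derived, because the analysis consumes spike-time
  statistics and parametric output admits analytic oracles: onset cells
  fire one spike (latency 6.8 ± 0.3 ms) per repetition with probability
  0.97 gated by a logistic function of ILD; choppers fire a gamma-renewal
  train (ISI mean 4 ms, CV 0.2 by default) whose rate is scaled by the same
  gate. The true logistic (midpoint, width, ceilings) is stored in the
  ground truth. Chopper onset spikes are *not* separately suppressed, so
  non-principal onset-window ILD midpoints sit at more positive ILDs than
  their sustained-window midpoints — inhibition overcomes sustained but not
  onset firing, as seen in vivo.
* **Spike waveforms** are a stereotyped 1 ms template (0.25 ms rise) pasted
  so the absolute peak equals resting + configured AP amplitude; the
  measured amplitude then equals the configured one by construction.
* **Current steps** follow V(t) = rest + I·R·(1 − e^(−t/τ)); hyperpolarizing
  steps add an I_h-style sag whose transient coefficient is solved
  numerically so the peak deflection equals steady/(1 − sag_fraction)
  exactly — the closed form the input-resistance tests check.
* **Cohorts** draw per-cell parameters from two documented distributions:
  principal EPSP half-widths U(0.4, 0.9) ms and AP amplitudes N(28, 8) mV
  truncated above 10 mV; non-principal U(2, 6) ms and N(66, 10) mV. Input
  resistance defaults to 45 MΩ (principal) vs 90 MΩ (non-principal),
  matching the observation that principal cells are electrically leakier.
  Spontaneous PSP rates and IPSP amplitudes are not constrained by
  published numbers; the defaults (e.g. 300 EPSPs/s at 3.5 mV for
  principal cells) were chosen once for qualitative fidelity to published
  spontaneous traces and are exposed as ordinary parameters.

Everything is a pure function of (parameters, seed); identical seeds give
bit-identical traces.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: conductance dynamics (Kv1, I_h beyond the
phenomenological sag), level-dependent EPSP amplitudes and non-monotonic
rate-level functions, acoustic cross-talk (an optional leak term exists but
is off by default), spontaneous activity superimposed on evoked sweeps,
electrode series-resistance artifacts, and recording drift. Tests
demonstrate that the estimators recover known structure under the stated
noise model, not that real LSO data satisfy that model.

## Problem sizes and tolerances

Default analysis conditions: 50 kHz sampling, 3 s spontaneous samples,
70 ms tones at 30 repetitions, ILD series of 13 contralateral levels in
5 dB steps, 100 ms current steps. The cohort-recovery check runs ten
12 + 12 cohorts with spontaneous + ipsi-tone protocols (the two protocols
classification consumes); regularity uses 50 repetitions. These sizes give
each stochastic check a comfortable margin (e.g. classification recovery
≈ 99–100 % against a 95 % bound; chopper CV error ≈ 3–5 % against 15 %)
while the whole suite stays fast. ILD midpoint recovery is assessed as the
mean absolute error over six cells because a single onset-window midpoint
at 30 repetitions has ≈ 1 dB sampling SD. Closed-form checks (kernel FWHM,
Ohm's law, sag ratio, logistic inversion) use 1–3 % tolerances reflecting
discretization; oracle-equivalence checks (medians, counts, correlations,
projections) are exact or at float precision.

## Known limitations

* The heuristic-SURE threshold assumes unit noise SD; traces in mV are not
  rescaled (by design, matching the originating convention), so the
  denoiser's aggressiveness depends on the absolute signal scale.
* The regularity analysis' interval-assignment rule (bin of first spike) is
  one defensible reading of binned ISI analysis; fractional assignment
  would change bin occupancy near pattern transitions.
* The ILD fit assumes a monotone decreasing rate-ILD relation; cells with
  non-monotonic functions (e.g. cross-talk at high levels) would need the
  optional leak term and a richer model.
* `peak_to_sustained` cannot be computed for cells that spike on nearly
  every repetition at the tested level; sub-threshold levels must be
  recorded (or simulated) for those cells.
* Positions assume the centerline is traced lateral-to-medial; the code
  cannot detect a reversed polyline.
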