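# Methods

This note records the package's model, its numerical choices, and the
design decisions taken where the procedure was genuinely open, in enough
detail to re-derive every default.

## Coupling measure

Cross-frequency coupling is quantified as phase–amplitude coupling
between a slow phase band (delta 0.5–3 Hz or theta 3–8 Hz) and a fast
amplitude band (low gamma 40–70 Hz; high gamma 70–140 Hz, narrowed to
70–120 Hz at 256 Hz sampling where 140 Hz exceeds Nyquist). Signals are
band-passed with an 8th-order Butterworth filter applied
forward–backward — zero phase lag, effective order 16 — realized in
second-order sections for stability at the delta band's very low
normalized corner frequencies. The analytic signal supplies the
instantaneous phase (cosine convention: phase 0 at the positive peak of
the slow wave) and envelope.

The fast-band envelope is averaged over 40 equal slow-phase bins per
contact and per 1-minute non-overlapping window. The binned distribution
is summarized by its amplitude-weighted circular mean, which is the
maximum-likelihood mean of a von Mises fit; no significance threshold is
applied to individual windows. The resultant length in [0, 1] is kept as
a concentration index: 1 when all envelope mass sits at one phase, ~0
for flat (uninformative) distributions. Empty bins are excluded from the
mean rather than zero-filled. Since the estimator is scale-invariant,
envelopes are used in raw microvolts with no per-window normalization.

Two numerical choices matter here:

* **Whole-record filtering.** Filtering is applied to the continuous
  record, not per window, to avoid 60-s edge transients; the first and
  last 5 s of a record are excluded from histogramming. For long
  records the per-band analytic signal is obtained in a single FFT pass:
  the spectrum is multiplied by the exact squared-magnitude response of
  the 8th-order Butterworth (the amplitude response of forward–backward
  filtering) and negative frequencies are zeroed. The record is
  reflection-padded by 60 s to suppress circular wrap-around. This is
  mathematically the ideal zero-phase filter that `sosfiltfilt`
  approximates with edge padding; the two routes agree away from record
  edges (asserted in the tests), and the FFT route is ~3× faster, which
  is what makes the seeded 12-hour grid-search studies tractable on one
  CPU. The `bandpass_filter`/`analytic_signal` primitives keep the
  literal forward–backward/Hilbert path.
* **Undefined phases.** Samples with exactly zero envelope have no
  phase and are flagged NaN; windows with no valid samples yield NaN
  φ_c and are excluded from occupancy numerators and denominators.

## Ensemble occupancy, smoothing, alarms

The circle (−π, π] is partitioned into 11 equal half-open intervals
(width 2π/11 ≈ 0.571 rad) anchored at −π, the last interval closed at π.
Occupancy of an interval is the per-window fraction of contacts whose
φ_c lies inside it. With all contacts defined, occupancies over the 11
intervals sum to one.

The raw proportion is smoothed with a causal first-order Kalman filter
(random-walk state, x_t = x_{t−1} + w, z_t = x_t + v), initialized at
the first observation with variance r. Defaults q = 1e-4, r = 1e-2 give
a steady-state gain ≈ 0.095, i.e. an effective memory of roughly ten
1-minute windows — long enough to suppress single-window fluctuations,
short enough to track a shift developing over tens of minutes. Both
variances are configurable.

An alarm fires at the start of any window whose *smoothed* occupancy
exceeds the threshold, after which alarms are suppressed for a
refractory period equal to the assumed preictal duration. Thresholds are
proportions of contacts (grid 5–50% in 1% steps). A contact is
*implicated* in a preictal change when its in-interval incidence during
preictal windows is at least twice (inclusive) its interictal incidence,
or when it is interictally silent but preictally active.

## Prospective protocol and scoring

Training uses the span covering the first 4 seizures (configurable 2–4)
plus the longest candidate SOP, and no less than 10 h. The exhaustive
search over 4 band pairs × 11 intervals × SOP ∈ {10, 30, 60} min ×
46 thresholds minimizes the distance to perfect performance,
d = √((1 − SS)² + (FPR/FPR_ref)²) with FPR_ref = 1 false alarm/h
(configurable). Ties resolve to lower FPR, then higher SS, then the
deterministic grid order; configurations that alarm so densely that the
FPR denominator vanishes are discarded. One configuration is frozen and
applied unchanged to the test span.

A seizure counts as predicted when at least one alarm falls in
[onset − SOP, onset); an alarm is false when no onset falls in
(t, t + SOP]. The FPR denominator is the evaluation span minus all
preictal windows and minus time already under false warning (each false
alarm's refractory tail, not double-counting overlap with preictal
windows), in hours.

The random predictor raises alarms as a Poisson process at rate FPR, so
it predicts one given seizure with P = 1 − exp(−FPR·SOP) — the
probability of at least one event in a preictal window. σ_rand is the
smallest k/K whose upper binomial tail Pr[Binom(K, P) ≥ k] is below
α = 0.01; when even k = K is not significant (saturating FPR), σ_rand
is 1 and the patient cannot beat chance. Group significance is the
upper-tail binomial probability of observing at least n significant
patients among N at per-patient rate α_patient.

## Band-power baseline

Power spectra are estimated per channel over consecutive 5-s windows by
the Burg method at AR order 16 — a standard compromise between spectral
resolution and variance for short EEG windows; order is configurable.
The implementation is a vectorized Burg lattice recursion over all
windows at once (coefficients identical to the classic per-window
algorithm, asserted against an independent implementation in the
tests); spectra are evaluated from the AR polynomial on a 4096-point
FFT grid. Relative power of delta (0.1–4 Hz), theta (4–8 Hz) or gamma
(30–140 Hz) is the band integral divided by the integral over the whole
analyzed range, 0.1 Hz to min(140, 0.9·Nyquist) Hz, averaged over
channels. The detector thresholds this raw channel-averaged series with
the same alarm/refractory/scoring machinery as the coupling pipeline;
no Kalman smoothing is applied (smoothing is part of the coupling
pipeline's definition, not the baseline's), and the same refractory rule
is used for comparability. Windows with a degenerate AR fit (constant
signal) are dropped from the channel average.

One caveat worth knowing: near-noiseless sinusoids produce AR spectral
lines too narrow for the integration grid, and band fractions become
unreliable. Any broadband floor — always present in real or simulated
EEG — removes the issue.

## Synthetic ground truth

Each channel is slow + coupled fast + noise, in microvolts:

* the slow component is white noise band-passed to the slow band,
  synthesized at 64 Hz (the slow band lies far below that Nyquist),
  where its Hilbert phase and envelope are exact, then linearly
  interpolated to the target rate and scaled to 50 µV RMS. Synthesizing
  at a low rate yields an exact per-sample ground-truth phase and is an
  order of magnitude cheaper than full-rate filtering; the result is the
  same narrowband stochastic process;
* the fast carrier is band-passed white noise (40–70 Hz by default)
  scaled to 10 µV RMS and multiplied by the envelope
  1 + depth·cos(φ_slow − φ_target), clipped at zero (relevant only at
  depth 1). Interictally φ_target is the channel's interictal phase
  (default 0.81 rad); during [onset − SOP, onset) a seed-determined
  fraction of channels (default 60%) switches to the preictal phase
  (default 0.24 rad);
* white measurement noise at 5 µV.

Defaults describe the canonical study patient: 16 contacts, 256 Hz,
12 h, 6 seizures spaced > 1.5 h, SOP 30 min, modulation depth 0.8. The
last seizure sits at 11 h so that, under the 4-seizure/10-hour training
rule, its whole preictal hour falls inside the prospective test span.
Because the envelope's mean and power are independent of φ_target, a
preictal phase *shift* leaves every band power flat — the generator is a
built-in null for the power baseline. An optional preictal gamma gain
plants a genuine power rise instead, for testing the baseline itself.

What the generator deliberately does not emulate: ictal waveforms
(nothing happens *at* an onset beyond the annotation), sleep–wake power
modulation, artifacts, inter-channel correlation, or drifting coupling
phases. Passing tests therefore demonstrate the pipeline's mechanics —
extraction accuracy, detection, protocol correctness, calibration of the
chance comparison — not clinical performance on real EEG.

## Study sizes

The seeded reproduction studies use: 10 seeds × 3-channel 5-minute
recordings for coupling-phase recovery (worst-case error, all windows
and channels); 10 seeds × 6-channel 12-hour patients for full
parameter-grid recovery (band pair + interval + SOP); one 8-channel
16-hour patient (3 test seizures) for the coupling-vs-power contrast,
where each power band is granted its best test-span threshold at the
coupling detector's test FPR (floored at 0.5/h when the coupling FPR is
0) — an upper bound on what a trained baseline could achieve at a
matched rate. Channel counts below the 16-channel default keep the full
suite within minutes-per-study on a single CPU; recovery behaviour is
unchanged because occupancy contrasts scale with the shifted fraction,
not the absolute contact count.

## Known limitations

* EDF writing pads the record to whole seconds (EDF stores integral
  data records); exact sample-count round-trips hold for whole-second
  recordings.
* The 11-interval grid is fixed and anchored at −π; a trained phase
  interval is reported by its center, and planted phases near an
  interval edge can scatter estimates into the neighboring interval.
* σ_rand assumes alarm times of the random predictor are Poisson;
  refractory interaction is ignored, as is standard for this
  comparison.
* With very few test seizures, σ_rand = 1/K or 1 makes single-patient
  significance coarse; group-level statements are the intended use.
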