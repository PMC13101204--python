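# Methods

## Scope and flow

The package simulates action-observation (AO) EEG sessions, extracts the
occipital and sensorimotor descriptors that characterize the three AO
paradigms, decodes four-class targets with task-discriminant component
analysis (TDCA), and evaluates four cross-paradigm training schemes under
leave-one-run-out cross-validation. Stages are pure functions of their
inputs and integer seeds; identical config + seed reproduces every array
and accuracy exactly.

## Synthetic session model

A trial is a 32-channel epoch over −0.8 … 4.0 s at 500 Hz (2400 samples;
the 0–3 s stimulus segment holds 1500). It superposes:

* **SSMVEP** — Σ_h A_h sin(2π h f t + hφ) for harmonics h = 1, 2 during
  0–3 s, with A = (2.0, 0.8) µV. The phase φ is stimulus-locked: a fixed
  per-target base phase (drawn deterministically from the generator seed)
  plus per-trial Gaussian jitter (sd 0.2 rad). A fully uniform per-trial
  phase would make class-average templates cancel in expectation and defeat
  any template-matching decoder; steady-state responses are phase-locked to
  stimulus onset, so the locked-plus-jitter model is the physiologically
  sensible choice. Setting `phase_jitter` large recovers the unlocked
  regime. The scalp spread is a fixed occipital gain vector (1.0 at
  O1/Oz/O2, 0.6 at POz, 0.3 at P3/P4/P7/P8, 0 elsewhere).
* **Motion-VEP transients** — Gaussian-envelope deflections at onset:
  P1 at 170 ms (+3 µV), N2 at 245 ms (−4 µV), σ = 25 ms, same occipital
  topography. Latencies sit inside the ranges such components show in
  AO recordings; amplitudes are free parameters.
* **Sensorimotor rhythms** — alpha (10 Hz, 5 µV) and beta (20 Hz, 3 µV)
  sinusoids at C3 and C4 with random phase per trial. During 0–3 s the
  amplitude is scaled by (1 − d) with per-paradigm, per-hemisphere ERD
  depths d: RHTD (C3 0.55, C4 0.30), RHNTD (0.40, 0.22), LHTD (0.30,
  0.55) — contralateral deeper than ipsilateral and task-driven deeper than
  non-task-driven, matching the qualitative ordering the analysis is meant
  to exhibit. After 3 s the amplitude is (1 + 0.2), an ERS rebound. The
  envelope is piecewise-constant, so the stimulus/baseline alpha power
  ratio is exactly (1 − d)², which the tests verify against a rectangular
  band-power oracle.
* **Noise** — per-channel Gaussian noise spectrally shaped to 1/f
  (exponent 1.0), scaled to 15 µV standard deviation. This level puts
  within-paradigm 3-s decoding accuracy near 90 % with a clear 1 s → 2 s →
  3 s data-length trend, i.e. the realistic, non-saturated operating regime
  such studies report.

Sessions follow the study layout: runs of 20 trials (each target 5× in
random permutation), 12 visual-feedback runs (3 paradigms × 4) plus 4
action-feedback runs (RHTD/LHTD × 2), 320 epochs in a full session.
Per-trial seeds are derived from the session seed via `SeedSequence`, so
any epoch can be regenerated in isolation.

What the generator does **not** emulate: ocular/muscular artifacts,
electrode drift and impedance changes, inter-subject variability,
volume-conducted coupling between the occipital and sensorimotor sources,
attention lapses. Passing tests therefore demonstrate correctness of the
algorithms under the assumed signal structure, not real-data performance;
the study's real-EEG accuracy values are not reproduction targets.

The domain-shift model (`apply_domain_shift`) is an instantaneous linear
channel mixing with gain and additive white noise. It preserves frequency
content — the regime the least-squares transformation is designed to
correct — and deliberately omits nonlinear or nonstationary shifts.

## Preprocessing

* Bandpass 3–40 Hz: windowed-sinc FIR, Hamming window, 2 Hz transition
  (825 taps at 500 Hz), applied forward–backward (zero phase; squared
  magnitude response — passband ripple stays below 1 %).
* Epoching: 0-based sample indexing, half-open windows, onset sample is the
  first stimulus sample; per-channel baseline mean over −0.8 … 0 s
  subtracted.
* Amplitude rejection: a trial is dropped iff any |sample| strictly exceeds
  200 µV; boundary samples are kept.
* Surface Laplacian: L_i = V_i − mean of the six neighbours, maps
  C3 ← {FC5, FC1, T7, CP5, CP1, Cz} and C4 ← {FC6, FC2, T8, CP6, CP2, Cz}.
* Component-based artifact removal is a logged no-op hook: synthetic
  sessions contain no ocular/muscular components, and fitting a component
  classifier is out of scope.

## Features

* Amplitude spectra: single-sided FFT of the (trial-averaged) 0–3 s
  segment, normalized so a unit sinusoid at a bin frequency reads 1. At
  3 s the resolution is 1/3 Hz, which separates all four 60/N target
  frequencies; note 7.5 Hz is bin-aligned only on segments whose length is
  a multiple of 2/15 s (tests use a 2-s segment for exact-amplitude
  checks).
* ERSP: short-time Fourier transform, 500 ms Hann window, 90 % overlap;
  per frequency, 10·log10(mean trial power / mean baseline power), with
  baseline frames those fully inside −0.8 … 0 s. Band ERD averages the dB
  map over a band × window rectangle (alpha 8–12, beta 13–30, broad
  5–30 Hz).
* Laterality index LI = (ERD_C3 − ERD_C4)/(ERD_C3 + ERD_C4). ERD values
  enter by default as desynchronization magnitudes max(−dB, 0), so deeper
  contralateral ERD gives positive LI for right-hand paradigms and negative
  for the left-hand paradigm, and same-sign inputs keep LI in [−1, 1]; raw
  signed-dB entry is available via `convention="signed"`. Denominators
  below 1e−6 raise `UndefinedLateralityError` instead of returning ±∞.

## TDCA decoder

Channels P7, P3, P4, P8, POz, O1, Oz, O2; zero-phase Butterworth 3–30 Hz
(order 4); stimulus segments of 1, 2 or 3 s (N_p = 500/1000/1500).
References hold sin/cos at f_i and 2f_i over t = 1/f_s … N_p/f_s;
projectors come from the economy QR of Y_iᵀ and are kept in factored form
Q_iQ_iᵀ for speed. Delay count is 0 and no filter bank is used (both
configurable). Scatter matrices are channel-space (augmented 8 × 2N_p
trials); S_w is regularized by ε = 1e−6·tr(S_w)/dim; the generalized
symmetric eigenproblem keeps the top 4 components (the retained dimension
is a free parameter — the original method's choice is not fixed by the
study design). Eigenvectors are normalized to unit norm with the
largest-magnitude entry positive, making templates and correlations
independent of the eigensolver's arbitrary scaling. Classification uses
Pearson correlation of flattened projected features; zero-variance features
score 0; ties break to the smallest class index. The implementation is
verified label-for-label against an independent brute-force route (normal
equation projectors, dense eigendecomposition of (S_w + εI)⁻¹S_b, explicit
correlation loops) on random toy instances.

## Transfer schemes and evaluation

M1 trains on the target session's training runs; M2 on the full source
sessions only; M3 concatenates both; M4 first aligns each source session
to the target class templates via the per-class least-squares map
P = x x̃ᵀ(x̃ x̃ᵀ)⁻¹ and then concatenates. Design choices:

* LST granularity is per class from class-average pairs (20 trials per
  class average) rather than per trial — stabler at session sizes of 4 runs.
* M4's target templates come from the current fold's training runs only, so
  no test information leaks into the alignment.
* Near-singular Gram matrices fall back to a ridge solve with
  λ = 1e−8·tr/dim.
* Source sessions always enter in full and are preprocessed identically to
  the target (same band, same segment length).

Cross-validation is leave-one-run-out over the target session's runs
(fourfold for 4 visual runs; twofold for the 2-run action-feedback
setting), with per-fold accuracies, their mean ± sd and a pooled 4 × 4
confusion matrix.

## Problem sizes and numerical checks

Accuracy-level quantities are averaged over 20 independent session seeds
with 4-run (80-trial) sessions per paradigm; chance-level checks pool 800
noise-only trials; laterality indices average 10 sessions; oracle
equivalence uses 100 random toy instances (2–4 channels, 40–60 samples).
These sizes give stable estimates at desk scale — the study-size structure
(runs, trials, epoch timing) is kept exactly, while subject-level
replication is replaced by seed-level replication.

Degenerate inputs: rank-deficient references raise; fewer than two trials
per class raise; empty training partitions raise; constant (zero-variance)
test features correlate at 0. Determinism: every stochastic step draws from
`numpy.random.default_rng` seeded via `SeedSequence` chains rooted at the
user-supplied seed.

## Known limitations

* The generator's linear superposition ignores interactions between the
  SSMVEP and SMR sources; decoding uses occipital channels only, so ERD
  realism affects the feature tables, not the accuracies.
* LST here corrects linear channel-space shifts; the content-driven
  differences between task-driven and non-task-driven paradigms reported
  for real data are not representable by this shift model, so the package
  makes no claim about closing that gap.
* EDF output quantizes to 16 bits over ±600 µV (≈0.02 µV steps); signals
  exceeding the range are clipped at write time.
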