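# Methods

This note documents the models, parameter choices, and numerical
conventions behind `hybridbci`, and what the synthetic protocol can and
cannot demonstrate.

## Pipeline model

The system is a two-stage decoder over four frontal EEG channels
(Fp1, F7, F8, Fp2; 256 Hz). Stage 1 answers "is the user looking at the
7 Hz LED?" from the frequency domain; stage 2 answers "which of four
trajectories are the eyes tracing?" from the time domain. The stages are
deliberately asymmetric: the SSVEP response is narrowband and
amplitude-unstable (hence a scale-invariant spectral ratio), while the
ocular deflections are broadband, large, and morphology-coded (hence
time-domain shape features).

### Stage 1: spectral gate

Each 3 s window, band-passed 1–15 Hz, gets a Welch PSD with 640-sample
Hamming windows and 639-sample overlap. These protocol parameters give a
0.4 Hz grid (so the 4, 6, 8, 10 Hz band edges are exact grid points; the
FFT length equals the window length for the same reason) and K = 129
maximally overlapped sub-windows. With only 768 samples per window the
estimate has roughly one effective degree of freedom per bin — the heavy
overlap smooths but cannot add information — which bounds how separable
the gate feature can be at a given in-band SNR (see "Simulator
calibration" below).

The gate feature is the trapezoidal band-area ratio
A(6–8)/A(4–10) per channel: bounded in (0, 1], equal to 1/3 for a flat
spectrum, invariant to global amplitude scaling. The narrow band sits in
the numerator so that larger values mean "more 7 Hz concentration"; with
four active channels the gate classifier sees a 4-vector rather than a
pooled scalar, letting it weight channels by reliability.

### Stage 2: time-domain trajectory features

Per channel and window (band-passed 0.5–32 Hz): power = mean square,
energy = sum of squares (the standard discrete-signal definitions; they
differ by the constant window length, which no classifier cares about),
and all 21 coefficients of a degree-20 least-squares polynomial fit.
The fit is performed on a time axis affinely mapped to [−1, 1]: a raw
Vandermonde system on 768 integer sample indices at degree 20 is
numerically singular in double precision. Coefficients are reported in
descending-power order and named `<channel>_poly_t<power>`; they are
defined in the scaled domain. Assembly order is channel-major
(Fp1, F7, F8, Fp2), giving 4 × (2 + 21) = 92 named columns.

A known property of this representation: monomial coefficients of a
high-degree fit are strongly anti-correlated and individually noisy (the
basis is ill-conditioned even on [−1, 1]), so single-coordinate
signal-to-noise is much lower than the multivariate information content.
Tree ensembles tolerate this but do not fully exploit it; it is the main
reason absolute stage-2 accuracies on the simulator sit in the 60–80%
range rather than near the ceiling.

### Standardization and CORAL

Features are z-scored with sample (n−1) standard deviation; a
zero-variance column gets its scale replaced by 1 with a logged warning.
By default **each session is standardized with its own label-free
statistics**. This is what makes the subsequent covariance alignment
coherent: the CORAL map x → xA with
A = (C_s + λI)^(−1/2)(C_t + λI)^(1/2) acts linearly *through the
origin*, so it can align second moments but can never move a mean offset.
Per-session z-scoring removes first-moment and per-feature scale drift;
CORAL then aligns what z-scoring cannot — the cross-feature correlation
structure (e.g. a channel-mixing rotation). With train-only
standardization the evening grand means stay displaced and the
origin-anchored rescaling moves the training distribution *away* from the
test distribution; in every configuration we measured, that made CORAL
worse than no adaptation. A `standardize_per_session: false` switch
restores train-only fitting for comparison.

Both square roots are symmetric PSD roots via eigendecomposition with
eigenvalues clamped at zero. The ridge λ defaults to 0.1: on
standardized features all covariance eigenvalues are O(1), so λ = 1
would halve the alignment itself, while λ = 0.1 keeps the inverse root
well posed at d = 92 with the ~200 rows available per subject. CORAL is
fitted per subject (a pooled fit cannot represent subject-specific
electrode-shift geometry); target labels are never read.

### Classifiers and evaluation

Bagging (100 trees, max depth 15), random forest (50 trees, √d feature
subsets), and a one-vs-one SVM whose kernel/γ/C are tuned by a
30-evaluation randomized search with stratified 5-fold cross-validation
on training data only. All stochastic choices derive from the run seed;
classification runs are repeated over derived seeds (10 by default) and
averaged.

Stage-2 training uses morning LED-on windows whose gate decision was
correct (switchable); test windows are evening trajectory windows that
pass the gate (a `gate_bypass` switch evaluates stage 2 in isolation).
Per-class accuracy equals class recall; precision/recall/F1 are
macro-averaged, so with balanced classes macro recall equals overall
accuracy — the internal-consistency property the evaluation tables are
checked against. ITR uses the Wolpaw bit rate with a configurable
selection time (default 2.5 s); it is reported, never hard-coded into
decisions. The signed-rank test enumerates its null exactly (a
generating-function recursion equivalent to all 2ⁿ sign assignments,
n ≤ 25), drops zero differences with a warning, and uses average ranks
under ties.

ANOVA selection computes the one-way F per feature with the plain
between/within mean-square formula; constant columns get F = 0, p = 1
(dropped), zero-within-variance informative columns get p = 0
(retained). Retention is monotone in α. Note that after per-session
standardization and CORAL rotation, univariate F values on these
features are modest and the retained count on synthetic data (typically
10–30 of 92 at α = 0.05) is well below what strongly time-locked real
recordings would give; selection is therefore off by default and
available as a config switch.

## The synthetic protocol

The simulator emulates the acquisition protocol: per trial, 16 s of
1/f ("pink") plus white background noise; for LED-on classes a 7 Hz
sinusoid with a weaker 14 Hz harmonic (random phase per trial,
channel-specific gains); a deterministic, time-locked trajectory
template active during the central 10 s; for the LED-off class randomly
timed saccade-like steps instead; blink artefacts (positive biphasic
pulses, Poisson arrivals at 0.15/s) in *all* classes so the gate cannot
key on artefact presence. Templates encode gaze direction by channel
pattern: vertical sweeps drive Fp1/Fp2 with equal sign, horizontal
sweeps drive F7/F8 with opposite signs, and the two diagonal classes are
sums differing only in the horizontal sign. The sweep period is 2.0 s
(five sweeps per 10 s window), placing trajectory energy safely inside
the 0.5–32 Hz stage-2 band. Everything is a pure function of
(config, subject, session, class, repetition); per-subject gains and
shift realizations come from per-subject substreams.

### Session shift

The evening session differs by a per-subject realization of:
channel mixing (I + εM, ε = 0.2, M standard normal) standing in for
electrode repositioning; per-channel gain drift uniform in [0.8, 1.25]
(impedance change); background-noise SD × 1.2 (end-of-day
restlessness); and a 1 µV-SD constant baseline offset (mostly removed by
the high-pass edge). Setting all four to neutral values reproduces
identically distributed sessions. Mixing is deliberately the dominant
component: it is the type of drift that per-session z-scoring cannot
absorb and covariance alignment can, which is exactly the mechanism the
pipeline exists to demonstrate. Gain-type drift is instead absorbed
by the per-session standardizer, as in the real method.

### Simulator calibration

Defaults were fixed once against the generator's own contracts: the
band-ratio gate must separate LED-on from LED-off at ≥95% under the
stage-1 protocol, the shifted sessions must cost a morning-trained
stage-2 decoder ≥5 accuracy points relative to within-session
performance, and CORAL must recover part of that loss. The SSVEP
fundamental is 8 µV against ~10 µV RMS pink + 2 µV white noise
(≈ +7 dB in the 6–8 Hz band): with only ~1.2 independent PSD averages
per 768-sample window, a weaker tone leaves the per-window ratio
distributions too overlapped for the near-saturated gate performance the
protocol is designed around. Ocular deflections are 40 µV peak —
conservative for full-screen gaze sweeps at frontal sites (EOG
sensitivity is roughly 10–20 µV per degree periorbitally, attenuated at
Fp/F sites). Subject-level lognormal gain spreads (σ = 0.1–0.25) mimic
the across-subject performance spread visible in per-subject result
tables.

### What the simulator does not show

Passing on synthetic data demonstrates the pipeline's mechanics —
correct feature definitions, leak-free train/test separation,
deterministic seeding, and the directional value of covariance
alignment under a linear session shift. It does not certify real-world
accuracy levels: real SSVEP/EOG data have non-Gaussian, non-stationary
noise, imperfect task time-locking, correlated artefacts, and shift
components (electrode pops, drowsiness) that are not linear maps of the
feature space. Absolute synthetic accuracies are therefore stand-ins;
only the contrasts (gate separability, with/without CORAL, neutral vs
shifted sessions) are meaningful.

## Numerical conventions and degenerate inputs

- Filters: Butterworth designs applied with second-order sections
  forward–backward (zero phase). Edge transients are handled by odd
  reflection padding of min(n−1, 3 s): the 0.5–1 Hz high-pass poles ring
  for hundreds of samples, so short generic paddings leave percent-level
  transients inside a 10 s trial. Signals shorter than the minimal pad
  are rejected.
- Welch: one-sided density scaling, so the trapezoidal integral of the
  PSD approximates the signal variance (checked against Parseval on
  white noise). Constant detrend per sub-window.
- Band areas: composite trapezoid over grid points inclusive of both
  edges; bands must lie inside the grid.
- Segmentation: half-open windows [start, start + 768) at multiples of
  the 448-sample stride. The protocol's stated "3 s windows with 1 s
  overlap" cannot produce its equally stated five windows over 2560
  samples; the count, which fixes all downstream dataset sizes, wins,
  and the stride is configurable.
- Polynomial fits reject rank-deficient systems and segments no longer
  than the degree.
- The standardizer guards zero-variance columns (scale ← 1, warning);
  CORAL rejects non-finite inputs and mismatched feature fingerprints;
  `predict` realigns permuted columns by name and rejects unknown ones.
- Exact Wilcoxon doubles average ranks to stay on an integer lattice;
  two-sided p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).

## Problem sizes used in the shipped checks

The test suite's stochastic study runs 3 subjects × 10 repetitions × 5
simulator seeds with 2 classifier repetitions; the acceptance script
runs 6 subjects × 10 repetitions at the full per-subject protocol.
These are the package's desk-scale study conditions (the protocol
itself specifies 15 subjects, which the defaults reproduce when run in
full via `configs/default.yml`).

## Known limitations

- The monomial-coefficient feature set is information-lossy per
  coordinate (see above); a Legendre or spline basis would classify
  better but would no longer be the documented feature definition.
- CORAL aligns second moments only; nonlinear or class-conditional
  shifts are out of its model class, and with ~200 rows at d = 92 the
  target covariance estimate is noisy — the ridge trades alignment
  fidelity for stability.
- The gate is trained and applied per subject; no cross-subject
  transfer is attempted.
- Online/streaming operation, vendor file formats, and stimulus
  hardware control are out of scope.
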