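# Methods

`floorgait` implements a functional gait-assessment pipeline for muscular
dystrophy (MD) built on ambient floor-vibration sensing: geophones on the
floor record the vibration transients that footsteps induce, and the
package turns those recordings into gait symptoms and a predicted MD
functional stage. Because recorded patient data cannot ship with the
package, a synthetic gait-vibration simulator with exact ground-truth
annotations is a first-class component: every stage of the pipeline is
validated against it.

## The functional scale

Disease stage is anchored to 100-m run performance. The normative
percentage compares a subject's actual run time with an age- and
BMI-normed reference speed:

    predicted 100m % = (36.72 − 1.51·age + 0.26·weight/height²)
                       / actual time × 100

with age in years, weight in kg, height in m. The percentage is
discretized into stages 0–7 with half-open intervals whose lower edges
are 100, 80, 60, 50, 40, 30, 20 and 0 (stage 0 = at or above the median
control speed; the printed table lists integer ranges, and the half-open
convention covers the continuum without gaps; exactly 100% maps to
stage 0). The sensing system predicts the ambulatory range 0–5.

## Synthetic gait-vibration model

**Footstep pulse.** Each footstep is a 0.35–0.55 s transient: a damped
oscillation at the floor's natural frequency (default 15 Hz, inside the
typical 5–25 Hz floor band, damping ratio 0.25) plus a contact burst
whose frequency encodes the initial-contact type — heel strikes mainly
excite the floor resonance itself, while midfoot and toe strikes add a
frictional burst at 60 and 120 Hz respectively, reproducing the
heel < midfoot < toe dominant-frequency ordering. The amplitude envelope
is a fast (8 ms) attack with a ~0.18 s sustain, so the transient stays
above a 3-sd detection threshold for 0.2–0.4 s, matching the duration
band the detector expects. Pulses are peak-normalized so that amplitude
encodes footstep force and propagation attenuation rather than contact
type; without this, the stage-dependent contact mix (which is
hump-shaped across stages) would contaminate the symmetry score.

**Stage conditioning.** A stage-s gait profile draws around per-stage
anchors: cadence 105/112/118/112/100/88 steps/min for stages 0–5 (an
increase through the heel→toe transition, then slowing as muscles
weaken), toe-contact probability 0.03→0.80 (monotone increasing),
left-right force ratio 1.0→1.85 (monotone departure from symmetry;
stage 0 exactly symmetric) and step-time jitter 10→40 ms. Per-subject
jitter is small relative to between-stage spacing, so the monotone
trends hold draw by draw, not just in expectation.

**Trace synthesis.** Strike intervals are Normal(60/cadence, jitter)
(clipped at a quarter of the mean); alternating steps are scaled by the
inverse force ratio; the walker advances 0.6 m per step along the
walkway, and each sensor receives the shared source waveform attenuated
by exp(−0.35·distance). Gaussian ambient noise is added everywhere, and
a 2.5 s footstep-free lead provides the noise reference (first 2 s).
The default layout is four sensors at 0/2/4/6 m sampled at 500 Hz —
sufficient because ~97% of footstep power lies below 250 Hz; faster
recordings are lowpassed and can be decimated before feature
extraction. Distractor transients (footstep-like but isolated, 1.0 s
rumbles, 0.06 s blips) can be superimposed with logged intervals.

**Cohorts.** Subject biometrics (age 7–15, height grown from age, BMI
15–22) and a run time drawn by inverting the normative model reproduce
the assigned stage exactly under the functional scale, so the stage
label round-trips. Trace counts per subject vary in 5–10 to exercise
the median-rebalancing step.

What the simulator does *not* model: floor heterogeneity and modal
structure (a single resonance stands in for the slab dynamics),
footwear and surface variation, overlapping walkers, and sensor
nonlinearity/clipping. Passing tests therefore demonstrate that the
algorithms recover the generating structure under idealized propagation
— not clinical performance on real floors.

## Detection and denoising

A 0.1-s sliding window (half-window hop) computes the rectified mean
amplitude of the stream; windows exceeding the noise-reference mean by
three noise standard deviations merge into candidate impulses (an
absolute floor of 1e-6 replaces a degenerate zero-noise threshold).
Two footstep signatures filter the candidates: duration within
0.2–0.6 s (inclusive, with a 1e-9 float guard), then membership in a
run of at least three consecutive candidates, "consecutive" meaning
inter-onset gaps of at most 2 s — longer than any plausible step time,
shorter than the spacing of isolated disturbances. The filter is
idempotent. Denoising is an order-8 zero-phase Butterworth lowpass at
500 Hz (identity at the lab rate) followed by spectral-subtraction
Wiener gains Ŝ/(Ŝ+N), Ŝ = max(|X|²−N, 0), clamped to [0, 1], estimated
from the noise-reference periodogram — per-bin output power never
exceeds input power.

## Symptom extraction

Foot strikes are localized with a continuous wavelet transform using a
generalized Morse wavelet (γ = 3, β = 3; implemented directly in the
frequency domain as an analytic filter bank of 12 log-spaced voices)
summed over the 5–25 Hz floor band. β = 3 keeps the wavelet duration
near 60 ms at 15 Hz, resolving strikes at ~0.05 s. Peak-picking keeps
maxima with prominence ≥ 3× the median envelope and ≥ 0.25 s
separation; each peak is then walked back to its rising edge (25% of
peak height) because the strike occurs at the impulse onset, not the
envelope maximum (the residual bias is ~30 ms and cancels in step-time
differences). Step time, cadence (= (N−1)/(t_N−t_1), reported per
minute) and step-time variability (sample sd, n−1) follow from the
strike sequence. The symmetry score

    1 − (1/(N−1)) Σ |X90ⁱ⁺¹ − X90ⁱ| / (0.5 (X90ⁱ⁺¹ + X90ⁱ))

uses the 90th percentile of absolute amplitude per denoised footstep
(robust to clipping); it is 1 for equal adjacent steps, unclamped below
(it can be negative for extreme asymmetry), scale-invariant, and
undefined when any X90 is zero.

Initial-contact type is classified from the unit-sum footstep power
spectrum (0–250 Hz, 25 bins, Hann window) with a quadratic-kernel
support vector machine; margins are calibrated to probabilities by
cross-validated sigmoid (Platt) fitting, one-vs-rest, renormalized to a
simplex. The toe-class probability is the per-step toe-contact feature.

## Signal-based features

Per footstep: sample moments (sd with n−1; kurtosis raw, Normal → 3;
constant signals report 0 skewness/kurtosis by convention), dominant
frequencies of the strike and push-off phases (first and last 40% of
the window — the split is a fixed package convention), a 3-band
log-spaced PSD summary, energy (sum of squares) and a clipping flag
(≥ 3 consecutive samples at ≥ 99% of full scale). Per trace: energy
variability as the population coefficient of variation (bounded and
deterministic at n = 2), and the representative footstep — the
unclipped footstep of maximal energy (fallback: smallest clipping
extent) — summarized as a 10-bin unit-sum spectrum.

## Hierarchical model

Step-level vectors (dimension 12: step time, toe probability, sensor
number, four moments, two dominant frequencies, three PSD bands) feed a
12→256→64 rectifier network; trace-level vectors (dimension 14:
symmetry, step-time variability, cadence, energy variability, 10-bin
representative spectrum) concatenated with the mean step-level 6-class
probability feed a 20→128→32 network; the mean trace-level probability
concatenated with (age, gender∈{0,1}, BMI) feeds a 9→64 network. The
printed widths cannot accommodate passing a 64-wide embedding upward,
so the softmax-normalized 6-class output is what each level
aggregates — an interpretation documented here deliberately. Per-step
step time comes from detected impulse-onset differences (the last
footstep inherits the preceding interval); trace-level cadence and
variability use the higher-precision wavelet strike path. Each
(walking pass, sensor) pair is one trace sample.

Training is teacher-enforced: each level is pretrained against the
broadcast stage labels with cross-entropy, 20% inverted dropout
(training only), Adam at 1e-3, up to 200 full-batch epochs with early
stopping on a 10% validation split (patience 20); then the whole stack
is fine-tuned jointly for 100 epochs with gradients flowing through the
softmax and mean-aggregation links (loss = sum of the three levels'
cross-entropies, which keeps the teacher signal during joint training).
The train/test split is at footstep granularity (80/20) as the
reference protocol prescribes; a subject-level split is available via
`ModelConfig(split_by_subject=True)`. Standardization statistics are
fitted on training footsteps only. Aggregation is the element-wise
mean, hence permutation-invariant and unchanged by duplicating a
person's traces. Argmax ties break toward the lower (clinically
conservative) stage. All randomness flows through seeded generators;
training is bit-reproducible.

Per-subject trace-sample counts are rebalanced to the cohort median
(interpolated median, rounded): bootstrapping below, down-sampling
without replacement above.

## Evaluation conventions

Macro (unweighted) F-1 over classes with 0/0 → 0 per class; MAE in the
units of the target; confusion matrices report counts (rows = truth)
and column-normalized precision percentages. Detection experiments set
the noise level so the weakest footstep keeps a 20× amplitude SNR at
its best sensor and score greedy one-to-one onset matching within
0.15 s, with strikes fused across sensors by 0.15 s clustering. The
temporal-recovery experiment uses the standard power SNR (10 dB over
the active walking span); step-time MAE is computed over matched strike
pairs and cadence MAE per trace. The recovery experiment (12 subjects,
uniform stages, 5–10 traces each, 8–12 steps per trace, noise sd 0.02)
runs the complete chain — simulation, detection, feature extraction,
rebalancing, hierarchical training — in about 20 s on one CPU; these
problem sizes are the package's defaults and are what the acceptance
script reports.

## Known limitations

* The simulator's single-resonance floor and white noise understate
  real-floor dispersion and colored interference; real-data MAEs will
  exceed the synthetic ones.
* Contact-type spectra are generator conventions (no public spectra
  exist to calibrate against); the classifier's near-perfect synthetic
  accuracy reflects that separability, and the honest claims are the
  ordering and the calibration machinery, not the accuracy value.
* The footstep-level split follows the reference protocol but lets the
  model see every subject during training; the subject-level switch
  exists precisely because the footstep-level number is optimistic for
  unseen walkers.
* Step-length (spatial) estimation and separation of overlapping
  walkers are out of scope.
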