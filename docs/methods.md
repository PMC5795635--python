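# Methods

This note documents the models, conventions and defaults behind the
package, the design choices made where more than one reading was
defensible, and what the synthetic evaluation does and does not show.

## Codec

Sensors are configured with open full-scale intervals: (−4, 4) g
accelerometer, (−2000, 2000) °/s gyroscope, (−4, 4) gauss magnetometer.
The sensitivity of the underlying parts justifies 3 retained decimals for
accelerometer/magnetometer and 1 for the gyroscope, so quantization is a
decimal shift with truncation: `q = sign(v) · floor(|v| · 10^d)`. The
resulting integers fit 12 magnitude bits (accel/mag, |q| < 4000) and 15
(gyro, |q| < 20000), plus one sign bit each.

Conventions frozen here (the wire description leaves them open):

* **Field and bit order.** MSB-first; ax ay az, gx gy gz, (mx my mz);
  sign bit before magnitude; trailing zero padding. Any fixed convention
  works; this one is documented in FORMAT.md and locked by tests.
* **Two layouts.** The 87-bit/11-byte accel+gyro packet is canonical; the
  9-axis FULL layout (126 bits, 16 bytes) is provided because both fit a
  20-byte BLE characteristic value. The codec supports both; nothing else
  in the pipeline depends on the choice.
* **Canonical zero.** Negative zero is forbidden; a zero magnitude always
  carries a positive sign bit, so encodings are unique and
  encode∘decode∘encode is byte-identical.
* **Clamping, not erroring.** A physical value at or beyond full scale is
  clamped to the largest in-range integer with a logged warning: a live
  stream must survive a transient spike. Decoders, by contrast, *reject*
  integers outside the documented bounds — a malformed packet is evidence
  of corruption, not of a spike.
* **Truncation stability.** `|v|·10^d` is snapped to the nearest integer
  when within 10⁻⁹ of it before truncating. Without this, re-quantizing a
  dequantized value (e.g. 3.999 → 3998.999…96 → 3998) would drift one
  step per round trip; with it, quantize∘dequantize is the identity on
  representable values. The snap can raise a dequantized magnitude above
  the original by at most 10⁻⁹·10⁻ᵈ, far below the quantization error
  bound of 10⁻ᵈ.

## Windowing

Windows are defined by sample count (120 or 360 at the nominal 60 Hz), not
wall time, so identical sample sequences yield identical features
regardless of timestamp jitter. The online assembler emits exactly the
windows batch segmentation would; an inter-sample gap above twice the
nominal period restarts the buffer, and the trailing partial window of a
record is dropped rather than padded — padding would bias moments and
spectra. Both choices are tested as batch/online equivalence properties.

## Feature catalog (105)

Per axis (9 × 5 = 45): mean, sample standard deviation (N−1 throughout,
as the bias-corrected skewness/kurtosis formulas require), bias-corrected
skewness, bias-corrected excess kurtosis, zero-crossing rate. Per sensor
(3 × 5 = 15): unweighted averages of those five statistics. Correlations:
all C(9,2) = 36 unordered axis pairs — the only reading that reaches the
documented total of 105; the 9 within-sensor pairs are a subset.
Per acceleration axis (3 × 3 = 9): DC component |X₀|/N, spectral entropy,
spectral energy.

Conventions where the field leaves freedom:

* **Zero-crossing rate** = (pairs of consecutive samples with strictly
  opposite sign)/(N−1); zeros inherit the previous nonzero sign, so
  touching the axis is not a crossing.
* **Spectral entropy** is Shannon entropy (base 2) of the normalized
  power over the *non-DC* bins, so it measures spectral shape, not
  offset. An all-zero spectrum has entropy 0.
* **Spectral energy** is the mean of FFT coefficient magnitudes over
  *all* bins, DC included — taken literally from its defining formula.
  The DC term makes it sensitive to the gravity projection as well as to
  movement intensity, which is what the controller's false-detection
  filter exploits.
* **Degenerate inputs.** A constant axis has skewness, kurtosis, and any
  correlation involving it defined as 0 (a constant signal is symmetric;
  correlation with a constant is undefined, and 0 is the conservative
  choice). These rules make the all-zero window map to the all-zero
  feature vector.

Every formula feature is verified against plain-Python direct-summation
oracles to 1e−9 relative, and skewness/kurtosis additionally against an
independent statistics library's bias-corrected forms.

## Recognition

Tree induction is delegated to scikit-learn's `RandomForestClassifier`;
B, F, the split criterion and the seed pass through unchanged. The
majority vote is computed in this package from the individual trees'
predictions, because the delegate's `predict` averages class
probabilities rather than counting votes; ties break toward the
lexicographically first class, and all stochastic steps are seeded.

The three F rules are ⌊log₂ m⌋+1, ⌊√m/2⌋ and ⌊√m⌋ (for m = 105: 7, 5 and
10). The tuned operating point used throughout is B = 100 with F = ⌊√m/2⌋
for daily activities and F = ⌊√m⌋ for exercises. The tuning grid sweeps
B ∈ {50, 100, …, 500} × the three rules (30 configurations per
recognizer), scored by subject-level holdout — full LOO per cell would
multiply cost by the subject count without changing the ranking on
synthetic data.

Metrics: multi-class accuracy is trace/total of the confusion matrix; the
binary TP/TN/FP/FN form reduces to the same number. Per-class
precision/recall/F use the 0-when-undefined convention. The headline
F-measure is support-weighted across classes (macro available by flag).
Cohen's kappa uses marginal-product expected agreement; the degenerate
P_e = 1 case is defined as 0. All metrics are cross-checked against an
independent library on random label/prediction pairs.

Feature reduction: PCA operates on standardized features and is always
fitted on training rows only, then applied unchanged to test rows. The
supervised filter is correlation-based greedy forward selection (CFS-style
merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)`), with a feature's class correlation
taken as its largest absolute Pearson correlation against any one-vs-rest
class indicator — independent of any numeric class encoding. The original
system used a third-party toolkit's attribute selector whose exact
algorithm is unpublished; this reconstruction is flagged as an
approximation.

## Dual-mode controller

Exactly one recognizer runs at a time. In daily mode, 2 s windows feed the
daily model; predicting the dedicated switch-gesture class flips to
exercise mode and clears both window buffers, so the first exercise
prediction arrives one full 6 s window later — deliberately avoiding
mixed-activity windows. In exercise mode, a prediction of class c with
window energy e (the mean of the three per-acceleration-axis spectral
energies) is a **false detection** iff |e − ē_c| > τ·s_c, where ē_c and
s_c are that exercise's training-set energy mean and dispersion (s_c = 0
accepts only an exact match). K consecutive false detections revert to
daily mode.

The thresholds behind "too many errors" and "unrelatable energy" are not
quantified anywhere authoritative; the defaults are τ = 3 (a three-sigma
band) and K = 3, both exposed in `SwitchPolicy`. The designed reaction
latency follows from the geometry: entering exercise mode costs ~6 s (one
window), leaving it costs the 6 s refill plus up to K·3 s of rejections —
about 15 s with defaults. Session-recovery checks therefore exclude a
20 s guard band after each scripted mode boundary; steady-state mode
agreement is what is scored.

## Synthetic data

Signatures are per-axis {offset, sinusoids, Gaussian noise} — abstractions
chosen to exercise the computation under controlled separability, not
biomechanical models. The default library encodes the ordering the
recognizer relies on (running > walking > postural classes in RMS and
dominant frequency; a fast 5 Hz wrist-shake switch gesture unlike anything
else) and, critically, the premise of the energy filter: every exercise's
window-energy band (mean ± 3 s.d. across training windows and subjects)
excludes every daily activity's energy. Without that property the filter
cannot work on any data, real or synthetic. Exercise amplitudes are
accordingly large (they represent whole-body movements observed at the
wrist); all signatures keep samples strictly inside sensor full scale, so
the codec never clamps simulator output.

The default protocol per subject: walking 30 s, running 30 s, sitting
down ×10, standing up ×10, seated 30 s, switch ×10, and each of the four
exercises ×10 with repetitions back to back (4 s per repetition, so an
exercise block is 40 s and every 6 s window falls inside one label).
The default cohort is 10 subjects; per-subject amplitude and frequency
factors are lognormal with spread `jitter` (default 0.05 — subjects
differ mildly, as in a homogeneous healthy cohort). Increasing jitter
monotonically (in expectation) degrades cross-subject scores, which is
tested; jitter 0 makes subjects identical up to noise.

What passing synthetic tests shows: the pipeline is internally correct —
codec-exact, features match their formulas, no train/test leakage, the
controller implements its state machine, and the whole stack recovers
planted structure. What it does not show: recognition rates on real human
movement, which depend on kinematic variability no sinusoid model
captures. Published figures from wearable studies of this design (LOO
F-measures in the 0.95–0.99 range on ~10 healthy subjects) are not
reproducible here because no such dataset ships with the package.

## Problem sizes

Defaults were chosen so a full evaluation is interactive on one core: the
10-subject cohort is ~310 s of 60 Hz data per subject (~1440 daily and
~510 exercise windows cohort-wide), LOO with B = 100 takes seconds, and
the 30-point tuning grid runs on a reduced 4-subject cohort. The codec
round-trip check uses 10⁵ random samples.

## Known limitations

* Sinusoid-plus-noise signatures cannot express within-subject
  variability across repetitions beyond phase and noise; real repetitions
  drift in tempo and amplitude.
* The supervised feature filter approximates an unpublished algorithm;
  selected subsets will differ from the original system's.
* The energy filter assumes exercise energies are stable per class; on
  real patients (fatigue, progression) the training-time profile may go
  stale — re-profiling cadence is out of scope.
* Streams are assumed regularly sampled; irregular streams are gap-split,
  never resampled.
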