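# Methods

`gaitid` implements an identification pipeline for walking subjects wearing
five body-mounted IMUs (ankle, wrist, knee, chest, lower back), each with a
triaxial accelerometer and gyroscope sampled at 50 Hz. The pipeline isolates
gait cycles, expands each cycle into a smoothed Wigner-Ville time-frequency
image, trains one compact CNN per sensor/modality source, and fuses the ten
sources either at the input level (channel stacking) or at the score level
with a minimum-error weight-learning algorithm (MESF). This note records the
model, its assumptions, and the design decisions taken where the design was
genuinely open.

## Synthetic data generator

No public dataset accompanies the task, so the package ships a generator
whose output has, by construction, the structural properties the pipeline
depends on. Each subject is a `SubjectProfile`:

* cycle frequency `fcycle ~ U(0.8, 1.2)` Hz around the 1 Hz average of
  normal walking;
* for every (sensor, modality, axis), amplitudes and phases of harmonics
  1..4 of `fcycle`. Amplitudes scale as `1/h^1.5` so the fundamental
  dominates, with a per-(subject, sensor) gain in `U(0.4, 1.6)` making the
  sensor locations unequally informative, and overall modality scales of
  0.45 g (accelerometer) and 45 deg/s (gyroscope);
* additive white Gaussian noise, default 0.03 g / 3 deg/s.

A `SessionSpec` adds a leading rest interval (default 5 s; constant bias of
1 g on the accelerometer's vertical axis, zero on gyros), a session-constant
random rotation of each triaxial stream emulating casual sensor mounting,
and a sampling rate (default 50 Hz). All randomness flows from one integer
seed; identical (profile, spec) pairs produce bit-identical streams.

One deliberate property: the vector resultant of a near-harmonic signature
contains strong energy at `2*fcycle` (two steps per stride in real gait, the
squared-cosine cross-terms here) but, because the harmonic differences fall
at multiples of `fcycle` and `2*fcycle >= 1.6` Hz, only the fundamental lies
inside the 0.5-1.5 Hz cycle-frequency search band. The generator does **not**
model biomechanics, soft tissue artifacts, inter-session gait variation,
sensor quantization, or non-walking activity; a passing suite therefore
shows the pipeline's machinery is correct and discriminative on separable
periodic signatures, not that it reaches any particular accuracy on real
recordings.

## Preprocessing

The per-sample Euclidean norm (resultant) of a triaxial stream is invariant
under any session-constant rotation, which removes the mounting-orientation
nuisance exactly; this is verified to 1e-9 in tests. Rest-bias calibration
subtracts each axis's mean over the rest interval, so gravity and gyro bias
do not leak into the walking resultant. The gyroscope's initial direction
estimate is copied from the accelerometer's first sample and kept as
metadata only — nothing downstream consumes it, since the magnitude path
needs no orientation tracking.

Walking energy lives in 0.5-3.5 Hz, extracted with a 10th-order Butterworth
band-pass. Two numerical choices: the filter is realized as second-order
sections (a direct-form order-10 band-pass is numerically fragile at 50 Hz),
and it is applied forward-backward (`sosfiltfilt`, with odd-reflection
padding) so the zero-phase output leaves cycle markers unshifted. The
band-pass gain at 1 Hz is within 0.2% of unity; tests check tone amplitudes
against the filter's own squared magnitude response.

## Gait-cycle extraction

The ankle accelerometer (sensor 1) is the reference; its markers cut all ten
streams, which are time-synchronized. Steps:

1. **Cycle frequency**: an aggressive 0.5-1.5 Hz band-pass (used only here),
   then the DFT-magnitude argmax inside the band. Requires >= 10 s of signal
   (bin width <= 0.1 Hz).
2. **Local windows**: samples of the 0.5-3.5 Hz resultant with |value| below
   0.05 are neglected; the remainder forms maximal windows. Sub-threshold
   gaps shorter than about one nominal cycle (1 s default) are bridged so
   the near-zero passes inside a cycle do not fragment a walking bout. The
   0.05 threshold applies to the absolute value of the band-passed (hence
   zero-mean) resultant in the signal's own units.
3. **Cycle walk**: nominal length `offset = round(fs / fcycle)`; from the
   first rising zero crossing in a window, each tentative end
   `start + offset` snaps to the nearest rising crossing within ±25% of the
   nominal length, and the next cycle starts at the previous end. Zero
   crossings are rising crossings of the band-passed resultant (the raw
   resultant is non-negative and has none). If no crossing lies within the
   snap radius, that stretch is dropped and the walk restarts at the next
   crossing past the target — this also discards trailing partial cycles.
   The ±25% snap radius doubles as the irregular-cycle rejection rule:
   every emitted cycle is within 25% of the nominal length by construction.

Indices are 0-based and half-open everywhere, including the CSV exports.

## Time-frequency expansion

Cycles vary in length, so each excerpt is linearly resampled to 128 samples
(the effective sampling rate rescales accordingly, keeping the frequency
axis physical). The smoothed pseudo Wigner-Ville distribution of the
analytic signal (discrete Hilbert transform; suppresses negative-frequency
aliasing) is computed with independent Hamming smoothing windows: length
~len/8 (odd) over time, ~len/4 (odd) over lag. The lag window is normalized
to 1 at zero lag and the time window to unit sum, which makes the double
integral of the distribution match the time-domain signal energy up to edge
effects (tests require 10%). With the half-sample-lag discretization,
frequency bin k maps to `k*fs/(2*grid)`; the default grid is 128 bins. The
transform of a Hermitian lag autocorrelation is real; the imaginary residue
is below 1e-9 and discarded.

Rendering: absolute value (the distribution is not positive; clipping at
zero is available as a config switch), per-image min-max normalization to
[0, 1], bilinear resize to 120x120 (frequency increasing upward), and a
fixed 256-entry jet-like colormap shipped as a versioned CSV asset so images
are bit-reproducible across platforms. Per-segment descriptors (energy,
marginal-frequency peak) are recorded; the "principal track length" is
stored as the count of time bins whose frequency-ridge magnitude exceeds
10% of the maximum — an interpretation, flagged as such, and unused by the
classifier.

## Convolutional identifier

One model per source maps a 120x120x3 image (or 120x120x30 after early
fusion) to an M-class posterior:

    CONV3x3x32(pad 1)-ReLU-POOL2x2 -> CONV3x3x32-ReLU-POOL2x2 ->
    CONV3x3x64-ReLU-POOL2x2 -> FC64-ReLU -> FC M -> softmax

Padding keeps convolutions size-preserving; each pooling stage halves the
spatial size (120 -> 60 -> 30 -> 15), so inputs must be divisible by 8. The
stack realizes the "ten convolution/activation/pooling layers plus one
fully-connected layer" design with the 32/64 feature maps and 64 FC units of
the fixed hyper-parameter table; the exact depth reading is an
interpretation (9 CONV/ReLU/POOL layers + FC), documented here. Training is
mini-batch SGD with momentum (lr 0.001, momentum 0.9, batch 40) for exactly
19 epochs by default — a fixed stop, not early stopping. No augmentation,
dropout, or weight decay. Weights are fan-in-scaled Gaussian, seeded;
shuffling is seeded; runs are bit-reproducible. Max pooling is the default;
min pooling is available for comparison. Argmax ties break toward the
lowest subject index.

The implementation is pure numpy (im2col convolution, index-routed pooling
backprop deterministic under ties, explicit backpropagation), with float32
training by default and float64 available for gradient checks; every layer
is verified against brute-force loop oracles and central finite differences
(<= 1e-4 relative).

## Fusion

**Early fusion** concatenates the ten RGB images of one cycle into a
30-channel input in a fixed order (sensor 1..5, acc before gyro) and trains
one wider CNN.

**Late fusion** operates on the log-softmax score vectors S_i(x). The fused
score for subject j is `Score_j = sum_i w_ij * S_ij` with subject-dependent
non-negative weights. Scores are normalized to a log-likelihood ratio
against the average competitor evidence,

    LLR_phi = Score_phi - log( (1/(M-1)) * sum_{j != phi} exp(Score_j) ),

computed with overflow-safe log-sum-exp, and subject phi is detected when
`LLR_phi > theta_phi`. For the M-class identification decision the package
takes the subject with the largest LLR among those exceeding their
threshold, falling back to the global argmax (flagged) when none does; ties
go to the lowest index. Thresholds are learned on the validation split by a
minimum-error scan (candidates: the classify-all-negative extreme, the
midpoints of successive ranked values, and an all-positive extreme —
m + 1 candidates for m distinct values; smallest threshold on ties) and are
used for nothing else.

**MESF** initializes all weights at one — exactly the SUM fusion — and
re-estimates them one at a time in lexicographic order (source index, then
subject index), with a pass cap of 50. For the weight w_{i,phi}: it is
zeroed; segments already decided positive for phi are marked (their
detection cannot be improved by the scan the algorithm performs); for the
unmarked rest the boundary-crossing weight

    Theta_{i,phi}(x) = C(x) / S_{i,phi}(x),
    C(x) = theta_phi + log<(1/(M-1)) sum_{j != phi} exp(Score_j(x))>
           - sum_{k != i} w_{k,phi} S_{k,phi}(x)

is ranked, and candidate weights (zero, the previous value, the ranked
midpoints and boundary values, one past the largest) are each scored by the
**exact identification error of the full fusion on the training set** —
not only the subject-phi detection error, because the weight also shifts
every other subject's LLR through the competitor average. The best
candidate is kept; since the previous value is always a candidate, the
recorded per-update error trace is non-increasing by construction, and the
converged training error never exceeds the SUM fusion's. Degeneracies: an
all-identical score tensor returns the unit weights with a warning; a zero
S_{i,phi} makes the boundary independent of the weight and is excluded from
the ranking; candidate weights are clamped to [0, inf).

Two derivation notes. First, the boundary measure is derived algebraically
from the LLR decision rule, which places `exp(+Score_j)` in the competitor
average; a sign-flipped variant (`exp(-Score_j)`) circulates but is not
self-consistent with the decision rule, so the derived form is used.
Second, with N = 10 sources and M = 10 subjects the fusion has N x M = 100
weight parameters.

**Comparators**: SUM fusion (unit weights, argmax), and a one-vs-rest
linear SVM over the concatenated N x M score vector (one maximum-margin
classifier per subject, C = 100 so separable score sets are separated
exactly; duplicating training segments provably leaves the hyperplane
unchanged).

## Evaluation protocol

Ten-fold cross-validation on n segments uses per-fold sizes
`floor(n/10)` test, `floor((n - n/10)/5)` validation and
`floor(4(n - n/10)/5)` training, with `n/10` a real number inside the
floors; the floors need not sum to n, and leftover segments join the
training set (for n = 4178: 417/752/3008 with one leftover). Fold
assignment interleaves the subjects so every subject appears in each fold's
test and training sets. Accuracies are percent correct, reported to two
decimals; the relative error reduction between accuracies a > b is
`100(a - b)/(100 - b)`, to one decimal. Model comparison uses the two-sample
t-test (reporting only).

The bundled experiment (`run_pipeline`) defaults to a stratified holdout
split (20% test, 16% validation per subject) because ten-fold CV multiplies
the training cost tenfold; `split="10cv"` runs the full protocol. The
acceptance script and the end-to-end tests run 5 subjects x 50 s sessions
(~200 cycles), 48x48 images and 5 training epochs — sizes chosen so the
whole experiment runs on a single CPU in minutes while leaving every stage
exercised; accuracy comparisons between fusion and single sources are made
within a run, so the scale cancels out of the conclusion.

## Known limitations

* The generator's subjects are stationary: no inter-session variation, so
  cross-session generalization is untested by construction.
* MESF's coordinate scans optimize training error exactly but greedily; no
  global optimality is claimed (the underlying objective is piecewise
  constant and non-convex).
* The SWVD cross-term suppression is window-dependent; the default Hamming
  lengths are sensible for 128-sample cycles but are not tuned per dataset.
* The identification decision's threshold gating can underperform a plain
  argmax when validation-learned thresholds transfer poorly; the fallback
  flag in the output makes such segments visible.
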