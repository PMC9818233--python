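# Methods

This note documents the models, conventions and numerical choices behind
`pvcnet`, and what the synthetic-data experiments do and do not show.

## Problem setting

The task is binary beat classification on single-lead ECG: premature
ventricular contraction (PVC) versus normal sinus beat. The pipeline is
patient-specific by construction — a classifier is always evaluated on
subjects it never saw during training — because inter-subject morphology
variation is the dominant failure mode of beat classifiers deployed on
wearable devices.

## Record model and I/O

A record is a voltage series in millivolts at a fixed sampling rate with
beat annotations (sample index + WFDB mnemonic). Serialization follows
the PhysioNet WFDB convention, implemented in-package: text headers,
format-16 little-endian signals (amplitudes quantized to `round(mV·gain)`
ADC units, default gain 200 /mV as in the MIT-BIH digitizer), and the MIT
annotation byte format including long-interval (SKIP) encoding. The codec
supports exactly this subset; correctness rests on documented-format
round-trip tests. Amplitudes are converted to mV at read time so one unit
convention holds everywhere downstream.

Annotation symbols map totally onto {NORMAL, PVC, OTHER}: `'N'` → NORMAL,
`'V'` → PVC, all else OTHER by default (configurable). OTHER beats are
retained in the record (lossless) and discarded at labelling time.
Record-selection policies support an id exclusion list (e.g. the four
paced MIT-BIH records 102/104/107/217), a require-PVC filter, and
truncation to the first *k* records in ascending id order; ascending-id
truncation is this package's deterministic convention for "use k of n
records" subsets whose exact membership is not otherwise specified.

## Synthetic ECG generator

Each beat is a sum of Gaussian bumps, one per wave (P, Q, R, S, T).
Defaults encode textbook timing for the normal beat — P wave < 80 ms wide
centred 170 ms before R (PR within 120–200 ms), QRS ≈ 100 ms (measured at
5 % fractional-amplitude crossings), upright T — and the classic PVC
morphology: no P wave, QRS ≈ 180 ms (> 120 ms), inverted prominent T, and
an R amplitude either 140 % (left-ventricular origin) or 45 %
(right-ventricular origin) of the normal R. The two classes differ in QRS
width by ≈ 80 ms, far above the 20 ms separation the tests require, which
is what makes desk-scale learnability guarantees possible.

Rhythm: normal RR intervals are `base_rr · (1 + jitter)` with `base_rr`
constrained to the normal 0.6–1.2 s band (default 0.8 s, 3 % fractional
jitter). A PVC shortens its coupling interval to 0.7 × the local RR and
stretches the following interval to 1.3 × (compensatory pause); both
factors are configurable. Additive white Gaussian noise (default
0.02 mV sd) is a deliberate simplification: real records carry baseline
wander, powerline interference and muscle artifact, none of which are
modelled. Consequently, passing detector/classifier tests on synthetic
data demonstrates algorithmic correctness and end-to-end learnability,
not clinical-grade performance on hospital recordings.

All randomness flows through a single `numpy.random.Generator` seeded per
record (label draws first, then RR jitter, then noise), so a seed fixes
the record bit-for-bit across platforms. Amplitudes are snapped to the
ADC grid at generation time, making a WFDB write/read round trip exactly
the identity.

## Pan–Tompkins detector

The original integer-coefficient difference equations for 200 Hz input
are used verbatim (low-pass `(1−z⁻⁶)²/(1−z⁻¹)²`, high-pass
`z⁻¹⁶ − (1/32)(1−z⁻³²)/(1−z⁻¹)`, five-point derivative, squaring, 150 ms
moving-window integration), which is why records at other rates are
resampled to 200 Hz first (polyphase rational resampling). Stage group
delays (5 + 16 + 2 + 15 samples) are tracked explicitly so detections map
back to signal-domain indices.

Decision logic: candidate fiducials are local maxima of the integrated
signal taken at refractory-scale minimum separation (so amplitude-
quantization ripple on a single QRS's rising edge cannot produce several
candidates); signal/noise levels update as 0.125·peak + 0.875·level;
`THR1 = noise + 0.25·(signal − noise)`, `THR2 = 0.5·THR1`; 200 ms
refractory; a peak within 360 ms of the previous detection whose maximal
derivative magnitude is below half the previous beat's is rejected as a
T wave; when the gap since the last beat exceeds 1.66 × the limited RR
average, the largest skipped candidate above THR2 is accepted
(search-back). The learning phase (the paper trail is silent here)
initializes the signal level from the maximum and the noise level from
the mean of the integrated signal over the first 2 s. Each detection is
refined to the local extremum of the band-passed signal within ±40 ms and
mapped to native-rate indices by the exact rational ratio, with a final
±40 ms refinement on the native raw signal. Because every threshold is
derived from the signal itself, the detection list is invariant under
positive amplitude scaling.

## Segmentation, labelling, rendering

Beat windows use floor-division midpoints with half-open intervals and
0-based indexing; the first and last peaks are dropped (no two-sided
midpoint), so windows tile the covered span exactly and per-record beat
count is `max(0, #peaks − 2)`. The alternative reading of the midpoint
rule (±half the local RR centred on R) coincides with this one for
uniform rhythm; the implemented reading is the tiling one. Peaks must be
≥ 2 samples apart — guaranteed by the detector's refractory period — or
a window could exclude its own R peak.

Beats are anchored on reference annotation positions by default and on
detector output as a config switch (`build_dataset(anchor=...)`): the
former matches how annotated datasets are used for training, the latter
the deployed pipeline. Each beat takes the label of the nearest
annotation within 0.15 s of its R index; unmatched and OTHER-matched
beats are discarded with logged counts.

Rendering is a pure function of (samples, config): per-beat min–max
amplitude normalization (removing inter-record gain differences; a
constant beat renders as a mid-height line), polyline rasterized at the
target size with a 2-pixel dark-blue stroke on white, no axes or margins.
224×224 is the default because it is the canonical input size of the
pretrained 18-layer backbone; the desk-scale tests render at 64×64.

## Residual network

Basic block: `y = σ(BN(conv3×3(σ(BN(conv3×3(x))))) + shortcut(x))`.
Identity shortcuts are used wherever input and output dimensions agree
(adding no parameters); where channels double and the map halves (first
block of stages 2–4, stride 2) the default shortcut is a learned 1×1
projection `W_s x`; a parameter-free subsample-and-zero-pad mode is also
provided. Batch normalization follows every convolution (the canonical
layout); a pass-through mode turns every norm into the identity so the
algebraic unit tests can probe the residual addition exactly. The full
spec is the 18-layer layout (7×7/64 stride-2 stem, 3×3/2 max-pool, stages
64/128/256/512 × 2 blocks, global average pooling, 2-class softmax head);
its parameter count (11,177,538 with a 2-class head) is checked against
an independent arithmetic count. The "tiny" spec (16-filter stem, stages
16/32, 64×64 input, ~45 k parameters) exists because training the full
network on CPU is impractical at desk scale; the full spec remains the
default for real runs.

The engine is an in-package numpy implementation with explicit
forward/backward passes (im2col convolution, verified against nested-loop
oracles and finite differences). A pretrained ImageNet backbone is
consumed as an optional external input: `build_model(...,
pretrained_backbone=True)` loads a user-supplied checkpoint into all
layers except the always-randomly-initialized head, and raises an
explicit error directing offline users to `pretrained_backbone=False`
when no weights file is given. Backbone freezing during fine-tuning is
off by default (a config option).

## Training protocol

Loss: `l = −(1/|X|) Σ η_{i(x)} [y ln p + (1−y) ln(1−p)]` with
`η_c = 1 − |X_c|/|X|` per batch and p the predicted PVC probability
clamped to `[1e−7, 1 − 1e−7]`. The bracketed sum is negated so the
minimized quantity is non-negative and zero exactly at (clamped) perfect
prediction. With balanced batches the loss is exactly half the unweighted
binary cross-entropy. A literal single-class batch would zero its own
gradient (η = 0 for the present class); the weighted sampler makes this
rare, and if it occurs the batch falls back to unweighted loss with a
logged warning.

Sampling: item weights inversely proportional to class frequency, drawn
with replacement, giving 50/50 expected class frequency per epoch.
Augmentation (optional, off by default): per-draw affine jitter —
translation ≤ 5 % of the frame, scale 0.95–1.05, rotation ≤ 5°, bilinear
resampling — never persisted, and no horizontal flip since time reversal
would change beat semantics.

Optimization: Adam, initial learning rate 0.001, batch size 32, up to 200
epochs. A random 10 % of training items (beat-level, not subject-level)
is held out as validation — subject leakage into validation is accepted
as part of the protocol and noted here; the evaluation harnesses keep
*test* subjects strictly disjoint and assert it. "No improvement" means
the validation loss fails to drop by more than 1e−6 below the best seen.
After 5 consecutive non-improving epochs the learning rate is multiplied
by 0.1 (plateau counter resets); after 8, training halts; the
best-validation weights are restored. The schedule state machine is a
standalone component (`PlateauEarlyStop` / `replay_validation_trace`) so
its worked example — losses flat from epoch 60 with patience 8 halt
training at epoch 67 — is testable without any training.

Because the engine trains small models for few epochs, batch-norm running
statistics would lag the fast-moving weights and make eval-mode
predictions unrepresentative. After each epoch the running statistics are
therefore recomputed exactly over the training set at the current weights
(precise-BN recalibration, one forward pass), and snapshots of the best
state include them.

## Evaluation

The metric engine computes per-class precision, recall, F1 and
specificity (each class in turn as positive), overall accuracy, unweighted
macro averages, and balanced accuracy = (PVC recall + PVC specificity)/2,
always from raw counts — never from pre-rounded table entries, which can
disagree in the last printed digit. Zero-denominator metrics are reported
as undefined with a flag, not as 0. Printed percentages round half away
from zero to two decimals. In the binary case the specificity of one
class equals the recall of the other exactly; this duality is asserted.

Harness conventions: subject identity equals record identity (one record
per subject, as in the datasets this pipeline targets). LOSOCV aggregates
fold confusion matrices by element-wise summation (micro), so the
aggregate equals the whole-dataset tally; per-fold matrices and reports
are also returned. Hold-out is a random beat-level split; stratified
k-fold preserves class proportions within ±1 beat per fold (delegated to
scikit-learn's splitters). Cross-dataset and LOSOCV runs refuse
train/test subject overlap with the offending ids.

## Problem sizes in the shipped experiments

The scaled-down end-to-end experiment uses 10 synthetic subjects × 40
beats (20 % PVC, 0.02 mV noise), 64×64 images, the tiny network, 8-epoch
budget; the cross-dataset run uses 5 + 5 subjects × 30 beats. These sizes
were chosen so a full run completes in minutes on one CPU core while the
two classes remain cleanly learnable; at these sizes the expected
balanced accuracy is ≈ 1.0, and the acceptance threshold of 0.95 allows
for fold-level variation from the tiny validation splits.

## Known limitations

- The noise model is additive white Gaussian only; detector performance
  on records with baseline wander or artifact is untested.
- The WFDB codec covers format 16 single-segment records only.
- The numpy engine is CPU-bound and float64; full 18-layer training at
  224×224 is supported in principle but slow, and no pretrained weights
  ship with the package.
- Validation splitting is beat-level; early stopping therefore sees
  training subjects, as described above.
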