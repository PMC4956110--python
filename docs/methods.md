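# Methods

`songscribe` annotates birdsong: given single-channel audio and (for
training) note annotations, it locates note boundaries on a 1-ms grid and
assigns each note to a class. This note describes the models, the numerical
choices, and what the synthetic benchmark does and does not show.

## Signal front end

Spectrograms are short-time Fourier transforms with a 512-sample window,
32-sample hop (1-ms frames at 32 kHz), tapered with the 0th-order discrete
prolate spheroidal sequence (DPSS) at time-half-bandwidth product
`NW = 4` (half bandwidth `W = 4/512` cycles/sample), renormalized to unit L2
energy. Only bins whose center frequency lies in `[1 kHz, 8 kHz)` are kept —
112 rows at the defaults. Values are natural-log magnitudes floored at
`log_floor = 1e-10` (so silence maps to a finite constant). Spectrograms are
normalized by a single global mean and population standard deviation fitted
on the training fold only (a per-row variant is available via
`fit_normalization(per_row=True)`).

Conventions fixed here: frames are 0-based; frame `t` transforms samples
`[t*hop, t*hop + fft_size)` and trailing partial frames are dropped;
intervals are half-open `[onset, offset)` in frames. Because a frame's
*center* sits `fft_size/2` samples (8 ms) after its nominal start,
annotations given in waveform time are mapped onto the frame grid by the
frame-center rule (`align_to_frame_grid`, a -8-frame shift at defaults).
Skipping this shift biases every detected boundary by 8 ms.

Two amplitude envelopes are provided for threshold segmentation: the default
sums the raw log-magnitude rows per frame; the alternative full-wave
rectifies the waveform, applies a 4th-order zero-phase Butterworth low-pass
(200 Hz cutoff), takes the floored log, and samples at frame centers.

## Boundary detection by thresholding

Three passes in fixed order: (1) frames strictly above `amp_thr` form runs;
(2) gaps strictly shorter than `gap_thr` ms are merged; (3) runs strictly
shorter than `dur_thr` ms are discarded. The thresholds are fitted by
exhaustive grid search minimizing the pooled timing error rate on the
training pairs — the same objective reported at evaluation — with ties going
to the smaller amplitude, then gap, then duration threshold.

Amplitude candidates are 64 *evenly spaced* values between the 1st and 99th
percentile of the pooled envelope. Quantile-spaced candidates were tried
first and rejected: envelope values are strongly bimodal (silence mode vs.
note mode), so quantiles cluster inside the modes and undersample the narrow
transition band where the optimum lies, costing several ms of boundary
accuracy.

A structural limit worth knowing: the 512-sample (16-ms) analysis window
means a silent gap shorter than the window is never isolated in any frame,
so the envelope cannot resolve it — sub-window gaps are invisible to
thresholding no matter the thresholds. This is exactly the failure mode that
motivates HMM boundary detection, and it is why the synthetic generator's
default minimum gap is 20 ms (see below).

## Frame-wise convolutional classifier

All three pipeline arrangements share one fully-convolutional architecture
on 112-row spectrogram windows: three sets of [convolution, CCCP pooling,
2x2 stride-2 max-pool] with 16 channels (filters 5x5, 5x5, 4x4; a CCCP —
cascaded cross-channel parametric pooling — layer is a 1x1 convolution
acting as a learned cross-channel activation), then a 240-channel
convolution whose 11x9 filter collapses the remaining rows and covers one
note, then a 1x1 softmax convolution. The 9-frame width is forced by the
arithmetic: it is what reduces a 96-frame window (111 ms of audio) to one
output frame. The wide-window arrangement inserts one more 240-channel
convolutional layer whose 25-frame width reduces the 288-frame (303-ms)
window to one frame, letting the network integrate context spanning roughly
three notes. Output classes: `n` note classes for the
boundary-detection-first arrangement; `3n+1` (three equal-duration
sub-divisions per class plus silence) otherwise. Sub-division targets split
a `d`-frame note at `floor(d/3)` and `floor(2d/3)`.

The network is implemented directly on numpy: valid stride-1 convolutions as
shifted BLAS matrix products (with a single im2col + GEMM for small fan-in
layers), hand-written backpropagation, float32 parameters (float64 for the
finite-difference gradient check, which passes at 1e-4 relative error).
Weights use He initialization (`sigma = sqrt(2/fan_in)`), biases zero,
deterministic per seed. One "example" is a whole spectrogram excerpt: a
single pass scores every stride-8 window it contains.

**Dense per-frame scores.** Three stride-2 pools give the strided network a
temporal stride of 8. Dense 1-ms scores are recovered by shift-and-stitch
evaluated efficiently: computation is shared up to each pool, where the two
temporal phases are evaluated separately and interleaved, so a dense pass
costs about one stride-1 pass per layer instead of eight full passes. Edges
are reflect-padded by half a window so every frame has a centered window. A
fast mode (stride-8 scores with nearest-neighbor fill) exists for smoke
tests and for interval averaging, where the 8-frame quantization washes out
over intervals of 30+ frames.

**Training protocol.** Simple SGD on the cross-entropy of labeled stride-8
output positions (frames outside notes are excluded from the loss in the
boundary-detection-first arrangement). Mini-batches are random sequence
subsets whose summed duration stays below a budget (32 s by default). The
training fold is split three ways; for each (train-2/3, validate-1/3)
combination, a probe over (learning rate, seed) pairs — by default 8
log-spaced rates in [0.001, 0.04] x 4 seeds, 32 probe iterations — keeps the
pair with the lowest sub-validation error; training then continues until the
sub-validation error stops improving (no improvement over 5 evaluations,
evaluated every 50 iterations), upon which the rate is halved and training
resumes from the best checkpoint — three halvings in total. The three
members form the ensemble; their softmax outputs are averaged at prediction.
The wide-window network is pre-trained without the inserted layer (on a
halved iteration budget — pre-training only supplies an initialization),
the inserted layer is added with fresh He weights, and the whole stack is
trained again.

`TrainConfig.scaled()` is the reduced protocol used by the test-suite
benchmarks: 2 learning rates (0.002, 0.004), 1 seed, 6 probe iterations,
4-s mini-batches, ~140 iteration cap. The narrower rate grid matters: on the
synthetic task rates at 0.008 and above sometimes kill the rectifier units
irrecoverably, and a 6-iteration probe is too short to detect that reliably
(the full 32-iteration probe is how the protocol guards against it).

## Song syntax and decoding

The syntax is a second-order Markov model over note classes with additive
smoothing applied to the conditional probabilities,
`P(Z|XY) = (P0(Z|XY) + alpha) / sum_Z'(P0(Z'|XY) + alpha)`; unseen contexts
and the first two notes of every sequence are uniform. The smoothing
constant is chosen by 3-fold cross-validation within the training data,
maximizing held-out label-sequence log-likelihood over the grid
{0, 1e-3, 1e-2, 1e-1, 1}.

Two decoders:

* **Interval decoder** (boundary-detection-first): classifier scores are
  averaged over each detected interval (averaged softmax columns still sum
  to one, so no renormalization) and a second-order Viterbi over intervals
  maximizes summed syntax + score log-probabilities. Ties break toward the
  lower class index.
* **Sub-state frame decoder**: each context (X, Y) expands into four
  left-to-right sub-states — the beginning/middle/end thirds of note Y plus
  the following silence. Within a context, `P(XY_i->XY_i) = P(XY_i->XY_{i+1})
  = 0.5` for i in {1, 2}; from `XY_3`: self and silence each `1/(n+2)` and
  the next note `n/(n+2) P(Z|XY)`; from `XY_s`: self `1/(n+1)` and next note
  `n/(n+1) P(Z|XY)`. Initial contexts are uniform; decoding may start in
  initial silence or directly in a first note (uniform over those n+1
  states) and may stop in any state (no termination penalty). Structural
  zeros forbid re-entering an earlier sub-state, so a burst of misclassified
  sub-division-1 evidence inside a note cannot create a boundary, and a
  completed note is at least 3 frames long. Note onsets are the first frame
  of a sub-division-1 state following a sub-division-3 or silence state;
  offsets are the end of the following sub-division-3 run (a note truncated
  by the end of the sequence ends at the last frame).

Classifier outputs are posteriors; optionally they are converted to
emission likelihoods by dividing by class priors (Bayes' rule up to a
constant), with priors taken as the empirical frame frequencies of each
output class in the training fold. Whether to convert is chosen within the
training data by decoding a few training sequences both ways with the
fold's ensemble — an approximation that avoids retraining classifiers for
the inner folds; it is slightly optimistic inside the training subset but
leaks nothing across the outer fold boundary.

All decoding is in the log domain with `-inf` structural zeros; all ties
break toward the lower state/class index for determinism. Both decoders are
tested for exact agreement with exhaustive enumeration on small instances.

## Evaluation measures

Six rates, each pooled over sequences by summing numerators and
denominators: note ER (total Levenshtein distance over total true notes);
note & timing ER (one minus the correctly recognized fraction of the
timeline, where correct note frames come from one-to-one longest-overlap
same-class matching and correct silence is frames covered by neither
annotation); timing ER (the same with classes collapsed — collapsing can
only enlarge the matchable set, so timing ER <= note & timing ER, asserted
as a property); identification ER (true notes whose nearest output note by
interval midpoint has the wrong class, or with two exactly equidistant
output notes); and duration ERs of notes (over correctly identified notes)
and of silent gaps (mutual-nearest-neighbor gap pairing; unpaired true gaps
count their full duration). Matching conflicts are resolved greedily in
descending overlap order; a maximum-weight assignment is available behind a
flag and a property test quantifies the (rare, small) difference.

## Synthetic songs

The generator renders discrete note classes as two-partial harmonic stacks
with class-specific fundamentals (spread over 1.2–3.3 kHz), linear frequency
modulation of a few Hz/ms, class-staggered durations of 40–112 ms, 5-ms
raised-cosine onset/offset ramps, second-order Markov syntax (default: a
concentrated cyclic rule whose preferred successor depends on the
second-from-last class, making it genuinely second-order), inter-note gaps
uniform on 20–150 ms with a configurable fraction of near-zero (0–3 ms)
gaps, per-song leading/trailing silence of 60–150 ms, and stationary white
Gaussian noise at a configurable SNR (30 dB default). Annotations are exact
on the 1-ms grid; everything is deterministic per seed.

Defaults that encode measured physical limits rather than taste: the 20-ms
minimum gap exists because sub-window (<16 ms) gaps are invisible to the
envelope (see above) — at 10-ms minimum gaps threshold boundary recovery
drops from ~97% to as low as ~50%; the uniform two-partial spectra keep
in-band energy (hence envelope rise height and crossing time) comparable
across classes; the 5-ms ramps avoid broadband onset splatter which, on a
log scale, smears the envelope by the full analysis window.

What passing synthetic benchmarks do **not** show: robustness to real
recording conditions — reverberation, cage noise, amplitude variation
within and across bouts, acoustically graded note categories, drifting
syntax — none of which the generator emulates. The benchmark shows the
pipeline machinery (features, training, decoding, scoring) is correct and
that the arrangements order as expected when gaps shrink, not that the
error rates transfer to real birds.

The song-extraction rules for long annotated recordings: classes under 1%
of total notes are relabeled unclassifiable; maximal runs separated by
calls or by gaps of >= 300 ms with more than 7 notes become songs; songs are
split at unclassifiable notes; fragments under 3 notes are dropped;
fragments over 15 notes are split greedily from the left into chunks of 15.
Extracted songs of more than 7 notes are fixed points of the procedure;
3–7-note fragments (which only arise from unclassifiable splitting) are not,
by construction of the rules.

## Cross-validated pipeline

`run_arrangement` performs k-fold (default 3) cross-validation: per fold, a
training subset of the requested duration is drawn at random from the
non-validation sequences, and normalization statistics, thresholds,
classifier ensemble, syntax model, smoothing constant, and conversion flag
are all fitted strictly inside it; every fitted object carries fold-tagged
provenance (fold id, derived seed, config hash). All randomness derives
from one master seed. `compare_arrangements` runs several arrangements on
identical folds and seeds and returns one table.

## Problem sizes in the test suite

The suite's end-to-end benchmarks use 5 synthetic classes at 30 dB SNR with
about 3 minutes of audio (two evaluated folds of ~2 min training / ~1 min
validation) for the wide-window benchmark, ~1.4 min with half near-zero
gaps for the arrangement comparison, and ~1.7-min datasets across 3 seeds
for the training-budget comparison, with the reduced training protocol
described above. These sizes are the package's scaled-down benchmark
design; the full protocol defaults remain available through `TrainConfig()`.

## Known limitations

* The classifier is CPU-bound numpy; training minutes-of-audio models takes
  minutes, not seconds, and the full protocol (8 rates x 4 seeds x 32-probe)
  is meant for offline runs.
* Threshold segmentation cannot resolve gaps shorter than the 16-ms
  analysis window (inherent to the envelope definition, not the search).
* The Bayes-flag inner selection reuses the fold ensemble rather than
  retraining per inner fold (see above).
* `extract_songs` operates on annotations only; calls are modeled as
  reserved labels, not rendered audio.
* Second-order syntax only; no higher-order or variable-length models.
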