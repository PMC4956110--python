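# songscribe

Automatic annotation of birdsong: find the boundaries of every note (vocal
element) in a recording on a 1-ms grid and assign each note to a class,
using a hybrid of a frame-wise deep convolutional network and a hidden
Markov model over the song's syntax.

## Who this is for

Researchers analyzing sequential vocalizations — Bengalese finch song is the
motivating case — who need both accurate note classification *and* accurate
timing (onsets/offsets), trained from a few minutes of hand-annotated song.
The package is a library first (importable pipeline stages), with a thin
`songscribe` command-line tool and runnable scripts in `examples/`.

## The method

A song is modeled as a sequence of notes drawn from `n` classes under a
second-order Markov syntax `P(Z | X Y)` (the probability of the next class
given the two preceding ones), rendered as sound and observed through a
DPSS-tapered log spectrogram (512/32 STFT at 32 kHz → 1-ms frames, 112 rows
spanning 1–8 kHz). Three arrangements of the same three steps — boundary
detection (BD), local classification (LC), global sequencing (GS) — are
implemented:

* **BD → LC → GS** — amplitude/duration thresholding of the envelope finds
  note intervals; a convolutional network scores each 111-ms window for the
  `n` classes; scores averaged per interval feed a second-order Viterbi.
* **LC → BD & GS** — the network scores every frame for `3n+1` classes
  (each note split into beginning/middle/end thirds, plus silence); a
  Viterbi over a sub-state HMM — four left-to-right sub-states per syntax
  context, with transitions `P(XY_i→XY_i)=P(XY_i→XY_{i+1})=0.5`,
  `P(XY_3→XY_s)=1/(n+2)`, `P(XY_3→YZ_1)=n/(n+2)·P(Z|XY)`, and
  `P(XY_s→YZ_1)=n/(n+1)·P(Z|XY)` — finds boundaries and classes jointly.
* **LC & GS → BD & GS** — the same, but the network's input window widens
  to 303 ms (an inserted convolutional layer of temporal width 25), so the
  network itself sees about three successive notes of syntax context.

Accuracy is reported with six measures, including the joint **note & timing
error rate**: match each true note to the same-class output note with the
longest overlap (one-to-one), count matched overlap plus mutually silent
frames as correct, and report one minus the correct fraction of the
timeline. Collapsing all classes to one gives the pure-boundary **timing
ER**; the **note ER** is the pooled Levenshtein distance per true note.

A seeded synthetic-song generator (harmonic-stack notes, second-order
syntax, controllable gaps and SNR, exact annotations) makes every stage
trainable and testable without recorded data.

## Worked example

```bash
python examples/03_end_to_end_benchmark.py
```

generates ~1.6 minutes of 5-class synthetic song at 30 dB SNR, runs
three-fold cross-validation of the LC → BD & GS arrangement (training on
~0.9 min per fold with the reduced training protocol), and prints:

```
pooled validation errors (fractions):
  note_er              0.0051
  timing_er            0.0224
  note_timing_er       0.0224
  identification_er    0.0000
  duration_er_notes    0.0366
  duration_er_gaps     0.0284
```

Read: 0.5% of notes would need an edit (insert/delete/substitute) to match
the true label sequences; 2.2% of the timeline is misassigned when classes
are ignored (boundary error), and jointly with classes (note & timing ER)
the same 2.2% — boundary placement, not classification, is the limiting
factor, as expected for a clean synthetic task.

Other examples: `01_spectrogram_and_envelope.py` (front end),
`02_threshold_segmentation.py` (threshold fitting),
`04_substate_hmm_decoding.py` (sub-state Viterbi on a toy score matrix),
`05_syntax_model.py` (smoothing and sampling). Each prints what it computes
and what the numbers mean.

The CLI offers the same flows: `songscribe generate | train | recognize |
evaluate | benchmark` (see `songscribe --help`).

## Layout

```
src/songscribe/
  signal_features.py   spectrograms, normalization, envelopes
  segmenter.py         threshold boundary detection + fitting
  architecture.py      layer stacks and shape arithmetic
  nnet.py              numpy conv net: forward, backprop, dense evaluation
  classifier.py        frame labels, staged SGD protocol, ensembling
  syntax.py            second-order syntax, sub-state HMM, Viterbi decoders
  metrics.py           the six error measures
  synthetic.py         song generator, song extraction, folds/subsets
  pipeline.py          cross-validated arrangements
  persist.py           HDF5 / plain-text persistence
  cli.py               thin command-line interface
docs/methods.md        models, conventions, numerical choices, limitations
```
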