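"""Boundary detection: fit amplitude/gap/duration thresholds and score them.

Fits the three thresholds on a few training songs by minimizing timing ER,
applies them to held-out songs, and prints the resulting timing error rate
and boundary accuracy.
"""

import numpy as np

from songscribe import (
    Annotation,
    Note,
    SpectrogramParams,
    align_to_frame_grid,
    compute_spectrogram,
    default_config,
    detect_note_intervals,
    envelope_from_spectrogram,
    fit_thresholds,
    generate_dataset,
    timing_error_rate,
)

params = SpectrogramParams()
cfg = default_config(n_classes=5, seed=1, total_minutes=0.4, p_short_gap=0.0)
dataset = generate_dataset(cfg)

prep = []
for wave, ann in dataset:
    spec = compute_spectrogram(wave, params)
    prep.append((envelope_from_spectrogram(spec),
                 align_to_frame_grid(ann, params, spec.n_frames)))

train, test = prep[:5], prep[5:]
thr = fit_thresholds(train)
print(f"fitted thresholds: amplitude {thr.amp_thr:.1f}, "
      f"gap {thr.gap_thr} ms, duration {thr.dur_thr} ms")

preds, truths = [], []
hits = total = 0
for env, ann in test:
    intervals = detect_note_intervals(env, thr)
    preds.append(Annotation([Note(a, b, "x") for a, b in intervals],
                            ann.timeline_length))
    truths.append(ann)
    bounds = [b for ab in intervals for b in ab]
    for n in ann.notes:
        for b in (n.onset, n.offset):
            total += 1
            hits += any(abs(b - x) <= 2 for x in bounds)

print(f"held-out timing ER: {100 * timing_error_rate(truths, preds):.2f} % "
      f"(fraction of the timeline on the wrong side of a boundary)")
print(f"boundaries within +/-2 ms: {100 * hits / total:.1f} %")
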