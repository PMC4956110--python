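"""Error measures for truth/prediction annotation pairs.

Six rates are computed, all pooled over sequence collections by summing
numerators and denominators ("total ... divided by total"):

* **note ER** — total Levenshtein distance between true and output label
  sequences divided by the total number of true notes (the sequence-level
  analogue of word error rate).
* **note & timing ER** — a joint classification/timing measure: each true note
  is matched to the same-class output note with the longest overlap (one-to-one);
  matched overlaps count as correctly recognized note frames, and true-silence
  frames with no predicted class count as correctly recognized silence; the ER
  is one minus the correctly recognized fraction of the timeline.
* **timing ER** — the note & timing ER with all note classes collapsed to one,
  i.e. pure boundary accuracy.
* **identification ER** — fraction of true notes whose nearest output note
  (by interval midpoint) has the wrong class, or which have two output notes
  at exactly equal distance.
* **duration ER (notes)** — summed |duration difference| between correctly
  identified true notes and their nearest output notes, over their total
  duration.
* **duration ER (gaps)** — summed |duration difference| over mutually nearest
  true/output silent-gap pairs, over the total true gap duration; unpaired
  true gaps contribute their full duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import Annotation, Note

__all__ = [
    "ErrorReport",
    "MatchResult",
    "edit_distance",
    "note_error_rate",
    "match_correct_intervals",
    "note_timing_error_rate",
    "timing_error_rate",
    "identification_error_rate",
    "duration_error_rates",
    "error_report",
]


class IncompatibleAnnotationsError(ValueError):
    pass


@dataclass
class MatchResult:
    """Outcome of longest-overlap interval matching for one annotation pair."""

    matches: list[tuple[int, int, int]]  # (true index, pred index, overlap frames)
    correct_note_frames: int
    correct_silence_frames: int


@dataclass
class ErrorReport:
    note_er: float
    timing_er: float
    note_timing_er: float
    identification_er: float
    duration_er_notes: float | None
    duration_er_gaps: float | None

    def as_dict(self) -> dict:
        return {
            "note_er": self.note_er,
            "timing_er": self.timing_er,
            "note_timing_er": self.note_timing_er,
            "identification_er": self.identification_er,
            "duration_er_notes": self.duration_er_notes,
            "duration_er_gaps": self.duration_er_gaps,
        }


# ---------------------------------------------------------------------------
# note ER


def edit_distance(a: Sequence, b: Sequence) -> int:
    """Levenshtein distance (insertions, deletions, substitutions) between
    two label sequences."""
    a, b = list(a), list(b)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, y in enumerate(b, start=1):
            cur[j] = min(prev[j - 1] + (x != y), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[-1]


def _as_pairs(true_seqs, out_seqs):
    if len(true_seqs) != len(out_seqs):
        raise ValueError("true and output collections must be paired")
    return list(zip(true_seqs, out_seqs))


def note_error_rate(true_seqs: Sequence[Sequence], out_seqs: Sequence[Sequence]) -> float:
    """Total edit distance over total true note count, pooled over pairs."""
    pairs = _as_pairs(true_seqs, out_seqs)
    num = sum(edit_distance(t, o) for t, o in pairs)
    den = sum(len(t) for t, _ in pairs)
    if den == 0:
        raise ValueError("no true notes")
    return num / den


# ---------------------------------------------------------------------------
# interval matching and the joint timing measures


def _overlap_pairs(truth: Annotation, pred: Annotation, ignore_classes: bool):
    """All (true idx, pred idx, overlap) with positive overlap and matching
    class (unless classes are ignored), via a linear sweep."""
    pairs = []
    j0 = 0
    for i, tn in enumerate(truth.notes):
        j = j0
        while j < len(pred.notes) and pred.notes[j].offset <= tn.onset:
            j += 1
        j0 = j
        while j < len(pred.notes) and pred.notes[j].onset < tn.offset:
            pn = pred.notes[j]
            ov = min(tn.offset, pn.offset) - max(tn.onset, pn.onset)
            if ov > 0 and (ignore_classes or pn.label == tn.label):
                pairs.append((i, j, ov))
            j += 1
    return pairs


def _coverage_intersection(truth: Annotation, pred: Annotation) -> int:
    """Total frames covered by both annotations (any classes)."""
    total = 0
    j = 0
    for tn in truth.notes:
        while j < len(pred.notes) and pred.notes[j].offset <= tn.onset:
            j += 1
        k = j
        while k < len(pred.notes) and pred.notes[k].onset < tn.offset:
            total += min(tn.offset, pred.notes[k].offset) - max(tn.onset, pred.notes[k].onset)
            k += 1
    return total


def match_correct_intervals(truth: Annotation, pred: Annotation,
                            ignore_classes: bool = False,
                            optimal: bool = False) -> MatchResult:
    """Match each true note to the same-class output note with the longest
    overlap, one-to-one.

    Conflicts (an output note overlapping several true notes, or vice versa)
    are resolved greedily in descending overlap order; ``optimal=True``
    switches to a maximum-weight assignment instead. Correctly recognized
    silence is the set of frames covered by neither annotation.
    """
    if truth.timeline_length != pred.timeline_length:
        raise IncompatibleAnnotationsError(
            f"timeline {truth.timeline_length} vs {pred.timeline_length}"
        )
    pairs = _overlap_pairs(truth, pred, ignore_classes)
    matches: list[tuple[int, int, int]] = []
    if optimal and pairs:
        from scipy.optimize import linear_sum_assignment

        ti = sorted({p[0] for p in pairs})
        pi = sorted({p[1] for p in pairs})
        trow = {t: r for r, t in enumerate(ti)}
        pcol = {p: c for c, p in enumerate(pi)}
        w = np.zeros((len(ti), len(pi)))
        for t, p, ov in pairs:
            w[trow[t], pcol[p]] = ov
        rows, cols = linear_sum_assignment(w, maximize=True)
        for r, c in zip(rows, cols):
            if w[r, c] > 0:
                matches.append((ti[r], pi[c], int(w[r, c])))
        matches.sort()
    else:
        used_t: set[int] = set()
        used_p: set[int] = set()
        for t, p, ov in sorted(pairs, key=lambda x: (-x[2], x[0], x[1])):
            if t not in used_t and p not in used_p:
                matches.append((t, p, ov))
                used_t.add(t)
                used_p.add(p)
        matches.sort()

    note_frames = sum(m[2] for m in matches)
    cov_t = sum(n.duration for n in truth.notes)
    cov_p = sum(n.duration for n in pred.notes)
    both = _coverage_intersection(truth, pred)
    silence_frames = truth.timeline_length - (cov_t + cov_p - both)
    return MatchResult(matches, note_frames, silence_frames)


def _collapse(ann: Annotation) -> Annotation:
    return Annotation([Note(n.onset, n.offset, "x") for n in ann.notes],
                      ann.timeline_length, ann.frame_ms)


def _joint_terms(truth: Annotation, pred: Annotation, collapse: bool,
                 optimal: bool = False) -> tuple[int, int]:
    if collapse:
        truth, pred = _collapse(truth), _collapse(pred)
    m = match_correct_intervals(truth, pred, optimal=optimal)
    correct = m.correct_note_frames + m.correct_silence_frames
    return truth.timeline_length - correct, truth.timeline_length


def _pooled(pairs, fn) -> float:
    num = den = 0
    for t, p in pairs:
        n, d = fn(t, p)
        num += n
        den += d
    return num / den if den else 0.0


def _pairs_arg(truth, pred):
    if isinstance(truth, Annotation):
        return [(truth, pred)]
    return _as_pairs(truth, pred)


def note_timing_error_rate(truth, pred, optimal: bool = False) -> float:
    """1 - (correct note + correct silence frames) / timeline, classes respected."""
    return _pooled(_pairs_arg(truth, pred),
                   lambda t, p: _joint_terms(t, p, collapse=False, optimal=optimal))


def timing_error_rate(truth, pred, optimal: bool = False) -> float:
    """The note & timing ER with all classes collapsed to one."""
    return _pooled(_pairs_arg(truth, pred),
                   lambda t, p: _joint_terms(t, p, collapse=True, optimal=optimal))


# ---------------------------------------------------------------------------
# nearest-note measures


def _identified(truth: Annotation, pred: Annotation) -> list[bool]:
    """Per true note: identified correctly by its nearest output note?

    A true note is incorrect when its nearest output note (by midpoint) has a
    different class, or when two output notes are exactly equidistant.
    """
    if not pred.notes:
        return [False] * len(truth.notes)
    pmid = np.array([n.midpoint for n in pred.notes])
    out = []
    for tn in truth.notes:
        d = np.abs(pmid - tn.midpoint)
        dmin = d.min()
        nearest = np.flatnonzero(d == dmin)
        if len(nearest) > 1:
            out.append(False)
        else:
            out.append(pred.notes[int(nearest[0])].label == tn.label)
    return out


def identification_error_rate(truth, pred) -> float:
    num = den = 0
    for t, p in _pairs_arg(truth, pred):
        ok = _identified(t, p)
        num += sum(1 for o in ok if not o)
        den += len(ok)
    if den == 0:
        raise ValueError("no true notes")
    return num / den


def _gap_pairs(tgaps, pgaps):
    """Mutual nearest-neighbor pairing of silent gaps by midpoint."""
    if not tgaps or not pgaps:
        return []
    tmid = np.array([(a + b) / 2 for a, b in tgaps])
    pmid = np.array([(a + b) / 2 for a, b in pgaps])
    t2p = np.abs(pmid[None, :] - tmid[:, None]).argmin(axis=1)
    p2t = np.abs(tmid[None, :] - pmid[:, None]).argmin(axis=1)
    return [(i, j) for i, j in enumerate(t2p) if p2t[j] == i]


def duration_error_rates(truth, pred) -> tuple[float | None, float | None]:
    """(duration ER over correctly identified notes, duration ER over gaps)."""
    n_num = n_den = 0
    g_num = g_den = 0
    for t, p in _pairs_arg(truth, pred):
        ok = _identified(t, p)
        if p.notes:
            pmid = np.array([n.midpoint for n in p.notes])
            for tn, good in zip(t.notes, ok):
                if not good:
                    continue
                j = int(np.abs(pmid - tn.midpoint).argmin())
                n_num += abs(tn.duration - p.notes[j].duration)
                n_den += tn.duration
        tg, pg = t.gaps, p.gaps
        paired = _gap_pairs(tg, pg)
        paired_t = {i for i, _ in paired}
        for i, j in paired:
            g_num += abs((tg[i][1] - tg[i][0]) - (pg[j][1] - pg[j][0]))
        for i, (a, b) in enumerate(tg):
            if i not in paired_t:
                g_num += b - a
            g_den += b - a
    notes_er = n_num / n_den if n_den else None
    if notes_er is None:
        warnings.warn("no correctly identified notes; note duration ER undefined")
    gaps_er = g_num / g_den if g_den else None
    return notes_er, gaps_er


def error_report(truth, pred) -> ErrorReport:
    """All six rates for paired annotation collections (or a single pair)."""
    pairs = _pairs_arg(truth, pred)
    tru = [t for t, _ in pairs]
    prd = [p for _, p in pairs]
    dn, dg = duration_error_rates(tru, prd)
    return ErrorReport(
        note_er=note_error_rate([t.labels for t in tru], [p.labels for p in prd]),
        timing_er=timing_error_rate(tru, prd),
        note_timing_er=note_timing_error_rate(tru, prd),
        identification_er=identification_error_rate(tru, prd),
        duration_er_notes=dn,
        duration_er_gaps=dg,
    )
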