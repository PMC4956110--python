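"""Second-order Markov song syntax and the sub-state HMM decoders.

The song syntax is a second-order Markov model over note classes: the
probability of the next note class Z given the two preceding classes (X, Y).
Empirical conditional probabilities are smoothed additively,

    P(Z|XY) = (P0(Z|XY) + alpha) / sum_Z' (P0(Z'|XY) + alpha),

with unseen contexts and the first two notes of every sequence uniform.

Two decoders use the syntax:

* an interval-level Viterbi (for pipelines that detect boundaries first):
  given one averaged class-score vector per detected interval, find the label
  sequence maximizing summed syntax + score log-probabilities;
* a frame-level Viterbi on a sub-state HMM: every context (X, Y) is expanded
  into four left-to-right sub-states — the beginning / middle / end thirds of
  note Y plus the following silence — so that decoding a state path locates
  note boundaries at sub-state transitions. Left-to-right structural zeros
  forbid re-entering an earlier sub-state, which prevents short bursts of
  misclassified evidence from creating spurious boundaries (a note must
  traverse sub-states 1, 2, 3, so its minimum decodable duration is 3 frames).

Frame scores from the classifier are posteriors P(class | spectrogram); they
may optionally be converted to emission likelihoods by dividing by class
priors (Bayes' rule, up to a constant), a choice made by cross-validation
within the training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotations import Annotation, Note

__all__ = [
    "SyntaxModel",
    "SubstateHMM",
    "StatePath",
    "fit_syntax_model",
    "sample_sequences",
    "build_substate_hmm",
    "convert_posterior_to_emission",
    "decode_interval_sequence",
    "decode_frame_sequence",
    "path_to_annotation",
]

_NEG_INF = -np.inf
_LOG_EPS = 1e-300  # floor inside log() of probabilities/scores


class UnknownClassError(ValueError):
    pass


class DegeneratePriorError(ValueError):
    pass


class DegenerateEmissionsError(ValueError):
    pass


class InvalidPathError(ValueError):
    pass


@dataclass
class SyntaxModel:
    classes: list[str]
    alpha: float
    trans: np.ndarray  # (n, n, n); trans[x, y, z] = P(Z=z | X=x, Y=y)

    @property
    def n(self) -> int:
        return len(self.classes)

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise UnknownClassError(label) from None

    def log_likelihood(self, sequences: Iterable[Sequence[str]]) -> float:
        """Log probability of label sequences (first two notes uniform)."""
        total = 0.0
        logu = -np.log(self.n)
        logt = np.log(np.maximum(self.trans, _LOG_EPS))
        for seq in sequences:
            idx = [self.class_index(c) for c in seq]
            total += logu * min(len(idx), 2)
            for x, y, z in zip(idx, idx[1:], idx[2:]):
                total += logt[x, y, z]
        return total


def fit_syntax_model(label_sequences: Iterable[Sequence[str]], alpha: float,
                     classes: Sequence[str] | None = None) -> SyntaxModel:
    """Estimate the smoothed second-order transition table from label sequences.

    ``classes`` fixes the class alphabet (and its order); by default it is the
    sorted set of labels observed. Unseen contexts get uniform vectors.
    """
    seqs = [list(s) for s in label_sequences]
    if classes is None:
        classes = sorted({c for s in seqs for c in s})
    classes = list(classes)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    n = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((n, n, n))
    for seq in seqs:
        try:
            idx = [index[c] for c in seq]
        except KeyError as e:
            raise UnknownClassError(str(e)) from None
        for x, y, z in zip(idx, idx[1:], idx[2:]):
            counts[x, y, z] += 1
    ctx_tot = counts.sum(axis=2, keepdims=True)
    seen = ctx_tot[..., 0] > 0
    p0 = np.divide(counts, ctx_tot, out=np.zeros_like(counts), where=ctx_tot > 0)
    trans = np.empty_like(p0)
    trans[~seen] = 1.0 / n
    if np.any(seen):
        sm = p0[seen] + alpha
        trans[seen] = sm / sm.sum(axis=1, keepdims=True)
    return SyntaxModel(classes=classes, alpha=alpha, trans=trans)


def sample_sequences(model: SyntaxModel, n_sequences: int,
                     length_range: tuple[int, int], rng) -> list[list[str]]:
    """Draw label sequences from the syntax (first two notes uniform)."""
    lo, hi = length_range
    out = []
    for _ in range(n_sequences):
        m = int(rng.integers(lo, hi + 1))
        idx = list(rng.integers(0, model.n, size=min(m, 2)))
        while len(idx) < m:
            p = model.trans[idx[-2], idx[-1]]
            idx.append(int(rng.choice(model.n, p=p)))
        out.append([model.classes[i] for i in idx])
    return out


# ---------------------------------------------------------------------------
# sub-state HMM

_SUBS = (1, 2, 3, "s")
_INITIAL = "<e>"  # initial-context symbol; cannot collide with class labels


@dataclass
class SubstateHMM:
    classes: list[str]
    states: list[tuple[str, str, object]]  # (X, Y, sub) with sub in {1,2,3,'s'}
    emission_class: np.ndarray  # per state: classifier output index
    log_init: np.ndarray  # per state
    # incoming edges, padded to fixed degree, ordered by ascending source index
    in_prev: np.ndarray  # (n_states, max_deg) source state index
    in_logp: np.ndarray  # (n_states, max_deg) log transition prob (-inf pad)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n(self) -> int:
        return len(self.classes)

    def state_index(self, state: tuple[str, str, object]) -> int:
        return self.states.index(state)

    def log_transition(self, i: int, j: int) -> float:
        """Log P(state j | state i)."""
        cols = np.flatnonzero(self.in_prev[j] == i)
        for c in cols:
            if np.isfinite(self.in_logp[j, c]):
                return float(self.in_logp[j, c])
        return _NEG_INF

    def transition_matrix(self) -> np.ndarray:
        """Dense transition probability matrix (rows sum to 1)."""
        a = np.zeros((self.n_states, self.n_states))
        for j in range(self.n_states):
            for p, lp in zip(self.in_prev[j], self.in_logp[j]):
                if np.isfinite(lp):
                    a[p, j] = np.exp(lp)
        return a


def build_substate_hmm(model: SyntaxModel) -> SubstateHMM:
    """Expand a syntax model into the four-sub-state left-to-right HMM.

    Within a context (X, Y): P(XY_i -> XY_i) = P(XY_i -> XY_{i+1}) = 0.5 for
    i in {1, 2}; from XY_3: self and silence each 1/(n+2) and the next note
    n/(n+2) * P(Z|XY); from XY_s: self 1/(n+1) and next note n/(n+1) * P(Z|XY).
    Transitions out of the initial contexts (first two notes) are uniform.
    Emitted classifier classes: (Y, sub-division) for sub-states 1-3 and the
    silence class for every _s state.
    """
    classes = model.classes
    n = model.n
    if _INITIAL in classes:
        raise ValueError(f"class label {_INITIAL!r} is reserved")
    silence_class = 3 * n

    states: list[tuple[str, str, object]] = [(_INITIAL, _INITIAL, "s")]
    for x in [_INITIAL] + classes:
        for y in classes:
            for sub in _SUBS:
                states.append((x, y, sub))
    sidx = {s: i for i, s in enumerate(states)}

    emission = np.empty(len(states), dtype=np.int64)
    for s, i in sidx.items():
        _, y, sub = s
        emission[i] = silence_class if sub == "s" else 3 * classes.index(y) + (sub - 1)

    def next_note_prob(x: str, y: str, z: int) -> float:
        if x == _INITIAL:
            return 1.0 / n  # first/second note: uniform
        return float(model.trans[classes.index(x), classes.index(y), z])

    edges: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(states))}

    def add(src: tuple, dst: tuple, p: float) -> None:
        if p > 0:
            edges[sidx[dst]].append((sidx[src], np.log(p)))

    ee = (_INITIAL, _INITIAL, "s")
    add(ee, ee, 1.0 / (n + 1))
    for z, zc in enumerate(classes):
        add(ee, (_INITIAL, zc, 1), 1.0 / (n + 1))

    for x in [_INITIAL] + classes:
        for y in classes:
            for i in (1, 2):
                add((x, y, i), (x, y, i), 0.5)
                add((x, y, i), (x, y, i + 1), 0.5)
            add((x, y, 3), (x, y, 3), 1.0 / (n + 2))
            add((x, y, 3), (x, y, "s"), 1.0 / (n + 2))
            add((x, y, "s"), (x, y, "s"), 1.0 / (n + 1))
            for z, zc in enumerate(classes):
                p = next_note_prob(x, y, z)
                add((x, y, 3), (y, zc, 1), n / (n + 2) * p)
                add((x, y, "s"), (y, zc, 1), n / (n + 1) * p)

    max_deg = max(len(v) for v in edges.values())
    in_prev = np.zeros((len(states), max_deg), dtype=np.int64)
    in_logp = np.full((len(states), max_deg), _NEG_INF)
    for j, lst in edges.items():
        for c, (p, lp) in enumerate(sorted(lst)):
            in_prev[j, c] = p
            in_logp[j, c] = lp

    log_init = np.full(len(states), _NEG_INF)
    log_init[sidx[ee]] = -np.log(n + 1)
    for zc in classes:
        log_init[sidx[(_INITIAL, zc, 1)]] = -np.log(n + 1)

    return SubstateHMM(classes=list(classes), states=states, emission_class=emission,
                       log_init=log_init, in_prev=in_prev, in_logp=in_logp)


@dataclass
class StatePath:
    states: np.ndarray  # per-frame state indices
    log_score: float
    hmm: SubstateHMM

    def state_tuples(self) -> list[tuple[str, str, object]]:
        return [self.hmm.states[i] for i in self.states]


# ---------------------------------------------------------------------------
# posterior -> emission conversion


def convert_posterior_to_emission(scores: np.ndarray, priors: np.ndarray,
                                  enabled: bool = True) -> np.ndarray:
    """Bayes conversion of class posteriors to (unnormalized) likelihoods.

    ``emission = posterior / prior`` per class when enabled; the posterior
    unchanged otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    if not enabled:
        return scores
    priors = np.asarray(priors, dtype=float).reshape(-1, 1)
    if priors.shape[0] != scores.shape[0]:
        raise ValueError("priors must match the number of score classes")
    if np.any(priors <= 0):
        raise DegeneratePriorError("priors must be strictly positive")
    return scores / priors


# ---------------------------------------------------------------------------
# decoders


def decode_interval_sequence(model: SyntaxModel,
                             interval_scores: Sequence[np.ndarray]) -> list[str]:
    """Second-order Viterbi over detected intervals.

    ``interval_scores[m]`` is the n-vector of averaged class scores for the
    m-th interval. Returns the label sequence maximizing summed transition and
    score log-probabilities; ties break toward the lower class index.
    """
    scores = [np.asarray(s, dtype=float) for s in interval_scores]
    m = len(scores)
    if m == 0:
        return []
    n = model.n
    loge = [np.log(np.maximum(s, _LOG_EPS)) for s in scores]
    logu = -np.log(n)
    logt = np.log(np.maximum(model.trans, _LOG_EPS))
    logt[model.trans == 0] = _NEG_INF

    if m == 1:
        return [model.classes[int(np.argmax(logu + loge[0]))]]

    # D[y, z]: best score of a sequence ending in (y, z) after step t
    d = (logu + loge[0])[:, None] + (logu + loge[1])[None, :]
    back = []
    for t in range(2, m):
        cand = d[:, :, None] + logt  # (x, y, z)
        best_x = cand.argmax(axis=0)  # (y, z); first max = lowest x
        d = cand.max(axis=0) + loge[t][None, :]
        back.append(best_x)
    flat = int(np.argmax(d))
    y, z = divmod(flat, n)
    seq = [z, y]
    for best_x in reversed(back):
        seq.append(int(best_x[seq[-1], seq[-2]]))
    seq.reverse()
    return [model.classes[i] for i in seq]


def decode_frame_sequence(hmm: SubstateHMM, emissions: np.ndarray) -> StatePath:
    """Frame-level Viterbi over the sub-state HMM.

    ``emissions`` is an (n_outputs, T) table of per-frame scores for the
    classifier output classes (posteriors or Bayes-converted likelihoods).
    Ties break toward the lower state index.
    """
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2:
        raise ValueError("emissions must be 2-D (classes x frames)")
    if np.any(emissions.sum(axis=0) == 0):
        raise DegenerateEmissionsError("all-zero emission column")
    n_frames = emissions.shape[1]
    logb = np.log(np.maximum(emissions, _LOG_EPS))[hmm.emission_class]  # (S, T)

    delta = hmm.log_init + logb[:, 0]
    pointers = np.empty((n_frames, hmm.n_states), dtype=np.int32)
    for t in range(1, n_frames):
        cand = delta[hmm.in_prev] + hmm.in_logp  # (S, max_deg)
        arg = cand.argmax(axis=1)  # first max = lowest source (sorted)
        rows = np.arange(hmm.n_states)
        delta = cand[rows, arg] + logb[:, t]
        pointers[t] = hmm.in_prev[rows, arg]
    last = int(np.argmax(delta))
    path = np.empty(n_frames, dtype=np.int32)
    path[-1] = last
    for t in range(n_frames - 1, 0, -1):
        path[t - 1] = pointers[t, path[t]]
    return StatePath(states=path, log_score=float(delta[last]), hmm=hmm)


def path_to_annotation(path: StatePath, frame_ms: float = 1.0) -> Annotation:
    """Convert a decoded state path to a note annotation.

    A note onset is the first frame of a sub-division-1 state following a
    sub-division-3 or silence state (or the path start); its offset is the end
    of the following sub-division-3 run.
    """
    hmm = path.hmm
    tuples = path.state_tuples()
    # validate transitions
    for t in range(1, len(tuples)):
        if hmm.log_transition(int(path.states[t - 1]), int(path.states[t])) == _NEG_INF:
            raise InvalidPathError(f"illegal transition at frame {t}")
    notes: list[Note] = []
    open_start: int | None = None
    open_label: str | None = None
    for t, (_, y, sub) in enumerate(tuples):
        in_note = sub != "s"
        if open_start is None:
            if in_note:
                open_start, open_label = t, y
        else:
            prev_sub = tuples[t - 1][2]
            if not in_note:
                notes.append(Note(open_start, t, open_label))
                open_start = open_label = None
            elif sub == 1 and prev_sub == 3:  # repetition without a gap
                notes.append(Note(open_start, t, open_label))
                open_start, open_label = t, y
    if open_start is not None:
        notes.append(Note(open_start, len(tuples), open_label))
    return Annotation(notes, len(tuples), frame_ms)
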