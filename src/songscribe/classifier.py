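"""Frame-wise classifier: label derivation, training protocol, ensembling.

Training follows a staged stochastic-gradient-descent protocol. The training
fold is split three ways; for each (train-on-2/3, validate-on-1/3) combination
a short probe run over a grid of (learning rate, initialization seed) pairs
selects the pair whose best sub-validation error within the probe iterations
is lowest; training then continues at that rate until the sub-validation
error stops improving, upon which the rate is halved and training resumes —
three halvings in total. The three resulting parameter sets form an ensemble
whose softmax outputs are averaged at prediction time.

Mini-batches are random subsets of training sequences whose summed audio
duration stays below a budget (32 s by default). Each sequence contributes
cross-entropy terms at stride-8 output positions (a random temporal phase per
draw), so every gradient step sees windows spread over several sequences.

Frame labels: for the boundary-detection-first arrangement each in-note frame
carries its note class and out-of-note frames are not trainable; for the
HMM-boundary arrangements each note of duration d frames is split into three
equal-duration sub-divisions at offsets floor(d/3) and floor(2d/3), with
output class 3*class + (sub-1), and silence frames carry class 3n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .annotations import Annotation
from .architecture import ArchitectureSpec, build_architecture
from .nnet import Network
from .signal_features import NormalizationStats, Spectrogram

__all__ = [
    "NOT_TRAINABLE",
    "TrainConfig",
    "ClassifierEnsemble",
    "ScoreMatrix",
    "derive_frame_labels",
    "train_ensemble",
    "predict_frame_scores",
    "class_priors",
]

log = logging.getLogger(__name__)

NOT_TRAINABLE = -1


class InvalidAnnotationError(ValueError):
    pass


class TrainingFailedError(RuntimeError):
    pass


class InputTooShortError(ValueError):
    pass


def derive_frame_labels(ann: Annotation, arrangement: str,
                        classes: list[str]) -> np.ndarray:
    """Per-frame classifier target classes for one annotated sequence."""
    index = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    sub_divided = arrangement in ("LC_BDGS", "LCGS_BDGS")
    labels = np.full(ann.timeline_length,
                     3 * n if sub_divided else NOT_TRAINABLE, dtype=np.int64)
    prev_off = 0
    for note in ann.notes:
        if note.onset < prev_off:
            raise InvalidAnnotationError("overlapping notes")
        prev_off = note.offset
        c = index[note.label]
        if not sub_divided:
            labels[note.onset : note.offset] = c
        else:
            d = note.duration
            s1 = note.onset + d // 3
            s2 = note.onset + (2 * d) // 3
            labels[note.onset : s1] = 3 * c
            labels[s1 : s2] = 3 * c + 1
            labels[s2 : note.offset] = 3 * c + 2
    return labels


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the staged SGD protocol.

    Defaults follow the full protocol (8 log-spaced learning rates in
    [0.001, 0.04], 4 seeds per rate, 32 probe iterations, 32 s mini-batches);
    the ``scaled()`` constructor returns a light configuration for small
    synthetic benchmarks.
    """

    lr_candidates: tuple[float, ...] = tuple(
        float(v) for v in np.geomspace(0.001, 0.04, 8)
    )
    seeds_per_rate: int = 4
    lr_probe_iterations: int = 32
    halvings: int = 3
    patience: int = 5
    eval_interval: int = 50
    minibatch_seconds: float = 32.0
    max_iterations: int = 4000
    seed: int = 0
    subval_max_frames: int = 20000  # subsample cap for sub-validation scoring

    @staticmethod
    def scaled(seed: int = 0, **overrides) -> "TrainConfig":
        base = dict(
            lr_candidates=(0.002, 0.004),
            seeds_per_rate=1,
            lr_probe_iterations=6,
            halvings=3,
            patience=2,
            eval_interval=15,
            minibatch_seconds=4.0,
            max_iterations=140,
            seed=seed,
        )
        base.update(overrides)
        return TrainConfig(**base)


@dataclass
class ScoreMatrix:
    """Per-frame class scores (columns are probability vectors)."""

    scores: np.ndarray  # (n_outputs, n_frames)
    frame_ms: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.scores.shape[1]


@dataclass
class ClassifierEnsemble:
    members: list[Network]
    architecture: ArchitectureSpec
    normalization: NormalizationStats
    classes: list[str]
    provenance: dict = field(default_factory=dict)


def _pad_sequence(values: np.ndarray, window: int) -> np.ndarray:
    """Reflect-pad along time so every frame has a centered window."""
    left = window // 2
    right = window - left - 1
    if values.shape[1] < 2:
        raise InputTooShortError("sequence too short to pad")
    return np.pad(values, ((0, 0), (left, right)), mode="reflect")


class _SequenceData:
    """Padded spectrogram + frame labels for one training sequence."""

    def __init__(self, spec: Spectrogram, labels: np.ndarray, window: int):
        if len(labels) != spec.n_frames:
            raise ValueError("labels must match spectrogram frames")
        self.padded = _pad_sequence(spec.values, window)
        self.labels = labels
        self.n_frames = spec.n_frames
        self.seconds = spec.n_frames * spec.frame_ms / 1000.0


def _subval_error(net: Network, seqs: list[_SequenceData], stride: int,
                  max_frames: int) -> float:
    """Strided classification error on held-out sequences (phase 0)."""
    wrong = total = 0
    for sd in seqs:
        probs = net.predict_strided(sd.padded)
        k = probs.shape[1]
        frames = np.arange(k) * stride
        frames = frames[frames < sd.n_frames]
        lab = sd.labels[frames]
        mask = lab >= 0
        if not mask.any():
            continue
        pred = probs[:, : len(frames)].argmax(axis=0)
        wrong += int((pred[mask] != lab[mask]).sum())
        total += int(mask.sum())
        if total >= max_frames:
            break
    return wrong / total if total else 1.0


def _train_iteration(net: Network, seqs: list[_SequenceData], stride: int,
                     lr: float, budget_s: float, rng) -> float:
    """One SGD step on a random mini-batch; returns mean loss per position."""
    order = rng.permutation(len(seqs))
    batch = []
    seconds = 0.0
    for i in order:
        if batch and seconds + seqs[i].seconds > budget_s:
            break
        batch.append(seqs[i])
        seconds += seqs[i].seconds
    net.zero_grad()
    loss = 0.0
    count = 0
    for sd in batch:
        phase = int(rng.integers(stride))
        x = sd.padded[:, phase:]
        k_max = (x.shape[1] - net.arch.input_width) // stride + 1
        frames = phase + np.arange(k_max) * stride
        valid = frames < sd.n_frames
        labels = np.full(k_max, NOT_TRAINABLE)
        labels[valid] = sd.labels[frames[valid]]
        li, ci = net.loss_and_grad(x[None], labels)
        loss += li
        count += ci
    if count == 0:
        return 0.0
    net.sgd_step(lr, scale=1.0 / count)
    mean = loss / count
    if not np.isfinite(mean):
        raise TrainingFailedError("non-finite training loss")
    return mean


def _staged_training(net: Network, train_seqs, val_seqs, lr: float, cfg: TrainConfig,
                     stride: int, rng) -> tuple[list, float]:
    """Patience-based training with halvings; returns (best state, best error)."""
    best_state = net.get_state()
    best_err = _subval_error(net, val_seqs, stride, cfg.subval_max_frames)
    halvings_left = cfg.halvings
    since_best = 0
    it = 0
    while it < cfg.max_iterations:
        for _ in range(cfg.eval_interval):
            _train_iteration(net, train_seqs, stride, lr, cfg.minibatch_seconds, rng)
            it += 1
            if it >= cfg.max_iterations:
                break
        err = _subval_error(net, val_seqs, stride, cfg.subval_max_frames)
        log.debug("iter %d lr %.4g subval %.4f", it, lr, err)
        if err < best_err - 1e-12:
            best_err = err
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                if halvings_left == 0:
                    break
                halvings_left -= 1
                lr *= 0.5
                net.set_state(best_state)
                since_best = 0
    return best_state, best_err


def _probe_candidates(arch: ArchitectureSpec, train_seqs, val_seqs, cfg: TrainConfig,
                      stride: int, rng, base_net: Network | None = None):
    """Short probe of (lr, seed) pairs; returns (lr, seed, state, err) of the best."""
    best = None
    seed_pool = [int(s) for s in rng.integers(0, 2**31 - 1, size=cfg.seeds_per_rate)]
    for lr in cfg.lr_candidates:
        for seed in seed_pool:
            if base_net is not None:
                net = base_net
                net_state = net.get_state()
            else:
                net = Network(arch, seed)
                net_state = None
            run_rng = np.random.default_rng(seed ^ 0x5EED)
            try:
                err = _subval_error(net, val_seqs, stride, cfg.subval_max_frames)
                state = net.get_state()
                for _ in range(cfg.lr_probe_iterations):
                    _train_iteration(net, train_seqs, stride, lr,
                                     cfg.minibatch_seconds, run_rng)
                    e = _subval_error(net, val_seqs, stride, cfg.subval_max_frames)
                    if e < err:
                        err = e
                        state = net.get_state()
            except TrainingFailedError:
                if net_state is not None:
                    net.set_state(net_state)
                continue
            if best is None or err < best[3] - 1e-12:
                best = (lr, seed, state, err)
            if net_state is not None:
                net.set_state(net_state)
            if base_net is not None:
                break  # pre-initialized network: seeds do not apply
    if best is None:
        raise TrainingFailedError("all (learning rate, seed) candidates diverged")
    return best


def _train_member(arch: ArchitectureSpec, train_seqs, val_seqs,
                  cfg: TrainConfig, rng) -> Network:
    stride = arch.temporal_stride
    if arch.arrangement == "LCGS_BDGS":
        # pre-train the stack without the inserted layer on narrow windows;
        # the pre-training only has to provide a reasonable initialization,
        # so it runs on a reduced iteration budget with a single halving
        narrow = build_architecture("LC_BDGS", arch.n_note_classes, arch.input_height)
        pre_cfg = replace(cfg, max_iterations=max(cfg.max_iterations // 2, 20),
                          halvings=1)
        lr, seed, state, _ = _probe_candidates(narrow, train_seqs, val_seqs, pre_cfg,
                                               narrow.temporal_stride, rng)
        pre = Network(narrow, seed)
        pre.set_state(state)
        pre_state, _ = _staged_training(pre, train_seqs, val_seqs, lr, pre_cfg,
                                        narrow.temporal_stride,
                                        np.random.default_rng(seed ^ 0xA))
        pre.set_state(pre_state)
        net = Network(arch, seed)
        _transfer_pretrained(pre, net)
        lr2, _, state2, _ = _probe_candidates(arch, train_seqs, val_seqs, cfg,
                                              stride, rng, base_net=net)
        net.set_state(state2)
        state, err = _staged_training(net, train_seqs, val_seqs, lr2, cfg, stride,
                                      np.random.default_rng(seed ^ 0xB))
        net.set_state(state)
        return net
    lr, seed, state, _ = _probe_candidates(arch, train_seqs, val_seqs, cfg, stride, rng)
    net = Network(arch, seed)
    net.set_state(state)
    state, err = _staged_training(net, train_seqs, val_seqs, lr, cfg, stride,
                                  np.random.default_rng(seed ^ 0xC))
    net.set_state(state)
    log.info("member trained: lr %.4g seed %d subval %.4f", lr, seed, err)
    return net


def _transfer_pretrained(pre: Network, full: Network) -> None:
    """Copy shared layers from the narrow pre-trained network into the wide one
    (the freshly inserted layer keeps its He initialization)."""
    pre_convs = [l for l in pre.layers if hasattr(l, "W")]
    full_convs = [l for l in full.layers if hasattr(l, "W")]
    pre_iter = iter(pre_convs)
    for layer in full_convs:
        if layer.spec.inserted:
            continue
        src = next(pre_iter)
        layer.W[...] = src.W
        layer.b[...] = src.b


def train_ensemble(data: list[tuple[Spectrogram, np.ndarray]],
                   arch: ArchitectureSpec, cfg: TrainConfig,
                   normalization: NormalizationStats,
                   classes: list[str]) -> ClassifierEnsemble:
    """Train the three sub-fold members and return the ensemble.

    ``data`` pairs normalized spectrograms with per-frame label arrays
    (entries < 0 excluded from the loss).
    """
    if len(data) < 3:
        raise ValueError("need at least 3 sequences to form sub-folds")
    window = arch.input_width
    seqs = [_SequenceData(s, l, window) for s, l in data]
    rng = np.random.default_rng(cfg.seed)
    assignment = rng.permutation(len(seqs)) % 3
    members = []
    for sub in range(3):
        train_seqs = [s for s, a in zip(seqs, assignment) if a != sub]
        val_seqs = [s for s, a in zip(seqs, assignment) if a == sub]
        if not val_seqs:
            raise ValueError("a sub-fold received no validation sequences")
        member_rng = np.random.default_rng([cfg.seed, sub])
        members.append(_train_member(arch, train_seqs, val_seqs, cfg, member_rng))
    return ClassifierEnsemble(members=members, architecture=arch,
                              normalization=normalization, classes=classes)


def predict_frame_scores(ens: ClassifierEnsemble, spec: Spectrogram,
                         dense: bool = True) -> ScoreMatrix:
    """Ensemble-averaged softmax scores for every 1-ms frame.

    Each member scores the window centered on each frame (the spectrogram is
    reflect-padded by half a window so edge frames have full windows); member
    outputs are averaged. ``dense=False`` scores stride-8 positions only and
    fills the gaps by nearest neighbor (fast mode for smoke tests).
    """
    if not spec.normalized:
        raise ValueError("spectrogram must be normalized with the ensemble stats")
    arch = ens.architecture
    padded = _pad_sequence(spec.values, arch.input_width)
    t = spec.n_frames
    acc = None
    for net in ens.members:
        if dense:
            probs = net.predict_dense(padded)[:, :t]
        else:
            stride = arch.temporal_stride
            strided = net.predict_strided(padded)
            idx = np.minimum(np.arange(t) // stride, strided.shape[1] - 1)
            probs = strided[:, idx]
        acc = probs if acc is None else acc + probs
    scores = acc / len(ens.members)
    if scores.shape[1] != t:
        raise InputTooShortError("spectrogram narrower than the input window")
    return ScoreMatrix(scores=scores, frame_ms=spec.frame_ms)


def class_priors(label_arrays: list[np.ndarray], n_outputs: int,
                 floor: float = 1e-6) -> np.ndarray:
    """Empirical frame frequencies of each output class in the training fold."""
    counts = np.zeros(n_outputs)
    for lab in label_arrays:
        lab = lab[lab >= 0]
        counts += np.bincount(lab, minlength=n_outputs)
    total = counts.sum()
    if total == 0:
        raise ValueError("no labeled frames")
    return np.maximum(counts / total, floor)
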