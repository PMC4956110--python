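"""End-to-end orchestration of the three recognition arrangements.

Each arrangement combines boundary detection (BD), local classification (LC)
and global sequencing (GS) differently:

* ``BD_LC_GS`` — amplitude/duration thresholding detects note intervals;
  frame scores from the classifier are averaged over each detected interval;
  an interval-level second-order Viterbi assigns classes.
* ``LC_BDGS`` — the classifier scores every frame for 3n+1 sub-division
  classes; a frame-level Viterbi on the sub-state HMM finds boundaries and
  classes simultaneously.
* ``LCGS_BDGS`` — as ``LC_BDGS`` but with the wide (303 ms) input window so
  the network itself sees roughly three successive notes of syntax context.

Evaluation is three-fold cross-validation: for each fold, a training subset
of the requested duration is drawn from the non-validation sequences, and
every fitted object (normalization statistics, thresholds, classifier,
syntax model, smoothing constant, Bayes-conversion flag) is estimated
strictly inside that training subset. Hyper-parameters are chosen by
cross-validation within the training data.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotations import Annotation, intervals_to_annotation, Note
from .architecture import ARRANGEMENTS, build_architecture
from .classifier import (
    ClassifierEnsemble,
    TrainConfig,
    class_priors,
    derive_frame_labels,
    predict_frame_scores,
    train_ensemble,
)
from .metrics import ErrorReport, error_report, note_timing_error_rate
from .segmenter import ThresholdSet, detect_note_intervals, fit_thresholds
from .signal_features import (
    SpectrogramParams,
    align_to_frame_grid,
    apply_normalization,
    compute_spectrogram,
    envelope_from_spectrogram,
    fit_normalization,
)
from .syntax import (
    SyntaxModel,
    build_substate_hmm,
    convert_posterior_to_emission,
    decode_frame_sequence,
    decode_interval_sequence,
    fit_syntax_model,
    path_to_annotation,
)
from .synthetic import select_training_subset, split_folds

__all__ = ["ArrangementConfig", "FoldResult", "RunResult",
           "run_arrangement", "compare_arrangements"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArrangementConfig:
    arrangement: str
    train_minutes: float = 2.0
    folds: int = 3
    seed: int = 0
    train_config: TrainConfig | None = None
    alpha: float | None = None  # fixed smoothing constant; None -> inner CV
    alpha_grid: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1, 1.0)
    bayes: bool | None = False  # fixed conversion flag; None -> inner CV
    amp_quantiles: int = 32
    gap_grid: tuple[int, ...] = (0, 1, 2, 3, 5, 8, 12, 20, 30)
    dur_grid: tuple[int, ...] = tuple(range(0, 51, 5))
    dense_scores: bool = True
    eval_folds: tuple[int, ...] | None = None  # None -> evaluate every fold
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement}")

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class FoldResult:
    fold: int
    report: ErrorReport
    truth: list[Annotation]
    predicted: list[Annotation]
    hyperparams: dict
    provenance: dict


@dataclass
class RunResult:
    config: ArrangementConfig
    fold_results: list[FoldResult]
    pooled: ErrorReport

    @property
    def hyperparams(self) -> list[dict]:
        return [f.hyperparams for f in self.fold_results]


def _select_alpha(label_seqs: list[list[str]], grid: Sequence[float],
                  classes: list[str], seed: int) -> float:
    """Smoothing constant by k-fold held-out syntax log-likelihood."""
    k = min(3, len(label_seqs))
    if k < 2:
        return grid[len(grid) // 2]
    folds = split_folds(label_seqs, k=k, seed=seed)
    best_alpha, best_ll = None, -np.inf
    for alpha in grid:
        ll = 0.0
        for f in range(k):
            train = [s for s, fi in zip(label_seqs, folds) if fi != f]
            held = [s for s, fi in zip(label_seqs, folds) if fi == f]
            model = fit_syntax_model(train, alpha, classes=classes)
            ll += model.log_likelihood(held)
        if ll > best_ll + 1e-12:
            best_ll, best_alpha = ll, alpha
    return best_alpha


def _decode_hmm(ens: ClassifierEnsemble, syntax: SyntaxModel, spec_norm,
                priors: np.ndarray, bayes: bool, dense: bool) -> Annotation:
    scores = predict_frame_scores(ens, spec_norm, dense=dense)
    emissions = convert_posterior_to_emission(scores.scores, priors, enabled=bayes)
    hmm = build_substate_hmm(syntax)
    path = decode_frame_sequence(hmm, emissions)
    return path_to_annotation(path, frame_ms=scores.frame_ms)


def _decode_intervals(ens: ClassifierEnsemble, syntax: SyntaxModel, spec_norm,
                      envelope, thresholds: ThresholdSet, dense: bool) -> Annotation:
    intervals = detect_note_intervals(envelope, thresholds)
    if not intervals:
        return Annotation([], spec_norm.n_frames, spec_norm.frame_ms)
    scores = predict_frame_scores(ens, spec_norm, dense=dense)
    means = [scores.scores[:, a:b].mean(axis=1) for a, b in intervals]
    labels = decode_interval_sequence(syntax, means)
    notes = [Note(a, b, lab) for (a, b), lab in zip(intervals, labels)]
    return Annotation(notes, spec_norm.n_frames, spec_norm.frame_ms)


def _select_bayes(ens, syntax, train_items, priors, dense, seed) -> bool:
    """Bayes-conversion flag by decoding a few training sequences both ways.

    Cross-validation within the training subset: held-out label sequences are
    decoded with and without the conversion and the flag with the lower
    note & timing ER wins (ties keep the posterior unchanged).
    """
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(train_items))[: min(4, len(train_items))]
    sample = [train_items[i] for i in idx]
    errs = {}
    for flag in (False, True):
        preds = [
            _decode_hmm(ens, syntax, spec_norm, priors, flag, dense)
            for spec_norm, _, _ in sample
        ]
        truths = [ann for _, _, ann in sample]
        errs[flag] = note_timing_error_rate(truths, preds)
    return errs[True] < errs[False]


def run_arrangement(dataset, classes: list[str], cfg: ArrangementConfig) -> RunResult:
    """Three-fold cross-validated recognition with one arrangement.

    ``dataset`` is a list of (waveform, Annotation) pairs; ``classes`` is the
    note-class alphabet. Returns per-fold and pooled error reports.
    """
    params = cfg.spectrogram
    prepared = []
    for wave, ann in dataset:
        raw = compute_spectrogram(wave, params)
        env = envelope_from_spectrogram(raw)
        # truth and predictions both live on the frame grid (frame-center rule)
        prepared.append((raw, env, align_to_frame_grid(ann, params, raw.n_frames)))

    folds = split_folds(prepared, k=cfg.folds, seed=cfg.seed)
    arch = build_architecture(cfg.arrangement, len(classes))
    tc = cfg.train_config or TrainConfig(seed=cfg.seed)
    fold_results = []
    all_truth: list[Annotation] = []
    all_pred: list[Annotation] = []

    for f in (cfg.eval_folds if cfg.eval_folds is not None else range(cfg.folds)):
        fold_seed = int(np.random.default_rng([cfg.seed, f]).integers(2**31 - 1))
        pool = [p for p, fi in zip(prepared, folds) if fi != f]
        val = [p for p, fi in zip(prepared, folds) if fi == f]
        train = select_training_subset(
            [(None, ann) for _, _, ann in pool], cfg.train_minutes, seed=fold_seed
        )
        train_ids = {id(t[1]) for t in train}
        train_items = [p for p in pool if id(p[2]) in train_ids]

        stats = fit_normalization([raw for raw, _, _ in train_items])
        label_seqs = [ann.labels for _, _, ann in train_items]
        alpha = cfg.alpha if cfg.alpha is not None else _select_alpha(
            label_seqs, cfg.alpha_grid, classes, fold_seed
        )
        syntax = fit_syntax_model(label_seqs, alpha, classes=classes)

        train_norm = [
            (apply_normalization(raw, stats), derive_frame_labels(ann, cfg.arrangement, classes), ann)
            for raw, _, ann in train_items
        ]
        ens = train_ensemble(
            [(s, l) for s, l, _ in train_norm], arch,
            replace(tc, seed=fold_seed), stats, classes,
        )
        ens.provenance = {"fold": f, "seed": fold_seed, "config": cfg.config_hash()}

        hyper = {"alpha": alpha}
        if cfg.arrangement == "BD_LC_GS":
            thresholds = fit_thresholds(
                [(env, ann) for _, env, ann in train_items],
                amp_quantiles=cfg.amp_quantiles,
                gap_grid=cfg.gap_grid, dur_grid=cfg.dur_grid,
            )
            hyper["thresholds"] = thresholds
            preds = [
                _decode_intervals(ens, syntax, apply_normalization(raw, stats),
                                  env, thresholds, cfg.dense_scores)
                for raw, env, _ in val
            ]
        else:
            priors = class_priors([l for _, l, _ in train_norm], arch.n_outputs)
            bayes = cfg.bayes if cfg.bayes is not None else _select_bayes(
                ens, syntax, [(s, l, a) for s, l, a in train_norm],
                priors, cfg.dense_scores, fold_seed,
            )
            hyper["bayes"] = bayes
            preds = [
                _decode_hmm(ens, syntax, apply_normalization(raw, stats),
                            priors, bayes, cfg.dense_scores)
                for raw, _, _ in val
            ]

        truths = [ann for _, _, ann in val]
        report = error_report(truths, preds)
        log.info("fold %d %s: note ER %.3f timing ER %.3f note&timing ER %.3f",
                 f, cfg.arrangement, report.note_er, report.timing_er,
                 report.note_timing_er)
        fold_results.append(FoldResult(
            fold=f, report=report, truth=truths, predicted=preds,
            hyperparams=hyper,
            provenance={"fold": f, "seed": fold_seed, "config": cfg.config_hash()},
        ))
        all_truth.extend(truths)
        all_pred.extend(preds)

    pooled = error_report(all_truth, all_pred)
    return RunResult(config=cfg, fold_results=fold_results, pooled=pooled)


def compare_arrangements(dataset, classes: list[str],
                         cfgs: Sequence[ArrangementConfig]):
    """Run several arrangements on identical folds/seeds; returns a table.

    The result is a pandas DataFrame with one row per arrangement and one
    column per error measure (fractions, not percent).
    """
    import pandas as pd

    results = {}
    rows = []
    for cfg in cfgs:
        res = run_arrangement(dataset, classes, cfg)
        results[cfg.arrangement] = res
        rows.append({"arrangement": cfg.arrangement, **res.pooled.as_dict()})
    table = pd.DataFrame(rows).set_index("arrangement")
    table.attrs["results"] = results
    return table
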